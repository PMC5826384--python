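"""Covariate-adjusted brain-behavior association.

Partial correlation between a network metric and a behavioral score,
controlling nuisance covariates (age, sex, education by default) by OLS
residualization of both variables; the p-value uses the t-transform with
n - 2 - C degrees of freedom.  p-values are reported uncorrected by
design (exploratory association screen); downstream reports flag this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["BehaviorCorrelation", "partial_correlation", "behavior_table"]


@dataclass(frozen=True)
class BehaviorCorrelation:
    metric_name: str
    score_name: str
    r_partial: float
    p_value: float
    n_effective: int
    covariates: tuple[str, ...]


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation(
    x,
    y,
    covariates=None,
) -> tuple[float, float, int]:
    """Partial Pearson correlation of x and y given covariates.

    Rows with any missing value are dropped listwise.  Collinear covariate
    columns are absorbed by the pseudoinverse; the effective covariate
    count used in the degrees of freedom is the rank of the centered
    covariate matrix (a warning is issued when columns are collinear).

    Returns
    -------
    (r, p, n_effective)
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        z = np.empty((x.size, 0))
    else:
        z = np.asarray(covariates, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        if z.shape[0] != x.size:
            raise ValueError("covariates must have one row per subject")

    complete = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(z), axis=1)
    x, y, z = x[complete], y[complete], z[complete]
    n = x.size

    design = np.column_stack([np.ones(n), z])
    n_cov = int(np.linalg.matrix_rank(design)) - 1 if z.shape[1] else 0
    if z.shape[1] and n_cov < z.shape[1]:
        warnings.warn(
            f"covariate matrix is rank deficient ({n_cov} independent of "
            f"{z.shape[1]} columns); collinear columns are absorbed",
            stacklevel=2,
        )
    if n < n_cov + 3:
        raise ValueError(
            f"need at least C+3={n_cov + 3} complete subjects, got {n}"
        )

    rx = _residualize(x, design)
    ry = _residualize(y, design)
    # a variable fully explained by the covariates has no residual signal
    eps = 1e-12
    ss_x = ((x - x.mean())**2).sum()
    ss_y = ((y - y.mean())**2).sum()
    if (rx**2).sum() <= eps * max(ss_x, 1e-300) or \
       (ry**2).sum() <= eps * max(ss_y, 1e-300):
        return 0.0, 1.0, n
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    r = float(np.clip((rx * ry).sum() / denom, -1.0, 1.0))
    df = n - 2 - n_cov
    if df <= 0:
        raise ValueError("not enough degrees of freedom for a p-value")
    if abs(r) >= 1.0:
        return r, 0.0, n
    t = r * np.sqrt(df / (1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p, n


def behavior_table(
    metrics: pd.DataFrame,
    scores: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Partial correlation for every (metric, score) pair.

    All frames must be indexed by subject id; only subjects present in all
    of them are used, with per-pair listwise deletion of missing scores.
    No multiple-testing correction is applied (deliberate, exploratory).
    """
    common = metrics.index.intersection(scores.index)
    if covariates is not None:
        common = common.intersection(covariates.index)
    if len(common) == 0:
        raise ValueError("no overlapping subjects between metric and score tables")
    metrics = metrics.loc[common]
    scores = scores.loc[common]
    cov_names: tuple[str, ...] = ()
    z = None
    if covariates is not None:
        cov = covariates.loc[common].copy()
        for col in cov.columns:
            if cov[col].dtype == object or str(cov[col].dtype) == "category":
                codes, _ = pd.factorize(cov[col])
                cov[col] = codes.astype(float)
        cov_names = tuple(cov.columns)
        z = cov.to_numpy(dtype=float)

    rows = []
    for metric in metrics.columns:
        for score in scores.columns:
            r, p, n = partial_correlation(
                metrics[metric].to_numpy(dtype=float),
                scores[score].to_numpy(dtype=float),
                covariates=z,
            )
            rows.append(
                BehaviorCorrelation(
                    metric_name=metric, score_name=score, r_partial=r,
                    p_value=p, n_effective=n, covariates=cov_names,
                )
            )
    return pd.DataFrame(
        [
            {
                "metric": c.metric_name,
                "score": c.score_name,
                "r": c.r_partial,
                "p": c.p_value,
                "n": c.n_effective,
                "covariates": ",".join(c.covariates),
            }
            for c in rows
        ]
    )
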