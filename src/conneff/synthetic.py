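"""Synthetic two-group resting-state cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
block-structured positive covariance over ROIs (community blocks standing in
for functional systems), lag-1 autoregressive BOLD-like noise sampled at a
fixed TR, random-walk rigid-body motion traces, matched covariates, and
behavioral scores linearly coupled to a subject-level network property.

Group A plays the patient-like role and carries an optional planted effect:
an additive covariance increment on a designated edge set (by default the
six edges of a 4-ROI clique inside the first community block, a "DMN-like"
target for component-recovery tests).  Everything is a pure function of
``(spec, seed)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .preprocess import MIN_VOLUMES, MotionParams, RoiTimeSeries

__all__ = [
    "SyntheticSpec",
    "Cohort",
    "build_population_cov",
    "sample_timeseries",
    "generate_motion",
    "generate_cohort",
    "nearest_positive_definite",
]

logger = logging.getLogger(__name__)

SCORE_NAMES = ("PSQI", "ISI", "SAS", "SDS", "ESS", "duration")

# Questionnaire score distributions (mean, sd) per group, typical of an
# insomnia-patient vs good-sleeper contrast.  Group B (control-like) has no
# sleepiness score or disease duration.
_SCORE_DISTRIBUTIONS = {
    "PSQI": {"A": (11.75, 3.78), "B": (1.68, 1.90)},
    "ISI": {"A": (17.28, 6.70), "B": (1.39, 2.40)},
    "SAS": {"A": (53.97, 10.12), "B": (42.45, 6.39)},
    "SDS": {"A": (52.92, 9.25), "B": (39.55, 10.58)},
    "ESS": {"A": (11.00, 4.63), "B": None},
    "duration": {"A": (28.61, 43.58), "B": None},
}


def _default_block_sizes(n_rois: int, n_blocks: int = 6) -> tuple[int, ...]:
    """Partition n_rois into n_blocks near-equal community blocks."""
    n_blocks = min(n_blocks, n_rois)
    base, extra = divmod(n_rois, n_blocks)
    return tuple(base + (1 if i < extra else 0) for i in range(n_blocks))


def _default_effect_edges(n_rois: int) -> tuple[tuple[int, int], ...]:
    """Six-edge clique on the first four ROIs (inside the first block)."""
    k = min(4, n_rois)
    return tuple((i, j) for i in range(k) for j in range(i + 1, k))


@dataclass
class SyntheticSpec:
    """Full parameterization of the synthetic cohort.

    Defaults describe the emulated study conditions: 246 ROIs, 230 retained
    volumes at TR = 2 s, 36 patient-like vs 38 control-like subjects.
    Correlation levels and the planted effect are chosen so that Bonferroni
    thresholding of a 230-frame correlation matrix retains the within-block
    edges (whole-network density in the ~0.15-0.2 range) while
    between-block edges fall below threshold.
    """

    n_rois: int = 246
    n_volumes: int = 230
    tr_seconds: float = 2.0
    n_group_a: int = 36
    n_group_b: int = 38
    block_sizes: tuple[int, ...] | None = None
    within_block_cov: float = 0.5
    between_block_cov: float = 0.1
    effect_edges: tuple[tuple[int, int], ...] | None = None
    effect_delta: float = 0.2
    shortcut_frac: float = 0.8
    ar_coeff: float = 0.3
    noise_sd: float = 0.3
    motion_amplitude_mm: float = 0.02
    subject_effect_sd: float = 0.05
    behavior_coupling: float = 20.0
    behavior_noise_sd: float = 0.5
    coupled_score: str = "ESS"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_sizes is None:
            self.block_sizes = _default_block_sizes(self.n_rois)
        else:
            self.block_sizes = tuple(int(b) for b in self.block_sizes)
        if self.effect_edges is None:
            self.effect_edges = _default_effect_edges(self.n_rois)
        else:
            self.effect_edges = tuple(
                (min(i, j), max(i, j)) for i, j in self.effect_edges
            )
        self.validate()

    def validate(self) -> "SyntheticSpec":
        if self.n_rois < 2:
            raise ValueError("n_rois must be at least 2")
        if self.n_volumes < MIN_VOLUMES:
            raise ValueError(f"n_volumes must be >= {MIN_VOLUMES}")
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ValueError("both groups need at least one subject")
        if sum(self.block_sizes) != self.n_rois:
            raise ValueError(
                f"block_sizes {self.block_sizes} must sum to n_rois={self.n_rois}"
            )
        if not 0.0 < self.within_block_cov < 1.0:
            raise ValueError("within_block_cov must be in (0, 1)")
        if not 0.0 <= self.between_block_cov < self.within_block_cov:
            raise ValueError("require 0 <= between_block_cov < within_block_cov")
        if not 0.0 <= self.shortcut_frac < 1.0:
            raise ValueError("shortcut_frac must be in [0, 1)")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValueError("ar_coeff must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.motion_amplitude_mm < 0:
            raise ValueError("motion_amplitude_mm must be non-negative")
        for i, j in self.effect_edges:
            if i == j or not (0 <= i < self.n_rois and 0 <= j < self.n_rois):
                raise ValueError(f"effect edge ({i}, {j}) out of range")
        if self.coupled_score not in SCORE_NAMES:
            raise ValueError(f"coupled_score must be one of {SCORE_NAMES}")
        return self

    @property
    def roi_labels(self) -> list[str]:
        return [f"ROI_{i + 1:03d}" for i in range(self.n_rois)]

    @property
    def n_subjects(self) -> int:
        return self.n_group_a + self.n_group_b

    def block_assignment(self) -> np.ndarray:
        """Block index per ROI."""
        return np.repeat(np.arange(len(self.block_sizes)), self.block_sizes)


@dataclass
class Cohort:
    """Bundle of everything the generator emits for one cohort."""

    spec: SyntheticSpec
    table: pd.DataFrame
    timeseries: dict[str, RoiTimeSeries]
    motion: dict[str, MotionParams]

    @property
    def subject_ids(self) -> list[str]:
        return list(self.table["subject_id"])

    def group_ids(self, group: str) -> list[str]:
        return list(self.table.loc[self.table["group"] == group, "subject_id"])


def nearest_positive_definite(
    m: np.ndarray, eps: float = 1e-8
) -> tuple[np.ndarray, float]:
    """Project a symmetric matrix onto the PD cone by eigenvalue clipping.

    Returns the repaired matrix and the largest absolute entry change.
    """
    sym = (m + m.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    floor = eps * max(1.0, float(vals.max(initial=1.0)))
    clipped = np.clip(vals, floor, None)
    repaired = (vecs * clipped) @ vecs.T
    repaired = (repaired + repaired.T) / 2.0
    return repaired, float(np.abs(repaired - m).max())


def _is_positive_definite(m: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(m)
        return True
    except np.linalg.LinAlgError:
        return False


def build_population_cov(
    spec: SyntheticSpec, group: str, repair_tol: float = 0.1
) -> np.ndarray:
    """Population covariance matrix for one group.

    Off-diagonals are ``within_block_cov`` inside a community block and
    ``between_block_cov`` across blocks; the diagonal is ``1 + noise_sd**2``
    (unit signal variance plus white measurement noise).  For group A,
    ``effect_delta`` is added symmetrically on the designated effect edges.
    Non-PD results are repaired by eigenvalue clipping; a repair that moves
    any entry by more than ``repair_tol`` is a hard error.
    """
    if group not in ("A", "B"):
        raise ValueError("group must be 'A' or 'B'")
    blocks = spec.block_assignment()
    same_block = blocks[:, None] == blocks[None, :]
    cov = np.where(same_block, spec.within_block_cov, spec.between_block_cov)
    # inter-community shortcuts: disjoint cross-block ROI pairs carry
    # within-block-level covariance, mimicking the strong between-system
    # links that keep real connectomes connected and small-world.  Pairing
    # each ROI at most once keeps the perturbation norm below the block
    # matrix's smallest eigenvalue, so the result stays positive definite.
    # The pairing depends only on (spec.seed, spec.shortcut_frac), so both
    # groups share it.
    if spec.shortcut_frac > 0.0 and len(spec.block_sizes) > 1:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 71]))
        order = rng.permutation(spec.n_rois)
        n_pairs = int(round(spec.shortcut_frac * spec.n_rois / 2))
        placed = 0
        for a, b in zip(order[0::2], order[1::2]):
            if placed >= n_pairs:
                break
            if blocks[a] != blocks[b]:
                cov[a, b] = spec.within_block_cov
                cov[b, a] = spec.within_block_cov
                placed += 1
    if group == "A" and spec.effect_delta != 0.0:
        for i, j in spec.effect_edges:
            cov[i, j] += spec.effect_delta
            cov[j, i] += spec.effect_delta
    np.fill_diagonal(cov, 1.0 + spec.noise_sd**2)
    if not _is_positive_definite(cov):
        cov, max_change = nearest_positive_definite(cov)
        logger.warning(
            "population covariance repaired to nearest PD "
            "(max entry change %.3e)", max_change,
        )
        if max_change > repair_tol or not _is_positive_definite(cov):
            raise ValueError(
                "covariance for group "
                f"{group} is not positive definite within repair tolerance: "
                f"within_block_cov={spec.within_block_cov}, "
                f"between_block_cov={spec.between_block_cov}, "
                f"effect_delta={spec.effect_delta}, noise_sd={spec.noise_sd}"
            )
    return cov


def sample_timeseries(
    cov: np.ndarray,
    n_volumes: int,
    ar_coeff: float = 0.0,
    seed: int | np.random.Generator = 0,
    tr_seconds: float = 2.0,
    subject_id: str = "synthetic",
    roi_labels: list[str] | None = None,
    burn_in: int = 100,
) -> RoiTimeSeries:
    """Sample an AR(1) multivariate Gaussian ROI time series.

    Innovations are drawn multivariate-normal with covariance ``cov`` and
    passed through ``x_t = ar_coeff * x_{t-1} + innov_t``; a burn-in segment
    is discarded so the retained signal is stationary.  The AR pass rescales
    all series identically, so the population correlation structure of the
    output equals that of ``cov``.
    """
    cov = np.asarray(cov, dtype=float)
    if n_volumes < MIN_VOLUMES:
        raise ValueError(
            f"n_volumes={n_volumes} too short for filtering/correlation "
            f"(minimum {MIN_VOLUMES})"
        )
    if not _is_positive_definite(cov):
        raise ValueError("cov must be positive definite")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(cov)
    innov = rng.standard_normal((n_volumes + burn_in, cov.shape[0])) @ chol.T
    if ar_coeff != 0.0:
        from scipy.signal import lfilter

        data = lfilter([1.0], [1.0, -ar_coeff], innov, axis=0)
    else:
        data = innov
    return RoiTimeSeries(
        subject_id=subject_id,
        data=data[burn_in:],
        tr_seconds=tr_seconds,
        roi_labels=roi_labels,
    )


def generate_motion(
    n_volumes: int,
    amplitude: float = 0.02,
    seed: int | np.random.Generator = 0,
    head_radius_mm: float = 50.0,
    subject_id: str = "synthetic",
) -> MotionParams:
    """Random-walk rigid-body motion trace, zero at the first frame.

    Translation steps have standard deviation ``amplitude`` (mm); rotation
    steps use ``amplitude / head_radius_mm`` (radians) so translations and
    rotations contribute comparably to framewise displacement.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_volumes - 1, 6))
    steps[:, :3] *= amplitude
    steps[:, 3:] *= amplitude / head_radius_mm
    data = np.zeros((n_volumes, 6))
    data[1:] = np.cumsum(steps, axis=0)
    return MotionParams(subject_id=subject_id, data=data)


def _effect_edge_mean(cov: np.ndarray, edges: Iterable[tuple[int, int]]) -> float:
    vals = [cov[i, j] for i, j in edges]
    return float(np.mean(vals)) if vals else 0.0


def generate_cohort(spec: SyntheticSpec) -> Cohort:
    """Generate the full cohort bundle.

    Per subject: a covariance equal to the group covariance plus a scalar
    jitter (sd ``subject_effect_sd``) on the effect edges, an AR(1) time
    series sampled from it, and a random-walk motion trace.  Covariates are
    drawn from the same distributions in both groups (matched by design).
    The coupled behavioral score is ``behavior_coupling`` times the
    subject's generating covariance mean over the effect edges, plus
    Gaussian noise; the remaining scores are drawn from group-typical
    questionnaire distributions (missing for group B where real controls
    have none).
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_cov, rng_demo, rng_scores, rng_subjects = [
        np.random.default_rng(child) for child in ss.spawn(4)
    ]

    group_cov = {g: build_population_cov(spec, g) for g in ("A", "B")}

    rows = []
    timeseries: dict[str, RoiTimeSeries] = {}
    motion: dict[str, MotionParams] = {}
    labels = spec.roi_labels

    groups = ["A"] * spec.n_group_a + ["B"] * spec.n_group_b
    subject_seeds = ss.spawn(len(groups))
    counters = {"A": 0, "B": 0}
    for group, sseed in zip(groups, subject_seeds):
        counters[group] += 1
        sid = f"sub-{group}{counters[group]:02d}"
        jitter = float(rng_cov.normal(0.0, spec.subject_effect_sd))
        cov = group_cov[group].copy()
        if jitter != 0.0 and spec.effect_edges:
            for i, j in spec.effect_edges:
                cov[i, j] += jitter
                cov[j, i] += jitter
            if not _is_positive_definite(cov):
                cov, change = nearest_positive_definite(cov)
                logger.warning(
                    "subject %s covariance repaired (max change %.3e)", sid, change
                )
        ts_rng, mot_rng = [np.random.default_rng(c) for c in sseed.spawn(2)]
        timeseries[sid] = sample_timeseries(
            cov,
            spec.n_volumes,
            ar_coeff=spec.ar_coeff,
            seed=ts_rng,
            tr_seconds=spec.tr_seconds,
            subject_id=sid,
            roi_labels=labels,
        )
        motion[sid] = generate_motion(
            spec.n_volumes,
            amplitude=spec.motion_amplitude_mm,
            seed=mot_rng,
            subject_id=sid,
        )

        latent = _effect_edge_mean(cov, spec.effect_edges)
        row = {
            "subject_id": sid,
            "group": group,
            "age": float(np.clip(rng_demo.normal(38.0, 9.5), 18, 70)),
            "sex": "M" if rng_demo.random() < 1.0 / 3.0 else "F",
            "education": float(np.clip(rng_demo.normal(11.0, 3.5), 0, 22)),
            "latent_effect_cov": latent,
        }
        for name in SCORE_NAMES:
            dist = _SCORE_DISTRIBUTIONS[name][group]
            if name == spec.coupled_score:
                if group == "A" or dist is not None:
                    row[name] = (
                        spec.behavior_coupling * latent
                        + float(rng_scores.normal(0.0, spec.behavior_noise_sd))
                    )
                else:
                    row[name] = np.nan
            elif dist is None:
                row[name] = np.nan
            else:
                mean, sd = dist
                row[name] = float(max(0.0, rng_scores.normal(mean, sd)))
        rows.append(row)

    table = pd.DataFrame(rows)
    if table["subject_id"].duplicated().any():
        raise RuntimeError("subject ids are not unique")
    return Cohort(spec=spec, table=table, timeseries=timeseries, motion=motion)
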