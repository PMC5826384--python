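"""Subject-level functional network construction.

A whole-brain functional network is built in two steps: (1) pairwise Pearson
correlation of the cleaned ROI time series, with two-tailed p-values from
the exact t-transform ``t = r * sqrt((n-2)/(1-r^2))`` on n-2 degrees of
freedom; (2) significance thresholding, retaining an edge only if its
p-value survives Bonferroni correction over the N(N-1)/2 unique ROI pairs
AND its correlation is positive (negative correlations are excluded).  The
retained weight is the raw correlation, unrescaled, so edge weights lie in
(0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import RoiTimeSeries

__all__ = [
    "ConnectivityMatrix",
    "WeightedGraph",
    "ComponentCensus",
    "correlation_matrix",
    "threshold_bonferroni",
    "network_density",
    "component_census",
    "ConnectivityGraphs",
]


@dataclass
class ConnectivityMatrix:
    """N x N Pearson correlations with per-edge two-tailed p-values.

    The diagonal is set to r = 0, p = 1 by convention and is excluded from
    every downstream statistic.
    """

    subject_id: str
    r: np.ndarray
    p: np.ndarray
    n_samples: int
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        n = self.r.shape[0]
        if self.r.shape != (n, n) or self.p.shape != (n, n):
            raise ValueError("r and p must be square matrices of equal shape")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("r must be symmetric")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")
        if self.p.min() < -1e-12 or self.p.max() > 1 + 1e-12:
            raise ValueError("p-values must lie in [0, 1]")
        if not self.roi_labels:
            self.roi_labels = [f"ROI_{i + 1:03d}" for i in range(n)]

    @property
    def n_rois(self) -> int:
        return self.r.shape[0]


@dataclass
class WeightedGraph:
    """Thresholded positive-weight undirected network.

    ``w[i, j]`` is the retained correlation in (0, 1] or 0 for absent
    edges; the diagonal is zero.  ``K`` counts unique (upper-triangle)
    edges.
    """

    w: np.ndarray
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        n = self.w.shape[0]
        if self.w.ndim != 2 or self.w.shape != (n, n):
            raise ValueError("weight matrix must be square")
        if not np.allclose(self.w, self.w.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(self.w) != 0):
            raise ValueError("weight matrix must have a zero diagonal")
        nz = self.w[self.w != 0]
        if nz.size and nz.min() <= 0:
            raise ValueError("all retained weights must be strictly positive")
        if not self.roi_labels:
            self.roi_labels = [f"ROI_{i + 1:03d}" for i in range(n)]

    @property
    def n_nodes(self) -> int:
        return self.w.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.w, k=1)))

    @property
    def density(self) -> float:
        return network_density(self)

    def degrees(self) -> np.ndarray:
        """Binary degree per node."""
        return (self.w > 0).sum(axis=1)


@dataclass(frozen=True)
class ComponentCensus:
    n_components: int
    largest_size: int
    isolated_nodes: list[int]


def correlation_matrix(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of the ROI columns with p-values.

    Constant columns yield r = 0, p = 1 with a warning.  p-values come from
    the two-tailed t-transform with n - 2 degrees of freedom.
    """
    data = ts.data
    n = data.shape[0]
    if n < 5:
        raise ValueError("need at least 5 time points for correlation")
    sd = data.std(axis=0)
    constant = sd <= 1e-12 * (np.abs(data.mean(axis=0)) + 1.0)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant column(s); their correlations "
            "are set to r=0, p=1",
            stacklevel=2,
        )
        data = data.copy()
        # give constant columns unit noise-free variance to keep corrcoef finite
        data[:, constant] = np.arange(n)[:, None]
    r = np.corrcoef(data, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    if constant.any():
        r[constant, :] = 0.0
        r[:, constant] = 0.0
    np.fill_diagonal(r, 0.0)

    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    t[np.abs(r) >= 1.0] = np.inf
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.abs(r) >= 1.0] = 0.0
    np.fill_diagonal(p, 1.0)
    if constant.any():
        p[constant, :] = 1.0
        p[:, constant] = 1.0
        np.fill_diagonal(p, 1.0)
    return ConnectivityMatrix(
        subject_id=ts.subject_id, r=r, p=p, n_samples=n, roi_labels=ts.roi_labels
    )


def threshold_bonferroni(cm: ConnectivityMatrix, alpha: float = 0.05) -> WeightedGraph:
    """Significance thresholding with Bonferroni correction over pairs.

    Edge (i, j) is retained iff ``p_ij < alpha / m`` with
    ``m = N(N-1)/2`` unique pairs (strict inequality) and ``r_ij > 0``.
    The retained weight is the raw correlation.
    """
    n = cm.n_rois
    m = n * (n - 1) // 2
    per_edge = alpha / m
    keep = (cm.p < per_edge) & (cm.r > 0)
    w = np.where(keep, cm.r, 0.0)
    np.fill_diagonal(w, 0.0)
    return WeightedGraph(w=w, roi_labels=cm.roi_labels)


def network_density(g: WeightedGraph | np.ndarray) -> float:
    """Fraction of possible edges present: 2K / (N(N-1))."""
    w = g.w if isinstance(g, WeightedGraph) else np.asarray(g)
    n = w.shape[0]
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    k = int(np.count_nonzero(np.triu(w, k=1)))
    return 2.0 * k / (n * (n - 1))


def component_census(g: WeightedGraph) -> ComponentCensus:
    """Connected components of the binarized topology.

    Isolated nodes (degree 0) each form their own component.
    """
    adj = csr_matrix((g.w > 0).astype(np.int8))
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    isolated = np.flatnonzero(g.degrees() == 0)
    return ComponentCensus(
        n_components=int(n_comp),
        largest_size=int(sizes.max(initial=0)),
        isolated_nodes=[int(i) for i in isolated],
    )


class ConnectivityGraphs(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: cleaned time series -> thresholded graphs.

    ``transform`` maps a list of :class:`RoiTimeSeries` to a list of
    :class:`WeightedGraph` via Pearson correlation and Bonferroni
    significance thresholding.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y=None):  # noqa: D102 - stateless, sklearn API
        self.n_features_in_ = None
        return self

    def transform(self, X):  # noqa: D102 - sklearn API
        single = isinstance(X, RoiTimeSeries)
        items = [X] if single else list(X)
        graphs = [
            threshold_bonferroni(correlation_matrix(ts), alpha=self.alpha)
            for ts in items
        ]
        return graphs[0] if single else graphs
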