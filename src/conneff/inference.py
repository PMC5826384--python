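"""Group inference: permutation tests, FDR-corrected nodal comparison,
network-based statistic (NBS), and demographic tests.

The permutation engine relabels pooled subjects preserving group sizes and
uses the add-one (never-zero) exceedance estimator
``p = (1 + #{null >= observed}) / (1 + n_perm)``; the classical
95th-percentile decision rule on the empirical null is reported alongside.

NBS controls family-wise error over connected components of suprathreshold
edges: edges positive in more than a given fraction of all subjects are
tested edge-by-edge with a pooled-variance t-test at a primary threshold,
connected components of surviving edges are measured in links, and each
component's corrected p-value comes from the permutation null distribution
of the maximal component size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationResult",
    "NbsComponent",
    "NbsResult",
    "TTestResult",
    "permutation_test_metric",
    "nodal_comparison",
    "NodalComparison",
    "fdr_bh",
    "nbs",
    "two_sample_t",
    "chi_square_2x2",
]


@dataclass
class PermutationResult:
    """Outcome of a two-group permutation test on a scalar metric."""

    metric_name: str
    observed_diff: float
    null_dist: np.ndarray
    p_value: float
    n_perm: int
    direction: str
    seed: int | None
    significant_percentile: bool

    def recount_p(self) -> float:
        """Recompute the add-one p from the stored null distribution."""
        if self.direction == "greater":
            exceed = int(np.sum(self.null_dist >= self.observed_diff))
        else:
            exceed = int(np.sum(self.null_dist <= self.observed_diff))
        return (1 + exceed) / (1 + self.n_perm)


@dataclass(frozen=True)
class NbsComponent:
    edges: list[tuple[int, int]]
    size: int
    corrected_p: float


@dataclass
class NbsResult:
    """NBS output for one directional contrast."""

    components: list[NbsComponent]
    primary_alpha: float
    n_perm: int
    null_max_sizes: np.ndarray
    included_edges: np.ndarray
    direction: str
    seed: int | None

    @property
    def significant_components(self) -> list[NbsComponent]:
        return [c for c in self.components if c.corrected_p <= 0.05]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def _check_direction(direction: str) -> str:
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    return direction


def _group_permutations(
    rng: np.random.Generator, n_total: int, n_perm: int
) -> np.ndarray:
    """n_perm random permutations of subject indices (rows)."""
    idx = np.empty((n_perm, n_total), dtype=np.intp)
    for row in range(n_perm):
        idx[row] = rng.permutation(n_total)
    return idx


def permutation_test_metric(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 10_000,
    direction: str = "greater",
    seed: int | None = 0,
    metric_name: str = "metric",
    method: str = "sampled",
) -> PermutationResult:
    """Permutation test on the difference of group means.

    ``observed_diff = mean(a) - mean(b)``; the null is built by randomly
    reallocating the pooled values into two groups of the original sizes.
    For ``direction='greater'`` the test asks whether group A exceeds
    group B (mirrored for ``'less'``); significance at 0.05 by the
    percentile rule means the observed difference exceeds the null's 95th
    percentile (5th percentile for ``'less'``).

    ``method='sampled'`` draws ``n_perm`` random relabelings and reports
    the add-one (never-zero) exceedance p.  ``method='exhaustive'``
    enumerates every distinct relabeling (small cohorts only) and reports
    the exact proportion, the identity relabeling included.
    """
    _check_direction(direction)
    if method not in ("sampled", "exhaustive"):
        raise ValueError("method must be 'sampled' or 'exhaustive'")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 subjects")
    pooled = np.concatenate([a, b])
    observed = float(a.mean() - b.mean())
    if np.ptp(pooled) == 0.0:
        return PermutationResult(
            metric_name, observed, np.zeros(n_perm), 1.0, n_perm, direction,
            seed if isinstance(seed, int) else None, False,
        )
    if method == "exhaustive":
        from itertools import combinations
        from math import comb

        n_total, na = pooled.size, a.size
        if comb(n_total, na) > 200_000:
            raise ValueError("cohort too large for exhaustive enumeration")
        total = pooled.sum()
        null = np.array([
            pooled[list(idx)].mean()
            - (total - pooled[list(idx)].sum()) / (n_total - na)
            for idx in combinations(range(n_total), na)
        ])
        n_eff = null.size
        if direction == "greater":
            p = np.sum(null >= observed - 1e-12) / n_eff
            sig = observed > np.percentile(null, 95.0)
        else:
            p = np.sum(null <= observed + 1e-12) / n_eff
            sig = observed < np.percentile(null, 5.0)
        return PermutationResult(
            metric_name, observed, null, float(p), n_eff, direction,
            None, bool(sig),
        )
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse null", stacklevel=2)
    rng = np.random.default_rng(seed)
    perms = _group_permutations(rng, pooled.size, n_perm)
    permuted = pooled[perms]
    null = permuted[:, : a.size].mean(axis=1) - permuted[:, a.size:].mean(axis=1)
    if direction == "greater":
        exceed = int(np.sum(null >= observed))
        sig = observed > np.percentile(null, 95.0)
    else:
        exceed = int(np.sum(null <= observed))
        sig = observed < np.percentile(null, 5.0)
    p = (1 + exceed) / (1 + n_perm)
    return PermutationResult(
        metric_name, observed, null, float(p), n_perm, direction,
        seed if isinstance(seed, int) else None, bool(sig),
    )


@dataclass
class NodalComparison:
    """Per-node permutation p-values with BH-FDR significance mask."""

    observed_diff: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    q: float
    n_perm: int
    direction: str
    seed: int | None


def nodal_comparison(
    nodal_a: np.ndarray,
    nodal_b: np.ndarray,
    n_perm: int = 10_000,
    q: float = 0.05,
    direction: str = "greater",
    seed: int | None = 0,
) -> NodalComparison:
    """Node-wise permutation tests with Benjamini-Hochberg correction.

    One permutation-index matrix is shared across all nodes, which is fast
    and preserves the cross-node dependence structure in the null.
    """
    _check_direction(direction)
    a = np.atleast_2d(np.asarray(nodal_a, dtype=float))
    b = np.atleast_2d(np.asarray(nodal_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("both groups must have the same number of nodes")
    na = a.shape[0]
    pooled = np.vstack([a, b])
    observed = a.mean(axis=0) - b.mean(axis=0)
    rng = np.random.default_rng(seed)
    perms = _group_permutations(rng, pooled.shape[0], n_perm)
    null = (
        pooled[perms[:, :na]].mean(axis=1) - pooled[perms[:, na:]].mean(axis=1)
    )  # (n_perm, N)
    if direction == "greater":
        exceed = (null >= observed[None, :]).sum(axis=0)
    else:
        exceed = (null <= observed[None, :]).sum(axis=0)
    p = (1 + exceed) / (1 + n_perm)
    mask = fdr_bh(p, q=q)
    return NodalComparison(
        observed_diff=observed, p_values=p, significant=mask, q=q,
        n_perm=n_perm, direction=direction,
        seed=seed if isinstance(seed, int) else None,
    )


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def _pooled_t_from_moments(sum_a, sumsq_a, na, sum_b, sumsq_b, nb):
    """Vectorized pooled-variance t statistic from group sums of x and x^2."""
    mean_a = sum_a / na
    mean_b = sum_b / nb
    ss_a = sumsq_a - na * mean_a**2
    ss_b = sumsq_b - nb * mean_b**2
    df = na + nb - 2
    pooled_var = (ss_a + ss_b) / df
    se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / se
    return t, df


def _max_component_links(edge_list: np.ndarray, mask: np.ndarray, n_nodes: int) -> int:
    """Largest connected-component size in links among masked edges."""
    sel = np.flatnonzero(mask)
    if sel.size == 0:
        return 0
    parent = {}

    def find(x):
        root = x
        while parent.get(root, root) != root:
            root = parent[root]
        while parent.get(x, x) != x:
            parent[x], x = root, parent[x]
        return root

    for e in sel:
        i, j = int(edge_list[e, 0]), int(edge_list[e, 1])
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    counts: dict[int, int] = {}
    for e in sel:
        root = find(int(edge_list[e, 0]))
        counts[root] = counts.get(root, 0) + 1
    return max(counts.values())


def nbs(
    conn_a: np.ndarray,
    conn_b: np.ndarray,
    primary_alpha: float = 0.05,
    n_perm: int = 10_000,
    positive_frac: float = 0.85,
    direction: str = "greater",
    seed: int | None = 0,
    null_counting: str = "ge",
    chunk_size: int = 500,
) -> NbsResult:
    """Network-based statistic on stacks of raw correlation matrices.

    Parameters
    ----------
    conn_a, conn_b : ndarray, shape (subjects, N, N)
        Raw (pre-threshold) correlation matrices per group.
    primary_alpha : float
        One-sided edge-level threshold applied to the pooled-variance t.
    positive_frac : float
        An edge enters the analysis only if its raw correlation is positive
        in strictly more than this fraction of ALL subjects (both groups).
    direction : {'greater', 'less'}
        'greater' tests A > B edge increases; 'less' tests decreases.
    null_counting : {'ge', 'gt'}
        Whether a null maximal component of size equal to an observed
        component counts against it ('ge', the conservative standard) or
        not ('gt', the strict larger-than reading).
    """
    _check_direction(direction)
    if null_counting not in ("ge", "gt"):
        raise ValueError("null_counting must be 'ge' or 'gt'")
    a = np.asarray(conn_a, dtype=float)
    b = np.asarray(conn_b, dtype=float)
    if a.ndim != 3 or b.ndim != 3 or a.shape[1:] != b.shape[1:]:
        raise ValueError("conn stacks must be (subjects, N, N) with equal N")
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 subjects")
    n_nodes = a.shape[1]
    iu = np.triu_indices(n_nodes, k=1)
    stack = np.concatenate([a, b], axis=0)[:, iu[0], iu[1]]  # (S, E_all)
    n_total = na + nb

    pos_frac = (stack > 0).mean(axis=0)
    included = pos_frac > positive_frac
    included_mask = np.zeros((n_nodes, n_nodes), dtype=bool)
    included_mask[iu[0][included], iu[1][included]] = True
    included_mask |= included_mask.T
    if not included.any():
        warnings.warn("no edges pass the positivity rule; empty NBS result",
                      stacklevel=2)
        return NbsResult([], primary_alpha, n_perm, np.zeros(n_perm, dtype=int),
                         included_mask, direction,
                         seed if isinstance(seed, int) else None)

    x = stack[:, included]  # (S, E)
    edge_list = np.column_stack([iu[0][included], iu[1][included]])
    df = n_total - 2
    t_crit = stats.t.isf(primary_alpha, df)

    def t_for_labels(group_a_rows: np.ndarray) -> np.ndarray:
        xa = x[group_a_rows]
        xb = np.delete(x, group_a_rows, axis=0)
        t, _ = _pooled_t_from_moments(
            xa.sum(axis=0), (xa**2).sum(axis=0), na,
            xb.sum(axis=0), (xb**2).sum(axis=0), nb,
        )
        return t

    t_obs = t_for_labels(np.arange(na))
    if direction == "less":
        t_obs = -t_obs
    supra = np.nan_to_num(t_obs, nan=-np.inf) > t_crit

    # observed components over suprathreshold edges
    comps: list[list[tuple[int, int]]] = []
    if supra.any():
        sel = np.flatnonzero(supra)
        adj = csr_matrix(
            (np.ones(sel.size), (edge_list[sel, 0], edge_list[sel, 1])),
            shape=(n_nodes, n_nodes),
        )
        _, labels = _cc(adj, directed=False)
        by_label: dict[int, list[tuple[int, int]]] = {}
        for e in sel:
            lab = labels[edge_list[e, 0]]
            by_label.setdefault(int(lab), []).append(
                (int(edge_list[e, 0]), int(edge_list[e, 1]))
            )
        comps = sorted(by_label.values(), key=len, reverse=True)

    # permutation null of the maximal component size (in links)
    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm, dtype=int)
    sums = x.sum(axis=0)
    sumsqs = (x**2).sum(axis=0)
    done = 0
    while done < n_perm:
        m = min(chunk_size, n_perm - done)
        sel_matrix = np.zeros((m, n_total), dtype=float)
        for row in range(m):
            sel_matrix[row, rng.choice(n_total, size=na, replace=False)] = 1.0
        sa = sel_matrix @ x
        sqa = sel_matrix @ (x**2)
        t_null, _ = _pooled_t_from_moments(
            sa, sqa, na, sums[None, :] - sa, sumsqs[None, :] - sqa, nb
        )
        if direction == "less":
            t_null = -t_null
        supra_null = np.nan_to_num(t_null, nan=-np.inf) > t_crit
        for row in range(m):
            null_max[done + row] = _max_component_links(
                edge_list, supra_null[row], n_nodes
            )
        done += m

    components = []
    for edges in comps:
        size = len(edges)
        if null_counting == "ge":
            exceed = int(np.sum(null_max >= size))
        else:
            exceed = int(np.sum(null_max > size))
        corrected = (1 + exceed) / (1 + n_perm)
        components.append(NbsComponent(edges=edges, size=size,
                                       corrected_p=float(corrected)))
    return NbsResult(
        components=components, primary_alpha=primary_alpha, n_perm=n_perm,
        null_max_sizes=null_max, included_edges=included_mask,
        direction=direction, seed=seed if isinstance(seed, int) else None,
    )


def two_sample_t(*args) -> TTestResult:
    """Pooled-variance two-sample Student t-test (two-tailed).

    Call either with two raw sample arrays ``two_sample_t(a, b)`` or with
    printed summaries ``two_sample_t(mean_a, sd_a, n_a, mean_b, sd_b, n_b)``.
    """
    if len(args) == 2:
        a = np.asarray(args[0], dtype=float)
        b = np.asarray(args[1], dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("each sample needs at least 2 observations")
        stats_args = (a.mean(), a.std(ddof=1), a.size,
                      b.mean(), b.std(ddof=1), b.size)
    elif len(args) == 6:
        stats_args = args
    else:
        raise TypeError("expected (a, b) samples or 6 summary statistics")
    mean_a, sd_a, n_a, mean_b, sd_b, n_b = stats_args
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    df = int(n_a + n_b - 2)
    pooled_var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    se = np.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
    if se == 0.0:
        t = 0.0 if mean_a == mean_b else np.inf * np.sign(mean_a - mean_b)
        return TTestResult(t=float(t), df=df, p=1.0 if t == 0.0 else 0.0)
    t = (mean_a - mean_b) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p))


def chi_square_2x2(table) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 count table, no continuity correction."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(tab < 0):
        raise ValueError("counts must be non-negative")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("all row and column margins must be positive")
    chi2, p, dof, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), int(dof), float(p)
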