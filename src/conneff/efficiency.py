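"""Weighted small-world efficiency metrics and rewiring null models.

For a weighted network G with N nodes, the length of an edge is the
reciprocal of its weight (a strong correlation is a short functional
distance) and d_ij is the shortest-path length over those edge lengths.
The metrics are:

    E_glob(G) = 1/(N(N-1)) * sum_{i != j} 1/d_ij            (global)
    e_i       = 1/(N-1)    * sum_{j != i} 1/d_ij            (nodal)
    E_loc(G)  = 1/N * sum_i E_glob(G_i)                      (local)

where G_i is the subgraph induced on the neighbors of node i (node i
excluded, original weights kept between neighbors).  Unreachable pairs
contribute 0 through the 1/inf = 0 convention, so networks with isolated
nodes are handled without dropping anything, and mean(e_i) == E_glob is an
exact identity.

Small-worldness is assessed by normalizing E_glob and E_loc against the
mean over random networks that preserve the number of nodes, edges, and
the exact degree sequence (double-edge-swap rewiring, with the weight
multiset randomly reassigned to the rewired edges): normalized global
efficiency ~ 1 together with normalized local efficiency > 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .connectivity import WeightedGraph, network_density

__all__ = [
    "GlobalMetrics",
    "shortest_path_lengths",
    "global_efficiency",
    "nodal_efficiency",
    "local_efficiency",
    "rewire_preserving_degree",
    "normalized_efficiencies",
    "global_metrics",
    "is_small_world",
]


@dataclass(frozen=True)
class GlobalMetrics:
    """Per-subject small-world efficiency summary."""

    e_glob: float
    e_loc: float
    norm_e_glob: float
    norm_e_loc: float
    n_random: int
    density: float


def _as_weight_matrix(g: WeightedGraph | np.ndarray) -> np.ndarray:
    if isinstance(g, WeightedGraph):
        return g.w
    w = np.asarray(g, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    return w


def shortest_path_lengths(g: WeightedGraph | np.ndarray) -> np.ndarray:
    """All-pairs shortest functional distances on lengths 1/w.

    Returns an N x N matrix with zeros on the diagonal and +inf for
    unreachable pairs.
    """
    w = _as_weight_matrix(g)
    if np.any(w < 0):
        raise ValueError("weights must be positive")
    rows, cols = np.nonzero(np.triu(w, k=1))
    lengths = 1.0 / w[rows, cols]
    n = w.shape[0]
    graph = csr_matrix((lengths, (rows, cols)), shape=(n, n))
    return dijkstra(graph, directed=False)


def _inverse_distances(d: np.ndarray) -> np.ndarray:
    inv = np.zeros_like(d)
    finite = np.isfinite(d) & (d > 0)
    inv[finite] = 1.0 / d[finite]
    return inv


def nodal_efficiency(g: WeightedGraph | np.ndarray) -> np.ndarray:
    """Per-node mean inverse distance to all other nodes (1/inf := 0)."""
    w = _as_weight_matrix(g)
    n = w.shape[0]
    if n < 2:
        raise ValueError("nodal efficiency needs at least 2 nodes")
    inv = _inverse_distances(shortest_path_lengths(w))
    return inv.sum(axis=1) / (n - 1)


def global_efficiency(g: WeightedGraph | np.ndarray) -> float:
    """Mean inverse shortest-path distance over ordered node pairs."""
    return float(np.mean(nodal_efficiency(g)))


def local_efficiency(g: WeightedGraph | np.ndarray) -> float:
    """Mean over nodes of the global efficiency of each neighbor subgraph.

    The subgraph for node i is induced on the neighbors of i (i excluded)
    with the original weights between them; subgraphs with fewer than two
    nodes contribute 0.
    """
    w = _as_weight_matrix(g)
    n = w.shape[0]
    if n < 1:
        raise ValueError("local efficiency needs at least 1 node")
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        if nbrs.size < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        total += global_efficiency(sub)
    return total / n


def rewire_preserving_degree(
    g: WeightedGraph | np.ndarray,
    seed: int | np.random.Generator = 0,
    swap_factor: int = 20,
) -> WeightedGraph | np.ndarray:
    """Degree-preserving randomization by double-edge swaps.

    ``swap_factor * K`` swaps are attempted; a swap is accepted only if it
    creates no self-loop or duplicate edge.  The binary topology is
    randomized while every node keeps its exact degree; the original weight
    multiset is then reassigned to the new edges in a seeded random
    permutation, so (N, K, degree sequence, weight multiset) are all
    preserved.  Graphs admitting no swap (e.g. complete graphs) are
    returned unchanged with a warning.
    """
    w = _as_weight_matrix(g)
    n = w.shape[0]
    rows, cols = np.nonzero(np.triu(w, k=1))
    k = rows.size
    if k < 2:
        raise ValueError("rewiring needs at least 2 edges")
    if k == n * (n - 1) // 2:
        warnings.warn("complete graph admits no double-edge swap; returned unchanged",
                      stacklevel=2)
        out = w.copy()
        return WeightedGraph(out, roi_labels=list(g.roi_labels)) if isinstance(
            g, WeightedGraph) else out

    rng = np.random.default_rng(seed)
    edges = [(int(i), int(j)) for i, j in zip(rows, cols)]
    edge_set = set(edges)
    n_attempts = swap_factor * k
    pair_idx = rng.integers(0, k, size=(n_attempts, 2))
    flips = rng.random(n_attempts) < 0.5
    for (e1, e2), flip in zip(pair_idx, flips):
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        new1 = (a, d) if a < d else (d, a)
        new2 = (c, b) if c < b else (b, c)
        if new1 == new2 or new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(edges[e1])
        edge_set.discard(edges[e2])
        edge_set.add(new1)
        edge_set.add(new2)
        edges[e1] = new1
        edges[e2] = new2

    weights = w[rows, cols]
    shuffled = weights[rng.permutation(k)]
    out = np.zeros_like(w)
    for (i, j), wt in zip(edges, shuffled):
        out[i, j] = wt
        out[j, i] = wt
    if isinstance(g, WeightedGraph):
        return WeightedGraph(out, roi_labels=list(g.roi_labels))
    return out


def normalized_efficiencies(
    g: WeightedGraph | np.ndarray,
    n_random: int = 100,
    seed: int | np.random.Generator = 0,
    swap_factor: int = 20,
) -> tuple[float, float]:
    """Efficiencies normalized by the mean over degree-matched rewires.

    Returns ``(norm_e_glob, norm_e_loc)`` where each is the graph's
    efficiency divided by the mean efficiency of ``n_random`` independently
    seeded degree-preserving rewirings.  A zero random-network mean yields
    NaN with a warning.
    """
    if n_random < 1:
        raise ValueError("n_random must be at least 1")
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    elif isinstance(seed, np.random.Generator):
        ss = np.random.SeedSequence(int(seed.integers(0, 2**31)))
    else:
        ss = np.random.SeedSequence(seed)
    e_glob = global_efficiency(g)
    e_loc = local_efficiency(g)
    rand_glob = np.empty(n_random)
    rand_loc = np.empty(n_random)
    for idx, child in enumerate(ss.spawn(n_random)):
        rnd = rewire_preserving_degree(g, seed=np.random.default_rng(child),
                                       swap_factor=swap_factor)
        rand_glob[idx] = global_efficiency(rnd)
        rand_loc[idx] = local_efficiency(rnd)

    def _ratio(value: float, rand_mean: float, name: str) -> float:
        if rand_mean == 0.0:
            warnings.warn(f"random-network mean {name} is zero; normalized "
                          "value undefined", stacklevel=3)
            return float("nan")
        return value / rand_mean

    return (
        _ratio(e_glob, float(rand_glob.mean()), "global efficiency"),
        _ratio(e_loc, float(rand_loc.mean()), "local efficiency"),
    )


def global_metrics(
    g: WeightedGraph | np.ndarray,
    n_random: int = 100,
    seed: int | np.random.Generator = 0,
    swap_factor: int = 20,
) -> GlobalMetrics:
    """Convenience bundle: raw and normalized efficiencies plus density."""
    norm_glob, norm_loc = normalized_efficiencies(
        g, n_random=n_random, seed=seed, swap_factor=swap_factor
    )
    return GlobalMetrics(
        e_glob=global_efficiency(g),
        e_loc=local_efficiency(g),
        norm_e_glob=norm_glob,
        norm_e_loc=norm_loc,
        n_random=n_random,
        density=network_density(_as_weight_matrix(g)),
    )


def is_small_world(m: GlobalMetrics, glob_tol: float = 0.1) -> bool:
    """Small-world criterion: norm E_glob within glob_tol of 1, norm E_loc > 1."""
    if not (np.isfinite(m.norm_e_glob) and np.isfinite(m.norm_e_loc)):
        raise ValueError("normalized efficiencies must be finite")
    return bool(abs(m.norm_e_glob - 1.0) <= glob_tol and m.norm_e_loc > 1.0)
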