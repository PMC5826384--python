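"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written the slow, obvious way and shares no
code path with the package.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def floyd_warshall(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths on lengths 1/w, O(N^3) triple loop."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def union_find_components(n_nodes: int, edges) -> list[set[int]]:
    """Connected components (as node sets) via a plain union-find."""
    parent = list(range(n_nodes))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups: dict[int, set[int]] = {}
    for node in range(n_nodes):
        groups.setdefault(find(node), set()).add(node)
    return list(groups.values())


def ols_residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residuals from the normal equations (X'X)^-1 X'y, explicit solve."""
    beta = np.linalg.solve(x.T @ x, x.T @ y)
    return y - x @ beta


def exhaustive_perm_p(a, b, direction: str = "greater") -> float:
    """Exact permutation p over all C(n, na) relabelings (identity included)."""
    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    na, n = len(a), len(pooled)
    observed = np.mean(a) - np.mean(b)
    diffs = []
    for idx in combinations(range(n), na):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        diffs.append(pooled[mask].mean() - pooled[~mask].mean())
    diffs = np.array(diffs)
    if direction == "greater":
        return float(np.mean(diffs >= observed - 1e-12))
    return float(np.mean(diffs <= observed + 1e-12))


def bh_stepup(p_values, q: float) -> np.ndarray:
    """Brute-force BH: largest k with p_(k) <= k/m * q, all smaller accepted."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k / m * q:
            k_star = k
    mask = np.zeros(m, dtype=bool)
    mask[order[:k_star]] = True
    return mask


def partial_r_one_covariate(x, y, z) -> float:
    """Closed-form single-covariate partial correlation."""
    def r(u, v):
        u = u - np.mean(u)
        v = v - np.mean(v)
        return float(u @ v / np.sqrt((u @ u) * (v @ v)))

    rxy, rxz, ryz = r(x, y), r(x, z), r(y, z)
    return (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
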