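"""Shared fixtures and synthetic graph/cohort builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from conneff.connectivity import correlation_matrix
from conneff.synthetic import SyntheticSpec, build_population_cov, sample_timeseries


def er_graph(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Erdos-Renyi G(n, M) weight matrix with unit weights."""
    iu = np.triu_indices(n, 1)
    pick = rng.choice(iu[0].size, size=k, replace=False)
    w = np.zeros((n, n))
    w[iu[0][pick], iu[1][pick]] = 1.0
    return w + w.T


def random_weighted_graph(n: int, density: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Random graph with weights uniform in (0.2, 1.0]."""
    iu = np.triu_indices(n, 1)
    k = max(1, int(round(density * iu[0].size)))
    pick = rng.choice(iu[0].size, size=k, replace=False)
    w = np.zeros((n, n))
    w[iu[0][pick], iu[1][pick]] = rng.uniform(0.2, 1.0, size=k)
    return w + w.T


def ring_lattice(n: int, k: int = 4) -> np.ndarray:
    """Ring lattice: each node linked to its k nearest ring neighbors."""
    w = np.zeros((n, n))
    for i in range(n):
        for d in range(1, k // 2 + 1):
            j = (i + d) % n
            w[i, j] = w[j, i] = 1.0
    return w


def lattice_with_shortcuts(n: int, k: int, p_rewire: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Watts-Strogatz-style graph: ring lattice with rewired shortcut edges."""
    w = ring_lattice(n, k)
    iu = np.transpose(np.nonzero(np.triu(w, 1)))
    for i, j in iu:
        if rng.random() < p_rewire:
            w[i, j] = w[j, i] = 0.0
            while True:
                a, b = rng.integers(0, n, 2)
                if a != b and w[a, b] == 0:
                    w[a, b] = w[b, a] = 1.0
                    break
    return w


def path_graph(n: int) -> np.ndarray:
    w = np.zeros((n, n))
    for i in range(n - 1):
        w[i, i + 1] = w[i + 1, i] = 1.0
    return w


def complete_graph(n: int) -> np.ndarray:
    w = np.ones((n, n)) - np.eye(n)
    return w


def cohort_correlation_stacks(spec: SyntheticSpec, seed: int):
    """Raw correlation-matrix stacks (group A, group B) for one cohort."""
    ss = np.random.SeedSequence(seed)
    covs = {g: build_population_cov(spec, g) for g in "AB"}
    children = ss.spawn(spec.n_group_a + spec.n_group_b)
    out = {"A": [], "B": []}
    k = 0
    for group, size in (("A", spec.n_group_a), ("B", spec.n_group_b)):
        for _ in range(size):
            ts = sample_timeseries(
                covs[group], spec.n_volumes, spec.ar_coeff,
                np.random.default_rng(children[k]),
                tr_seconds=spec.tr_seconds,
            )
            k += 1
            out[group].append(correlation_matrix(ts).r)
    return np.array(out["A"]), np.array(out["B"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spec() -> SyntheticSpec:
    """Small, fast cohort: 20 ROIs, 8 + 8 subjects."""
    return SyntheticSpec(n_rois=20, n_group_a=8, n_group_b=8, seed=7)
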