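# conneff

Graph-theoretic small-world efficiency analysis of resting-state functional
brain networks, with permutation-based group inference.

`conneff` is aimed at researchers who start from per-subject ROI × time BOLD
signal tables (for example, atlas-parcellated resting-state fMRI with 246
regions) and want to compare the topological organization of two groups'
functional connectomes — patients versus controls — at the global, nodal,
and edge level, and to relate network organization to behavioral scores.
Because patient fMRI data can rarely be shared, the package also ships a
synthetic cohort generator that reproduces the statistical structure such
an analysis assumes, so every stage is testable end to end without any
download.

## What it computes

**Network construction.** Each subject's cleaned ROI time series (linear
detrend, 0.01–0.08 Hz zero-phase band-pass, nuisance regression including
the Friston 24-parameter motion expansion) are correlated pairwise to give
an N × N Pearson matrix. An edge is kept only if its two-tailed p-value
survives Bonferroni correction over the N(N−1)/2 unique pairs and the
correlation is positive; the retained weight is the raw correlation
w_ij ∈ (0, 1].

**Small-world efficiency.** Edge length is the reciprocal weight 1/w_ij
(a strong correlation is a short functional distance) and d_ij is the
shortest-path length. For a weighted graph G with N nodes:

    E_glob(G) = 1/(N(N−1)) · Σ_{i≠j} 1/d_ij          global efficiency
    e_i       = 1/(N−1)    · Σ_{j≠i} 1/d_ij          nodal efficiency
    E_loc(G)  = 1/N · Σ_i E_glob(G_i)                local efficiency

where G_i is the subgraph induced on the neighbors of node i. Unreachable
pairs contribute 0 (1/∞ convention), so networks with isolated nodes are
handled without dropping anything, and mean(e_i) = E_glob exactly.
Efficiencies are normalized by the mean over random networks that preserve
N, K, and the exact degree sequence (double-edge-swap rewiring with the
weight multiset reassigned); a network with normalized E_glob ≈ 1 and
normalized E_loc > 1 is classified small-world.

**Group inference.** Global metrics are compared with one-tailed
permutation tests (group relabeling, 10,000 permutations by default, add-one
exceedance p plus the classical 95th-percentile decision rule); nodal
efficiency comparisons are corrected with Benjamini–Hochberg FDR; edge-level
differences use the network-based statistic (NBS): edge-wise pooled-variance
t-tests at a primary threshold (p < 0.05, restricted to edges positive in
more than 85% of all subjects), connected components of suprathreshold
edges, and family-wise-corrected component p-values from the permutation
null of the maximal component size. Demographic tables are checked with
pooled-variance t-tests and the Pearson chi-square test.

**Brain–behavior.** Partial correlation between network metrics and
behavioral scores, controlling age, sex, and education by OLS
residualization (uncorrected p-values, by design, for exploratory screens).

## Worked example

```python
import numpy as np
from conneff import (SyntheticSpec, generate_cohort, correlation_matrix,
                     threshold_bonferroni, global_metrics, is_small_world, nbs)

# a small synthetic cohort at the study's sampling parameters
spec = SyntheticSpec(n_rois=30, n_group_a=8, n_group_b=8, seed=7)
cohort = generate_cohort(spec)

graphs = {}
for sid, ts in cohort.timeseries.items():
    graphs[sid] = threshold_bonferroni(correlation_matrix(ts), alpha=0.05)

sid = cohort.subject_ids[0]
m = global_metrics(graphs[sid], n_random=100, seed=1)
print(f"{sid}: density={m.density:.3f}  E_glob={m.e_glob:.3f}  E_loc={m.e_loc:.3f}")
print(f"norm E_glob={m.norm_e_glob:.3f}  norm E_loc={m.norm_e_loc:.3f}  "
      f"small-world={is_small_world(m)}")

# NBS on a cohort with a planted 6-edge effect
effect = SyntheticSpec(n_rois=20, n_group_a=8, n_group_b=8, effect_delta=0.25,
                       between_block_cov=0.0, shortcut_frac=0.0,
                       noise_sd=0.5, ar_coeff=0.0, seed=7)
eff_cohort = generate_cohort(effect)
conn = {sid: correlation_matrix(ts).r for sid, ts in eff_cohort.timeseries.items()}
stack_a = np.array([conn[s] for s in eff_cohort.group_ids("A")])
stack_b = np.array([conn[s] for s in eff_cohort.group_ids("B")])
result = nbs(stack_a, stack_b, primary_alpha=0.05, n_perm=2000, seed=2)
top = result.components[0]
print(f"largest NBS component: {top.size} edges, corrected p = {top.corrected_p:.4f}")
```

prints

```
sub-A01: density=0.170  E_glob=0.209  E_loc=0.323
norm E_glob=0.835  norm E_loc=5.206  small-world=False
largest NBS component: 6 edges, corrected p = 0.0230
```

The first two lines summarize one subject's thresholded network: 17% of
possible edges survive significance thresholding; its global efficiency is
well below its degree-matched rewired ensemble (normalized E_glob 0.835 —
this small modular network is lattice-like, not yet small-world) while its
local efficiency is far above it (5.2, high clustering). The last line
shows the NBS recovering a planted 6-edge component exactly, with a
family-wise-corrected p of 0.023 from 2,000 permutations.

## Command-line pipeline

The same analysis runs as a file-mediated pipeline
(`simulate → clean → build → metrics → compare → nbs → behavior → report`),
driven by a YAML/JSON config; every stage output is plain TSV/JSON and the
whole run is reproducible from one master seed:

```bash
conneff all --config config.yaml          # full pipeline
conneff metrics --config config.yaml      # re-run a single stage
```

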