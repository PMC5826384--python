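# Methods

This note documents the models, numerical choices, and deliberate design
decisions behind `conneff`, in the order the pipeline runs them.

## Synthetic cohort model

The generator (`conneff.synthetic`) emulates a two-group resting-state
cohort at the statistical level the downstream analysis actually consumes:
per-subject ROI × time signals, rigid-body motion traces, matched
covariates, and behavioral scores. It makes no attempt at voxel-level or
physiological realism (no images, no cardiac/respiratory structure).

**Population covariance.** ROIs are partitioned into community blocks
(default: six near-equal blocks over 246 ROIs) standing in for functional
systems. Off-diagonal covariance is `within_block_cov` (default 0.5)
inside a block and `between_block_cov` (default 0.1) across blocks; the
diagonal is `1 + noise_sd**2` (unit signal variance plus white measurement
noise, `noise_sd = 0.3`). With 230 samples these defaults put within-block
correlations (≈ 0.46) above the Bonferroni retention threshold and
between-block correlations (≈ 0.09) below it, giving thresholded networks
in a realistic density regime.

**Shortcuts.** A purely block-diagonal structure produces networks that
are unions of disconnected cliques, which no real connectome resembles.
A seeded set of disjoint cross-block ROI pairs (default: 80% of ROIs
participate in one pair each) therefore carries within-block-level
covariance — the community-plus-shortcut architecture that makes real
brain networks connected and small-world-leaning. Pairing each ROI at
most once bounds the spectral norm of the shortcut perturbation by one
shortcut magnitude, which is below the smallest eigenvalue of the block
matrix, so the construction stays positive definite at every network size.
Should a configuration still fail the Cholesky check (e.g. an extreme
planted effect), the matrix is projected to the nearest positive-definite
matrix by eigenvalue clipping; the repair is logged, and a repair that
moves any entry by more than 0.1 is a hard error naming the offending
parameters.

**Planted group effect.** Group A (patient-like) has `effect_delta`
(default 0.2) added symmetrically on a designated edge set, by default the
six edges of a 4-ROI clique inside the first block — a named target for
component-recovery tests. With `effect_delta = 0` the two group
covariances are identical.

**Time series.** Innovations are multivariate normal with the group
covariance, passed through a lag-1 autoregression (`ar_coeff = 0.3`,
a modeling convention for BOLD-like temporal smoothness, not a measured
value); 100 burn-in frames are discarded so the retained 230 frames
(TR = 2 s) are stationary. The AR pass rescales all channels equally, so
the population correlation structure is that of the innovation covariance.

**Motion.** Random-walk traces in six rigid-body parameters, zero at the
first frame; rotation steps are scaled by 1/50 mm⁻¹ so rotations and
translations contribute comparably to framewise displacement. The default
amplitude (0.02 mm per step) keeps synthetic subjects below the exclusion
limits; tests use large amplitudes to exercise the exclusion rule.

**Covariates and scores.** Age, sex (Bernoulli, P(male) = 1/3), and
education are drawn from the same distributions in both groups — matched
by design, carrying no effect unless configured. Questionnaire scores are
drawn from group-typical distributions for an insomnia-versus-good-sleeper
contrast; the sleepiness score and disease duration are missing for the
control-like group, as in real cohorts. One score (default ESS) is
*coupled*: each subject receives a scalar covariance jitter
(`subject_effect_sd`, default 0.05) on the effect edges, and the coupled
score is `behavior_coupling ×` (the subject's generating covariance mean
over the effect edges) plus Gaussian noise. The subject-level jitter is
what makes within-group brain–behavior recovery possible at all: with a
purely group-level covariance the latent property would be constant within
a group and no within-group correlation could exist. The latent value is
stored in the cohort table (`latent_effect_cov`) so tests can check
recovery against the truth.

Everything is a pure function of `(spec, seed)`: the spec seed feeds a
`SeedSequence` whose spawned children drive covariance jitter,
demographics, scores, and every subject's time series and motion
independently.

## Signal cleaning

Order is fixed: linear detrend → band-pass → nuisance regression, and the
order matters (regressors are fit to the filtered signal); an integration
test asserts the composite equals that composition and differs from the
reversed order. The band-pass is a 4th-order Butterworth applied
forward-backward (`sosfiltfilt`), i.e. zero-phase — a causal filter would
lag signals and distort inter-regional correlations. Pass/stop-band
behavior is verified on sinusoids measured away from the series ends,
because the forward-backward pass has start-up transients there. Nuisance
regression always appends an intercept and uses the least-squares
pseudoinverse, so rank-deficient confound matrices are handled silently.
Framewise displacement follows the Power convention — sum of absolute
backward differences, rotations converted to arc length on a 50 mm sphere —
and the exclusion rule is > 2 mm translation or > 2° rotation (rotations
are stored in radians and converted). Both the FD convention and the
filter design are configurable decisions, not fixed facts of the analysis.

## Network construction

Pearson correlations with p-values from the exact t-transform
`t = r√((n−2)/(1−r²))` on n−2 degrees of freedom (cross-checked in tests
against `scipy.stats.pearsonr` and a permutation null). Bonferroni
correction counts m = N(N−1)/2 unique pairs; ties at the threshold lose
(strict inequality). Negative edges are excluded; retained weights equal
the raw correlations, unrescaled. Constant columns yield r = 0, p = 1
with a warning. Isolated nodes are kept: efficiency handles them through
the 1/∞ = 0 convention rather than by dropping nodes.

## Efficiency metrics

Shortest paths are computed by Dijkstra (`scipy.sparse.csgraph`) on edge
lengths 1/w; a Floyd–Warshall oracle in the test suite verifies equality
entry-for-entry on hundreds of random graphs. The local-efficiency
subgraph for node i is induced on the neighbors of i with the original
weights between them (not rescaled by the weights to i) — the plainest
reading of the neighbor-subgraph formulation; subgraphs with fewer than
two nodes contribute 0.

**Rewiring null model.** Degree-preserving randomization attempts
`swap_factor × K` double-edge swaps (default 20 per edge, enough that
topology autocorrelation is negligible on test graphs), accepting a swap
only if it creates no self-loop or duplicate edge; the original weight
multiset is then reassigned to the new edges in a seeded permutation.
This preserves N, K, the exact degree sequence, *and* the weight
distribution, which keeps efficiency ratios meaningful. Whether null
networks should carry weights with edges or shuffle them is genuinely
open; shuffling is the default here and the rewire/assignment steps are
separable if a user needs the other convention. Complete graphs admit no
swap and are returned unchanged with a warning.

**Small-world rule.** Normalized E_glob within `glob_tol` of 1 (default
0.1 — "approximately equal" has no canonical tolerance, so it is a
configurable default) and normalized E_loc strictly greater than 1.
Note an exchangeability caveat the test suite makes explicit: for a *pure
random* graph, the graph is statistically identical to its own
degree-preserving rewires, so its normalized local efficiency falls above
or below 1 with roughly equal probability. Classification of random
graphs as "not small-world" is therefore a statistical tendency (about
half of seeds, never systematically), not a per-graph guarantee; the
tests assert the rate, not each seed.

## Group inference

The permutation engine relabels pooled subjects preserving group sizes.
p-values use the add-one (never-zero) exceedance estimator
`(1 + #{null ≥ obs})/(1 + n_perm)`; the classical 95th-percentile
decision is reported alongside, and the two agree except within 1/n_perm.
For small cohorts an exhaustive mode enumerates all C(n, n_a) relabelings
and returns the exact proportion (identity included). Nodal comparisons
share one permutation-index matrix across nodes — fast, and it preserves
the cross-node dependence of the null — with Benjamini–Hochberg step-up
(via statsmodels) across nodes.

**NBS.** Edges enter only if their raw (pre-threshold) correlation is
positive in strictly more than 85% of all subjects, both groups pooled.
Edge-level tests are pooled-variance t statistics, one-sided per contrast
(increases and decreases are two separate runs — whether the original
edge-level test was one- or two-tailed is not determinable, so one-sided
per direction is the default and it is configurable). Component size is
counted in links. The null records the maximal component size per
relabeling; a null component *equal* to the observed size counts against
it by default (`null_counting="ge"`, the conservative standard), with the
strict "larger than" reading available as a flag. The engine vectorizes
the per-permutation t-statistics via group-selection matrix products and
uses a union-find pass per permutation for the maximal component, so a
20-ROI, 16-subject, 1,000-permutation run takes tens of milliseconds.

Demographic tests are the pooled-variance (not Welch) Student t — the
choice that reproduces standard matched-cohort tables — and the Pearson
chi-square without continuity correction.

## Brain–behavior

Partial correlation residualizes both variables on [intercept |
covariates] and correlates the residuals; p from the t-transform with
n − 2 − C degrees of freedom, where C is the *rank* of the covariate
block (collinear columns are absorbed with a warning). Sex is encoded
0/1; any affine coding gives the same result, which a test asserts.
Incomplete rows are dropped listwise. p-values are deliberately
uncorrected (exploratory screen) and the pipeline report flags this.

## Pipeline and I/O

Stages communicate only through plain-text files (TSV matrices with ROI
label headers written at 17 significant digits, round-tripping to better
than 1e-12; JSON with sorted keys and no timestamps), so a re-run from
the same config and master seed is byte-identical and any stage can be
re-run alone. One master seed derives all stage seeds as the first words
of `SeedSequence(master_seed)`'s generated state, masked to 31 bits.
The simulate stage replaces the synthetic spec's own seed with its derived
stage seed, so the config's master seed alone determines the cohort.

## Problem sizes used in tests and the acceptance script

The full study scale (246 ROIs, 74 subjects, 10,000 permutations, 100
random networks per subject) is the package default and runs in hours;
the shipped verification suites use the scales the analysis is invariant
to: 16–30 ROIs, 8 + 8 or 36 + 38 subjects, 1,000–2,000 permutations, and
8–100 random networks, chosen so each property being tested (calibration,
recovery, identity, determinism) is measured at useful statistical
resolution. The NBS calibration uses 1,000 null cohorts; the
planted-effect recovery cohorts use isolated background blocks
(`between_block_cov = 0`, no shortcuts) with a moderate effect
(`effect_delta = 0.25`, `noise_sd = 0.5`): with fully independent
background blocks the positivity rule meaningfully filters the edge set,
and a moderate per-edge effect is the regime where NBS has power — an
extreme effect paradoxically *weakens* the corrected p, because
relabelings that overlap the true grouping retain enough residual signal
to enlarge the null's maximal components.

## Known limitations

- The generator's Gaussian AR(1) model has no physiological noise,
  scanner drift, or spatial autocorrelation; passing tests demonstrate
  the statistical machinery, not robustness to real artifacts.
- Significance thresholding depends on the number of pairs m, so graph
  density is scale-dependent; cross-scale comparisons of absolute
  efficiencies are not meaningful.
- Equicorrelated community blocks are more clique-like than real
  functional systems, so normalized local efficiency of synthetic
  networks runs higher than typical empirical values.
- No proportional/fixed-density thresholding sweep, no negative-weight
  analysis, no covariate-adjusted NBS, and no imaging-format ingestion;
  the artifact's boundary is ROI-level tabular data.
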