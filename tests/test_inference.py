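"""Tests for the permutation engine, NBS, FDR, and demographic tests."""

import numpy as np
import pytest
from scipy import stats

from conneff.inference import (
    chi_square_2x2,
    fdr_bh,
    nbs,
    nodal_comparison,
    permutation_test_metric,
    two_sample_t,
)
from conneff.synthetic import SyntheticSpec

from ._oracles import bh_stepup, exhaustive_perm_p, union_find_components
from .conftest import cohort_correlation_stacks


class TestPermutationTest:
    def test_matches_exhaustive_enumeration_3v3(self):
        a = [5.0, 7.0, 9.0]
        b = [4.0, 6.0, 5.0]
        for direction in ("greater", "less"):
            res = permutation_test_metric(a, b, direction=direction,
                                          method="exhaustive")
            assert res.p_value == pytest.approx(
                exhaustive_perm_p(a, b, direction), abs=1e-12
            )
            assert res.n_perm == 20  # C(6,3)

    def test_sampled_p_converges_to_exhaustive(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 1.0, 4)
        b = rng.normal(0.0, 1.0, 4)
        exact = exhaustive_perm_p(a, b, "greater")
        res = permutation_test_metric(a, b, n_perm=20_000, seed=1)
        assert res.p_value == pytest.approx(exact, abs=0.02)

    def test_degenerate_identical_values(self):
        res = permutation_test_metric([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert res.observed_diff == 0.0
        assert res.p_value == 1.0

    def test_recount_matches_reported_p(self, rng):
        a = rng.normal(0.5, 1, 10)
        b = rng.normal(0.0, 1, 12)
        res = permutation_test_metric(a, b, n_perm=2000, seed=3)
        assert res.recount_p() == pytest.approx(res.p_value, abs=1e-12)

    def test_seed_reproducibility(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=8)
        r1 = permutation_test_metric(a, b, n_perm=500, seed=9)
        r2 = permutation_test_metric(a, b, n_perm=500, seed=9)
        np.testing.assert_array_equal(r1.null_dist, r2.null_dist)
        assert r1.p_value == r2.p_value

    def test_label_swap_mirrors(self, rng):
        # swapping groups negates the observed difference, and the mirrored
        # direction reproduces the exact p (exhaustive engine)
        a, b = rng.normal(0.3, 1, 4), rng.normal(size=4)
        r1 = permutation_test_metric(a, b, direction="greater",
                                     method="exhaustive")
        r2 = permutation_test_metric(b, a, direction="less",
                                     method="exhaustive")
        assert r2.observed_diff == pytest.approx(-r1.observed_diff)
        assert r2.p_value == pytest.approx(r1.p_value, abs=1e-12)

    def test_percentile_rule_agrees_with_p(self, rng):
        # the 95th-percentile criterion and p <= 0.05 agree up to the
        # add-one smoothing
        for seed in range(20):
            g = np.random.default_rng(seed)
            a = g.normal(0.4, 1, 10)
            b = g.normal(0.0, 1, 10)
            res = permutation_test_metric(a, b, n_perm=999, seed=seed)
            if res.p_value <= 0.04:
                assert res.significant_percentile
            if res.p_value > 0.06:
                assert not res.significant_percentile


class TestNodalComparison:
    def test_all_tiny_p_all_significant(self, rng):
        a = rng.normal(5.0, 0.1, size=(10, 6))
        b = rng.normal(0.0, 0.1, size=(10, 6))
        res = nodal_comparison(a, b, n_perm=2000, seed=0)
        assert res.significant.all()
        assert np.all(res.p_values < 0.01)

    def test_null_nodes_rarely_flagged(self, rng):
        a = rng.normal(size=(12, 20))
        b = rng.normal(size=(12, 20))
        res = nodal_comparison(a, b, n_perm=1000, seed=1)
        assert res.significant.sum() <= 2

    def test_shared_permutations_reproducible(self, rng):
        a = rng.normal(size=(8, 5))
        b = rng.normal(size=(8, 5))
        r1 = nodal_comparison(a, b, n_perm=500, seed=7)
        r2 = nodal_comparison(a, b, n_perm=500, seed=7)
        np.testing.assert_array_equal(r1.p_values, r2.p_values)


class TestFdrBh:
    def test_single_p_reduces_to_raw_threshold(self):
        assert fdr_bh([0.04], q=0.05).tolist() == [True]
        assert fdr_bh([0.06], q=0.05).tolist() == [False]

    def test_empty_input(self):
        assert fdr_bh([], q=0.05).size == 0

    def test_hand_worked_stepup(self):
        # 0.03 <= 3/4 * 0.05 = 0.0375 -> first three pass
        mask = fdr_bh([0.01, 0.02, 0.03, 0.20], q=0.05)
        assert mask.tolist() == [True, True, True, False]

    def test_matches_bruteforce_enumeration(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06]
        np.testing.assert_array_equal(fdr_bh(p, q=0.05), bh_stepup(p, 0.05))

    def test_random_cases_match_oracle(self, rng):
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 30)))
            q = float(rng.choice([0.01, 0.05, 0.1, 0.2]))
            np.testing.assert_array_equal(fdr_bh(p, q=q), bh_stepup(p, q))

    def test_mask_monotone_in_q(self, rng):
        p = rng.uniform(size=15)
        small = fdr_bh(p, q=0.01)
        large = fdr_bh(p, q=0.10)
        assert np.all(large[small])  # everything accepted at q=.01 stays at q=.10

    def test_false_discovery_proportion_controlled(self, rng):
        # no true effects: the expected FDP equals the rate of any rejection
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            p = rng.uniform(size=20)
            hits += fdr_bh(p, q=0.05).any()
        assert hits / n_sim <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / n_sim)


class TestTwoSampleT:
    def test_age_summaries_from_matched_cohort(self):
        res = two_sample_t(38.67, 9.53, 36, 37.79, 9.92, 38)
        assert res.p == pytest.approx(0.699, abs=5e-4)
        assert res.df == 72

    def test_education_summaries(self):
        res = two_sample_t(10.06, 3.81, 36, 11.66, 3.20, 38)
        assert res.p == pytest.approx(0.054, abs=5e-4)

    def test_identical_groups(self):
        res = two_sample_t(5.0, 0.0, 10, 5.0, 0.0, 10)
        assert res.t == 0.0 and res.p == 1.0

    def test_raw_samples_match_scipy(self, rng):
        a = rng.normal(1, 2, 14)
        b = rng.normal(0, 2, 17)
        res = two_sample_t(a, b)
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
        assert res.t == pytest.approx(t_ref, rel=1e-10)
        assert res.p == pytest.approx(p_ref, rel=1e-10)


class TestChiSquare:
    def test_sex_table(self):
        chi2, dof, p = chi_square_2x2([[12, 24], [12, 26]])
        assert dof == 1
        assert p == pytest.approx(0.872, abs=5e-4)

    def test_proportional_table_independent(self):
        chi2, _, p = chi_square_2x2([[10, 20], [20, 40]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_expected_counts(self):
        # [[5,15],[15,5]]: expected all 10, chi2 = 4 * 25/10 = 10
        chi2, _, p = chi_square_2x2([[5, 15], [15, 5]])
        assert chi2 == pytest.approx(10.0)
        assert p == pytest.approx(stats.chi2.sf(10.0, 1))

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2([[0, 0], [5, 5]])


class TestNbs:
    def test_component_labeling_matches_union_find(self, rng):
        # engineered suprathreshold set {(0,1),(1,2),(5,6)} -> sizes 2 and 1
        n, per_group = 8, 10
        # background edges are constant across subjects (zero variance, so
        # they can never reach threshold); only the effect edges vary
        base = np.full((2 * per_group, n, n), 0.3)
        for s in range(2 * per_group):
            np.fill_diagonal(base[s], 0)
        effect = [(0, 1), (1, 2), (5, 6)]
        for i, j in effect:
            noise = rng.normal(0.0, 0.05, size=2 * per_group)
            base[:, i, j] += noise
            base[:, j, i] += noise
            base[:per_group, i, j] += 1.0
            base[:per_group, j, i] += 1.0
        res = nbs(base[:per_group], base[per_group:], n_perm=200, seed=0)
        sizes = sorted(c.size for c in res.components)
        comp_edges = [set(c.edges) for c in res.components]
        assert sizes == [1, 2]
        assert {(0, 1), (1, 2)} in comp_edges and {(5, 6)} in comp_edges
        # oracle agreement on the node partition
        comps = union_find_components(n, effect)
        assert {frozenset(c) for c in comps if len(c) > 1} == {
            frozenset({0, 1, 2}), frozenset({5, 6})
        }

    def test_positivity_rule_excludes_inconsistent_edges(self, rng):
        n, per_group = 6, 12
        conn = np.abs(rng.normal(0.4, 0.05, size=(2 * per_group, n, n)))
        conn = (conn + conn.transpose(0, 2, 1)) / 2
        for s in range(2 * per_group):
            np.fill_diagonal(conn[s], 0)
        conn[: per_group + 4, 0, 1] = -0.2  # positive in < 85% of subjects
        conn[: per_group + 4, 1, 0] = -0.2
        res = nbs(conn[:per_group], conn[per_group:], n_perm=100, seed=0)
        assert not res.included_edges[0, 1]
        assert res.included_edges[2, 3]

    def test_no_included_edges_warns(self, rng):
        conn = -np.abs(rng.normal(0.3, 0.05, size=(8, 4, 4)))
        conn = (conn + conn.transpose(0, 2, 1)) / 2
        for s in range(8):
            np.fill_diagonal(conn[s], 0)
        with pytest.warns(UserWarning, match="positivity"):
            res = nbs(conn[:4], conn[4:], n_perm=50, seed=0)
        assert res.components == []

    def test_null_distribution_seed_invariance(self, tiny_spec):
        # two seeds at n_perm=2000 give the same null distribution (KS test)
        conn_a, conn_b = cohort_correlation_stacks(tiny_spec, seed=1234)
        r1 = nbs(conn_a, conn_b, n_perm=2000, seed=10)
        r2 = nbs(conn_a, conn_b, n_perm=2000, seed=20)
        ks = stats.ks_2samp(r1.null_max_sizes, r2.null_max_sizes)
        assert ks.pvalue > 0.01

    def test_planted_component_recovered(self):
        spec = SyntheticSpec(
            n_rois=20, n_group_a=8, n_group_b=8, effect_delta=0.25,
            between_block_cov=0.0, shortcut_frac=0.0, noise_sd=0.5, ar_coeff=0.0, seed=0,
        )
        conn_a, conn_b = cohort_correlation_stacks(spec, seed=777)
        res = nbs(conn_a, conn_b, n_perm=1000, seed=5)
        assert res.components
        top = res.components[0]
        planted = set(spec.effect_edges)
        found = set(top.edges)
        jaccard = len(found & planted) / len(found | planted)
        assert jaccard >= 0.6
        assert top.corrected_p < 0.05

    def test_strict_null_counting_never_more_conservative(self, tiny_spec):
        conn_a, conn_b = cohort_correlation_stacks(tiny_spec, seed=99)
        ge = nbs(conn_a, conn_b, n_perm=300, seed=4, null_counting="ge")
        gt = nbs(conn_a, conn_b, n_perm=300, seed=4, null_counting="gt")
        for c_ge, c_gt in zip(ge.components, gt.components):
            assert c_gt.corrected_p <= c_ge.corrected_p
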