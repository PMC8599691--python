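"""Correlation, association, and survival statistics against independent
oracles (enumeration, hand computation, lifelines)."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank
from scipy.stats import hypergeom, rankdata

from tgfbsig.errors import DegenerateTableError, GroupingError, ValidationError
from tgfbsig.stats import (
    chi_square_test,
    compare_score_by_group,
    fisher_exact_2x2,
    km_estimate,
    logrank_test,
    pairwise_logrank_bonferroni,
    spearman_rho,
)


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman_rho([1, 2, 3], [2, 4, 9]).rho == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [9, 4, 2]).rho == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        assert spearman_rho([1, 2, 3], [3, 1, 2]).rho == pytest.approx(-0.5)

    def test_matches_pearson_on_ranks_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            x = rng.normal(size=30)
            y = rng.normal(size=30) + 0.5 * x
            rho = spearman_rho(x, y).rho
            oracle = np.corrcoef(rankdata(x), rankdata(y))[0, 1]
            assert rho == pytest.approx(oracle, abs=1e-12)

    def test_exact_small_sample_p_from_enumeration(self):
        x, y = [1, 2, 3, 4], [1, 2, 4, 3]
        res = spearman_rho(x, y)
        rx, ry = rankdata(x), rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        hits = sum(
            abs(np.corrcoef(rx, p)[0, 1]) >= obs - 1e-12
            for p in itertools.permutations(ry)
        )
        assert res.p_value == pytest.approx(hits / math.factorial(4))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = spearman_rho(x, y).rho
        assert spearman_rho(np.exp(x), y**3).rho == pytest.approx(base, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            spearman_rho([1, 1, 1], [1, 2, 3])


class TestMannWhitney:
    def test_identical_groups_no_separation(self):
        res = compare_score_by_group([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert res.statistic == pytest.approx(4.5)
        assert res.p_value >= 0.99

    def test_exact_p_on_fully_separated_quartet(self):
        res = compare_score_by_group([1, 2, 3, 4], [0, 0, 1, 1])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1 / 3, abs=1e-12)

    def test_matches_full_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=10).round(1)  # rounding forces some ties
        labels = np.array([0] * 5 + [1] * 5)
        res = compare_score_by_group(scores, labels)
        ranks = rankdata(np.concatenate([scores[labels == 0], scores[labels == 1]]))
        mu = 5 * 5 / 2.0
        u_obs = ranks[:5].sum() - 15
        hits = total = 0
        for idx in itertools.combinations(range(10), 5):
            u = ranks[list(idx)].sum() - 15
            hits += abs(u - mu) >= abs(u_obs - mu) - 1e-12
            total += 1
        assert res.p_value == pytest.approx(hits / total)

    def test_large_separated_groups_significant(self):
        scores = np.concatenate([np.arange(10), np.arange(100, 110)])
        labels = np.repeat([0, 1], 10)
        assert compare_score_by_group(scores, labels).p_value < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(GroupingError):
            compare_score_by_group([1, 2, 3], [0, 0, 0])


class TestFisherExact:
    def test_symmetric_table(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]).p_value == pytest.approx(1.0)

    def test_diagonal_table(self):
        assert fisher_exact_2x2([[5, 0], [0, 5]]).p_value == pytest.approx(
            2 / 252, abs=1e-9)

    def test_matches_hypergeometric_enumeration(self):
        table = [[2, 3], [3, 2]]
        res = fisher_exact_2x2(table)
        # margins: row1=5, col1=5, n=10; a ranges over 0..5
        probs = {a: hypergeom.pmf(a, 10, 5, 5) for a in range(6)}
        p_obs = probs[2]
        expected = sum(p for p in probs.values() if p <= p_obs + 1e-12)
        assert res.p_value == pytest.approx(expected, abs=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            fisher_exact_2x2([[0, 0], [1, 2]])


class TestChiSquare:
    def test_no_association(self):
        res = chi_square_test([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        res = chi_square_test([[20, 10], [10, 20]])
        assert res.statistic == pytest.approx(20 / 3, abs=1e-4)

    def test_dof_for_2x3(self):
        res = chi_square_test([[5, 5, 5], [5, 5, 5]])
        assert res.table_shape == (2, 3)
        assert res.p_value == pytest.approx(1.0)

    def test_converges_to_fisher_on_large_balanced_tables(self):
        # Yates-corrected chi-square tracks the exact test at moderate counts;
        # the uncorrected statistic converges as counts grow
        table = [[60, 50], [50, 60]]
        assert abs(chi_square_test(table, yates=True).p_value
                   - fisher_exact_2x2(table).p_value) < 0.01
        big = [[500, 450], [450, 500]]
        assert abs(chi_square_test(big).p_value
                   - fisher_exact_2x2(big).p_value) < 0.01


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate([1, 2, 3], [0, 0, 0])
        assert curve.event_times.size == 0
        assert curve.survival_at(5) == 1.0

    def test_no_censoring_equals_empirical_survival(self):
        times = [1.0, 2.0, 3.0]
        curve = km_estimate(times, [1, 1, 1])
        np.testing.assert_allclose(curve.survival_probs, [2 / 3, 1 / 3, 0.0])
        # exact identity with the empirical survivor function
        rng = np.random.default_rng(9)
        t = rng.exponential(10, 40)
        curve = km_estimate(t, np.ones(40, dtype=int))
        for et, s in zip(curve.event_times, curve.survival_probs):
            assert s == pytest.approx((t > et).mean(), abs=1e-12)

    def test_censored_subject_leaves_risk_set(self):
        # times 1, 2(censored), 3: S(1)=2/3, then risk set of 1 at t=3
        curve = km_estimate([1, 2, 3], [1, 0, 1])
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.survival_at(3) == pytest.approx(0.0)
        np.testing.assert_array_equal(curve.at_risk, [3, 1])

    def test_matches_lifelines_with_censoring(self):
        rng = np.random.default_rng(12)
        t = rng.exponential(10, 60).round(1)
        e = rng.integers(0, 2, 60)
        curve = km_estimate(t, e)
        km = KaplanMeierFitter().fit(t, e)
        for et, s in zip(curve.event_times, curve.survival_probs):
            assert s == pytest.approx(km.predict(et), abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([], [])


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 0, 1, 1, 0]
        g = ["A"] * 3 + ["B"] * 3
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_four_subject_example(self):
        # O1=2, E1=5/6, V=17/36 -> (7/6)^2/(17/36) = 2.8824
        res = logrank_test([1, 2, 3, 4], [1, 1, 1, 1], ["A", "A", "B", "B"])
        assert res.statistic == pytest.approx((7 / 6) ** 2 / (17 / 36), abs=1e-9)
        assert res.statistic == pytest.approx(2.88, abs=0.01)

    def test_invariant_to_group_relabeling(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10, 30)
        e = rng.integers(0, 2, 30)
        g = rng.choice(["A", "B"], 30)
        g[:2] = ["A", "B"]  # both groups guaranteed non-empty
        flipped = np.where(g == "A", "B", "A")
        assert logrank_test(t, e, g).statistic == pytest.approx(
            logrank_test(t, e, flipped).statistic, abs=1e-12)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(10, 50).round(1)
        e = rng.integers(0, 2, 50)
        g = np.array(["A"] * 25 + ["B"] * 25)
        ours = logrank_test(t, e, g)
        theirs = ll_logrank(t[g == "A"], t[g == "B"], e[g == "A"], e[g == "B"])
        assert ours.statistic == pytest.approx(theirs.test_statistic, abs=1e-8)
        assert ours.p_value == pytest.approx(theirs.p_value, abs=1e-8)

    def test_empty_group_rejected(self):
        with pytest.raises(GroupingError):
            logrank_test([1, 2], [1, 1], ["A", "A"])


class TestPairwiseBonferroni:
    def _three_strata(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(10, 60)
        e = rng.integers(0, 2, 60)
        g = np.repeat(["low", "intermediate", "high"], 20)
        return t, e, g

    def test_three_groups_give_three_tests_with_3p_adjustment(self):
        t, e, g = self._three_strata()
        results = pairwise_logrank_bonferroni(t, e, g)
        assert len(results) == 3
        for res in results:
            assert res.p_adjusted == pytest.approx(min(1.0, res.p_value * 3))
            assert res.p_adjusted >= res.p_value

    def test_two_groups_unadjusted(self):
        t = [1, 2, 3, 4]
        results = pairwise_logrank_bonferroni(t, [1, 1, 1, 1], ["A", "A", "B", "B"])
        assert len(results) == 1
        assert results[0].p_adjusted == pytest.approx(results[0].p_value)

    def test_identical_strata_all_adjusted_to_one(self):
        t = [1, 2, 3] * 3
        e = [1, 1, 0] * 3
        g = np.repeat(["a", "b", "c"], 3)
        for res in pairwise_logrank_bonferroni(t, e, g):
            assert res.p_adjusted == pytest.approx(1.0)
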