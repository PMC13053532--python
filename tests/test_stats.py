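"""Rank tests, ROC/Youden, logistic models and power design."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from panotex.stats import (
    PowerSpec,
    RocDirection,
    empirical_power,
    logistic_model,
    mann_whitney,
    power_two_sample_t,
    roc_with_youden,
    sample_size_two_group_t,
    spearman_correlation,
    wilcoxon_signed_rank,
)


def exhaustive_mann_whitney_p(a, b):
    """Permutation-null oracle: two-sided p of U over all group assignments."""
    pooled = sorted(a) + sorted(b)
    n1 = len(a)

    def u_stat(group_a, group_b):
        return sum(
            1.0 if x > y else 0.5 if x == y else 0.0
            for x in group_a for y in group_b
        )

    u_obs = u_stat(a, b)
    mean_u = n1 * len(b) / 2.0
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(ga, gb))
    extreme = sum(1 for u in us if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12)
    return extreme / len(us)


def exhaustive_wilcoxon_p(diffs):
    """Sign-flip oracle: two-sided p of W+ over all 2^n sign assignments,
    with midranks for tied absolute differences."""
    d = np.asarray(diffs, dtype=float)
    absd = np.abs(d)
    order = sorted(absd)
    ranks = np.array([
        np.mean([i + 1 for i, v in enumerate(order) if v == a]) for a in absd
    ])
    w_obs = ranks[d > 0].sum()
    n = len(d)
    mean_w = n * (n + 1) / 4.0
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    extreme = sum(1 for w in ws if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12)
    return extreme / len(ws)


class TestMannWhitney:
    def test_complete_separation_has_unit_effect_size(self):
        res = mann_whitney([1, 2, 3], [10, 11, 12])
        assert res.statistic == 0.0
        assert res.effect_r == 1.0

    def test_identical_multisets_have_zero_effect(self):
        res = mann_whitney([1, 2, 2, 5], [1, 2, 2, 5])
        assert res.effect_r == 0.0

    def test_toy_vectors_match_exhaustive_enumeration(self):
        a, b = [1, 3], [2, 4]
        res = mann_whitney(a, b)
        assert res.statistic == 1.0  # (1<2,1<4 -> 0) + (3>2 -> 1, 3<4 -> 0)
        assert res.p_value == pytest.approx(exhaustive_mann_whitney_p(a, b))

    @given(
        st.lists(st.integers(0, 40), min_size=3, max_size=6),
        st.lists(st.integers(0, 40), min_size=3, max_size=6),
    )
    @settings(max_examples=20, deadline=None)
    def test_effect_size_is_bounded(self, a, b):
        res = mann_whitney(a, b)
        assert abs(res.effect_r) <= 1.0 + 1e-12

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])


class TestWilcoxon:
    def test_identical_pairs_are_degenerate(self):
        res = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert res.degenerate
        assert res.p_value == 1.0

    def test_constant_shift_matches_closed_form_standardization(self):
        n = 10
        x = np.arange(1.0, n + 1)
        res = wilcoxon_signed_rank(x + 5.0, x)
        # all differences equal +5: W+ = n(n+1)/2 on midranks; the variance
        # n(n+1)(2n+1)/24 carries the tie correction (t^3 - t)/48 for the
        # single tie group of size n
        sigma2 = n * (n + 1) * (2 * n + 1) / 24 - (n**3 - n) / 48
        expected_z = (n * (n + 1) / 2 - n * (n + 1) / 4) / math.sqrt(sigma2)
        assert res.statistic == pytest.approx(expected_z)
        assert res.statistic > 0  # x exceeds y -> positive Z by convention
        assert res.effect_r == 1.0

    def test_toy_pairs_match_sign_flip_enumeration(self):
        x = [5.0, 3.0, 8.0, 1.0, 9.0, 2.0]
        y = [3.5, 4.0, 4.0, 2.5, 5.0, 1.0]
        res = wilcoxon_signed_rank(x, y)
        diffs = np.array(x) - np.array(y)
        assert res.p_value == pytest.approx(exhaustive_wilcoxon_p(diffs))


class TestSpearman:
    def test_monotone_relationships_have_unit_rho(self):
        x = [1, 2, 5, 9]
        assert spearman_correlation(x, [2, 4, 9, 20]).statistic == pytest.approx(1.0)
        assert spearman_correlation(x, [0, -1, -4, -9]).statistic == pytest.approx(-1.0)

    def test_tied_data_match_pearson_on_midranks(self):
        from scipy.stats import pearsonr, rankdata

        x = [1.0, 2.0, 2.0, 4.0, 5.0]
        y = [3.0, 1.0, 4.0, 4.0, 6.0]
        rho = spearman_correlation(x, y).statistic
        expected = pearsonr(rankdata(x), rankdata(y)).statistic
        assert rho == pytest.approx(expected)

    def test_constant_vector_is_flagged(self):
        res = spearman_correlation([1, 1, 1], [2, 3, 4])
        assert res.degenerate


class TestRoc:
    def test_perfect_separation(self):
        res = roc_with_youden([1, 2, 9, 10], [False, False, True, True])
        assert res.auc == 1.0
        assert res.youden_j == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_toy_auc_equals_concordant_pair_fraction(self):
        # positives {3,5}, negatives {1,4}: concordant 3 of 4 pairs
        res = roc_with_youden([3, 5, 1, 4], [True, True, False, False])
        assert res.auc == pytest.approx(0.75)

    def test_lower_is_positive_direction(self):
        res = roc_with_youden([1, 2, 9, 10], [True, True, False, False])
        assert res.direction is RocDirection.LOWER_IS_POSITIVE
        assert res.auc == 1.0
        assert res.threshold_rule.startswith("<=")

    def test_youden_identity_exact(self, rng):
        for _ in range(20):
            scores = rng.normal(size=30)
            labels = rng.random(30) < 0.5
            if labels.all() or not labels.any():
                continue
            res = roc_with_youden(scores, labels)
            assert res.youden_j == res.sensitivity + res.specificity - 1.0

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=60)
        labels = np.concatenate([np.ones(30, bool), np.zeros(30, bool)])
        base = roc_with_youden(scores, labels).auc
        for f in (np.exp, lambda s: 3 * s + 7, lambda s: s**3):
            assert roc_with_youden(f(scores), labels).auc == pytest.approx(base)

    def test_agrees_with_sklearn_on_random_data(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=200) + np.repeat([0.0, 0.7], 100)
        labels = np.repeat([False, True], 100)
        ours = roc_with_youden(scores, labels).auc
        assert ours == pytest.approx(roc_auc_score(labels, scores))

    def test_null_scores_give_chance_auc(self, rng):
        scores = rng.normal(size=4000)
        labels = np.concatenate([np.ones(2000, bool), np.zeros(2000, bool)])
        assert 0.45 <= roc_with_youden(scores, labels).auc <= 0.55

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_with_youden([1, 2, 3], [True, True, True])


class TestLogistic:
    def test_single_binary_predictor_matches_cross_product_ratio(self):
        # 2x2 table: exposed 30 cases / 10 controls, unexposed 20 / 40
        x = np.concatenate([np.ones(40), np.zeros(60)])
        y = np.concatenate([np.ones(30), np.zeros(10), np.ones(20), np.zeros(40)])
        res = logistic_model(x, y, predictor_names=["exposure"])
        expected_or = (30 * 40) / (10 * 20)
        assert res.predictors[0].odds_ratio == pytest.approx(expected_or, rel=1e-4)
        assert res.predictors[0].ci_low < expected_or < res.predictors[0].ci_high

    def test_intercept_only_model(self):
        y = np.array([0, 1] * 20)
        res = logistic_model(np.empty((40, 0)), y)
        assert res.lr_chi2 == 0.0
        assert res.in_sample_auc == 0.5

    def test_null_predictor_ci_covers_one_in_most_replicates(self):
        rng = np.random.default_rng(2024)
        covered = 0
        reps = 40
        for _ in range(reps):
            x = rng.normal(size=500)
            y = rng.random(500) < 0.5
            res = logistic_model(x, y)
            p = res.predictors[0]
            covered += p.ci_low <= 1.0 <= p.ci_high
        assert covered / reps >= 0.90

    def test_separation_is_flagged(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = x.copy()
        res = logistic_model(x, y)
        assert res.separation_flag


class TestPowerDesign:
    def test_study_design_returns_21_per_group(self):
        assert sample_size_two_group_t(PowerSpec(0.90, 0.05, 0.80)) == 21

    def test_medium_effect_matches_statsmodels_oracle(self):
        from statsmodels.stats.power import TTestIndPower

        ours = sample_size_two_group_t(PowerSpec(0.50, 0.05, 0.80))
        oracle = math.ceil(
            TTestIndPower().solve_power(effect_size=0.5, alpha=0.05, power=0.8)
        )
        assert ours == oracle
        # never below the closed-form normal-approximation bound
        z = __import__("scipy.stats", fromlist=["norm"]).norm.ppf
        bound = 2 * (z(0.975) + z(0.80)) ** 2 / 0.5**2
        assert ours >= bound

    def test_sample_size_monotone_in_effect_size(self):
        n_large = sample_size_two_group_t(PowerSpec(0.9, 0.05, 0.80))
        n_medium = sample_size_two_group_t(PowerSpec(0.5, 0.05, 0.80))
        assert n_large < n_medium

    def test_power_function_agrees_with_statsmodels(self):
        from statsmodels.stats.power import TTestIndPower

        for d, n in ((0.9, 21), (0.5, 30)):
            ours = power_two_sample_t(d, n)
            oracle = TTestIndPower().power(effect_size=d, nobs1=n, alpha=0.05)
            assert ours == pytest.approx(oracle, abs=1e-9)

    def test_pathological_design_rejected(self):
        with pytest.raises(ValueError):
            sample_size_two_group_t(PowerSpec(0.9, 0.5, 0.3))

    def test_type_one_error_calibrated_under_null(self):
        rate = empirical_power(0.0, 25, alpha=0.05, reps=10_000, seed=3)
        se = math.sqrt(0.05 * 0.95 / 10_000)
        assert abs(rate - 0.05) <= 3 * se

    def test_huge_effect_saturates(self):
        assert empirical_power(5.0, 21, reps=1000, seed=4) > 0.999
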