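"""ROC / KS-cutoff / AUC-p / Spearman statistics against independent oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import roc_auc_score

from fogturn import accuracy_rate, auc_pvalue, roc_analysis, spearman
from fogturn.validation import ks_optimal_cutoff


def pairwise_auc(scores, labels):
    """Brute-force concordant-pair fraction (ties count 1/2)."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def exhaustive_ks(scores, labels):
    """Best J = sens + spec - 1 over every candidate threshold."""
    pos, neg = scores[labels], scores[~labels]
    cands = np.concatenate(([-np.inf, np.inf], np.unique(scores)))
    best = max((pos >= c).mean() + (neg < c).mean() - 1.0 for c in cands)
    return best


class TestROC:
    def test_perfect_separation(self):
        scores = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
        roc = roc_analysis(scores, labels)
        assert roc.auc == 1.0
        assert roc.accuracy_rate == 1.0
        assert roc.sens_at_cutoff == 1.0 and roc.spec_at_cutoff == 1.0
        assert 3.0 < roc.cutoff < 10.0
        assert roc.ks_statistic == 1.0

    @pytest.mark.parametrize(
        "scores, expected_auc",
        [([1, 2, 3, 4], 1.0), ([1, 3, 2, 4], 0.75)],
    )
    def test_small_instances_match_pair_counting(self, scores, expected_auc):
        labels = np.array([0, 0, 1, 1], dtype=bool)
        scores = np.array(scores, dtype=float)
        roc = roc_analysis(scores, labels)
        assert roc.auc == pytest.approx(expected_auc)
        assert roc.auc == pytest.approx(pairwise_auc(scores, labels))

    def test_independent_labels_give_chance_auc(self):
        rng = np.random.default_rng(7)
        n = 2000
        scores = rng.normal(size=2 * n)
        labels = np.repeat([False, True], n)
        roc = roc_analysis(scores, labels)
        se = np.sqrt((2 * n + 1) / (12 * n * n))
        assert abs(roc.auc - 0.5) < 3 * se

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            roc_analysis(np.arange(4.0), np.ones(4, dtype=bool))
        with pytest.raises(ValueError, match="positive"):
            roc_analysis(np.arange(4.0), np.zeros(4, dtype=bool))

    def test_nan_scores_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            roc_analysis(np.array([1.0, np.nan, 2.0, 3.0]), np.array([0, 0, 1, 1], dtype=bool))

    @given(st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_auc_equals_pair_fraction_and_sklearn(self, seed):
        """Trapezoid AUC = Mann-Whitney pair fraction = sklearn, with ties."""
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 50)
        scores = rng.integers(0, 8, size=n).astype(float)  # heavy ties
        labels = np.zeros(n, dtype=bool)
        labels[rng.choice(n, size=rng.integers(2, n - 1), replace=False)] = True
        if labels.all() or not labels.any():
            return
        roc = roc_analysis(scores, labels)
        assert roc.auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)
        assert roc.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
        assert roc.accuracy_rate == pytest.approx(2 * roc.auc - 1, abs=0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_ks_cutoff_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 40)
        scores = rng.normal(size=n).round(1)
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            return
        roc = roc_analysis(scores, labels)
        assert roc.ks_statistic == pytest.approx(exhaustive_ks(scores, labels), abs=1e-12)
        j = roc.sens_at_cutoff + roc.spec_at_cutoff - 1.0
        assert j == pytest.approx(roc.ks_statistic, abs=1e-12)
        assert ks_optimal_cutoff(roc) == roc.cutoff

    def test_ks_tie_broken_toward_higher_sensitivity(self):
        # several thresholds tie at the maximal J here; the rule must pick
        # the most sensitive one
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([1, 0, 1, 0], dtype=bool)
        roc = roc_analysis(scores, labels)
        best_j = roc.ks_statistic
        ties = [
            (s, th)
            for th, s, p in zip(roc.thresholds, roc.sensitivity, roc.specificity)
            if np.isclose(s + p - 1, best_j)
        ]
        assert roc.sens_at_cutoff == max(s for s, _ in ties)

    def test_degenerate_scores_flagged(self):
        roc = roc_analysis(np.ones(6), np.array([0, 1, 0, 1, 0, 1], dtype=bool))
        assert roc.degenerate
        assert roc.ks_statistic == pytest.approx(0.0)
        assert roc.auc == pytest.approx(0.5)

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_label_inversion_flips_auc(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=20)
        labels = np.array([False] * 10 + [True] * 10)
        a = roc_analysis(scores, labels).auc
        b = roc_analysis(scores, ~labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)


class TestAccuracyRate:
    @pytest.mark.parametrize(
        "auc, ar", [(0.65, 0.30), (0.5, 0.0), (0.58, 0.16), (1.0, 1.0), (0.0, -1.0)]
    )
    def test_values(self, auc, ar):
        assert accuracy_rate(auc) == pytest.approx(ar)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            accuracy_rate(1.2)


class TestAUCPValue:
    def test_perfect_separation_small_n(self):
        scores = np.concatenate([np.arange(20.0), np.arange(100.0, 120.0)])
        labels = np.repeat([False, True], 20)
        assert auc_pvalue(scores, labels) < 0.001

    def test_exact_permutation_tiny_n(self):
        """n=3 vs 3 fully separated: only the 2 extreme assignments of 20 are as extreme."""
        scores = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        labels = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
        p = auc_pvalue(scores, labels)
        # independent enumeration of all C(6,3)=20 label assignments
        ranks = stats.rankdata(scores)
        u_obs = ranks[labels].sum() - 6.0
        devs = [
            abs(ranks[list(idx)].sum() - 6.0 - 4.5)
            for idx in itertools.combinations(range(6), 3)
        ]
        p_oracle = np.mean([d >= abs(u_obs - 4.5) - 1e-12 for d in devs])
        assert p == pytest.approx(p_oracle)
        assert p == pytest.approx(2 / 20)

    def test_null_p_values_roughly_uniform(self):
        """Under identical distributions the p-value is ~Uniform(0,1)."""
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(500):
            scores = rng.normal(size=40)
            labels = np.repeat([False, True], 20)
            ps.append(auc_pvalue(scores, labels))
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_matches_scipy_mannwhitney_large_n(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=60) + np.repeat([0.0, 0.8], 30)
        labels = np.repeat([False, True], 30)
        p = auc_pvalue(scores, labels)
        ref = stats.mannwhitneyu(
            scores[labels], scores[~labels], alternative="two-sided", method="asymptotic",
            use_continuity=False,
        ).pvalue
        assert p == pytest.approx(ref, rel=1e-9)

    def test_degenerate_class_sizes_rejected(self):
        with pytest.raises(ValueError):
            auc_pvalue(np.arange(5.0), np.array([1, 0, 0, 0, 0], dtype=bool))


class TestSpearman:
    def test_monotone_transform_invariance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert spearman(x, x**2).rho == pytest.approx(1.0)
        assert spearman(x, -x).rho == pytest.approx(-1.0)

    def test_hand_computed_rank_formula(self):
        """d^2 = (1,1,1,1,0): rho = 1 - 6*4/(5*24) = 0.8."""
        x = np.array([1, 2, 3, 4, 5], dtype=float)
        y = np.array([2, 1, 4, 3, 5], dtype=float)
        res = spearman(x, y)
        assert res.rho == pytest.approx(0.8)
        assert res.n == 5

    def test_constant_input_flagged(self):
        res = spearman(np.ones(5), np.arange(5.0))
        assert res.constant_input
        assert np.isnan(res.rho)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 2.0], [2.0, 1.0])
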