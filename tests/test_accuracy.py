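"""Dual and global diagnostic-accuracy statistics against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.optimize import brentq

from riskitems.accuracy import (
    TwoByTwo,
    binary_auc,
    dual_statistics,
    proportion_ci,
    roc_auc,
    two_by_two,
)
from riskitems.errors import DegenerateInputError


def brute_force_auc(scores, outcomes):
    """Exhaustive pairwise Mann-Whitney probability over all pos x neg pairs."""
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes)
    pos = scores[outcomes == 1]
    neg = scores[outcomes == 0]
    diff = pos[:, None] - neg[None, :]
    return ((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (len(pos) * len(neg))


def wilson_by_root_finding(k, n, alpha=0.05):
    """Score interval endpoints as roots of (phat-p)^2 = z^2 p(1-p)/n."""
    z = sps.norm.ppf(1 - alpha / 2)
    phat = k / n

    def f(p):
        return (phat - p) ** 2 - z * z * p * (1 - p) / n

    lo = 0.0 if k == 0 else brentq(f, 1e-15, phat, xtol=1e-12)
    hi = 1.0 if k == n else brentq(f, phat, 1 - 1e-15, xtol=1e-12)
    return lo, hi


class TestTwoByTwo:
    def test_perfect_agreement(self):
        pred = [1] * 10 + [0] * 10
        out = [1] * 10 + [0] * 10
        tab = two_by_two(pred, out)
        assert (tab.tp, tab.fp, tab.fn, tab.tn) == (10, 0, 0, 10)

    def test_missing_prediction_excluded_listwise(self):
        pred = pd.Series([1, None, 0, 1], dtype="object")
        tab = two_by_two(pred, [1, 1, 0, 0])
        assert tab.n_excluded == 1 and tab.n_analysed == 3

    def test_label_predictions_accepted(self):
        tab = two_by_two(pd.Series(["high", "low"]), [1, 0])
        assert (tab.tp, tab.tn) == (1, 1)

    def test_errors(self):
        with pytest.raises(ValueError):
            two_by_two([1, 0], [1])
        with pytest.raises(ValueError):
            two_by_two([1, 0], [1, None])
        with pytest.raises(DegenerateInputError):
            two_by_two(pd.Series([None, None], dtype="object"), [1, 0])

    def test_fixture_lifetime_history_counts(self, fixture_table):
        tab = two_by_two(fixture_table["lifetime_history_self_harm"], fixture_table["outcome"])
        assert (tab.tp, tab.fp, tab.fn, tab.tn) == (134, 225, 11, 113)


class TestDualStatistics:
    def test_lifetime_history_matches_published_percentages(self):
        acc = dual_statistics(TwoByTwo(134, 225, 11, 113))
        assert round(100 * acc.sensitivity, 1) == 92.4
        assert round(100 * acc.specificity, 1) == 33.4

    def test_prior_psychiatric_treatment_matches_published(self):
        acc = dual_statistics(TwoByTwo(124, 185, 21, 153))
        assert round(100 * acc.sensitivity, 1) == 85.5
        assert round(100 * acc.specificity, 1) == 45.3

    def test_perfect_table(self):
        acc = dual_statistics(TwoByTwo(10, 0, 0, 10))
        assert acc.sensitivity == acc.specificity == acc.ppv == acc.npv == 1.0
        assert acc.lr_neg == 0.0 and math.isnan(acc.lr_pos)  # spec=1 -> LR+ undefined

    def test_undefined_ppv_is_nan_not_error(self):
        acc = dual_statistics(TwoByTwo(0, 0, 5, 5))
        assert math.isnan(acc.ppv)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            dual_statistics(TwoByTwo(5, 0, 5, 0))

    def test_cis_contain_point_estimates(self):
        acc = dual_statistics(TwoByTwo(124, 185, 21, 153))
        for val, ci in [
            (acc.sensitivity, acc.sensitivity_ci),
            (acc.specificity, acc.specificity_ci),
            (acc.ppv, acc.ppv_ci),
            (acc.npv, acc.npv_ci),
            (acc.lr_pos, acc.lr_pos_ci),
            (acc.lr_neg, acc.lr_neg_ci),
        ]:
            assert ci[0] <= val <= ci[1]

    @given(
        tp=st.integers(0, 60),
        fp=st.integers(0, 60),
        fn=st.integers(0, 60),
        tn=st.integers(0, 60),
    )
    def test_ppv_equals_bayes_form(self, tp, fp, fn, tn):
        if tp + fn == 0 or fp + tn == 0 or tp + fp == 0:
            return
        acc = dual_statistics(TwoByTwo(tp, fp, fn, tn))
        n = tp + fp + fn + tn
        pi = (tp + fn) / n
        bayes = (acc.sensitivity * pi) / (
            acc.sensitivity * pi + (1 - acc.specificity) * (1 - pi)
        )
        assert acc.ppv == pytest.approx(bayes, abs=1e-12)


class TestProportionCI:
    def test_wilson_zero_successes_lower_bound_is_zero(self):
        lo, hi = proportion_ci(0, 10, "wilson")
        assert lo == 0.0 and 0 < hi < 1

    def test_clopper_pearson_full_successes_upper_bound_is_one(self):
        lo, hi = proportion_ci(10, 10, "clopper-pearson")
        assert hi == 1.0 and 0 < lo < 1

    @pytest.mark.parametrize("k,n", [(145, 483), (1, 50), (250, 483), (482, 483)])
    def test_wilson_matches_root_finding_oracle(self, k, n):
        lo, hi = proportion_ci(k, n, "wilson")
        olo, ohi = wilson_by_root_finding(k, n)
        assert lo == pytest.approx(olo, abs=1e-6)
        assert hi == pytest.approx(ohi, abs=1e-6)

    def test_wald_is_symmetric_about_phat(self):
        lo, hi = proportion_ci(30, 100, "wald")
        assert (lo + hi) / 2 == pytest.approx(0.30, abs=1e-12)

    def test_errors(self):
        with pytest.raises(DegenerateInputError):
            proportion_ci(0, 0)
        with pytest.raises(ValueError):
            proportion_ci(5, 4)
        with pytest.raises(ValueError):
            proportion_ci(1, 10, "magic")


class TestRocAuc:
    def test_constant_scores_give_half(self):
        res = roc_auc([3.0] * 20, [1] * 8 + [0] * 12)
        assert res.auc == 0.5

    def test_fixture_binary_item_published_auc(self, fixture_table):
        res = roc_auc(fixture_table["prior_psychiatric_treatment"], fixture_table["outcome"])
        assert round(res.auc, 2) == 0.65

    def test_matches_exhaustive_pairwise_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(10, 120))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            x = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            assert roc_auc(x, y).auc == pytest.approx(brute_force_auc(x, y), abs=1e-12)

    def test_cross_checked_against_scikit_learn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(21)
        for _ in range(10):
            n = int(rng.integers(20, 200))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            x = rng.integers(0, 8, size=n).astype(float)
            assert roc_auc(x, y).auc == pytest.approx(roc_auc_score(y, x), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=80)
        y = rng.integers(0, 2, size=80)
        a = roc_auc(x, y).auc
        assert roc_auc(np.exp(3 * x) + 1, y).auc == pytest.approx(a, abs=1e-12)

    def test_sign_reversal_flips_auc(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=60)
        y = np.r_[np.ones(20, int), np.zeros(40, int)]
        assert roc_auc(-x, y).auc == pytest.approx(1 - roc_auc(x, y).auc, abs=1e-12)

    def test_missing_scores_excluded(self):
        x = pd.Series([1.0, None, 0.0, 1.0])
        res = roc_auc(x, [1, 1, 0, 0])
        assert res.n_pos + res.n_neg == 3

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_ci_within_unit_interval(self):
        res = roc_auc([0, 1, 0, 1, 1, 0], [0, 1, 0, 1, 0, 1])
        assert 0 <= res.ci[0] <= res.auc <= res.ci[1] <= 1


class TestBinaryAuc:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((124, 185, 21, 153), 0.65),  # prior psychiatric treatment
            ((124, 186, 21, 152), 0.65),  # previous attempt or psychiatric care
            ((10, 0, 0, 10), 1.0),
        ],
    )
    def test_published_binary_aucs(self, counts, expected):
        assert round(binary_auc(TwoByTwo(*counts)), 2) == expected

    @given(
        tp=st.integers(0, 40),
        fp=st.integers(0, 40),
        fn=st.integers(0, 40),
        tn=st.integers(0, 40),
    )
    def test_identical_to_roc_on_expanded_binary_scores(self, tp, fp, fn, tn):
        if tp + fn == 0 or fp + tn == 0:
            return
        scores = [1] * tp + [0] * fn + [1] * fp + [0] * tn
        outcomes = [1] * (tp + fn) + [0] * (fp + tn)
        tab = TwoByTwo(tp, fp, fn, tn)
        assert binary_auc(tab) == pytest.approx(roc_auc(scores, outcomes).auc, abs=1e-12)
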