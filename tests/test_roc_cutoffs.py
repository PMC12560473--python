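"""ROC/AUC machinery, Wilson intervals, likelihood ratios, cutoff tables."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import norm

from sdc_glioma import (
    auc_from_mann_whitney,
    cutoff_table,
    delong_auc_ci,
    likelihood_ratio,
    roc,
    wilson_brown_ci,
    wilson_ci,
)
from sdc_glioma.roc import candidate_thresholds


def brute_force_auc(values, labels):
    """Pairwise-comparison oracle: mean over all (positive, negative) pairs
    of 1[p > n] + 0.5 * 1[p == n]."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = values[labels == 1]
    neg = values[labels == 0]
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean()


class TestROC:
    def test_perfect_separation(self):
        r = roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0
        assert r.fpr[0] == 0 and r.tpr[-1] == 1

    def test_curve_endpoints_and_monotonicity(self, rng):
        v = rng.normal(size=40)
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        r = roc(v, y)
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)

    def test_auc_equals_mann_whitney_oracle_on_random_instances(self, rng):
        """Rank-statistic identity on 100 random instances, with ties."""
        for _ in range(100):
            n1, n2 = rng.integers(2, 25, size=2)
            vals = np.round(rng.normal(size=n1 + n2), 1)  # force ties
            y = np.r_[np.ones(n1, int), np.zeros(n2, int)]
            want = brute_force_auc(vals, y)
            assert roc(vals, y).auc == pytest.approx(want, abs=1e-12)
            assert auc_from_mann_whitney(vals, y) == pytest.approx(
                want, abs=1e-12)

    def test_complement_orientation_tie_free(self, rng):
        v = rng.permutation(60) / 7.0
        y = np.r_[np.ones(25, int), np.zeros(35, int)]
        a1 = roc(v, y).auc
        a2 = roc(-v, y).auc
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)
        assert roc(v, y, positive_direction="less").auc == pytest.approx(a2)

    def test_invariance_under_monotone_transform(self, rng):
        v = rng.normal(size=50)
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        a = roc(v, y).auc
        assert roc(np.exp(v), y).auc == pytest.approx(a, abs=1e-12)
        assert roc(v ** 3, y).auc == pytest.approx(a, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc([1, 2, 3], [1, 1, 1])

    def test_binormal_recovery(self, rng):
        """Large-sample AUC approaches Phi(dmu / sqrt(s1^2 + s2^2))."""
        n = 20000
        a = rng.normal(0.339, 0.055, n)
        b = rng.normal(0.437, 0.097, n)
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        want = norm.cdf((0.437 - 0.339) / math.hypot(0.055, 0.097))
        assert roc(np.r_[a, b], y).auc == pytest.approx(want, abs=0.01)


PRINTED_WILSON = [
    # (successes, n, lo%, hi%) -- plain Wilson rows of the cutoff table
    (25, 33, 58.98, 87.17), (23, 30, 59.07, 88.21),
    (27, 33, 65.61, 91.39), (22, 30, 55.55, 85.82),
    (28, 33, 69.08, 93.35), (21, 30, 52.12, 83.34),
    (30, 33, 76.43, 96.86), (18, 30, 42.32, 75.41),
    (26, 35, 57.93, 85.84), (28, 35, 64.11, 89.96),
    (12, 15, 54.81, 92.95), (30, 35, 70.62, 93.74),
    (32, 35, 77.62, 97.04), (11, 15, 48.05, 89.10),
]


class TestWilson:
    @pytest.mark.parametrize("k,n,lo,hi", PRINTED_WILSON)
    def test_printed_bounds_to_two_decimals(self, k, n, lo, hi):
        got = wilson_ci(k, n)
        assert round(got[0], 2) == pytest.approx(lo)
        assert round(got[1], 2) == pytest.approx(hi)

    def test_zero_successes_lower_bound_is_zero(self):
        lo, hi = wilson_ci(0, 10)
        assert lo == 0.0 and hi > 0

    def test_contains_point_estimate_and_narrows_in_n(self):
        for k, n in [(3, 10), (7, 9), (50, 80)]:
            lo, hi = wilson_ci(k, n)
            assert lo <= 100 * k / n <= hi
        w = [np.diff(wilson_ci(7 * m, 10 * m))[0] for m in (1, 4, 16)]
        assert w[0] > w[1] > w[2]

    @pytest.mark.parametrize("k,n,lo,hi", [
        (32, 33, 84.68, 99.84),   # boundary rows: Poisson-adjusted upper
        (34, 35, 85.47, 99.85),
    ])
    def test_boundary_adjusted_bounds(self, k, n, lo, hi):
        got = wilson_brown_ci(k, n)
        assert round(got[0], 2) == pytest.approx(lo)
        assert round(got[1], 2) == pytest.approx(hi)

    def test_hybrid_equals_plain_away_from_boundary(self):
        for k, n in [(21, 30), (30, 33), (5, 35)]:
            assert wilson_brown_ci(k, n) == wilson_ci(k, n)


class TestLikelihoodRatio:
    def test_uninformative_test(self):
        assert likelihood_ratio(0.5, 0.5) == 1.0

    @pytest.mark.parametrize("sens,spec,lr,digits", [
        (Fraction(23, 30), Fraction(25, 33), 3.163, 3),
        (Fraction(22, 30), Fraction(27, 33), 4.033, 3),
        (Fraction(21, 30), Fraction(28, 33), 4.62, 2),
        (Fraction(21, 30), Fraction(30, 33), 7.7, 1),
        (Fraction(18, 30), Fraction(32, 33), 19.8, 1),
        (Fraction(13, 15), Fraction(26, 35), 3.370, 3),
        (Fraction(12, 15), Fraction(28, 35), 4.000, 3),
        (Fraction(12, 15), Fraction(30, 35), 5.600, 3),
        (Fraction(11, 15), Fraction(32, 35), 8.556, 3),
        (Fraction(11, 15), Fraction(34, 35), 25.67, 2),
    ])
    def test_exact_fraction_rows(self, sens, spec, lr, digits):
        """Count-fraction LRs match table display at its printed precision;
        rounded-percentage inputs would get some of these wrong (25.64)."""
        assert round(likelihood_ratio(sens, spec), digits) == lr

    def test_perfect_specificity_is_infinite(self):
        assert likelihood_ratio(Fraction(1, 2), Fraction(1, 1)) == math.inf


class TestCutoffTable:
    def test_fully_separated_threshold(self):
        rows = cutoff_table([0.45, 0.50, 0.30, 0.35], [1, 1, 0, 0],
                            thresholds=[0.40])
        r = rows[0]
        assert r.sensitivity == 100.0 and r.specificity == 100.0
        assert r.likelihood_ratio == math.inf

    def test_auto_thresholds_are_midpoints(self):
        v = [0.1, 0.2, 0.2, 0.4]
        assert np.allclose(candidate_thresholds(v), [0.15, 0.3])

    def test_counts_and_degenerate_out_of_range_rows(self, rng):
        v = rng.normal(size=30)
        y = np.r_[np.ones(10, int), np.zeros(20, int)]
        rows = cutoff_table(v, y, thresholds=[v.min() - 1, v.max() + 1])
        low, high = rows
        assert low.sensitivity == 100.0 and low.specificity == 0.0
        assert high.sensitivity == 0.0 and high.specificity == 100.0
        for r in rows:
            assert r.tp + r.fn == 10 and r.tn + r.fp == 20

    def test_strict_greater_rule(self):
        rows = cutoff_table([1.0, 2.0], [0, 1], thresholds=[1.0])
        # value exactly at threshold is classified negative
        assert rows[0].specificity == 100.0
        assert rows[0].sensitivity == 100.0

    def test_ci_bounds_bracket_point_estimates(self, rng):
        v = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        for r in cutoff_table(v, y):
            assert r.sens_ci[0] <= r.sensitivity <= r.sens_ci[1]
            assert r.spec_ci[0] <= r.specificity <= r.spec_ci[1]


class TestDeLong:
    def test_ci_contains_auc_and_covers_binormal_truth(self, rng):
        truth = norm.cdf((0.437 - 0.339) / math.hypot(0.055, 0.097))
        hits = 0
        for _ in range(50):
            a = rng.normal(0.339, 0.055, 33)
            b = rng.normal(0.437, 0.097, 30)
            v = np.r_[a, b]
            y = np.r_[np.zeros(33, int), np.ones(30, int)]
            auc, lo, hi = delong_auc_ci(v, y)
            assert lo <= auc <= hi
            hits += lo <= truth <= hi
        assert hits >= 40   # ~95% nominal coverage, generous floor
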