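"""Metric definitions, calibration, conformal bands, tertile errors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odorkit.evaluation import (
    classification_report,
    conformal_band,
    coverage,
    order_quantile,
    regression_report,
    tertile_rmse,
)


class TestClassificationReport:
    def test_perfect_predictions(self):
        y = ["neg", "pos"] * 10
        p = np.array([0.0, 1.0] * 10)
        rep = classification_report(y, p, labels=["neg", "pos"])
        assert rep.metrics["macro_f1"] == 1.0
        assert rep.metrics["brier"] == 0.0
        assert np.allclose(rep.confusion, np.eye(2))

    def test_hand_computed_macro_f1(self):
        """TP=2, FP=1, FN=1, TN=6 → macro-F1 = ((2/3)+(6/7))/2 ≈ 0.7619."""
        y = ["pos"] * 3 + ["neg"] * 7
        p = np.array([0.9, 0.9, 0.1] + [0.9] + [0.1] * 6)
        rep = classification_report(y, p, labels=["neg", "pos"])
        assert rep.metrics["macro_f1"] == pytest.approx(((2 / 3) + (6 / 7)) / 2)
        assert rep.metrics["accuracy"] == pytest.approx(0.8)

    def test_constant_probability_ap_equals_prevalence(self):
        """With an uninformative constant score, average precision collapses
        to the positive-class prevalence baseline."""
        y = ["pos"] * 93 + ["neg"] * 7
        p = np.full(100, 0.5)
        rep = classification_report(y, p, labels=["neg", "pos"])
        assert rep.metrics["ap"] == pytest.approx(0.93)

    def test_single_class_auc_is_nan_marker(self):
        rep = classification_report(["pos"] * 5, np.full(5, 0.9), labels=["neg", "pos"])
        assert math.isnan(rep.metrics["auc"])
        assert math.isnan(rep.metrics["ap"])

    def test_confusion_rows_sum_to_one(self, rng):
        y = rng.choice(["neg", "pos"], size=200, p=[0.2, 0.8])
        p = rng.random(200)
        rep = classification_report(y, p, labels=["neg", "pos"])
        assert np.allclose(rep.confusion.sum(axis=1), 1.0)

    def test_weighted_f1_bounded_by_class_f1s(self, rng):
        y = rng.choice(["neg", "pos"], size=300, p=[0.3, 0.7])
        p = np.clip(rng.normal(0.6, 0.3, 300), 0, 1)
        rep = classification_report(y, p, labels=["neg", "pos"])
        from sklearn.metrics import f1_score

        y_pred = np.where(p >= 0.5, "pos", "neg")
        per_class = f1_score(y, y_pred, average=None, labels=["neg", "pos"])
        assert min(per_class) - 1e-12 <= rep.metrics["weighted_f1"] <= max(per_class) + 1e-12

    def test_calibration_bins_cover_all_points(self, rng):
        p = rng.random(500)
        y = (rng.random(500) < p).astype(int)
        rep = classification_report(y, p, labels=[0, 1])
        assert sum(rep.calibration["count"]) == 500


class TestRegressionReport:
    def test_identity(self):
        rep = regression_report([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.metrics["r2"] == 1.0
        assert rep.metrics["rmse"] == 0.0

    def test_hand_arithmetic(self):
        rep = regression_report([0.0, 1.0, 2.0], [0.0, 1.0, 3.0])
        assert rep.metrics["rmse"] == pytest.approx(math.sqrt(1 / 3))

    def test_mean_predictor_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        rep = regression_report(y, np.full(4, y.mean()))
        assert rep.metrics["r2"] == pytest.approx(0.0)

    def test_constant_target_flagged(self):
        rep = regression_report([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert math.isnan(rep.metrics["r2"])


class TestTertiles:
    def test_exact_predictions_zero_everywhere(self):
        y = np.arange(9, dtype=float)
        assert tertile_rmse(y, y) == (0.0, 0.0, 0.0)

    def test_error_localized_to_top_stratum(self):
        y = np.arange(9, dtype=float)
        yhat = y.copy()
        yhat[-3:] += 2.0
        low, mid, high = tertile_rmse(y, yhat)
        assert low == 0.0 and mid == 0.0 and high == pytest.approx(2.0)

    def test_constant_offset(self):
        y = np.arange(1, 10, dtype=float)
        low, mid, high = tertile_rmse(y, y + 1)
        assert (low, mid, high) == (1.0, 1.0, 1.0)

    def test_tied_quantiles_report_nan_stratum(self):
        y = np.array([1.0] * 8 + [2.0])
        low, mid, high = tertile_rmse(y, y)
        assert math.isnan(mid)


class TestConformal:
    def test_zero_residuals(self):
        band = conformal_band(np.zeros(100))
        assert band.q == 0.0
        assert coverage(np.ones(10), np.ones(10), band.q) == 1.0

    def test_order_statistic_rule(self):
        band = conformal_band(np.arange(1, 101, dtype=float))
        assert band.q == 95.0

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            conformal_band(np.ones(5))

    def test_disjoint_calibration_coverage_is_near_nominal(self):
        """Monte-Carlo conformal validity: with additive Gaussian noise and
        disjoint calibration/evaluation splits of 500 points each, coverage
        concentrates near the nominal 95% across 20 seeds."""
        covs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y_cal = rng.normal(size=500)
            y_eval = rng.normal(size=500)
            band = conformal_band(y_cal - 0.0)
            covs.append(coverage(y_eval, np.zeros(500), band.q))
        assert 0.92 <= float(np.mean(covs)) <= 0.98

    @given(st.floats(0.0, 5.0), st.floats(0.0, 5.0))
    @settings(max_examples=30, deadline=None)
    def test_coverage_monotone_in_q(self, q1, q2):
        rng = np.random.default_rng(11)
        y = rng.normal(size=50)
        lo, hi = sorted((q1, q2))
        assert coverage(y, np.zeros(50), lo) <= coverage(y, np.zeros(50), hi)


class TestPermutationInvariance:
    def test_metrics_invariant_to_row_permutation(self, rng):
        y = rng.choice(["neg", "pos"], size=100)
        p = rng.random(100)
        perm = rng.permutation(100)
        a = classification_report(y, p, labels=["neg", "pos"]).metrics
        b = classification_report(y[perm], p[perm], labels=["neg", "pos"]).metrics
        for k in a:
            if not (isinstance(a[k], float) and math.isnan(a[k])):
                assert a[k] == pytest.approx(b[k]), k


def test_order_quantile_higher_side():
    assert order_quantile(np.array([3.0, 1.0, 2.0]), 0.5) == 2.0
    assert order_quantile(np.arange(1, 101, dtype=float), 0.95) == 95.0
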