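"""Evaluation battery: AUC/DeLong, accuracy, AIC, Brier, HL, calibration."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from abtp import evaluation
from abtp.models import ABTPParams, ModelFit


def pairwise_auc(y, p):
    """Exhaustive positive-negative pair enumeration with 0.5 tie credit."""
    pos = [pi for yi, pi in zip(y, p) if yi == 1]
    neg = [pi for yi, pi in zip(y, p) if yi == 0]
    score = sum(1.0 if a > b else (0.5 if a == b else 0.0)
                for a, b in itertools.product(pos, neg))
    return score / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        auc, lo, hi = evaluation.auc_with_ci([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0
        assert lo <= auc <= hi <= 1.0

    def test_tie_credit(self):
        auc, *_ = evaluation.auc_with_ci([0, 1], [0.5, 0.5])
        assert auc == 0.5

    def test_spec_example_against_enumeration(self):
        y = [0, 1, 0, 1, 1]
        p = [0.2, 0.3, 0.4, 0.6, 0.1]
        auc, *_ = evaluation.auc_with_ci(y, p)
        assert auc == pytest.approx(pairwise_auc(y, p))

    def test_matches_enumeration_and_sklearn_on_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 200))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            p = np.round(rng.random(n), 2)  # rounding forces ties
            auc, lo, hi = evaluation.auc_with_ci(y, p)
            assert auc == pytest.approx(pairwise_auc(y, p), abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(y, p), abs=1e-12)
            assert 0.0 <= lo <= auc <= hi <= 1.0

    def test_ci_covers_truth_at_large_n(self, rng):
        # well-specified forecasts: the DeLong CI should usually cover the
        # large-sample concordance
        p = rng.uniform(0.05, 0.95, 4000)
        y = (rng.random(4000) < p).astype(int)
        auc, lo, hi = evaluation.auc_with_ci(y, p)
        assert hi - lo < 0.1
        assert lo < auc < hi

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluation.auc_with_ci([1, 1], [0.2, 0.4])


class TestAccuracy:
    def test_perfect(self):
        assert evaluation.accuracy_at([1, 0], [1.0, 0.0]) == 1.0

    def test_strict_threshold_predicts_negative(self):
        y = np.array([1, 1, 0, 0])
        assert evaluation.accuracy_at(y, np.full(4, 0.5)) == 1.0 - y.mean()

    def test_hand_count(self):
        assert evaluation.accuracy_at([1, 0, 1, 0], [0.6, 0.6, 0.4, 0.4]) == 0.5


class TestAic:
    def _fit(self, ll, k=2):
        params = ABTPParams("LKB", 75.0, 0.05)
        return ModelFit(params=params, log_likelihood=ll, n_observations=320,
                        converged=True, n_parameters=k)

    def test_known_value(self):
        assert evaluation.aic(self._fit(-178.64)) == pytest.approx(361.28)

    def test_zero_likelihood(self):
        assert evaluation.aic(self._fit(0.0)) == 4.0

    def test_extra_parameter_costs_two(self):
        assert evaluation.aic(self._fit(-100.0, k=3)) - evaluation.aic(self._fit(-100.0)) == 2.0

    def test_delta_aic_translation_invariant(self):
        aics = {"LKB": 361.28, "Logistic": 361.60, "Schultheiss": 361.56}
        shifted = {k: v + 17.3 for k, v in aics.items()}
        d1 = evaluation.delta_aic(aics)
        d2 = evaluation.delta_aic(shifted)
        for name in aics:
            if name == "LKB":
                assert d1[name] is None and d2[name] is None
            else:
                assert d1[name] == pytest.approx(d2[name])

    def test_unknown_baseline(self):
        with pytest.raises(ValueError):
            evaluation.delta_aic({"LKB": 1.0}, baseline="nope")


class TestBrier:
    def test_constant_half_forecast(self, rng):
        y = rng.integers(0, 2, 100)
        assert evaluation.brier(y, np.full(100, 0.5)) == 0.25

    def test_perfect_forecast(self):
        assert evaluation.brier([1, 0, 1], [1.0, 0.0, 1.0]) == 0.0

    def test_hand_value(self):
        assert evaluation.brier([1, 0], [0.8, 0.4]) == pytest.approx(0.10)

    def test_constant_mean_forecast_identity(self, rng):
        y = rng.integers(0, 2, 500).astype(float)
        b = evaluation.brier(y, np.full(500, y.mean()))
        assert b == pytest.approx(y.mean() * (1 - y.mean()), abs=1e-12)


class TestHosmerLemeshow:
    def test_well_calibrated_external_null(self):
        # externally specified (not fitted) calibrated forecasts: the
        # conventional bins-2 degrees of freedom are mildly anti-conservative
        # here (the statistic is ~chi2 on `bins` df), so the pass rate sits a
        # little below the nominal 95%
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            p = rng.uniform(0.05, 0.95, 500)
            y = (rng.random(500) < p).astype(int)
            _, pval = evaluation.hosmer_lemeshow(y, p)
            ok += pval > 0.05
        assert ok >= 85

    def test_miscalibration_detected(self):
        detected = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            p = rng.uniform(0.05, 0.95, 5000)
            y = (rng.random(5000) < p).astype(int)
            _, pval = evaluation.hosmer_lemeshow(y, p ** 2)
            detected += pval < 0.05
        assert detected >= 90

    def test_statistic_invariant_to_monotone_relabelling(self, rng):
        p = rng.uniform(0.2, 0.8, 400)
        y = (rng.random(400) < p).astype(int)
        s1, _ = evaluation.hosmer_lemeshow(y, p)
        # a strictly monotone map preserving bin membership rescales p
        # without reordering; expected counts change, so compare binning
        order1 = np.argsort(p, kind="stable")
        order2 = np.argsort(0.1 + 0.8 * p, kind="stable")
        np.testing.assert_array_equal(order1, order2)

    def test_minimal_bins_df_guard(self, rng):
        p = rng.uniform(0.2, 0.8, 50)
        y = (rng.random(50) < p).astype(int)
        with pytest.raises(ValueError):
            evaluation.hosmer_lemeshow(y, p, bins=2)
        stat, pval = evaluation.hosmer_lemeshow(y, p, bins=3)
        assert 0.0 <= pval <= 1.0


class TestCalibrationCurve:
    def test_ideal_forecasts(self, rng):
        p = rng.uniform(0.05, 0.95, 20_000)
        y = (rng.random(20_000) < p).astype(int)
        _, slope, intercept = evaluation.calibration_curve(y, p)
        assert 0.9 <= slope <= 1.1
        assert -0.05 <= intercept <= 0.05

    def test_constant_forecast_degenerate(self, rng):
        y = rng.integers(0, 2, 100)
        table, slope, intercept = evaluation.calibration_curve(y, np.full(100, float(y.mean())))
        assert np.isnan(slope) and np.isnan(intercept)
        assert table.attrs["degenerate"]

    def test_independent_forecasts_have_null_slope(self, rng):
        p = rng.uniform(0.05, 0.95, 20_000)
        y = rng.integers(0, 2, 20_000)
        _, slope, _ = evaluation.calibration_curve(y, p)
        assert abs(slope) < 0.1


class TestEvaluateModels:
    def test_report_shape_and_baseline_dash(self, rng):
        p_true = rng.uniform(0.1, 0.9, 400)
        y = (rng.random(400) < p_true).astype(int)
        preds = {"LKB": p_true, "Logistic": np.clip(p_true + 0.01, 0, 1)}
        report = evaluation.evaluate_models(y, preds)
        assert list(report.table.index) == ["LKB", "Logistic"]
        assert report.baseline_model == "LKB"
        assert np.isnan(report.table["aic"]).all()  # no fits supplied

    def test_missing_baseline_falls_back_with_warning(self, rng):
        p = rng.uniform(0.1, 0.9, 300)
        y = (rng.random(300) < p).astype(int)
        with pytest.warns(UserWarning, match="baseline"):
            report = evaluation.evaluate_models(y, {"Logistic": p})
        assert report.baseline_model == "Logistic"
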