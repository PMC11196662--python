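"""ABTP curve families, likelihood, MLE fitting and TTq inversion."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import integrate, special

from abtp import models
from abtp.herd import generate_labels_direct
from abtp.models import (ABTPParams, fit_abtp, invert_ttq, log_likelihood,
                         predict, prob_lkb, prob_logistic, prob_poisson,
                         prob_schultheiss)

PARAM_STRATEGY = st.tuples(
    st.sampled_from(models.FAMILIES),
    st.floats(50.0, 100.0),                  # tn50
    st.floats(0.02, 2.0),                    # shape (valid for every family)
)


class TestCurves:
    def test_lkb_one_sigma_point_matches_gaussian_quadrature(self):
        # P(tn50*(1+m)) = Phi(1); oracle = numerical integration of the density
        phi1, _ = integrate.quad(lambda t: math.exp(-t * t / 2) / math.sqrt(2 * math.pi),
                                 -np.inf, 1.0)
        assert prob_lkb(75.0 * 1.05, 75.0, 0.05) == pytest.approx(phi1, abs=1e-10)

    def test_lkb_limits(self):
        assert prob_lkb(-1e6, 75.0, 0.05) == pytest.approx(0.0, abs=1e-12)
        assert prob_lkb(1e6, 75.0, 0.05) == pytest.approx(1.0, abs=1e-12)

    def test_logistic_known_odds(self):
        # s = ln 3  =>  p = 1/(1 + 1/3) = 0.75
        assert prob_logistic(math.log(3.0), 0.0, 1.0) == pytest.approx(0.75)
        assert prob_logistic(75.0, -22.5, 0.30) == pytest.approx(0.5)

    def test_logistic_extreme_argument_safe(self):
        p = prob_logistic(-745.0, 0.0, 1.0)
        assert 0.0 <= p < 5e-323

    def test_schultheiss_double_tn50(self):
        assert prob_schultheiss(150.0, 75.0, 1.0) == pytest.approx(2.0 / 3.0)

    def test_schultheiss_step_limit(self):
        assert prob_schultheiss(76.0, 75.0, 5000.0) > 0.999999

    def test_schultheiss_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            prob_schultheiss(0.0, 75.0, 1.0)

    def test_poisson_oracle_value(self):
        # gamma=1, n=1.1*tn50: 2^(-exp(-e/10))
        expected = 2.0 ** (-math.exp(-math.e * 0.1))
        assert prob_poisson(82.5, 75.0, 1.0) == pytest.approx(expected, abs=1e-12)

    def test_poisson_limits(self):
        assert prob_poisson(1e9, 75.0, 1.0) == pytest.approx(1.0, abs=1e-12)
        # the n -> 0+ floor is 2^(-exp(e*gamma)), not zero
        assert prob_poisson(1e-12, 75.0, 1.0) == pytest.approx(
            2.0 ** (-math.exp(math.e)), rel=1e-9)

    @pytest.mark.parametrize("family", models.FAMILIES)
    def test_invalid_shape_rejected(self, family):
        with pytest.raises(ValueError):
            ABTPParams(family, 75.0, 0.0 if family != "Logistic" else 0.0)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(params=PARAM_STRATEGY)
    def test_half_probability_at_tn50(self, params):
        family, tn50, shape = params
        assert float(predict(ABTPParams(family, tn50, shape), tn50)) == pytest.approx(0.5, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(params=PARAM_STRATEGY)
    def test_monotone_increasing_on_grid(self, params):
        family, tn50, shape = params
        grid = np.linspace(0.5 * tn50, 1.5 * tn50, 200)
        p = np.asarray(predict(ABTPParams(family, tn50, shape), grid))
        # non-decreasing everywhere (flat tails may underflow to equal
        # doubles) and strictly increasing through the centre
        assert np.all(np.diff(p) >= 0)
        assert p[-1] > p[0]


class TestLogLikelihood:
    def test_known_values(self):
        assert log_likelihood([1], [0.5]) == pytest.approx(math.log(0.5))
        assert log_likelihood([1, 0], [0.5, 0.5]) == pytest.approx(2 * math.log(0.5))

    def test_perfect_prediction_near_zero(self):
        y = np.array([1.0, 0.0, 1.0])
        assert abs(log_likelihood(y, y)) < 3 * 1e-11

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            log_likelihood([1, 0], [0.5])


class TestFitAbtp:
    def test_logistic_parameter_recovery(self, logistic_truth, rng):
        thi = rng.uniform(55, 95, 5000)
        y = generate_labels_direct(thi, logistic_truth, seed=99)
        fit = fit_abtp("Logistic", thi, y)
        assert fit.converged
        assert fit.params.tn50 == pytest.approx(75.0, abs=1.0)
        assert fit.params.beta1 == pytest.approx(0.30, rel=0.2)

    def test_noiseless_step_lkb(self):
        thi = np.linspace(55, 95, 400)
        y = (thi > 75).astype(int)
        fit = fit_abtp("LKB", thi, y)
        assert fit.params.tn50 == pytest.approx(75.0, abs=1.0)
        # separable data drives the slope toward its lower search bound
        assert fit.params.shape < 0.01

    def test_refit_is_bit_identical(self, logistic_truth, rng):
        thi = rng.uniform(55, 95, 320)
        y = generate_labels_direct(thi, logistic_truth, seed=5)
        a = fit_abtp("Schultheiss", thi, y)
        b = fit_abtp("Schultheiss", thi, y)
        assert a.params == b.params
        assert a.log_likelihood == b.log_likelihood

    def test_fitted_ll_beats_grid(self, logistic_truth, rng):
        thi = rng.uniform(55, 95, 320)
        y = generate_labels_direct(thi, logistic_truth, seed=6)
        for family in models.FAMILIES:
            fit = fit_abtp(family, thi, y)
            assert fit.log_likelihood >= fit.trace["grid_best_ll"]
            assert fit.log_likelihood <= 0

    @pytest.mark.parametrize("family, shape", [
        ("LKB", 0.05), ("Logistic", 0.30), ("Schultheiss", 25.0), ("Poisson", 1.0),
    ])
    def test_tn50_bias_shrinks_with_sample_size(self, family, shape):
        # simulate from each family itself so the MLE targets the true tn50
        truth = ABTPParams(family, 75.0, shape)
        errors = {}
        for n in (320, 10_000):
            errs = []
            for seed in range(5):
                rng = np.random.default_rng(1000 + seed)
                thi = rng.uniform(55, 95, n)
                y = generate_labels_direct(thi, truth, seed=2000 + seed)
                errs.append(abs(fit_abtp(family, thi, y).params.tn50 - 75.0))
            errors[n] = np.mean(errs)
        assert errors[10_000] < errors[320]
        assert errors[10_000] < 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_abtp("LKB", np.linspace(55, 95, 50), np.zeros(50))


class TestInvertTtq:
    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(params=PARAM_STRATEGY)
    def test_tn50_at_half(self, params):
        family, tn50, shape = params
        assert invert_ttq(ABTPParams(family, tn50, shape), 0.5) == pytest.approx(tn50, rel=1e-9)

    def test_lkb_tt20_closed_form(self):
        # Phi^{-1}(0.2) = -0.8416...; 75 * (1 - 0.8416 * 0.05)
        value = invert_ttq(ABTPParams("LKB", 75.0, 0.05), 0.2)
        assert value == pytest.approx(71.8440, abs=2e-3)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(params=PARAM_STRATEGY, q=st.floats(0.05, 0.95))
    def test_round_trip_identity(self, params, q):
        family, tn50, shape = params
        pars = ABTPParams(family, tn50, shape)
        # restrict to quantiles the curve actually attains on n > 0
        if family == "LKB":
            assume(1.0 + shape * float(special.ndtri(q)) > 1e-3)
        if family == "Poisson":
            assume(q > float(predict(pars, 1e-12)) + 1e-3)
        n_q = invert_ttq(pars, q)
        assert float(predict(pars, n_q)) == pytest.approx(q, abs=1e-6)

    def test_lkb_unreachable_quantile(self):
        with pytest.raises(ValueError):
            invert_ttq(ABTPParams("LKB", 75.0, 2.0), 1e-6)

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.1])
    def test_invalid_q(self, q):
        with pytest.raises(ValueError):
            invert_ttq(ABTPParams("LKB", 75.0, 0.05), q)

    def test_logistic_gamma50(self):
        pars = ABTPParams.from_logistic_coefficients(-22.5, 0.30)
        assert models.logistic_gamma50(pars) == pytest.approx(0.30 * 75.0 / 4.0)
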