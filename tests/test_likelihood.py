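"""Outcome probabilities, convolution integral and joint log-likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trisurv import (
    FamilySpec,
    ModelSpec,
    ParameterVector,
    SurveillanceRecord,
    individual_loglik,
    prob_interval_aa,
    prob_interval_crc,
    prob_right_censored,
    total_loglik,
)
from trisurv.likelihood import convolution_integral, loglik_vector, records_to_frame
from trisurv.distributions import cumulative, density

from conftest import exp_exp_conv_closed_form


class TestOutcomeProbabilities:
    def test_right_censoring_exponential(self, exp_exp_model, exp_exp_psi):
        assert prob_right_censored(exp_exp_model, exp_exp_psi, 10.0) == \
            pytest.approx(np.exp(-0.3), abs=1e-12)
        assert prob_right_censored(exp_exp_model, exp_exp_psi, 0.0) == 1.0
        assert prob_right_censored(exp_exp_model, exp_exp_psi, 1e4) < 1e-100

    def test_interval_probabilities_closed_form(self, exp_exp_model, exp_exp_psi):
        aa = prob_interval_aa(exp_exp_model, exp_exp_psi, 0.0, 10.0)
        crc = prob_interval_crc(exp_exp_model, exp_exp_psi, 0.0, 10.0)
        assert aa == pytest.approx(0.21149, abs=5e-6)
        assert crc == pytest.approx(0.04769, abs=5e-6)

    def test_degenerate_y(self, exp_exp_model):
        # Y far beyond the interval width: no CRC possible, AA takes the mass
        psi = ParameterVector(exp_exp_model, np.array([0.03]), np.array([1e-12]))
        aa = prob_interval_aa(exp_exp_model, psi, 0.0, 10.0)
        crc = prob_interval_crc(exp_exp_model, psi, 0.0, 10.0)
        diff = cumulative(exp_exp_model.spec_x, psi.x, 10.0) - \
            cumulative(exp_exp_model.spec_x, psi.x, 0.0)
        assert aa == pytest.approx(diff, rel=1e-9)
        assert crc == pytest.approx(0.0, abs=1e-10)

    def test_instantaneous_y(self, exp_exp_model):
        # Y ~ instantaneous: every AA becomes CRC within the interval
        psi = ParameterVector(exp_exp_model, np.array([0.03]), np.array([1e6]))
        crc = prob_interval_crc(exp_exp_model, psi, 0.0, 10.0)
        diff = cumulative(exp_exp_model.spec_x, psi.x, 10.0)
        assert crc == pytest.approx(diff, rel=1e-4)

    def test_vanishing_interval(self, exp_exp_model, exp_exp_psi):
        assert prob_interval_aa(exp_exp_model, exp_exp_psi, 5.0, 5.0 + 1e-9) < 1e-8
        assert prob_interval_crc(exp_exp_model, exp_exp_psi, 5.0, 5.0 + 1e-9) < 1e-8

    def test_crc_monotone_in_interval_width(self, weib_weib_model, weib_weib_psi):
        widths = np.linspace(1.0, 25.0, 10)
        vals = [prob_interval_crc(weib_weib_model, weib_weib_psi, 2.0, 2.0 + h)
                for h in widths]
        assert np.all(np.diff(vals) > 0)

    def test_exact_time_rejected(self, exp_exp_model, exp_exp_psi):
        with pytest.raises(ValueError):
            prob_interval_aa(exp_exp_model, exp_exp_psi, 5.0, 5.0)


class TestPartitionIdentity:
    @pytest.mark.parametrize("a,b", [(0.0, 10.0), (2.0, 4.0), (0.0, 1.0),
                                     (5.0, 30.0)])
    def test_exponential(self, exp_exp_model, exp_exp_psi, a, b):
        lhs = prob_interval_aa(exp_exp_model, exp_exp_psi, a, b) \
            + prob_interval_crc(exp_exp_model, exp_exp_psi, a, b) \
            + prob_right_censored(exp_exp_model, exp_exp_psi, b)
        assert lhs == pytest.approx(
            prob_right_censored(exp_exp_model, exp_exp_psi, a), abs=1e-10)

    @pytest.mark.parametrize("a,b", [(0.0, 5.0), (1.5, 8.0), (10.0, 20.0)])
    def test_weibull_with_covariates(self, a, b):
        model = ModelSpec(FamilySpec("weibull", ("w",)),
                          FamilySpec("weibull", ("w",)))
        psi = ParameterVector(model, np.array([1.5, 23.0, 0.6]),
                              np.array([0.8, 28.0, -0.4]))
        w = [0.7]
        lhs = prob_interval_aa(model, psi, a, b, w) \
            + prob_interval_crc(model, psi, a, b, w) \
            + prob_right_censored(model, psi, b, w)
        assert lhs == pytest.approx(prob_right_censored(model, psi, a, w),
                                    abs=1e-8)

    def test_three_outcomes_sum_to_one_from_zero(self, weib_weib_model,
                                                 weib_weib_psi):
        b = 12.0
        total = prob_interval_aa(weib_weib_model, weib_weib_psi, 0.0, b) \
            + prob_interval_crc(weib_weib_model, weib_weib_psi, 0.0, b) \
            + prob_right_censored(weib_weib_model, weib_weib_psi, b)
        assert total == pytest.approx(1.0, abs=1e-10)


class TestConvolutionIntegral:
    @pytest.mark.parametrize("lam1,lam2", [(0.03, 0.04), (0.1, 0.1),
                                           (0.05, 0.05 + 5e-9), (0.3, 0.02)])
    @pytest.mark.parametrize("a,b", [(0.0, 10.0), (2.0, 6.0)])
    def test_exponential_quadrature_vs_closed_form(self, exp_exp_model,
                                                   lam1, lam2, a, b):
        psi = ParameterVector(exp_exp_model, np.array([lam1]), np.array([lam2]))
        aa = prob_interval_aa(exp_exp_model, psi, a, b)
        assert aa == pytest.approx(exp_exp_conv_closed_form(lam1, lam2, a, b),
                                   abs=1e-10)

    def test_constant_density_full_cdf(self):
        # f = c on the interval, G identically 1 -> c * (b - a)
        val = convolution_integral(lambda x: 0.2, lambda y: 1.0, 1.0, 3.0)
        assert val == pytest.approx(0.4, abs=1e-10)

    def test_weibull_weibull_brute_force(self, weib_weib_model, weib_weib_psi):
        # Riemann-sum oracle (midpoint, 10^6 panels) on (0, 5]
        sx, sy = weib_weib_model.spec_x, weib_weib_model.spec_y
        x = (np.arange(1_000_000) + 0.5) * 5.0 / 1_000_000
        riemann = np.sum(density(sx, weib_weib_psi.x, x)
                         * cumulative(sy, weib_weib_psi.y, 5.0 - x)) * 5.0 / 1e6
        val = convolution_integral(
            lambda t: density(sx, weib_weib_psi.x, t),
            lambda t: cumulative(sy, weib_weib_psi.y, t), 0.0, 5.0)
        assert val == pytest.approx(riemann, abs=1e-8)
        assert prob_interval_crc(weib_weib_model, weib_weib_psi, 0.0, 5.0) == \
            pytest.approx(riemann, abs=1e-8)

    def test_invalid_ordering(self):
        with pytest.raises(ValueError):
            convolution_integral(lambda x: 1.0, lambda y: 1.0, 3.0, 2.0)


class TestLogLikelihood:
    def test_right_censored_contribution(self, exp_exp_model, exp_exp_psi):
        rec = SurveillanceRecord(1, 0.0, 10.0, 0, 0)
        assert individual_loglik(exp_exp_model, exp_exp_psi, rec) == \
            pytest.approx(-0.3, abs=1e-10)

    def test_crc_contribution(self, exp_exp_model, exp_exp_psi):
        rec = SurveillanceRecord(1, 0.0, 10.0, 0, 1)
        assert individual_loglik(exp_exp_model, exp_exp_psi, rec) == \
            pytest.approx(np.log(0.04769), abs=1e-4)

    def test_left_censored_uses_interval_from_zero(self, exp_exp_model,
                                                   exp_exp_psi):
        rec = SurveillanceRecord(1, 0.0, 4.0, 1, 0)
        assert rec.left_censored
        assert individual_loglik(exp_exp_model, exp_exp_psi, rec) == \
            pytest.approx(np.log(prob_interval_aa(exp_exp_model, exp_exp_psi,
                                                  0.0, 4.0)), abs=1e-10)

    def test_underflow_gives_minus_inf_not_nan(self, exp_exp_model):
        psi = ParameterVector(exp_exp_model, np.array([500.0]), np.array([1e-9]))
        rec = SurveillanceRecord(1, 0.0, 2000.0, 0, 0)
        val = individual_loglik(exp_exp_model, psi, rec)
        assert val == -np.inf and not np.isnan(val)

    def test_additivity(self, exp_exp_model, exp_exp_psi):
        recs = [SurveillanceRecord(i, 0.0, 10.0, 0, 0) for i in range(2)]
        assert total_loglik(exp_exp_model, exp_exp_psi, recs) == \
            pytest.approx(-0.6, abs=1e-10)

    def test_empty_dataset(self, exp_exp_model, exp_exp_psi):
        assert total_loglik(exp_exp_model, exp_exp_psi, []) == 0.0

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_partition_additivity_random_split(self, seed):
        exp_exp_model = ModelSpec(FamilySpec("exponential"),
                                  FamilySpec("exponential"))
        exp_exp_psi = ParameterVector(exp_exp_model, np.array([0.03]),
                                      np.array([0.04]))
        rng = np.random.default_rng(seed)
        recs = []
        for i in range(12):
            a = rng.uniform(0, 5)
            b = a + rng.uniform(0.5, 10)
            kind = rng.integers(3)
            recs.append(SurveillanceRecord(i, 0.0 if kind == 2 else a, b,
                                           int(kind == 0), int(kind == 1)))
        total = total_loglik(exp_exp_model, exp_exp_psi, recs)
        cut = rng.integers(0, len(recs) + 1)
        split = total_loglik(exp_exp_model, exp_exp_psi, recs[:cut]) + \
            total_loglik(exp_exp_model, exp_exp_psi, recs[cut:])
        assert total == pytest.approx(split, rel=1e-12)

    def test_vectorized_matches_per_record(self, weib_weib_model, weib_weib_psi):
        recs = [SurveillanceRecord(0, 0.0, 3.0, 1, 0),
                SurveillanceRecord(1, 2.0, 9.0, 0, 1),
                SurveillanceRecord(2, 0.0, 14.0, 0, 0),
                SurveillanceRecord(3, 5.0, 6.5, 1, 0)]
        df = records_to_frame(recs)
        vec = loglik_vector(weib_weib_model, weib_weib_psi.to_working(), df)
        scal = [individual_loglik(weib_weib_model, weib_weib_psi, r)
                for r in recs]
        np.testing.assert_allclose(vec, scal, atol=1e-6)


class TestRecordValidation:
    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            SurveillanceRecord(1, 5.0, 5.0, 1, 0)
        with pytest.raises(ValueError):
            SurveillanceRecord(1, -1.0, 5.0, 0, 0)

    def test_double_event_rejected(self):
        with pytest.raises(ValueError):
            SurveillanceRecord(1, 0.0, 5.0, 1, 1)
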