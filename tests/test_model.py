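"""Structural model, covariate multiplier and residual-variance checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import egfrdp as E
from egfrdp.model import ZERO_EFFECTS


def _final_theta():
    return {
        "metformin": 0.029,
        "fbs": -0.0038,
        "arbs": 0.0361,
        "statin": 0.0314,
        "cvd": -0.0925,
    }


REF_COVS = {"metformin": 0.0, "fbs": 7.4, "arbs": 0.0, "statin": 0.0, "cvd": 0.0}


class TestStructuralPredict:
    @pytest.mark.parametrize(
        "t, expected",
        [(0.0, 84.6), (10.0, 84.6 * (1 - 0.041))],
    )
    def test_linear_at_reference_covariates(self, t, expected):
        spec = E.final_model_spec()
        params = E.ParameterSet(s0=84.6, alpha=-0.0041, theta=_final_theta(), sigma_add=6.29)
        pred = E.structural_predict(spec, params, ZERO_EFFECTS, REF_COVS, t)
        assert pred == pytest.approx(expected, rel=1e-12)

    def test_emax_half_maximal_at_s50(self):
        spec = E.ModelSpec(structural="emax")
        params = E.ParameterSet(s0=80.0, smax=-20.0, s50=2.0, sigma_add=1.0)
        assert E.structural_predict(spec, params, ZERO_EFFECTS, {}, 2.0) == pytest.approx(70.0)

    def test_emax_baseline_and_asymptote(self):
        spec = E.ModelSpec(structural="emax")
        params = E.ParameterSet(s0=80.0, smax=-20.0, s50=2.0, sigma_add=1.0)
        t = np.linspace(0.0, 500.0, 2000)
        pred = E.structural_predict(spec, params, ZERO_EFFECTS, {}, t)
        assert pred[0] == pytest.approx(80.0)
        assert np.all(np.diff(pred) < 0)  # monotone toward the asymptote
        assert pred[-1] == pytest.approx(60.0, abs=0.1)

    def test_negative_time_rejected(self, base_spec, base_params):
        with pytest.raises(ValueError, match="non-negative"):
            E.structural_predict(base_spec, base_params, ZERO_EFFECTS, {}, -1.0)

    def test_missing_covariate_named_in_error(self):
        spec = E.final_model_spec()
        params = E.ParameterSet(s0=84.6, alpha=-0.0041, theta=_final_theta(), sigma_add=6.29)
        covs = dict(REF_COVS)
        covs.pop("statin")
        with pytest.raises(KeyError, match="statin"):
            E.structural_predict(spec, params, ZERO_EFFECTS, covs, 1.0)

    @settings(deadline=None, max_examples=60)
    @given(
        eta_s0=st.floats(-3, 3),
        eta_alpha=st.floats(-3, 3),
        t=st.floats(0, 6.6),
    )
    def test_exponential_bsv_preserves_sign(self, eta_s0, eta_alpha, t):
        """S0_i stays positive and the subject rate keeps the sign of alpha."""
        spec = E.base_model_spec()
        params = E.ParameterSet(s0=84.5, alpha=-0.0021, sigma_add=6.46)
        eff = E.SubjectEffects(eta_s0, eta_alpha)
        pred0 = E.structural_predict(spec, params, eff, {}, 0.0)
        assert pred0 > 0
        slope = E.structural_predict(spec, params, eff, {}, 1.0) - pred0
        assert slope <= 0

    def test_median_of_individual_baselines_is_typical_value(self):
        rng = np.random.default_rng(5)
        params = E.default_base_parameters()
        eta = rng.normal(0, np.sqrt(params.omega2_s0), size=10**5)
        s0_i = params.s0 * np.exp(eta)
        # Monte-Carlo error of the median at 1e5 draws
        assert np.median(s0_i) == pytest.approx(params.s0, rel=5e-3)


class TestCovariateMultiplier:
    def test_all_at_reference_is_one(self):
        terms = E.final_model_spec().covariates
        assert E.covariate_multiplier(terms, _final_theta(), REF_COVS) == pytest.approx(1.0)

    def test_single_binary_effect(self):
        terms = (E.CovariateTerm("metformin"),)
        m = E.covariate_multiplier(terms, {"metformin": 0.029}, {"metformin": 1.0})
        assert m == pytest.approx(1.029)

    def test_continuous_centering(self):
        terms = (E.CovariateTerm("fbs", "continuous", 7.4),)
        m = E.covariate_multiplier(terms, {"fbs": -0.0038}, {"fbs": 8.4})
        assert m == pytest.approx(1.0 - 0.0038)

    def test_empty_terms_exactly_one(self):
        assert E.covariate_multiplier((), {}, {}) == 1.0

    def test_nonpositive_multiplier_rejected(self):
        terms = (E.CovariateTerm("cvd"),)
        with pytest.raises(ValueError, match="non-positive"):
            E.covariate_multiplier(terms, {"cvd": -1.5}, {"cvd": 1.0})

    def test_zero_thetas_reduce_to_base_model(self):
        """Nested-model identity: theta=0 covariate model equals the base."""
        spec = E.final_model_spec()
        params = E.ParameterSet(
            s0=84.5, alpha=-0.0021, sigma_add=6.46,
            theta={k: 0.0 for k in _final_theta()},
        )
        covs = {"metformin": 1.0, "fbs": 12.0, "arbs": 1.0, "statin": 0.0, "cvd": 1.0}
        t = np.linspace(0, 6.5, 14)
        with_cov = E.structural_predict(spec, params, ZERO_EFFECTS, covs, t)
        base = E.structural_predict(E.base_model_spec(), params, ZERO_EFFECTS, {}, t)
        np.testing.assert_array_equal(with_cov, base)


class TestResidualVariance:
    def test_additive(self):
        spec = E.base_model_spec()
        params = E.ParameterSet(s0=84.5, sigma_add=6.46)
        assert E.residual_variance(spec, params, 50.0) == pytest.approx(6.46**2)
        assert E.residual_variance(spec, params, 120.0) == pytest.approx(41.7316)

    def test_proportional(self):
        spec = E.ModelSpec(residual="proportional")
        params = E.ParameterSet(s0=84.5, sigma_prop=0.1)
        assert E.residual_variance(spec, params, 80.0) == pytest.approx(64.0)

    def test_combined_reduces_to_additive_at_zero_prop(self):
        spec_c = E.ModelSpec(residual="combined")
        spec_a = E.ModelSpec(residual="additive")
        params = E.ParameterSet(s0=84.5, sigma_add=6.46, sigma_prop=0.0)
        pred = np.array([40.0, 84.5, 130.0])
        np.testing.assert_array_equal(
            E.residual_variance(spec_c, params, pred),
            E.residual_variance(spec_a, params, pred),
        )

    def test_degenerate_sigmas_rejected(self):
        spec = E.ModelSpec(residual="combined")
        params = E.ParameterSet(s0=84.5)
        with pytest.raises(ValueError, match="sigma"):
            E.residual_variance(spec, params, 80.0)


class TestSpecValidation:
    def test_emax_with_covariates_rejected(self):
        with pytest.raises(ValueError, match="linear"):
            E.ModelSpec(structural="emax", covariates=(E.CovariateTerm("cvd"),))

    def test_duplicate_covariates_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            E.ModelSpec(covariates=(E.CovariateTerm("cvd"), E.CovariateTerm("cvd")))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            E.ParameterSet(s0=-5.0)
        with pytest.raises(ValueError):
            E.ParameterSet(s0=80.0, omega2_s0=-0.1)
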