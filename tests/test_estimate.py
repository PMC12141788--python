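"""FOCE-I objective, quadrature oracle, conditional modes, and fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import egfrdp as E
from egfrdp.estimate import quadrature_ofv


def _closed_form_ofv(data, s0, alpha, sigma):
    """Fixed-effects OFV (no random effects, additive error)."""
    total = 0.0
    for s in data.subjects():
        pred = s0 * (1.0 + alpha * s.times)
        total += np.sum((s.dv - pred) ** 2 / sigma**2 + np.log(sigma**2))
    return total


class TestOfvAgainstClosedForm:
    def test_no_random_effects_equals_closed_form(self, small_cohort, base_spec):
        p = E.ParameterSet(s0=84.5, alpha=-0.0021, sigma_add=6.46)
        got = E.marginal_ofv(small_cohort, base_spec, p)
        want = _closed_form_ofv(small_cohort, 84.5, -0.0021, 6.46)
        assert got == pytest.approx(want, abs=1e-8)
        # the quadrature integral degenerates to the same value
        assert quadrature_ofv(small_cohort, base_spec, p) == pytest.approx(want, abs=1e-8)

    def test_doubling_sigma_on_perfect_fit_adds_2n_log2(self, base_spec):
        """With y == pred and omegas 0, OFV = 2n log(sigma); doubling sigma adds 2n log 2."""
        t = np.arange(8) * 0.5
        p1 = E.ParameterSet(s0=80.0, alpha=-0.01, sigma_add=3.0)
        df = pd.DataFrame({"ID": 1, "TIME": t, "DV": 80.0 * (1 - 0.01 * t)})
        data = E.LongitudinalDataset(df)
        o1 = E.marginal_ofv(data, base_spec, p1)
        o2 = E.marginal_ofv(data, base_spec, p1.replace(sigma_add=6.0))
        assert o2 - o1 == pytest.approx(2 * 8 * np.log(2.0), abs=1e-10)

    def test_constant_convention_cancels_in_delta_ofv(self, small_cohort, base_spec, base_params):
        """ΔOFV between nested models is identical with or without n log 2pi."""
        p_null = base_params.replace(alpha=-1e-9)
        for flag in (False, True):
            d = E.marginal_ofv(small_cohort, base_spec, base_params, include_constant=flag)
            d0 = E.marginal_ofv(small_cohort, base_spec, p_null, include_constant=flag)
            if not flag:
                delta_plain = d - d0
            else:
                assert d - d0 == pytest.approx(delta_plain, abs=1e-8)


class TestQuadratureOracle:
    def test_node_convergence(self, base_spec, base_params):
        cfg = E.CohortConfig(n_subjects=2, target_obs=26, seed=55)
        data = E.generate_cohort(cfg)
        p = base_params.replace(omega2_s0=0.04, omega2_alpha=0.25)
        q7 = quadrature_ofv(data, base_spec, p, nodes=7)
        q15 = quadrature_ofv(data, base_spec, p, nodes=15)
        assert abs(q7 - q15) < 1e-3

    def test_foce_matches_quadrature_near_linear(self, base_spec, base_params):
        """FOCE is exact in the linear limit; small omegas keep it within 0.1."""
        cfg = E.CohortConfig(n_subjects=2, target_obs=26, seed=55)
        data = E.generate_cohort(cfg)
        p = base_params.replace(omega2_s0=0.01, omega2_alpha=0.02)
        foce = E.marginal_ofv(data, base_spec, p)
        agq = quadrature_ofv(data, base_spec, p, nodes=15)
        assert abs(foce - agq) < 0.1

    def test_foce_quadrature_agreement_family(self, base_spec):
        """Randomized small instances: |FOCE − AGQ| < 0.5, shrinking with omega."""
        rng = np.random.default_rng(77)
        errs = {0.25: [], 1.0: []}
        for rep in range(4):
            n = int(rng.integers(2, 6))
            cfg = E.CohortConfig(
                n_subjects=n, target_obs=13 * n, seed=int(rng.integers(1, 2**16))
            )
            data = E.generate_cohort(cfg)
            for scale in errs:
                p = E.ParameterSet(
                    s0=84.5, alpha=-0.0021, sigma_add=6.46,
                    omega2_s0=0.04 * scale, omega2_alpha=0.3 * scale,
                )
                err = abs(
                    E.marginal_ofv(data, base_spec, p)
                    - quadrature_ofv(data, base_spec, p, nodes=15)
                )
                errs[scale].append(err)
        assert max(errs[1.0]) < 0.5
        assert np.mean(errs[0.25]) <= np.mean(errs[1.0]) + 0.05

    def test_subject_guard(self, study_cohort, base_spec, base_params):
        with pytest.raises(ValueError, match="subset"):
            quadrature_ofv(study_cohort, base_spec, base_params)


class TestMapEtas:
    def test_zero_for_data_equal_to_population_prediction(self, base_spec, base_params):
        t = np.arange(10) * 0.5
        dv = base_params.s0 * (1.0 + base_params.alpha * t)
        data = E.LongitudinalDataset(pd.DataFrame({"ID": 1, "TIME": t, "DV": dv}))
        etas = E.map_etas(data, base_spec, base_params)
        assert etas[1].eta_s0 == pytest.approx(0.0, abs=1e-6)
        assert etas[1].eta_alpha == pytest.approx(0.0, abs=1e-6)

    def test_flat_prior_limit_is_least_squares(self, base_spec):
        """omega -> inf: the conditional mode approaches the per-subject LS fit."""
        rng = np.random.default_rng(8)
        t = np.arange(12) * 0.5
        true = E.ParameterSet(s0=84.5, alpha=-0.0021, sigma_add=6.46)
        dv = 70.0 * (1.0 - 0.05 * t) + rng.normal(0, 2, size=t.size)
        data = E.LongitudinalDataset(pd.DataFrame({"ID": 1, "TIME": t, "DV": dv}))
        p = true.replace(omega2_s0=1e4, omega2_alpha=1e4)
        etas = E.map_etas(data, base_spec, p)

        def sse(x):
            pred = true.s0 * np.exp(x[0]) * (1.0 + true.alpha * np.exp(x[1]) * t)
            return np.sum((dv - pred) ** 2)

        ls = optimize.minimize(sse, [0.0, 0.0], method="Nelder-Mead",
                               options={"xatol": 1e-10, "fatol": 1e-12}).x
        assert etas[1].eta_s0 == pytest.approx(ls[0], abs=1e-3)
        assert etas[1].eta_alpha == pytest.approx(ls[1], abs=1e-3)

    def test_ebe_shrinkage_monotone_in_sigma(self, medium_cohort, base_spec, base_params):
        """Noisier data pulls the conditional modes toward zero."""
        spreads = []
        for sigma in (2.0, 6.46, 20.0):
            etas = E.map_etas(medium_cohort, base_spec, base_params.replace(sigma_add=sigma))
            spreads.append(np.std([e.eta_s0 for e in etas.values()]))
        assert spreads[0] > spreads[1] > spreads[2]


class TestFitModel:
    def test_fixed_effects_fit_matches_ols(self, base_spec):
        """omegas fixed at 0: the MLE equals pooled OLS of DV on time."""
        rng = np.random.default_rng(21)
        frames = []
        for i in range(30):
            t = np.arange(10) * 0.5
            dv = 85.0 * (1.0 - 0.01 * t) + rng.normal(0, 3, size=t.size)
            frames.append(pd.DataFrame({"ID": i + 1, "TIME": t, "DV": dv}))
        data = E.LongitudinalDataset(pd.concat(frames, ignore_index=True))
        inits = E.ParameterSet(s0=80.0, alpha=-0.005, sigma_add=2.0)
        fit = E.fit_model(data, base_spec, inits)
        t = data.df["TIME"].to_numpy()
        y = data.df["DV"].to_numpy()
        X = np.column_stack([np.ones_like(t), t])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma_mle = float(np.sqrt(np.mean((y - X @ beta) ** 2)))
        assert fit.estimates.s0 == pytest.approx(beta[0], rel=1e-4)
        assert fit.estimates.alpha == pytest.approx(beta[1] / beta[0], rel=1e-3)
        assert fit.estimates.sigma_add == pytest.approx(sigma_mle, rel=1e-3)

    def test_subject_order_invariance(self, medium_cohort, base_spec, base_params):
        shuffled = medium_cohort.df.sort_values(
            ["ID", "TIME"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        a = E.marginal_ofv(medium_cohort, base_spec, base_params)
        b = E.marginal_ofv(E.LongitudinalDataset(shuffled), base_spec, base_params)
        assert a == pytest.approx(b, abs=1e-8)

    def test_refit_from_estimates_is_stable(self, medium_cohort, base_spec):
        fit1 = E.fit_model(medium_cohort, base_spec)
        fit2 = E.fit_model(medium_cohort, base_spec, fit1.estimates)
        assert abs(fit1.ofv - fit2.ofv) < 0.01

    def test_recovery_tightens_with_sample_size(self, base_params, base_spec):
        """Consistency: baseline and residual-SD errors stay within their
        shrinking sampling bands as the cohort grows."""
        for n in (100, 400):
            cfg = E.CohortConfig(
                n_subjects=n, target_obs=int(round(12.91 * n)), seed=1000 + n,
                truth_params=base_params,
            )
            fit = E.fit_model(E.generate_cohort(cfg), base_spec)
            se_s0 = base_params.s0 * np.sqrt(base_params.omega2_s0 / n)
            se_sig = base_params.sigma_add / np.sqrt(2 * 12.91 * n)
            assert abs(fit.estimates.s0 - base_params.s0) < 4 * se_s0
            assert abs(fit.estimates.sigma_add - base_params.sigma_add) < 6 * se_sig
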