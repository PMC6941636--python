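import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import jointfrailty as jf
from jointfrailty.model import _FitData, ModelSpec, hazard_ratio_entry
from jointfrailty.synthetic import ParameterError

from conftest import make_history


class TestConditionalLoglik:
    def test_constant_hazard_poisson_form(self, grade_schema):
        """One type-1 event at t, follow-up tau: log lam - lam*tau per process."""
        lam1, lam2, tau = 0.1, 0.05, 20.0
        h = make_history(
            [("s1", "1", 0, 8, 1), ("s1", "1", 8, tau, 0), ("s1", "2", 0, tau, 0)],
            [{"subject_id": "s1", "grade": "I"}], grade_schema)
        params = jf.JointFrailtyParams(
            baselines={"1": jf.WeibullHazard(1.0, 1 / lam1),
                       "2": jf.WeibullHazard(1.0, 1 / lam2)},
            betas={"1": np.zeros(2), "2": np.zeros(2)},
            frailty=jf.FrailtyCovariance(0, 0, 0))
        ll = jf.conditional_loglik_subject(h, "s1", params, (0.0, 0.0))
        expected = (math.log(lam1) - lam1 * tau) + (-lam2 * tau)
        np.testing.assert_allclose(ll, expected, rtol=1e-12)

    def test_zero_coefficient_leaves_value_unchanged(self, grade_schema):
        h = make_history(
            [("s1", "1", 0, 8, 1), ("s1", "1", 8, 20, 0), ("s1", "2", 0, 20, 0)],
            [{"subject_id": "s1", "grade": "II"}], grade_schema)
        base = {"1": jf.WeibullHazard(1.0, 10.0), "2": jf.WeibullHazard(1.0, 20.0)}
        p0 = jf.JointFrailtyParams(baselines=base,
                                   betas={"1": np.zeros(2), "2": np.zeros(2)},
                                   frailty=jf.FrailtyCovariance(0, 0, 0))
        p1 = jf.JointFrailtyParams(baselines=base, betas={},
                                   frailty=jf.FrailtyCovariance(0, 0, 0))
        # empty beta vector means no covariate term at all
        ll0 = jf.conditional_loglik_subject(h, "s1", p0, (0.3, -0.2))
        ll1 = jf.conditional_loglik_subject(h, "s1", p1, (0.3, -0.2))
        np.testing.assert_allclose(ll0, ll1, rtol=1e-12)

    def test_piecewise_constant_hand_computation(self, grade_schema):
        """Two-rate baseline: log-lik matches the Poisson cell sum by hand."""
        base = jf.PiecewiseConstantHazard(rates=(0.2, 0.05), cutpoints=(5.0,))
        h = make_history(
            [("s1", "1", 0, 3, 1), ("s1", "1", 3, 8, 0), ("s1", "2", 0, 8, 0)],
            [{"subject_id": "s1", "grade": "I"}], grade_schema)
        params = jf.JointFrailtyParams(
            baselines={"1": base, "2": base},
            betas={"1": np.zeros(2), "2": np.zeros(2)},
            frailty=jf.FrailtyCovariance(0, 0, 0))
        u, v = 0.4, -0.1
        ll = jf.conditional_loglik_subject(h, "s1", params, (u, v))
        Lam8 = 0.2 * 5 + 0.05 * 3
        expected = (math.log(0.2) + u - math.exp(u) * Lam8) \
            + (-math.exp(v) * Lam8)
        np.testing.assert_allclose(ll, expected, rtol=1e-12)


class TestMarginalLoglik:
    def test_degenerate_frailty_equals_conditional_sum(self, toy_history,
                                                       toy_params):
        p0 = jf.JointFrailtyParams(baselines=toy_params.baselines,
                                   betas=toy_params.betas,
                                   frailty=jf.FrailtyCovariance(0, 0, 0))
        m = jf.marginal_loglik(toy_history, p0)
        c = sum(jf.conditional_loglik_subject(toy_history, s, p0, (0.0, 0.0))
                for s in toy_history.subjects)
        np.testing.assert_allclose(m, c, atol=1e-10)

    @pytest.mark.parametrize("theta,eta,rho", [
        (0.5, 0.5, 0.0), (1.0, 1.0, 0.3), (1.10, 7.39, 0.5), (2.0, 4.0, -0.4),
    ])
    def test_agrees_with_dense_grid_oracle(self, toy_history, toy_params,
                                           theta, eta, rho):
        params = jf.JointFrailtyParams(
            baselines=toy_params.baselines, betas=toy_params.betas,
            frailty=jf.FrailtyCovariance(theta, eta, rho))
        oracle = jf.oracle_marginal_loglik(toy_history, params,
                                           grid_span=14, grid_points=1200)
        gh = jf.marginal_loglik(toy_history, params, quad_nodes=20)
        np.testing.assert_allclose(gh, oracle, atol=1e-4)

    def test_node_doubling_leaves_value_unchanged(self, toy_history, toy_params):
        params = jf.JointFrailtyParams(
            baselines=toy_params.baselines, betas=toy_params.betas,
            frailty=jf.FrailtyCovariance(0.5, 0.5, 0.2))
        a = jf.marginal_loglik(toy_history, params, quad_nodes=20)
        b = jf.marginal_loglik(toy_history, params, quad_nodes=40)
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_oracle_grid_refinement_converges(self, toy_history, toy_params):
        """Richardson-style check: halving the spacing moves the value < 1e-6."""
        coarse = jf.oracle_marginal_loglik(toy_history, toy_params,
                                           grid_span=14, grid_points=700)
        fine = jf.oracle_marginal_loglik(toy_history, toy_params,
                                         grid_span=14, grid_points=1400)
        assert abs(fine - coarse) < 1e-6

    def test_fixed_rule_agrees_on_moderate_variances(self, toy_history,
                                                     toy_params):
        params = jf.JointFrailtyParams(
            baselines=toy_params.baselines, betas=toy_params.betas,
            frailty=jf.FrailtyCovariance(0.4, 0.4, 0.2))
        ad = jf.marginal_loglik(toy_history, params, quad_nodes=32)
        fx = jf.marginal_loglik(toy_history, params, quad_nodes=32,
                                method="fixed")
        np.testing.assert_allclose(ad, fx, atol=2e-3)

    def test_mixed_degenerate_frailty_rejected(self, toy_history, toy_params):
        params = jf.JointFrailtyParams(
            baselines=toy_params.baselines, betas=toy_params.betas,
            frailty=jf.FrailtyCovariance(0.0, 2.0, 0.0))
        with pytest.raises(ParameterError):
            jf.marginal_loglik(toy_history, params)


class TestObjectiveGradient:
    def test_analytic_gradient_matches_finite_differences(self, toy_history):
        spec = ModelSpec(n_knots=2, quad_nodes=16, n_starts=1,
                         kappa={"1": 0.5, "2": 0.1})
        fd = _FitData(toy_history, spec)
        _, size = fd.pack_layout()
        rng = np.random.default_rng(3)
        for trial in range(3):
            x = fd.initial_point() + 0.2 * rng.standard_normal(size)
            _, g, _ = fd.loglik_and_grad(x)
            num = np.zeros(size)
            for j in range(size):
                h = 1e-6 * max(1.0, abs(x[j]))
                xp, xm = x.copy(), x.copy()
                xp[j] += h
                xm[j] -= h
                num[j] = (fd.loglik_and_grad(xp)[0]
                          - fd.loglik_and_grad(xm)[0]) / (2 * h)
            rel = np.abs(g - num) / np.maximum(1e-6, np.abs(g) + np.abs(num))
            assert rel.max() < 1e-5

    def test_gradient_with_terminal_submodel(self):
        from jointfrailty.presets import registry_config
        cfg = registry_config(seed=23, n_subjects=40, include_terminal=True)
        history, _ = jf.simulate_cohort(cfg)
        spec = ModelSpec(n_knots=1, quad_nodes=12, include_terminal=True)
        fd = _FitData(history, spec)
        _, size = fd.pack_layout()
        x = fd.initial_point() + 0.1 * np.random.default_rng(1).standard_normal(size)
        _, g, _ = fd.loglik_and_grad(x)
        num = np.zeros(size)
        for j in range(size):
            h = 1e-6 * max(1.0, abs(x[j]))
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            num[j] = (fd.loglik_and_grad(xp)[0]
                      - fd.loglik_and_grad(xm)[0]) / (2 * h)
        rel = np.abs(g - num) / np.maximum(1e-6, np.abs(g) + np.abs(num))
        assert rel.max() < 1e-5


class TestDegenerateFits:
    def test_no_frailty_constant_baseline_matches_poisson_glm(self,
                                                              medium_history):
        """With Sigma = 0 the model is Poisson regression with log-exposure
        offset; the fit must match the IRLS solution to 1e-6."""
        spec = ModelSpec(estimate_frailty=False, n_knots=0, spline_order=1,
                         n_starts=1, gtol=1e-9)
        fit = jf.fit_joint_frailty(medium_history, spec)
        for etype in ("1", "2"):
            ev = medium_history.events[medium_history.events.event_type == etype]
            d = ev.groupby("subject_id")["status"].sum()
            expo = (ev["stop"] - ev["start"]).groupby(ev["subject_id"]).sum()
            Z, _ = medium_history.design_matrix(etype)
            glm = sm.GLM(d.values, sm.add_constant(Z),
                         family=sm.families.Poisson(),
                         offset=np.log(expo.values)).fit(tol=1e-12)
            np.testing.assert_allclose(fit.params.betas[etype],
                                       glm.params[1:], atol=1e-6)

    def test_single_process_exponential_mle_is_events_over_exposure(self):
        schema = jf.CovariateSchema(covariates=())
        cfg = jf.SimulationConfig(
            n_subjects=120, schema=schema, covariate_model={},
            baseline_1=jf.WeibullHazard(1.0, 15.0),
            baseline_2=jf.WeibullHazard(1.0, 25.0),
            frailty=jf.FrailtyCovariance(0, 0, 0), horizon=40.0, seed=2)
        history, _ = jf.simulate_cohort(cfg)
        spec = ModelSpec(processes=("1",), estimate_frailty=False, n_knots=0,
                         spline_order=1, n_starts=1, gtol=1e-10)
        fit = jf.fit_joint_frailty(history, spec)
        basis = fit.params.baselines["1"]
        lam_hat = basis.hazard([10.0])[0]  # constant hazard
        ev = history.events[history.events.event_type == "1"]
        lam_mle = ev["status"].sum() / (ev["stop"] - ev["start"]).sum()
        np.testing.assert_allclose(lam_hat, lam_mle, atol=1e-6)

    def test_zero_event_process_refused(self, grade_schema):
        h = make_history([("s1", "1", 0, 3, 1), ("s1", "1", 3, 5, 1),
                          ("s1", "2", 0, 5, 0)],
                         [{"subject_id": "s1", "grade": "I"}], grade_schema)
        with pytest.raises(ParameterError, match="no observed events"):
            jf.fit_joint_frailty(h, ModelSpec(n_knots=0, spline_order=1))


@pytest.fixture(scope="module")
def medium_fit(medium_history):
    spec = ModelSpec(quad_nodes=12, n_knots=2, n_starts=1)
    return jf.fit_joint_frailty(medium_history, spec)


class TestJointFit:
    def test_recovers_generating_parameters_roughly(self, medium_fit,
                                                    medium_config):
        """Single information-rich replicate: estimates land near truth."""
        assert medium_fit.converged
        assert abs(medium_fit.frailty.theta - 0.8) < 0.5
        assert abs(medium_fit.frailty.eta - 1.5) < 0.8
        np.testing.assert_allclose(medium_fit.params.betas["1"], [0.5, 1.0],
                                   atol=0.45)

    def test_free_sigma_loglik_at_least_fixed_zero(self, medium_history,
                                                   medium_fit):
        spec0 = ModelSpec(estimate_frailty=False, n_knots=2, n_starts=1)
        fit0 = jf.fit_joint_frailty(medium_history, spec0)
        assert medium_fit.loglik_marginal >= fit0.loglik_marginal - 1e-6

    def test_penalized_loglik_below_marginal_when_smoothing(self,
                                                            medium_history):
        spec = ModelSpec(quad_nodes=8, n_knots=2, n_starts=1,
                         kappa={"1": 10.0, "2": 10.0})
        fit = jf.fit_joint_frailty(medium_history, spec)
        assert fit.loglik_penalized <= fit.loglik_marginal

    def test_standard_errors_available_and_positive(self, medium_fit):
        assert medium_fit.se_available
        assert all(se > 0 for se in medium_fit.beta_se["1"])
        assert all(se > 0 for se in medium_fit.frailty_se)

    def test_reference_level_change_is_known_contrast(self, medium_config):
        """Re-encoding grade against level II shifts betas by the contrast
        and leaves the maximized log-likelihood unchanged."""
        history, _ = jf.simulate_cohort(medium_config)
        spec = ModelSpec(estimate_frailty=False, n_knots=0, spline_order=1,
                         n_starts=1, gtol=1e-10)
        fit_a = jf.fit_joint_frailty(history, spec)
        schema_b = jf.CovariateSchema(
            covariates=(jf.Covariate("grade", ("I", "II", "III"), "II"),),
            design_1=("grade",), design_2=("grade",))
        history_b = jf.EventHistory(events=history.events.copy(),
                                    covariates=history.covariates.copy(),
                                    schema=schema_b)
        fit_b = jf.fit_joint_frailty(history_b, spec)
        np.testing.assert_allclose(fit_a.loglik_marginal, fit_b.loglik_marginal,
                                   atol=1e-6)
        bI, bIII = fit_b.params.betas["1"]  # labels: grade[I], grade[III]
        aII, aIII = fit_a.params.betas["1"]
        np.testing.assert_allclose(bI, -aII, atol=1e-5)
        np.testing.assert_allclose(bIII, aIII - aII, atol=1e-5)

    def test_increasing_kappa_never_roughens_fitted_baseline(self,
                                                             medium_history):
        from jointfrailty.splines import roughness_penalty
        values = []
        for kap in (0.0, 1e2, 1e4, 1e6):
            spec = ModelSpec(estimate_frailty=False, n_knots=4, n_starts=1,
                             kappa={"1": kap, "2": kap})
            fit = jf.fit_joint_frailty(medium_history, spec)
            rough = sum(roughness_penalty(fit.params.baselines[e],
                                          fit.params.baselines[e].coefficients)
                        for e in ("1", "2"))
            values.append(rough)
        assert all(b <= a * (1 + 1e-8) + 1e-12
                   for a, b in zip(values, values[1:]))

    def test_rho_wald_interval_covers_zero_when_uncorrelated(self,
                                                             grade_schema):
        """True rho = 0: the atanh-scale 95% Wald interval covers 0 in most
        seeded replicates (Wald analogue of a bootstrap coverage check)."""
        covered = 0
        n_rep = 12
        for rep in range(n_rep):
            cfg = jf.SimulationConfig(
                n_subjects=150, schema=grade_schema,
                covariate_model={"grade": jf.CategoricalModel(
                    ("I", "II", "III"), (0.3, 0.4, 0.3))},
                baseline_1=jf.WeibullHazard(1.0, 50.0),
                baseline_2=jf.WeibullHazard(1.0, 70.0),
                frailty=jf.FrailtyCovariance(1.0, 1.0, 0.0),
                beta_1={"grade": {"II": 0.5, "III": 1.0}},
                beta_2={"grade": {"II": 0.3, "III": 0.8}},
                horizon=50.0, max_recurrences_per_type=200, seed=400 + rep)
            history, _ = jf.simulate_cohort(cfg)
            fit = jf.fit_joint_frailty(history,
                                       ModelSpec(quad_nodes=10, n_knots=1,
                                                 n_starts=1))
            if not fit.se_available:
                continue
            rho = fit.frailty.rho
            se_t3 = fit.frailty_se[2] / max(1 - rho ** 2, 1e-12)
            t3 = np.arctanh(np.clip(rho, -0.999999, 0.999999))
            covered += (t3 - 1.96 * se_t3) <= 0 <= (t3 + 1.96 * se_t3)
        assert covered >= round(0.9 * n_rep) - 1


class TestHazardRatioTable:
    def test_closed_form_entries(self):
        hr, lo, hi = hazard_ratio_entry(0.0, 0.1)
        assert round(hr, 2) == 1.00
        assert (round(lo, 2), round(hi, 2)) == (0.82, 1.22)

    def test_published_style_row_from_backsolved_se(self):
        """beta 1.0508, SE 0.2469 formats as HR 2.86 with CI (1.76, 4.64)."""
        hr, lo, hi = hazard_ratio_entry(1.0508, 0.2469)
        assert round(hr, 2) == 2.86
        assert (round(lo, 2), round(hi, 2)) == (1.76, 4.64)

    def test_zero_se_degenerates_to_point(self):
        hr, lo, hi = hazard_ratio_entry(0.5, 0.0)
        assert lo == hi == hr

    def test_missing_se_omits_interval(self):
        hr, lo, hi = hazard_ratio_entry(0.5, None)
        assert lo is None and hi is None

    def test_table_layout_reference_rows(self, medium_history):
        spec = ModelSpec(estimate_frailty=False, n_knots=0, spline_order=1,
                         n_starts=1)
        fit = jf.fit_joint_frailty(medium_history, spec)
        table = jf.hazard_ratio_table(fit)
        refs = table[table.reference]
        assert set(refs["level"]) == {"I"}
        assert (refs["hr"] == 1.0).all()
        others = table[~table.reference]
        assert ((others["ci_low"] <= others["hr"])
                & (others["hr"] <= others["ci_high"])).all()
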