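"""Diagnosis-time density, lifetime probability and dose-response curves."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from ramlmodel.incidence import (
    LQApproxCoefficients,
    cumulative_incidence,
    diagnosis_density,
    dose_response_curve,
    fit_hrs_coefficients,
    fit_lq_approximation,
    hrs_modified_linear_coefficient,
    make_incidence_evaluator,
    raml_probability,
    raml_probability_batch,
)
from ramlmodel.leukemogenesis import (
    HRSScenario,
    initial_intermediate_cells,
    potential_diagnosis_density,
)


class TestDiagnosisDensity:
    def test_zero_dose_identically_zero(self, lp, rp, mp):
        t = np.linspace(0.0, 40.0, 100)
        curve = diagnosis_density(t, 0.0, HRSScenario.HRS_MINUS, lp, rp, mp)
        assert np.all(curve.values == 0.0)

    def test_bounded_by_potential_density(self, lp, rp, mp):
        t = np.linspace(0.0, 60.0, 400)
        curve = diagnosis_density(t, 4.5, HRSScenario.HRS_MINUS, lp, rp, mp)
        I0 = float(initial_intermediate_cells(4.5, HRSScenario.HRS_MINUS, lp, rp))
        fA = potential_diagnosis_density(t, I0, lp)
        assert np.all(curve.values <= fA + 1e-15)
        # f_d is exactly f_A thinned by the corrected survival probability
        from ramlmodel.competing_mortality import corrected_sf

        np.testing.assert_allclose(curve.values, fA * corrected_sf(t, 4.5, mp),
                                   rtol=1e-12)

    def test_improper_mass_below_one(self, lp, rp, mp):
        t = np.linspace(0.0, 120.0, 4000)
        curve = diagnosis_density(t, 4.5, HRSScenario.HRS_MINUS, lp, rp, mp)
        assert 0.0 < curve.integral() < 1.0


class TestRamlProbability:
    def test_zero_dose(self, lp, rp, mp):
        assert raml_probability(0.0, HRSScenario.HRS_MINUS, lp, rp, mp) == 0.0

    def test_argmax_near_2p5_gy(self, lp, rp, mp):
        res = minimize_scalar(
            lambda D: -raml_probability(D, HRSScenario.HRS_MINUS, lp, rp, mp),
            bounds=(1.5, 3.5), method="bounded", options={"xatol": 1e-4})
        assert res.x == pytest.approx(2.5, abs=0.25)

    def test_batch_matches_adaptive_quadrature(self, lp, rp, mp):
        doses = np.array([0.02, 0.06, 0.2, 0.75, 2.5, 4.5, 6.0])
        batch = raml_probability_batch(doses, HRSScenario.HRS_MINUS, lp, rp, mp)
        for d, pb in zip(doses, batch):
            assert pb == pytest.approx(
                raml_probability(d, HRSScenario.HRS_MINUS, lp, rp, mp), abs=1e-8)

    def test_cumulative_plateau_equals_lifetime_probability(self, lp, rp, mp):
        t = np.linspace(0.0, 120.0, 200)
        cum = cumulative_incidence(t, 4.5, HRSScenario.HRS_MINUS, lp, rp, mp)
        assert np.all(np.diff(cum) >= -1e-15)
        assert cum[np.searchsorted(t, lp.t_lag) - 1] == 0.0
        p = raml_probability(4.5, HRSScenario.HRS_MINUS, lp, rp, mp)
        assert cum[-1] == pytest.approx(p, abs=1e-6)


class TestDoseResponse:
    def test_scenario_ordering_and_convergence(self, lp, rp, mp):
        low = np.linspace(0.02, 0.1, 9)
        p_minus = raml_probability_batch(low, HRSScenario.HRS_MINUS, lp, rp, mp)
        p_plus1 = raml_probability_batch(low, HRSScenario.HRS_PLUS_1, lp, rp, mp)
        assert np.all(p_plus1 < p_minus)
        # the HRS+2 excess persists only at very low doses (crossing ~0.066 Gy)
        very_low = np.linspace(0.02, 0.06, 5)
        p2 = raml_probability_batch(very_low, HRSScenario.HRS_PLUS_2, lp, rp, mp)
        pm = raml_probability_batch(very_low, HRSScenario.HRS_MINUS, lp, rp, mp)
        assert np.all(p2 > pm)
        high = np.linspace(0.5, 6.0, 12)
        ph_minus = raml_probability_batch(high, HRSScenario.HRS_MINUS, lp, rp, mp)
        for scen in (HRSScenario.HRS_PLUS_1, HRSScenario.HRS_PLUS_2):
            np.testing.assert_allclose(
                raml_probability_batch(high, scen, lp, rp, mp) / ph_minus,
                1.0, atol=0.01)

    def test_low_dose_suppression_ratio_matches_preleukemic_ratio(self, lp, rp, mp):
        """At low doses the incidence suppression under HRS+1 equals the
        pre-leukemic cell ratio I0(HRS+1)/I0(HRS-): competing mortality is
        dose-insensitive there."""
        D = np.array([0.02, 0.06, 0.1])
        p_ratio = raml_probability_batch(D, HRSScenario.HRS_PLUS_1, lp, rp, mp) / \
            raml_probability_batch(D, HRSScenario.HRS_MINUS, lp, rp, mp)
        i_ratio = initial_intermediate_cells(D, HRSScenario.HRS_PLUS_1, lp, rp) / \
            initial_intermediate_cells(D, HRSScenario.HRS_MINUS, lp, rp)
        np.testing.assert_allclose(p_ratio, i_ratio, rtol=1e-3)

    def test_maximum_suppression_near_characteristic_dose(self, lp, rp, mp):
        D = np.linspace(0.01, 0.3, 59)
        ratio = raml_probability_batch(D, HRSScenario.HRS_PLUS_1, lp, rp, mp) / \
            raml_probability_batch(D, HRSScenario.HRS_MINUS, lp, rp, mp)
        assert D[np.argmin(ratio)] == pytest.approx(0.06, abs=0.02)

    def test_curves_start_at_zero(self, lp, rp, mp):
        doses = np.linspace(0.0, 1.0, 5)
        for scen in HRSScenario:
            curve = dose_response_curve(doses, scen, lp, rp, mp)
            assert curve.probabilities[0] == 0.0
            assert np.all(curve.probabilities < 1.0)

    def test_evaluator_matches_reference_routes(self, lp, rp, mp):
        doses = np.array([0.75, 1.5, 3.0, 4.5, 6.0])
        times = np.linspace(6.0, 30.0, 20)
        ev = make_incidence_evaluator(doses, times, 4.5, HRSScenario.HRS_MINUS,
                                      lp, rp, mp)
        yhat, zhat = ev(lp.b, lp.mu_p)
        np.testing.assert_allclose(
            yhat, 100.0 * raml_probability_batch(doses, HRSScenario.HRS_MINUS,
                                                 lp, rp, mp), rtol=1e-12)
        np.testing.assert_allclose(
            zhat, 100.0 * cumulative_incidence(times, 4.5, HRSScenario.HRS_MINUS,
                                               lp, rp, mp), rtol=1e-12)


class TestLowDoseLQApproximation:
    def test_exact_lq_input_recovered(self):
        D = np.linspace(0.0, 0.2, 21)
        fit = fit_lq_approximation(D, 2.0 * D + 5.0 * D ** 2)
        assert fit.c1 == pytest.approx(2.0, abs=1e-10)
        assert fit.c2 == pytest.approx(5.0, abs=1e-10)

    def test_all_zero_curve(self):
        D = np.linspace(0.0, 0.2, 21)
        fit = fit_lq_approximation(D, np.zeros_like(D))
        assert fit.c1 == 0.0 and fit.c2 == 0.0

    def test_pipeline_coefficients_near_published(self, lp, rp, mp):
        D = np.linspace(0.0, 0.2, 21)
        pct = 100.0 * raml_probability_batch(D, HRSScenario.HRS_MINUS, lp, rp, mp)
        fit = fit_lq_approximation(D, pct)
        assert fit.c1 == pytest.approx(3.63, rel=0.10)
        assert fit.c2 == pytest.approx(10.1, rel=0.10)

    def test_dose_range_enforced(self):
        with pytest.raises(ValueError):
            fit_lq_approximation(np.linspace(0, 0.5, 11), np.zeros(11))

    def test_singular_design_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            fit_lq_approximation(np.zeros(5), np.zeros(5))


class TestHRSModifiedCoefficient:
    def test_boundary_values(self):
        c = LQApproxCoefficients(c1=3.63, c2=10.1, c1_r=3.63, c1_s=71.9,
                                 D_c_fit=0.06)
        assert hrs_modified_linear_coefficient(0.0, c, HRSScenario.HRS_PLUS_1) \
            == pytest.approx(c.c1_r)
        c2 = LQApproxCoefficients(c1=3.0, c2=10.1, c1_r=3.0, c1_s=10.8,
                                  D_c_fit=0.026)
        assert hrs_modified_linear_coefficient(0.0, c2, HRSScenario.HRS_PLUS_2) \
            == pytest.approx(c2.c1_s)

    def test_approach_c1r_well_above_characteristic_dose(self):
        c = LQApproxCoefficients(c1=3.63, c2=10.1, c1_r=3.63, c1_s=71.9,
                                 D_c_fit=0.06)
        v = hrs_modified_linear_coefficient(10 * 0.06, c, HRSScenario.HRS_PLUS_1)
        assert v == pytest.approx(c.c1_r, rel=0.01)
        c2 = LQApproxCoefficients(c1=3.0, c2=10.1, c1_r=3.0, c1_s=10.8,
                                  D_c_fit=0.026)
        v2 = hrs_modified_linear_coefficient(10 * 0.026, c2, HRSScenario.HRS_PLUS_2)
        assert v2 == pytest.approx(c2.c1_r, rel=0.01)

    def test_control_scenario_rejected(self):
        c = LQApproxCoefficients(c1=3.63, c2=10.1, c1_r=3.63, c1_s=71.9,
                                 D_c_fit=0.06)
        with pytest.raises(ValueError):
            hrs_modified_linear_coefficient(0.1, c, HRSScenario.HRS_MINUS)

    def test_z_constant_fixed(self):
        with pytest.raises(ValueError):
            LQApproxCoefficients(c1=1.0, c2=1.0, z_const=2.0)

    def test_fitted_forms_track_model_curves(self, lp, rp, mp):
        """The closed-form c1(D) modifications reproduce the HRS scenario
        incidence curves on the low-dose range."""
        D = np.linspace(0.0, 0.3, 31)
        base = fit_lq_approximation(
            np.linspace(0.0, 0.2, 21),
            100.0 * raml_probability_batch(np.linspace(0.0, 0.2, 21),
                                           HRSScenario.HRS_MINUS, lp, rp, mp))
        for scen in (HRSScenario.HRS_PLUS_1, HRSScenario.HRS_PLUS_2):
            pct = 100.0 * raml_probability_batch(D, scen, lp, rp, mp)
            coeffs = fit_hrs_coefficients(D, pct, scen, c2=base.c2, c1_r=base.c1)
            approx = hrs_modified_linear_coefficient(D, coeffs, scen) * D \
                + base.c2 * D ** 2
            # agreement to a few hundredths of a percentage point
            np.testing.assert_allclose(approx, pct, atol=0.05)
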