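"""rAML incidence: combining diagnosis and competing-mortality distributions.

The actual diagnosis-time density is the improper density

    f_d(t) = (1 - Fhat_Abar(t)) * f_A(t),

the potential diagnosis density thinned by the probability of still being
alive, and the lifetime rAML probability is its integral,
``P(rAML) = P(t_A < t_Abar) = int_0^inf f_d(t) dt < 1``.

Also provided: time-resolved cumulative incidence, dose-response curves per
HRS scenario, the low-dose linear-quadratic approximation of the incidence
(in percent), and the HRS-modified linear-coefficient closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .competing_mortality import MortalityParams, corrected_sf, integration_horizon
from .leukemogenesis import (
    HRSScenario,
    LeukemogenesisParams,
    first_malignant_density,
    initial_intermediate_cells,
    potential_diagnosis_density,
)
from .radiobiology import RadiosensitivityParams

__all__ = [
    "DensityCurve",
    "DoseResponseCurve",
    "LQApproxCoefficients",
    "diagnosis_density",
    "raml_probability",
    "raml_probability_batch",
    "cumulative_incidence",
    "make_incidence_evaluator",
    "dose_response_curve",
    "fit_lq_approximation",
    "hrs_modified_linear_coefficient",
    "fit_hrs_coefficients",
]


@dataclass(frozen=True)
class DensityCurve:
    """Non-negative density values on a strictly increasing time grid."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-d of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v < -1e-12):
            raise ValueError("density values must be non-negative")

    def integral(self) -> float:
        return float(np.trapezoid(self.values, self.times))


@dataclass(frozen=True)
class DoseResponseCurve:
    """Lifetime rAML probability as a function of dose for one scenario."""

    doses: np.ndarray
    probabilities: np.ndarray
    scenario: HRSScenario

    def percent(self) -> np.ndarray:
        return 100.0 * np.asarray(self.probabilities)


@dataclass(frozen=True)
class LQApproxCoefficients:
    """Coefficients of the low-dose LQ incidence approximation (percent).

    ``y(D) = c1*D + c2*D**2`` describes the HRS- incidence; the HRS-modified
    linear-coefficient forms additionally use ``c1_r``, ``c1_s`` and
    ``D_c_fit``.  ``z_const`` is the fixed 1/Gy constant that makes the
    product z*D dimensionless.
    """

    c1: float
    c2: float
    c1_r: float | None = None
    c1_s: float | None = None
    D_c_fit: float | None = None
    z_const: float = 1.0

    def __post_init__(self) -> None:
        if self.z_const != 1.0:
            raise ValueError("z_const is fixed at 1 per Gy")


def _default_params(lp, rp, mp):
    lp = lp if lp is not None else LeukemogenesisParams()
    rp = rp if rp is not None else RadiosensitivityParams()
    mp = mp if mp is not None else MortalityParams()
    return lp, rp, mp


def diagnosis_density(times, D, scenario: HRSScenario,
                      lp: LeukemogenesisParams = None,
                      rp: RadiosensitivityParams = None,
                      mp: MortalityParams = None) -> DensityCurve:
    """Improper diagnosis-time density f_d(t) on the given time grid."""
    lp, rp, mp = _default_params(lp, rp, mp)
    times = np.asarray(times, dtype=float)
    I0 = float(initial_intermediate_cells(D, scenario, lp, rp))
    fA = potential_diagnosis_density(times, I0, lp)
    return DensityCurve(times, corrected_sf(times, D, mp) * fA)


def raml_probability(D, scenario: HRSScenario,
                     lp: LeukemogenesisParams = None,
                     rp: RadiosensitivityParams = None,
                     mp: MortalityParams = None) -> float:
    """Lifetime probability of rAML after an acute dose D (fraction).

    Adaptive quadrature of f_d over [t_lag, t_max] where t_max is the
    point beyond which the survival multiplier is < 1e-10.  The integral
    is evaluated in the shifted variable s = t - t_lag so that the kink of
    f_A at t_lag sits at the boundary.
    """
    lp, rp, mp = _default_params(lp, rp, mp)
    I0 = float(initial_intermediate_cells(D, scenario, lp, rp))
    if I0 == 0.0:
        return 0.0
    s_max = integration_horizon(D, mp) - lp.t_lag

    def integrand(s):
        return first_malignant_density(s, I0, lp) * corrected_sf(s + lp.t_lag, D, mp)

    val, err = integrate.quad(integrand, 0.0, s_max, epsabs=1e-10, epsrel=1e-8,
                              limit=200)
    if err > 1e-6:
        raise RuntimeError(f"quadrature did not converge (error estimate {err:g})")
    return float(min(val, 1.0))


# fixed-order Gauss-Legendre nodes for the vectorized dose-batch route;
# 256 nodes resolve the smooth integrand to well below 1e-10 over the
# <= 120-month horizon (consistency with quad asserted in the test suite)
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(256)


def raml_probability_batch(doses, scenario: HRSScenario,
                           lp: LeukemogenesisParams = None,
                           rp: RadiosensitivityParams = None,
                           mp: MortalityParams = None) -> np.ndarray:
    """Vectorized P(rAML) over a dose array (fixed-order Gauss-Legendre).

    Numerically equivalent to :func:`raml_probability` (agreement < 1e-8);
    used by dose-response and fitting loops where many doses are needed.
    """
    lp, rp, mp = _default_params(lp, rp, mp)
    doses = np.asarray(doses, dtype=float)
    I0 = np.atleast_1d(initial_intermediate_cells(doses, scenario, lp, rp))
    flat_D = np.atleast_1d(doses)
    s_max = np.array([integration_horizon(d, mp) for d in flat_D]) - lp.t_lag
    # map GL nodes from [-1, 1] onto [0, s_max] per dose
    half = s_max / 2.0
    s = half[:, None] * (_GL_NODES[None, :] + 1.0)          # (n_doses, n_nodes)
    growth = np.exp((lp.b - lp.mu_p) * s)
    I_t = I0[:, None] * growth
    M_t = lp.mu_p / (lp.b - lp.mu_p) * (I_t - I0[:, None])
    f_m1 = lp.mu_p * I_t * np.exp(-M_t)
    xi = mp.xi_intercept - mp.xi_dose_slope * flat_D
    from scipy import stats

    sf = stats.skewnorm.sf(s + lp.t_lag, mp.shape, loc=xi[:, None], scale=mp.omega)
    sf0 = stats.skewnorm.sf(0.0, mp.shape, loc=xi, scale=mp.omega)
    vals = half * np.sum(_GL_WEIGHTS[None, :] * f_m1 * sf / sf0[:, None], axis=1)
    vals = np.minimum(vals, 1.0)
    return vals.reshape(np.shape(doses)) if np.ndim(doses) else float(vals[0])


def cumulative_incidence(times, D, scenario: HRSScenario,
                         lp: LeukemogenesisParams = None,
                         rp: RadiosensitivityParams = None,
                         mp: MortalityParams = None,
                         n_grid: int = 4001) -> np.ndarray:
    """Running integral of f_d evaluated at the requested times (fraction).

    Non-decreasing; its plateau equals :func:`raml_probability` once the
    survival multiplier has extinguished f_d.
    """
    lp, rp, mp = _default_params(lp, rp, mp)
    times = np.asarray(times, dtype=float)
    I0 = float(initial_intermediate_cells(D, scenario, lp, rp))
    if I0 == 0.0:
        return np.zeros_like(times)
    t_hi = max(float(np.max(times)), lp.t_lag + 1.0)
    t_hi = min(t_hi, integration_horizon(D, mp))
    grid = np.linspace(lp.t_lag, t_hi, n_grid)
    fd = first_malignant_density(grid - lp.t_lag, I0, lp) * corrected_sf(grid, D, mp)
    cum = integrate.cumulative_trapezoid(fd, grid, initial=0.0)
    return np.interp(times, grid, cum, left=0.0, right=float(cum[-1]))


def dose_response_curve(dose_grid, scenario: HRSScenario,
                        lp: LeukemogenesisParams = None,
                        rp: RadiosensitivityParams = None,
                        mp: MortalityParams = None) -> DoseResponseCurve:
    """Lifetime rAML probability over a dose grid for one HRS scenario."""
    dose_grid = np.asarray(dose_grid, dtype=float)
    if dose_grid.size < 2:
        raise ValueError("dose grid needs at least 2 points")
    probs = raml_probability_batch(dose_grid, scenario, lp, rp, mp)
    return DoseResponseCurve(dose_grid, probs, scenario)


def make_incidence_evaluator(doses, times, tc_dose: float, scenario: HRSScenario,
                             lp: LeukemogenesisParams = None,
                             rp: RadiosensitivityParams = None,
                             mp: MortalityParams = None, n_grid: int = 4001):
    """Factory for fast repeated incidence evaluation at varying (b, mu_p).

    Precomputes everything that does not depend on the proliferation
    parameters (initial pre-leukemic cell counts, quadrature nodes and the
    competing-mortality survival factors) and returns a callable
    ``evaluate(b, mu_p) -> (yhat_percent, zhat_percent)`` giving the
    lifetime incidence (percent) at each dose and the cumulative incidence
    (percent) at each time point after ``tc_dose``.  Agrees with
    :func:`raml_probability_batch` / :func:`cumulative_incidence` exactly;
    exists so the fitting loop does not re-evaluate dose-only factors.
    """
    from scipy import stats

    lp, rp, mp = _default_params(lp, rp, mp)
    doses = np.asarray(doses, dtype=float)
    times = np.asarray(times, dtype=float)

    I0_d = np.atleast_1d(initial_intermediate_cells(doses, scenario, lp, rp))
    s_max = np.array([integration_horizon(d, mp) for d in doses]) - lp.t_lag
    half = s_max / 2.0
    s = half[:, None] * (_GL_NODES[None, :] + 1.0)
    xi = mp.xi_intercept - mp.xi_dose_slope * doses
    sf = stats.skewnorm.sf(s + lp.t_lag, mp.shape, loc=xi[:, None], scale=mp.omega)
    sf0 = stats.skewnorm.sf(0.0, mp.shape, loc=xi, scale=mp.omega)
    sf_ratio = sf / sf0[:, None]

    I0_tc = float(initial_intermediate_cells(tc_dose, scenario, lp, rp))
    t_hi = max(float(np.max(times)), lp.t_lag + 1.0)
    t_hi = min(t_hi, integration_horizon(tc_dose, mp))
    grid = np.linspace(lp.t_lag, t_hi, n_grid)
    sf_grid = corrected_sf(grid, tc_dose, mp)
    s_grid = grid - lp.t_lag

    def evaluate(b: float, mu_p: float):
        net = b - mu_p
        growth = np.exp(net * s)
        I_t = I0_d[:, None] * growth
        M_t = mu_p / net * (I_t - I0_d[:, None])
        f_m1 = mu_p * I_t * np.exp(-M_t)
        yhat = 100.0 * half * np.sum(_GL_WEIGHTS[None, :] * f_m1 * sf_ratio, axis=1)

        I_g = I0_tc * np.exp(net * s_grid)
        fd = mu_p * I_g * np.exp(-(mu_p / net) * (I_g - I0_tc)) * sf_grid
        cum = integrate.cumulative_trapezoid(fd, grid, initial=0.0)
        zhat = 100.0 * np.interp(times, grid, cum, left=0.0, right=float(cum[-1]))
        return yhat, zhat

    return evaluate


def fit_lq_approximation(doses, incidence_percent) -> LQApproxCoefficients:
    """OLS fit of y(D) = c1*D + c2*D^2 (through the origin) on percentages.

    Restricted to the low-dose region: all doses must be <= 0.2 Gy.
    """
    doses = np.asarray(doses, dtype=float)
    y = np.asarray(incidence_percent, dtype=float)
    if doses.size < 3:
        raise ValueError("need at least 3 dose points")
    if np.max(doses) > 0.2 + 1e-12:
        raise ValueError("low-dose LQ approximation is defined on D <= 0.2 Gy")
    X = np.column_stack([doses, doses ** 2])
    if np.linalg.matrix_rank(X) < 2:
        raise np.linalg.LinAlgError("singular design: need >= 2 distinct positive doses")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return LQApproxCoefficients(c1=float(coef[0]), c2=float(coef[1]))


def hrs_modified_linear_coefficient(D, coeffs: LQApproxCoefficients,
                                    scenario: HRSScenario):
    """Dose-dependent linear coefficient c1(D) of the HRS-modified LQ form.

    HRS+1:  c1_r * (1 - (c1_s/c1_r - 1) * z*D * exp(-D/D_c))
    HRS+2:  c1_r * (1 + (c1_s/c1_r - 1) * exp(-D/D_c))

    The HRS+1 form equals c1_r at D = 0 (the suppression needs dose to
    act); the HRS+2 form equals c1_s at D = 0; both approach c1_r at doses
    well above D_c.
    """
    D = np.asarray(D, dtype=float)
    if coeffs.c1_r is None or coeffs.c1_s is None or coeffs.D_c_fit is None:
        raise ValueError("coefficients must carry c1_r, c1_s and D_c_fit")
    ratio = coeffs.c1_s / coeffs.c1_r - 1.0
    damp = np.exp(-D / coeffs.D_c_fit)
    if scenario is HRSScenario.HRS_PLUS_1:
        return coeffs.c1_r * (1.0 - ratio * coeffs.z_const * D * damp)
    if scenario is HRSScenario.HRS_PLUS_2:
        return coeffs.c1_r * (1.0 + ratio * damp)
    raise ValueError(f"no HRS-modified coefficient for scenario {scenario!r}")


def fit_hrs_coefficients(doses, incidence_percent, scenario: HRSScenario,
                         c2: float, c1_r: float | None = None,
                         D_c: float | None = None) -> LQApproxCoefficients:
    """Fit the HRS-modified linear-coefficient form to a scenario curve.

    Fits ``y(D) = c1(D)*D + c2*D**2`` on percentages over the supplied
    low-dose grid (intended range [0, 0.3] Gy).  For HRS+1 the free
    parameter is c1_s (c1_r and D_c fixed, defaulting to the HRS- linear
    coefficient and 0.06 Gy); for HRS+2 all of (c1_r, c1_s, D_c) are free.
    """
    from scipy.optimize import curve_fit

    doses = np.asarray(doses, dtype=float)
    y = np.asarray(incidence_percent, dtype=float)
    if scenario is HRSScenario.HRS_PLUS_1:
        if c1_r is None:
            raise ValueError("HRS+1 fit requires the HRS- linear coefficient c1_r")
        Dc = 0.06 if D_c is None else D_c

        def model(D, c1_s):
            c = LQApproxCoefficients(c1=c1_r, c2=c2, c1_r=c1_r, c1_s=c1_s, D_c_fit=Dc)
            return hrs_modified_linear_coefficient(D, c, scenario) * D + c2 * D ** 2

        popt, _ = curve_fit(model, doses, y, p0=[10.0 * c1_r])
        return LQApproxCoefficients(c1=c1_r, c2=c2, c1_r=c1_r,
                                    c1_s=float(popt[0]), D_c_fit=Dc)
    if scenario is HRSScenario.HRS_PLUS_2:

        def model(D, c1r, c1s, Dc):
            c = LQApproxCoefficients(c1=c1r, c2=c2, c1_r=c1r, c1_s=c1s, D_c_fit=Dc)
            return hrs_modified_linear_coefficient(D, c, scenario) * D + c2 * D ** 2

        p0 = [3.6 if c1_r is None else c1_r, 11.0, 0.03 if D_c is None else D_c]
        popt, _ = curve_fit(model, doses, y, p0=p0, maxfev=10000)
        return LQApproxCoefficients(c1=float(popt[0]), c2=c2, c1_r=float(popt[0]),
                                    c1_s=float(popt[1]), D_c_fit=float(popt[2]))
    raise ValueError(f"no HRS coefficient form for scenario {scenario!r}")
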