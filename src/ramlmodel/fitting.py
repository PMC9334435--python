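"""Weighted least-squares estimation of the proliferation parameters.

The proliferation rate ``b`` and point-mutation rate ``mu_p`` are estimated
from two data blocks: 20 dose-group incidence percentages (weighted by the
fraction of mice behind each point) and 20 points of the cumulative rAML
incidence in time after acute 4.5 Gy, normalized to its final value and
weighted by the mean incidence at 4.5 Gy.  The cost is

    C(p) = sum_i (w1(i) * (y(i) - yhat(i,p)))^2
         + sum_i (w2 * (z(t_i)/z(t_20) - zhat(t_i,p)/zhat(t_20,p)))^2

minimized over p = (b, mu_p) with positivity enforced through a log
parameterization.  The two sums are stacked into a single 40-element
residual vector whose sum of squares equals C(p) exactly, so a
Levenberg-Marquardt least-squares routine applies directly and yields
asymptotic standard errors from the residual Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .competing_mortality import MortalityParams
from .incidence import make_incidence_evaluator
from .leukemogenesis import HRSScenario, LeukemogenesisParams
from .radiobiology import RadiosensitivityParams

__all__ = [
    "CohortData",
    "TimeCourseData",
    "FitResult",
    "DEFAULT_START",
    "cost_function",
    "fit_proliferation_parameters",
    "read_cohort_csv",
    "read_timecourse_csv",
]

#: fit start values for (b, mu_p), per month
DEFAULT_START = (0.0624, 6.87e-5)


@dataclass(frozen=True)
class CohortData:
    """Dose-group incidence records: dose (Gy), mice and rAML cases."""

    dose: np.ndarray
    n_mice: np.ndarray
    n_cases: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dose, dtype=float)
        n = np.asarray(self.n_mice, dtype=float)
        c = np.asarray(self.n_cases, dtype=float)
        if not (d.shape == n.shape == c.shape):
            raise ValueError("dose, n_mice, n_cases must align")
        if np.any(c > n) or np.any(n <= 0) or np.any(c < 0):
            raise ValueError("need 0 <= n_cases <= n_mice and n_mice > 0")
        object.__setattr__(self, "dose", d)
        object.__setattr__(self, "n_mice", n)
        object.__setattr__(self, "n_cases", c)

    @property
    def incidence_percent(self) -> np.ndarray:
        """Observed y(i) = 100 * n_cases / n_mice."""
        return 100.0 * self.n_cases / self.n_mice

    @property
    def weights(self) -> np.ndarray:
        """w1(i) = n_mice(i) / sum(n_mice); sums to 1."""
        return self.n_mice / self.n_mice.sum()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose_Gy": self.dose, "n_mice": self.n_mice, "n_cases": self.n_cases}
        )


@dataclass(frozen=True)
class TimeCourseData:
    """Cumulative rAML incidence in time after one acute dose.

    ``cum_percent`` is the observed cumulative incidence z(t_i) in percent,
    ``w2`` the weighting constant (mean incidence percent observed at the
    time-course dose) and ``dose`` the exposure (4.5 Gy in the historical
    design).
    """

    times: np.ndarray
    cum_percent: np.ndarray
    w2: float
    dose: float = 4.5

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        z = np.asarray(self.cum_percent, dtype=float)
        if t.shape != z.shape:
            raise ValueError("times and cum_percent must align")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(z) < 0):
            raise ValueError("cumulative incidence must be non-decreasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "cum_percent", z)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_months": self.times, "cum_percent": self.cum_percent}
        )


@dataclass(frozen=True)
class FitResult:
    """Outcome of the (b, mu_p) fit."""

    b_hat: float
    mu_p_hat: float
    se_b: float
    se_mu_p: float
    cost: float
    converged: bool
    identifiable: bool
    start: tuple[float, float]
    message: str = ""


def _make_residual_fn(cohort: CohortData, timecourse: TimeCourseData,
                      scenario: HRSScenario, lp: LeukemogenesisParams,
                      rp: RadiosensitivityParams, mp: MortalityParams):
    """Residual function r(b, mu_p) with dose-only factors precomputed."""
    doses, inverse = np.unique(cohort.dose, return_inverse=True)
    evaluate = make_incidence_evaluator(doses, timecourse.times, timecourse.dose,
                                        scenario, lp, rp, mp)
    z = timecourse.cum_percent
    if z[-1] <= 0.0:
        raise ZeroDivisionError("observed cumulative incidence is zero at t_20")
    z_norm = z / z[-1]
    y = cohort.incidence_percent
    w1 = cohort.weights

    def residuals(b: float, mu_p: float) -> np.ndarray:
        yhat, zhat = evaluate(b, mu_p)
        if zhat[-1] <= 0.0:
            raise ZeroDivisionError("model cumulative incidence is zero at "
                                    "t_20; normalization undefined")
        r1 = w1 * (y - yhat[inverse])
        r2 = timecourse.w2 * (z_norm - zhat / zhat[-1])
        return np.concatenate([r1, r2])

    return residuals


def cost_function(p, cohort: CohortData, timecourse: TimeCourseData,
                  scenario: HRSScenario = HRSScenario.HRS_MINUS,
                  lp: LeukemogenesisParams = None,
                  rp: RadiosensitivityParams = None,
                  mp: MortalityParams = None) -> float:
    """C(p) for p = (b, mu_p); the sum of squares of the stacked residuals."""
    b, mu_p = p
    if not (b > 0 and mu_p > 0 and b > mu_p):
        raise ValueError("need b > mu_p > 0")
    lp = lp if lp is not None else LeukemogenesisParams()
    rp = rp if rp is not None else RadiosensitivityParams()
    mp = mp if mp is not None else MortalityParams()
    r = _make_residual_fn(cohort, timecourse, scenario, lp, rp, mp)(b, mu_p)
    return float(np.sum(r * r))


def fit_proliferation_parameters(cohort: CohortData, timecourse: TimeCourseData,
                                 start: tuple[float, float] = DEFAULT_START,
                                 scenario: HRSScenario = HRSScenario.HRS_MINUS,
                                 lp: LeukemogenesisParams = None,
                                 rp: RadiosensitivityParams = None,
                                 mp: MortalityParams = None) -> FitResult:
    """Minimize the cost over (b, mu_p), log-parameterized for positivity.

    Standard errors are asymptotic, from the Jacobian of the residual
    vector at the optimum (delta method back from log scale).  A cohort
    with fewer than two distinct doses is flagged non-identifiable.
    Non-convergence is reported in the result, not raised.
    """
    lp = lp if lp is not None else LeukemogenesisParams()
    rp = rp if rp is not None else RadiosensitivityParams()
    mp = mp if mp is not None else MortalityParams()
    if not (start[0] > 0 and start[1] > 0):
        raise ValueError("start values must be positive")

    residual_fn = _make_residual_fn(cohort, timecourse, scenario, lp, rp, mp)

    def resid(logp):
        b, mu_p = np.exp(logp)
        return residual_fn(b, mu_p)

    x0 = np.log(np.asarray(start, dtype=float))
    sol = least_squares(resid, x0, method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12)
    b_hat, mu_p_hat = np.exp(sol.x)
    cost = float(2.0 * sol.cost)  # least_squares reports 0.5 * sum r^2

    identifiable = np.unique(cohort.dose).size >= 2
    se_b = se_mu = float("nan")
    JTJ = sol.jac.T @ sol.jac
    cond = np.linalg.cond(JTJ)
    if cond > 1e12:
        identifiable = False
    else:
        dof = max(sol.fun.size - 2, 1)
        cov_log = np.linalg.inv(JTJ) * cost / dof
        se_log = np.sqrt(np.diag(cov_log))
        se_b = float(b_hat * se_log[0])
        se_mu = float(mu_p_hat * se_log[1])
    return FitResult(
        b_hat=float(b_hat), mu_p_hat=float(mu_p_hat), se_b=se_b, se_mu_p=se_mu,
        cost=cost, converged=bool(sol.success), identifiable=bool(identifiable),
        start=tuple(start), message=str(sol.message),
    )


def read_cohort_csv(path) -> CohortData:
    """Read a cohort CSV with columns dose_Gy, n_mice, n_cases."""
    df = pd.read_csv(path)
    return CohortData(df["dose_Gy"].to_numpy(), df["n_mice"].to_numpy(),
                      df["n_cases"].to_numpy())


def read_timecourse_csv(path, w2: float | None = None, dose: float = 4.5) -> TimeCourseData:
    """Read a time-course CSV with columns time_months, cum_cases, n_mice.

    If ``w2`` is not supplied it defaults to the final observed cumulative
    incidence percentage (the mean incidence at the time-course dose).
    """
    df = pd.read_csv(path)
    z = 100.0 * df["cum_cases"].to_numpy(dtype=float) / df["n_mice"].to_numpy(dtype=float)
    if w2 is None:
        w2 = float(z[-1])
    return TimeCourseData(df["time_months"].to_numpy(dtype=float), z, w2=w2, dose=dose)
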