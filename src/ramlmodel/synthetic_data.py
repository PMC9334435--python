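"""Synthetic cohort and time-course data with the structure of the
historical CBA/H mouse experiments.

The historical incidence data (dose groups at 0.75-6.0 Gy and a 4.5 Gy
time course) are not public tables, so the fitting machinery is exercised
on synthetic datasets generated from the model itself: per dose-group
replicate, case counts are binomial around the analytic lifetime
probability; time-course case times are drawn from the normalized analytic
diagnosis-time density and accumulated at the design's observation times.
A noise-free mode reports the analytic values exactly (the infinite-mice
limit), which makes parameter recovery a sharp self-consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .competing_mortality import MortalityParams
from .fitting import CohortData, TimeCourseData
from .incidence import cumulative_incidence, raml_probability_batch
from .leukemogenesis import HRSScenario, LeukemogenesisParams
from .radiobiology import RadiosensitivityParams

__all__ = ["CohortDesign", "generate_cohort_dataset"]


@dataclass(frozen=True)
class CohortDesign:
    """Experimental design of the synthetic cohort.

    Defaults mirror the historical design: 5 dose groups x 4 replicate
    experiments = 20 incidence points, and a 20-point cumulative time
    course after 4.5 Gy on [6, 30] months.  50 mice per replicate (200 per
    dose group, 1000 mice over the dose groups) and a 400-mouse time-course
    cohort match the scale of the historical CBA/H irradiation programmes,
    which followed on the order of a thousand mice across dose groups with
    the 4.5 Gy time-course experiment the largest.
    """

    doses: tuple = (0.75, 1.5, 3.0, 4.5, 6.0)
    replicates_per_dose: int = 4
    mice_per_replicate: int = 50
    timecourse_dose: float = 4.5
    timecourse_points: int = 20
    timecourse_span: tuple = (6.0, 30.0)
    timecourse_mice: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be positive")
        if min(self.replicates_per_dose, self.mice_per_replicate,
               self.timecourse_points, self.timecourse_mice) < 1:
            raise ValueError("counts must be >= 1")

    @property
    def timecourse_times(self) -> np.ndarray:
        lo, hi = self.timecourse_span
        return np.linspace(lo, hi, self.timecourse_points)


def _sample_diagnosis_times(n: int, D: float, scenario: HRSScenario,
                            lp, rp, mp, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draws from the normalized diagnosis-time density f_d."""
    from .competing_mortality import integration_horizon

    t_hi = integration_horizon(D, mp)
    grid = np.linspace(lp.t_lag, t_hi, 4001)
    cum = cumulative_incidence(grid, D, scenario, lp, rp, mp)
    cdf = cum / cum[-1]
    return np.interp(rng.random(n), cdf, grid)


def generate_cohort_dataset(design: CohortDesign = CohortDesign(),
                            scenario: HRSScenario = HRSScenario.HRS_MINUS,
                            lp: LeukemogenesisParams = None,
                            rp: RadiosensitivityParams = None,
                            mp: MortalityParams = None,
                            noise: bool = True) -> tuple[CohortData, TimeCourseData]:
    """Generate one (CohortData, TimeCourseData) pair from true parameters.

    With ``noise=True`` replicate case counts are Binomial(mice, P(dose))
    and the time course accumulates sampled case diagnosis times; with
    ``noise=False`` the analytic probabilities/curves are reported directly
    (fractional case counts), so the fit cost at the true parameters is
    zero up to quadrature tolerance.  w2 is the mouse-weighted mean
    incidence percent of the generated records at the time-course dose,
    falling back to the analytic value if the design has none.
    """
    lp = lp if lp is not None else LeukemogenesisParams()
    rp = rp if rp is not None else RadiosensitivityParams()
    mp = mp if mp is not None else MortalityParams()
    rng = np.random.default_rng(design.seed)

    doses = np.repeat(np.asarray(design.doses, dtype=float),
                      design.replicates_per_dose)
    p_dose = raml_probability_batch(np.asarray(design.doses, dtype=float),
                                    scenario, lp, rp, mp)
    p_rep = np.repeat(p_dose, design.replicates_per_dose)
    n_mice = np.full(doses.size, design.mice_per_replicate, dtype=float)
    if noise:
        n_cases = rng.binomial(design.mice_per_replicate, p_rep).astype(float)
    else:
        n_cases = n_mice * p_rep
    cohort = CohortData(doses, n_mice, n_cases)

    # w2: mouse-weighted mean incidence (percent) at the time-course dose
    at_tc = np.isclose(doses, design.timecourse_dose)
    if at_tc.any():
        w2 = float(100.0 * n_cases[at_tc].sum() / n_mice[at_tc].sum())
    else:
        w2 = float(100.0 * raml_probability_batch(
            np.array([design.timecourse_dose]), scenario, lp, rp, mp)[0])

    times = design.timecourse_times
    if noise:
        p_tc = float(raml_probability_batch(
            np.array([design.timecourse_dose]), scenario, lp, rp, mp)[0])
        total_cases = rng.binomial(design.timecourse_mice, p_tc)
        case_times = _sample_diagnosis_times(total_cases, design.timecourse_dose,
                                             scenario, lp, rp, mp, rng)
        cum_counts = np.searchsorted(np.sort(case_times), times, side="right")
        z = 100.0 * cum_counts / design.timecourse_mice
    else:
        z = 100.0 * cumulative_incidence(times, design.timecourse_dose,
                                         scenario, lp, rp, mp)
    timecourse = TimeCourseData(times, z, w2=w2, dose=design.timecourse_dose)
    return cohort, timecourse
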