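"""Clonogenic cell-killing models: linear-quadratic and induced repair.

The expected number of lethal events after an acute dose ``D`` (Gy) is
``L(D) = alpha*D + beta*D**2`` and the clonogenic surviving fraction is
``S(D) = exp(-L(D))``.  Low-dose hyper-radiosensitivity (HRS) is described
with the induced-repair model, in which the linear coefficient interpolates
from a steep low-dose slope ``alpha_s`` down to the conventional ``alpha_r``
with characteristic dose ``D_c``:

    alpha(D) = alpha_r * (1 + (alpha_s/alpha_r - 1) * exp(-D/D_c))

Units throughout: dose in Gy, time in months, dose rate in Gy/month.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "RadiosensitivityParams",
    "ExposureProtocol",
    "SurvivalModelKind",
    "lethal_events_lq",
    "alpha_induced_repair",
    "lethal_events_hrs",
    "lethal_events_hrs_deletion",
    "survival_fraction",
    "lethal_event_rate",
]


@dataclass(frozen=True)
class RadiosensitivityParams:
    """Linear-quadratic and induced-repair coefficients.

    Attributes
    ----------
    alpha_r : float
        Conventional (high-dose) linear coefficient, Gy^-1.
    alpha_s : float
        Low-dose HRS slope for cell killing, Gy^-1.
    beta : float
        Quadratic coefficient, Gy^-2.
    D_c : float
        Dose at which induction of increased radioresistance is 63%
        complete, Gy.
    deletion_slope_ratio : float
        Assumed alpha_s/alpha_r ratio for HRS-stimulated deletion
        induction (dimensionless); affects deletion induction only,
        never cell killing.
    """

    alpha_r: float = 0.0402
    alpha_s: float = 20.0
    beta: float = 0.122
    D_c: float = 0.06
    deletion_slope_ratio: float = 3.0

    def __post_init__(self) -> None:
        for name in ("alpha_r", "alpha_s", "beta", "D_c", "deletion_slope_ratio"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.alpha_s < self.alpha_r:
            raise ValueError("alpha_s must be >= alpha_r")
        if self.deletion_slope_ratio < 1:
            raise ValueError("deletion_slope_ratio must be >= 1")


class SurvivalModelKind(Enum):
    """Which cell-survival model governs killing."""

    LQ = "lq"
    INDUCED_REPAIR = "induced_repair"


@dataclass(frozen=True)
class ExposureProtocol:
    """Constant-dose-rate exposure: total dose D (Gy) at rate Ddot (Gy/month)."""

    total_dose: float
    dose_rate: float

    def __post_init__(self) -> None:
        if self.total_dose < 0:
            raise ValueError("total_dose must be >= 0")
        if not self.dose_rate > 0:
            raise ValueError("dose_rate must be > 0")

    @property
    def duration(self) -> float:
        """Exposure time T = D / Ddot in months."""
        return self.total_dose / self.dose_rate


def _check_dose(D):
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("dose must be >= 0")
    return D


def lethal_events_lq(D, p: RadiosensitivityParams):
    """Expected lethal events L(D) = alpha_r*D + beta*D^2 (dimensionless)."""
    D = _check_dose(D)
    return p.alpha_r * D + p.beta * D * D


def alpha_induced_repair(D, p: RadiosensitivityParams, slope_ratio_override=None):
    """Dose-dependent linear coefficient alpha(D) of the induced-repair model.

    ``alpha(0) = alpha_s`` and ``alpha(D) -> alpha_r`` as ``D -> inf``.
    With ``slope_ratio_override`` the low-dose slope becomes
    ``slope_ratio_override * alpha_r`` instead of ``alpha_s``.
    """
    D = _check_dose(D)
    if slope_ratio_override is None:
        ratio = p.alpha_s / p.alpha_r
    else:
        ratio = float(slope_ratio_override)
    return p.alpha_r * (1.0 + (ratio - 1.0) * np.exp(-D / p.D_c))


def lethal_events_hrs(D, p: RadiosensitivityParams):
    """Lethal events under induced repair: L_HRS(D) = alpha(D)*D + beta*D^2."""
    D = _check_dose(D)
    return alpha_induced_repair(D, p) * D + p.beta * D * D


def lethal_events_hrs_deletion(D, p: RadiosensitivityParams):
    """Deletion-induction analogue of L_HRS with low-dose slope
    ``deletion_slope_ratio * alpha_r`` (default 3*alpha_r).

    Governs HRS-stimulated induction of the Sfpi1 deletion only; cell
    killing always uses :func:`lethal_events_hrs`.
    """
    D = _check_dose(D)
    a = alpha_induced_repair(D, p, slope_ratio_override=p.deletion_slope_ratio)
    return a * D + p.beta * D * D


def survival_fraction(D, p: RadiosensitivityParams, kind: SurvivalModelKind):
    """Clonogenic surviving fraction S(D) = exp(-L(D)) for the chosen model."""
    if kind is SurvivalModelKind.LQ:
        return np.exp(-lethal_events_lq(D, p))
    if kind is SurvivalModelKind.INDUCED_REPAIR:
        return np.exp(-lethal_events_hrs(D, p))
    raise ValueError(f"unknown survival model kind: {kind!r}")


def lethal_event_rate(t, proto: ExposureProtocol, p: RadiosensitivityParams,
                      kind: SurvivalModelKind):
    """Lethal-event rate Ldot(t) (per month) during constant-rate exposure.

    For ``0 <= t <= T = D/Ddot`` the LQ rate is
    ``alpha_r*Ddot + 2*beta*Ddot^2*t``; the induced-repair variant replaces
    ``alpha_r`` with ``alpha(D)`` evaluated at the protocol's *total* dose
    (constant during the exposure).  Zero outside the exposure window.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    if kind is SurvivalModelKind.LQ:
        a = p.alpha_r
    elif kind is SurvivalModelKind.INDUCED_REPAIR:
        a = alpha_induced_repair(proto.total_dose, p)
    else:
        raise ValueError(f"unknown survival model kind: {kind!r}")
    rate = a * proto.dose_rate + 2.0 * p.beta * proto.dose_rate ** 2 * t
    return np.where(t <= proto.duration, rate, 0.0)
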