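"""Flat YAML run configuration mirroring the model's parameter symbols.

Keys are the parameter symbol names (alpha_r, alpha_s, D_c, beta, mu_del,
b, mu_p, N0, t_lag, xi_intercept, xi_dose_slope, omega, shape,
deletion_slope_ratio) plus run settings (scenarios, dose grid, time grid,
seed, output paths).  Defaults reproduce the published parameter table;
a RunConfig round-trips losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .competing_mortality import MortalityParams
from .leukemogenesis import HRSScenario, LeukemogenesisParams
from .radiobiology import RadiosensitivityParams

__all__ = ["RunConfig", "load_config", "scenario_from_name"]

_RADIO_KEYS = ("alpha_r", "alpha_s", "beta", "D_c", "deletion_slope_ratio")
_LEUK_KEYS = ("N0", "mu_del", "b", "mu_p", "t_lag")
_MORT_KEYS = ("xi_intercept", "xi_dose_slope", "omega", "shape")
_SCENARIO_NAMES = {
    "HRS-": HRSScenario.HRS_MINUS,
    "HRS+1": HRSScenario.HRS_PLUS_1,
    "HRS+2": HRSScenario.HRS_PLUS_2,
}


def scenario_from_name(name: str) -> HRSScenario:
    try:
        return _SCENARIO_NAMES[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {sorted(_SCENARIO_NAMES)}"
        ) from None


@dataclass(frozen=True)
class RunConfig:
    """All parameter blocks plus run settings for the CLI pipelines."""

    radiosensitivity: RadiosensitivityParams = field(default_factory=RadiosensitivityParams)
    leukemogenesis: LeukemogenesisParams = field(default_factory=LeukemogenesisParams)
    mortality: MortalityParams = field(default_factory=MortalityParams)
    scenarios: tuple = ("HRS-", "HRS+1", "HRS+2")
    dose_min: float = 0.0
    dose_max: float = 6.0
    n_doses: int = 121
    time_min: float = 0.0
    time_max: float = 40.0
    n_times: int = 201
    seed: int | None = None
    out_dir: str = "."

    def scenario_values(self) -> list[HRSScenario]:
        return [scenario_from_name(s) for s in self.scenarios]

    def to_dict(self) -> dict:
        d = {}
        for key in _RADIO_KEYS:
            d[key] = getattr(self.radiosensitivity, key)
        for key in _LEUK_KEYS:
            d[key] = getattr(self.leukemogenesis, key)
        for key in _MORT_KEYS:
            d[key] = getattr(self.mortality, key)
        d.update(
            scenarios=list(self.scenarios), dose_min=self.dose_min,
            dose_max=self.dose_max, n_doses=self.n_doses,
            time_min=self.time_min, time_max=self.time_max,
            n_times=self.n_times, seed=self.seed, out_dir=self.out_dir,
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = set(_RADIO_KEYS) | set(_LEUK_KEYS) | set(_MORT_KEYS) | {
            f.name for f in dataclasses.fields(cls)
        }
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        rp = RadiosensitivityParams(**{k: d.pop(k) for k in _RADIO_KEYS if k in d})
        lp = LeukemogenesisParams(**{k: d.pop(k) for k in _LEUK_KEYS if k in d})
        mp = MortalityParams(**{k: d.pop(k) for k in _MORT_KEYS if k in d})
        if "scenarios" in d:
            d["scenarios"] = tuple(d["scenarios"])
        return cls(radiosensitivity=rp, leukemogenesis=lp, mortality=mp, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_config(path) -> RunConfig:
    """Load a RunConfig from a flat YAML file (missing keys -> defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping of parameter keys")
    return RunConfig.from_dict(data)
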