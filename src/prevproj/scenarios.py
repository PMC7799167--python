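"""Scenario transforms: base-year rates -> time-varying rate schedules.

Seven named scenarios. All of them pair with an increasing-survival
demographic path; they differ only in how the disease-specific rates evolve:

==================  ========================================================
expansion1          all disease rates constant (baseline)
expansion2          incidence multiplier ramps linearly to 1.3 by 2060
compression1        patient survival sr - md frozen at its base-year level,
                    so md grows one-for-one with sr (clamped to [0, sr])
compression2        incidence age profile shifted to older ages by the gain
                    in life expectancy at birth since the base year
prevention          incidence multiplier ramps linearly to 0.7 by 2035 and
                    is held there afterwards
extended_recovery   recovery multiplier ramps linearly to 1.5 by 2060
status_quo          comparator; rates as expansion1 (the pipeline instead
                    freezes age-specific prevalence)
==================  ========================================================

Ramps are multiplicative on the base-year age profile, which preserves the
age shape of the rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .demography import GENDERS, AGES, SurvivalSchedule, life_expectancy_at_birth
from .exceptions import ConfigurationError
from .illness_death import RateSchedule

logger = logging.getLogger(__name__)

SCENARIO_NAMES = (
    "expansion1",
    "expansion2",
    "compression1",
    "compression2",
    "prevention",
    "extended_recovery",
    "status_quo",
)


@dataclass
class ScenarioSpec:
    name: str
    incidence_multiplier_end: float = 1.0
    recovery_multiplier_end: float = 1.0
    ramp_end_year: int = 2060

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ConfigurationError(
                f"unknown scenario {self.name!r}; expected one of {SCENARIO_NAMES}"
            )
        if self.incidence_multiplier_end <= 0 or self.recovery_multiplier_end <= 0:
            raise ConfigurationError("scenario multipliers must be positive")

    @classmethod
    def named(cls, name: str, horizon: int = 2060) -> "ScenarioSpec":
        """Canonical parameterisation for each scenario name."""
        if name == "expansion2":
            return cls(name, incidence_multiplier_end=1.3, ramp_end_year=horizon)
        if name == "prevention":
            return cls(name, incidence_multiplier_end=0.7, ramp_end_year=2035)
        if name == "extended_recovery":
            return cls(name, recovery_multiplier_end=1.5, ramp_end_year=horizon)
        return cls(name, ramp_end_year=horizon)


def _ramp(years: np.ndarray, base_year: int, end_year: int, end_mult: float) -> np.ndarray:
    """Multiplier per year: 1 at base_year, end_mult at end_year, flat after."""
    frac = np.clip((years - base_year) / max(end_year - base_year, 1), 0.0, 1.0)
    return 1.0 + (end_mult - 1.0) * frac


def _shifted_incidence(i0: np.ndarray, delta: float) -> np.ndarray:
    """Evaluate the base incidence age profile at age - delta.

    Fractional ages are linearly interpolated; ages below the shifted support
    take the age-0 value.
    """
    return np.interp(AGES - delta, AGES, i0)


def apply_scenario(
    spec: ScenarioSpec,
    base_rates: RateSchedule,
    schedule: SurvivalSchedule,
    horizon: int,
) -> RateSchedule:
    """Expand base-year rates into a (101, 2, n_years) scenario schedule."""
    base_year = base_rates.base_year
    n = horizon - base_year + 1
    years = base_year + np.arange(n)
    i0, r0, md0 = (base_rates.i[:, :, 0], base_rates.r[:, :, 0], base_rates.md[:, :, 0])

    i = np.repeat(i0[:, :, None], n, axis=2)
    r = np.repeat(r0[:, :, None], n, axis=2)
    md = np.repeat(md0[:, :, None], n, axis=2)

    if spec.name == "expansion2" or spec.name == "prevention":
        end = spec.ramp_end_year if spec.name == "prevention" else horizon
        mult = _ramp(years, base_year, end, spec.incidence_multiplier_end)
        i = np.clip(i * mult[None, None, :], 0.0, 1.0)
    elif spec.name == "extended_recovery":
        mult = _ramp(years, base_year, spec.ramp_end_year, spec.recovery_multiplier_end)
        r = np.clip(r * mult[None, None, :], 0.0, 1.0)
    elif spec.name == "compression1":
        # patient survival frozen: sr_t - md_t = sr_base - md_base
        sr_base = schedule.at(base_year)
        clamped = 0
        for t, year in enumerate(years):
            sr_t = schedule.at(min(year, schedule.base_year + schedule.n_years - 1))
            raw = sr_t - (sr_base - md0)
            md[:, :, t] = np.clip(raw, 0.0, sr_t)
            clamped += int(np.sum((raw < 0) | (raw > sr_t)))
        if clamped:
            logger.warning(
                "compression1: clamped %d md cells into [0, sr] for %s",
                clamped,
                base_rates.disease_id,
            )
    elif spec.name == "compression2":
        # delay onset by the per-gender gain in life expectancy at birth
        for g in range(2):
            e0_base = life_expectancy_at_birth(schedule, GENDERS[g], base_year)
            for t, year in enumerate(years):
                y = min(year, schedule.base_year + schedule.n_years - 1)
                delta = life_expectancy_at_birth(schedule, GENDERS[g], y) - e0_base
                i[:, g, t] = _shifted_incidence(i0[:, g], delta)
    elif spec.name in ("expansion1", "status_quo"):
        pass
    else:  # pragma: no cover - guarded by ScenarioSpec
        raise ConfigurationError(f"unknown scenario {spec.name!r}")

    return RateSchedule(base_rates.disease_id, base_rates.p0, i, r, md, base_year)
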