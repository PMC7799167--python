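"""Cohort-component population projections and survival-schedule calibration.

Populations are carried on a fixed age grid 0..100 (the open-ended class is
collapsed to exact age 100; survivors of age 100 die at year end) with two
genders, indexed 0 = women, 1 = men.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    CalibrationError,
    ConfigurationError,
    ScheduleIncompleteError,
    UndefinedRatioError,
)

logger = logging.getLogger(__name__)

N_AGES = 101
AGES = np.arange(N_AGES)
GENDERS = ("women", "men")

#: share of newborns that are girls (complement: boys)
FEMALE_BIRTH_SHARE = 0.488

#: age range of women entering the birth computation (inclusive)
FERTILE_AGES = (15, 49)

VARIANTS = ("stationary", "le_constant", "le_increasing", "migration")


def _check_grid(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3 or arr.shape[0] != N_AGES or arr.shape[1] != 2:
        raise ScheduleIncompleteError(
            f"{name} must have shape (101, 2[, n_years]), got {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ScheduleIncompleteError(f"{name} contains non-finite values")
    return arr


@dataclass
class SurvivalSchedule:
    """One-year survival probabilities ``sr[age, gender, year]``."""

    sr: np.ndarray
    base_year: int

    def __post_init__(self) -> None:
        self.sr = _check_grid(self.sr, "sr")
        if np.any(self.sr < 0) or np.any(self.sr > 1):
            raise ScheduleIncompleteError("survival rates must lie in [0, 1]")

    @property
    def n_years(self) -> int:
        return self.sr.shape[2]

    @property
    def years(self) -> np.ndarray:
        return self.base_year + np.arange(self.n_years)

    def year_index(self, year: int) -> int:
        idx = int(year) - self.base_year
        if not 0 <= idx < self.n_years:
            raise ScheduleIncompleteError(
                f"year {year} outside schedule range {self.base_year}.."
                f"{self.base_year + self.n_years - 1}"
            )
        return idx

    def at(self, year: int) -> np.ndarray:
        """Return the (101, 2) survival slice for a calendar year."""
        return self.sr[:, :, self.year_index(year)]

    @classmethod
    def constant(cls, sr_slice: np.ndarray, base_year: int, horizon: int) -> "SurvivalSchedule":
        sr_slice = _check_grid(sr_slice, "sr")[:, :, 0]
        n = horizon - base_year + 1
        return cls(np.repeat(sr_slice[:, :, None], n, axis=2), base_year)

    def to_frame(self) -> pd.DataFrame:
        return _grid_to_frame(self.sr, self.base_year, "sr")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalSchedule":
        arr, base_year = _frame_to_grid(df, "sr")
        return cls(arr, base_year)


@dataclass
class PopulationPyramid:
    """Cohort sizes ``K[age, gender, year]`` (persons, possibly fractional)."""

    K: np.ndarray
    base_year: int

    def __post_init__(self) -> None:
        self.K = _check_grid(self.K, "K")
        if np.any(self.K < 0):
            raise ScheduleIncompleteError("cohort sizes must be non-negative")

    @property
    def n_years(self) -> int:
        return self.K.shape[2]

    @property
    def years(self) -> np.ndarray:
        return self.base_year + np.arange(self.n_years)

    def year_index(self, year: int) -> int:
        idx = int(year) - self.base_year
        if not 0 <= idx < self.n_years:
            raise ScheduleIncompleteError(
                f"year {year} outside pyramid range {self.base_year}.."
                f"{self.base_year + self.n_years - 1}"
            )
        return idx

    def at(self, year: int) -> np.ndarray:
        return self.K[:, :, self.year_index(year)]

    def total(self, year: int | None = None) -> float | np.ndarray:
        if year is None:
            return self.K.sum(axis=(0, 1))
        return float(self.at(year).sum())

    def to_frame(self) -> pd.DataFrame:
        return _grid_to_frame(self.K, self.base_year, "K")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PopulationPyramid":
        arr, base_year = _frame_to_grid(df, "K")
        return cls(arr, base_year)


@dataclass
class ProjectionAssumptions:
    """Demographic assumptions for one population variant."""

    variant: str = "le_constant"
    fertility_rate: float = 1.55
    le_targets: tuple[float, float] = (88.1, 84.4)  # (women, men), final year
    horizon: int = 2060
    base_year: int = 2018
    annual_net_migration: np.ndarray | None = None  # (101, 2) persons/year

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown population variant {self.variant!r}; expected one of {VARIANTS}"
            )
        if self.fertility_rate <= 0:
            raise ConfigurationError("fertility_rate must be positive")
        if self.horizon <= self.base_year:
            raise ConfigurationError("horizon must lie after base_year")
        if self.annual_net_migration is not None:
            self.annual_net_migration = _check_grid(
                np.asarray(self.annual_net_migration, dtype=float), "annual_net_migration"
            )[:, :, 0]


def _survivorship(sr: np.ndarray) -> np.ndarray:
    """l[a] = probability of reaching exact age a, with l[0] = 1.

    The final age is terminal: its survival probability is ignored.
    """
    sr = np.asarray(sr, dtype=float)
    l = np.ones(sr.shape[0])
    l[1:] = np.cumprod(sr[:-1])
    return l


def life_expectancy_at_birth(
    schedule: SurvivalSchedule | np.ndarray,
    gender: str | int | None = None,
    year: int | None = None,
) -> float:
    """Period life expectancy at birth from one-year survival probabilities.

    Uses the half-year convention (deaths occur mid-interval on average):
    ``e0 = sum_a l(a) - 0.5`` where ``l(a)`` is the survivorship curve.
    Accepts either a full :class:`SurvivalSchedule` (with ``gender`` and
    ``year``) or a bare 1-D survival vector, in which case the last entry is
    treated as a terminal age.
    """
    if isinstance(schedule, SurvivalSchedule):
        if gender is None or year is None:
            raise ScheduleIncompleteError("gender and year required with a full schedule")
        g = GENDERS.index(gender) if isinstance(gender, str) else int(gender)
        sr = schedule.at(year)[:, g]
    else:
        sr = np.asarray(schedule, dtype=float)
    if sr.ndim != 1 or sr.size == 0 or not np.all(np.isfinite(sr)):
        raise ScheduleIncompleteError("survival vector must be 1-D, non-empty and finite")
    return float(_survivorship(sr).sum() - 0.5)


def _e0_from_scaled_deaths(q: np.ndarray, k: float) -> float:
    return life_expectancy_at_birth(1.0 - np.clip(k * q, 0.0, 1.0))


def _solve_death_scale(q: np.ndarray, target_e0: float, tol: float = 1e-9) -> float:
    """Bisect the death-probability scale factor k so e0(1 - k*q) == target."""
    lo, hi = 0.0, 1.0
    e_lo = _e0_from_scaled_deaths(q, lo)
    e_hi = _e0_from_scaled_deaths(q, hi)
    if target_e0 > e_lo + 1e-12:
        raise CalibrationError(
            f"target e0={target_e0:.3f} exceeds the zero-mortality bound {e_lo:.3f}"
        )
    if target_e0 < e_hi - 1e-12:
        # target below current schedule: allow scaling deaths up (k > 1)
        while _e0_from_scaled_deaths(q, hi) > target_e0 and hi < 1e6:
            hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _e0_from_scaled_deaths(q, mid) >= target_e0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, hi):
            break
    return 0.5 * (lo + hi)


def build_survival_trajectory(
    base: SurvivalSchedule | np.ndarray,
    assumptions: ProjectionAssumptions,
) -> SurvivalSchedule:
    """Expand a base-year survival slice into a full year-by-year schedule.

    ``stationary``/``le_constant`` hold the slice fixed. ``le_increasing``
    (and ``migration``, which shares its mortality path) scales death
    probabilities per gender and year by a bisection-solved factor so that
    life expectancy at birth ramps linearly from its base value to the
    variant's target in the final year.
    """
    if isinstance(base, SurvivalSchedule):
        base_slice = base.at(assumptions.base_year)
    else:
        base_slice = _check_grid(base, "sr")[:, :, 0]
    n = assumptions.horizon - assumptions.base_year + 1
    if assumptions.variant in ("stationary", "le_constant"):
        return SurvivalSchedule.constant(base_slice, assumptions.base_year, assumptions.horizon)

    sr = np.empty((N_AGES, 2, n))
    sr[:, :, 0] = base_slice
    for g in range(2):
        q = 1.0 - base_slice[:, g]
        e0_base = life_expectancy_at_birth(base_slice[:, g])
        e0_target = assumptions.le_targets[g]
        if e0_target < e0_base - 1e-9:
            raise CalibrationError(
                f"le_increasing target {e0_target} below base e0 {e0_base:.2f} "
                f"for gender {GENDERS[g]}"
            )
        for t in range(1, n):
            e0_t = e0_base + (e0_target - e0_base) * t / (n - 1)
            k = _solve_death_scale(q, e0_t)
            sr[:, g, t] = 1.0 - np.clip(k * q, 0.0, 1.0)
    return SurvivalSchedule(sr, assumptions.base_year)


def _annual_births(K_slice: np.ndarray, fertility_rate: float) -> float:
    lo, hi = FERTILE_AGES
    women = K_slice[lo : hi + 1, 0].sum()
    return fertility_rate * women / (hi - lo + 1)


def project_population(
    base_pyramid: PopulationPyramid | np.ndarray,
    schedule: SurvivalSchedule,
    assumptions: ProjectionAssumptions,
) -> PopulationPyramid:
    """Cohort-component projection of the base-year pyramid to the horizon.

    Ages the population with the survival schedule, adds births from the
    fertility rate (uniform profile over ages 15-49, 48.8 % girls) and, for
    the migration variant, a constant annual net-migration schedule.
    Negative net cohorts are floored at zero with a logged warning.
    """
    if isinstance(base_pyramid, PopulationPyramid):
        base_slice = base_pyramid.at(assumptions.base_year)
    else:
        base_slice = _check_grid(base_pyramid, "K")[:, :, 0]
    n = assumptions.horizon - assumptions.base_year + 1
    if schedule.base_year > assumptions.base_year or (
        schedule.base_year + schedule.n_years - 1 < assumptions.horizon - 1
    ):
        raise ScheduleIncompleteError("survival schedule does not cover the projection span")

    migration = np.zeros((N_AGES, 2))
    if assumptions.variant == "migration":
        if assumptions.annual_net_migration is None:
            raise ConfigurationError("migration variant requires annual_net_migration")
        migration = assumptions.annual_net_migration

    K = np.zeros((N_AGES, 2, n))
    K[:, :, 0] = base_slice
    births0 = _annual_births(base_slice, assumptions.fertility_rate)
    floored = 0
    for t in range(1, n):
        year_prev = assumptions.base_year + t - 1
        sr_prev = schedule.at(year_prev)
        K[1:, :, t] = K[:-1, :, t - 1] * sr_prev[:-1, :]
        # survivors of the terminal age leave the population (age cap)
        K[:, :, t] += migration
        if np.any(K[:, :, t] < 0):
            floored += int(np.sum(K[:, :, t] < 0))
            K[:, :, t] = np.maximum(K[:, :, t], 0.0)
        if assumptions.variant == "stationary":
            births = births0
        else:
            births = _annual_births(K[:, :, t], assumptions.fertility_rate)
        K[0, 0, t] += births * FEMALE_BIRTH_SHARE
        K[0, 1, t] += births * (1.0 - FEMALE_BIRTH_SHARE)
    if floored:
        logger.warning("floored %d negative cohort sizes at 0 (net out-migration)", floored)
    return PopulationPyramid(K, assumptions.base_year)


def old_age_dependency_ratio(
    pyramid: PopulationPyramid,
    year: int,
    old_ages: tuple[int, int] = (65, 100),
    working_ages: tuple[int, int] = (20, 64),
) -> float:
    """Population aged 65+ per 100 persons aged 20-64, in percent."""
    K = pyramid.at(year)
    num = K[old_ages[0] : old_ages[1] + 1].sum()
    den = K[working_ages[0] : working_ages[1] + 1].sum()
    if den <= 0:
        raise UndefinedRatioError(
            f"no population in working ages {working_ages} in year {year}"
        )
    return float(100.0 * num / den)


# ---------------------------------------------------------------------------
# long-format text I/O


def _grid_to_frame(arr: np.ndarray, base_year: int, value_name: str) -> pd.DataFrame:
    n = arr.shape[2]
    ages = np.repeat(AGES, 2 * n)
    genders = np.tile(np.repeat(np.array(GENDERS), n), N_AGES)
    years = np.tile(base_year + np.arange(n), N_AGES * 2)
    return pd.DataFrame(
        {"age": ages, "gender": genders, "year": years, value_name: arr.reshape(-1)}
    )


def _frame_to_grid(df: pd.DataFrame, value_name: str) -> tuple[np.ndarray, int]:
    required = {"age", "gender", "year", value_name}
    missing = required - set(df.columns)
    if missing:
        raise ScheduleIncompleteError(f"missing columns {sorted(missing)}")
    years = np.sort(df["year"].unique())
    base_year = int(years[0])
    n = len(years)
    if not np.array_equal(years, base_year + np.arange(n)):
        raise ScheduleIncompleteError("years must be contiguous")
    arr = np.full((N_AGES, 2, n), np.nan)
    g_idx = df["gender"].map({g: i for i, g in enumerate(GENDERS)})
    if g_idx.isna().any():
        raise ScheduleIncompleteError(f"gender values must be in {GENDERS}")
    arr[df["age"].to_numpy(int), g_idx.to_numpy(int), df["year"].to_numpy(int) - base_year] = df[
        value_name
    ].to_numpy(float)
    if np.isnan(arr).any():
        raise ScheduleIncompleteError("table does not cover the full age/gender/year grid")
    return arr, base_year
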