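"""Synthetic inputs: reference-table fixtures and an individual-level microsimulator.

Two jobs live here:

1. Fixture builders that expand published German age-group averages for ten
   chronic diseases (base year 2018, sickness-fund treatment rates) into
   model-ready single-age schedules: a population pyramid totalling 83.0
   million, one-year survival rates, and per-disease p/i/r/md curves. The
   expansion is mean-preserving: population-weighted means within each age
   group reproduce the tabulated group values exactly.

2. A stochastic illness-death microsimulator that realises the deterministic
   engine person by person and emits claims-panel records, used to validate
   both the projection engine and the claims-based rate estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import (
    AGES,
    FEMALE_BIRTH_SHARE,
    GENDERS,
    N_AGES,
    PopulationPyramid,
    SurvivalSchedule,
)
from .exceptions import ContractViolationError, ScheduleIncompleteError
from .illness_death import RateSchedule

DISEASES = (
    "arthrosis",
    "CA",
    "CHD",
    "COPD",
    "CVD",
    "dementia",
    "depression",
    "diabetes",
    "dorsal_pain",
    "HF",
)

#: age-group boundaries (inclusive) used by every reference table
AGE_GROUP_BOUNDS = ((0, 17), (18, 29), (30, 44), (45, 64), (65, 84), (85, 100))

#: population shares per age group in percent; the under-18 share is the
#: remainder of the published adult-group shares
REFERENCE_POPULATION = {
    "total": 83.0e6,
    "shares_pct": (16.1, 13.8, 18.7, 29.7, 18.9, 2.8),
    # (women, men) split of each adult group share; under-18 uses birth ratio
    "gender_split_pct": (
        (16.1 * FEMALE_BIRTH_SHARE, 16.1 * (1 - FEMALE_BIRTH_SHARE)),
        (6.6, 7.2),
        (9.2, 9.5),
        (14.8, 14.8),
        (10.3, 8.5),
        (1.8, 0.9),
    ),
}

#: one-year survival in percent per age group, (women, men); the under-18
#: values are an assumption (not published alongside the adult groups)
REFERENCE_SURVIVAL_PCT = (
    (99.96, 99.94),
    (99.98, 99.96),
    (99.94, 99.90),
    (99.65, 99.37),
    (97.67, 96.43),
    (86.08, 84.31),
)

#: published average rates in percent. Each variable maps to
#: ``(total, groups)`` where ``total`` is the national (total, women, men)
#: triple and ``groups`` holds one (total, women, men) triple per adult age
#: group in order. Missing entries (irreversible disease, no excess
#: mortality reported, empty cells) are zero.
REFERENCE_RATES_PCT: dict[str, dict[str, tuple]] = {
    "arthrosis": {
        "p": ((13.4, 15.8, 10.8), ((0.4, 0.3, 0.4), (2.1, 2.1, 2.1), (15.6, 17.6, 13.5), (37.3, 41.6, 32.1), (46.9, 49.5, 41.5))),
        "i": ((1.5, 1.6, 1.3), ((0.2, 0.2, 0.2), (0.7, 0.7, 0.7), (2.6, 2.8, 2.3), (2.7, 2.8, 2.5), (2.1, 2.0, 2.2))),
        "r": ((1.6, 1.4, 1.8), ((11.5, 12.4, 10.8), (6.3, 6.0, 6.6), (2.2, 2.0, 2.5), (1.0, 1.0, 1.1), (0.2, 0.2, 0.2))),
        "md": ((0.0, 0.0, 0.0), ((0.0,) * 3,) * 5),
    },
    "CA": {
        "p": ((0.20, 0.14, 0.26), ((0.0, 0.0, 0.0), (0.01, 0.01, 0.01), (0.22, 0.17, 0.27), (0.63, 0.39, 0.92), (0.35, 0.21, 0.63))),
        "i": ((0.07, 0.05, 0.09), ((0.0, 0.0, 0.0), (0.01, 0.01, 0.01), (0.08, 0.06, 0.11), (0.21, 0.13, 0.32), (0.12, 0.07, 0.22))),
        "r": ((1.9, 2.5, 1.6), ((0.0, 0.0, 0.0), (0.5, 0.7, 0.2), (2.2, 2.7, 1.9), (1.8, 2.4, 1.4), (1.8, 2.2, 1.5))),
        "md": ((24.4, 22.0, 25.7), ((0.0, 0.0, 0.0), (14.9, 14.2, 15.8), (23.4, 20.9, 25.0), (24.8, 22.7, 25.8), (29.1, 25.1, 31.9))),
    },
    "CHD": {
        "p": ((5.9, 4.5, 7.3), ((0.0, 0.0, 0.0), (0.3, 0.1, 0.5), (4.8, 2.5, 7.2), (19.2, 14.1, 25.4), (29.2, 25.8, 36.4))),
        "i": ((0.7, 0.6, 0.8), ((0.0, 0.0, 0.0), (0.1, 0.1, 0.2), (0.8, 0.5, 1.0), (1.9, 1.6, 2.1), (2.0, 1.9, 2.1))),
        "r": ((1.4, 2.0, 1.0), ((0.0, 0.0, 0.0), (8.3, 13.2, 6.9), (2.7, 5.2, 1.8), (1.0, 1.7, 0.6), (0.2, 0.3, 0.1))),
        "md": ((1.3, 1.3, 1.2), ((0.0, 0.0, 0.0), (1.1, 1.6, 0.9), (1.0, 1.0, 1.0), (1.4, 1.5, 1.4), (0.9, 0.9, 0.9))),
    },
    "COPD": {
        "p": ((4.1, 3.6, 4.6), ((0.3, 0.3, 0.3), (0.9, 0.9, 1.0), (4.9, 4.2, 5.6), (10.8, 8.7, 13.3), (11.3, 9.1, 15.7))),
        "i": ((0.5, 0.4, 0.5), ((0.1, 0.1, 0.1), (0.2, 0.2, 0.2), (0.7, 0.6, 0.8), (1.0, 0.8, 1.2), (0.9, 0.8, 1.1))),
        "r": ((2.5, 2.9, 2.2), ((7.8, 8.3, 7.3), (6.3, 6.5, 6.1), (2.8, 3.2, 2.5), (1.6, 2.2, 1.2), (0.4, 0.6, 0.2))),
        "md": ((1.4, 1.2, 1.7), ((0.0, 0.0, 0.0), (0.3, 0.1, 0.4), (0.9, 0.7, 1.1), (2.0, 1.6, 2.3), (1.7, 1.2, 2.2))),
    },
    "CVD": {
        "p": ((4.6, 4.4, 4.8), ((0.1, 0.1, 0.1), (0.4, 0.4, 0.4), (3.2, 2.7, 3.8), (15.1, 13.3, 17.4), (25.5, 24.2, 28.3))),
        "i": ((0.7, 0.7, 0.7), ((0.0, 0.0, 0.0), (0.1, 0.1, 0.1), (0.7, 0.6, 0.8), (2.2, 2.0, 2.4), (3.0, 3.0, 3.0))),
        "r": ((2.9, 3.2, 2.5), ((8.9, 9.0, 8.9), (6.7, 7.3, 6.0), (4.1, 3.1, 3.7), (2.6, 3.1, 2.2), (1.7, 1.9, 1.3))),
        "md": ((1.4, 1.4, 1.4), ((1.2, 1.1, 1.3), (1.4, 1.2, 1.6), (1.1, 1.0, 1.3), (1.5, 1.5, 1.5), (1.6, 1.7, 1.3))),
    },
    "dementia": {
        "p": ((2.0, 2.4, 1.6), ((0.0, 0.0, 0.0), (0.0, 0.0, 0.0), (0.4, 0.3, 0.5), (6.3, 6.3, 6.2), (26.4, 28.1, 22.9))),
        "i": ((0.4, 0.5, 0.4), ((0.0, 0.0, 0.0), (0.0, 0.0, 0.0), (0.1, 0.1, 0.1), (1.4, 1.4, 1.5), (4.8, 4.9, 4.7))),
        "r": ((0.0, 0.0, 0.0), ((0.0,) * 3,) * 5),
        "md": ((6.0, 5.2, 7.2), ((0.0, 0.0, 0.0), (1.5, 1.5, 1.5), (3.3, 2.5, 3.9), (6.3, 5.4, 7.3), (5.9, 5.1, 8.1))),
    },
    "depression": {
        "p": ((12.5, 16.1, 8.7), ((5.0, 6.6, 3.6), (9.9, 12.7, 7.2), (17.7, 22.3, 13.1), (20.8, 25.9, 14.7), (24.8, 28.5, 17.1))),
        "i": ((0.9, 1.0, 0.8), ((0.8, 1.1, 0.7), (0.9, 1.1, 0.7), (1.0, 1.1, 1.0), (1.1, 1.2, 1.0), (1.4, 1.5, 1.4))),
        "r": ((3.2, 2.9, 3.6), ((5.8, 5.8, 5.8), (4.1, 4.0, 4.4), (3.1, 2.8, 3.6), (2.6, 2.4, 3.0), (1.3, 1.4, 1.1))),
        "md": ((0.1, 0.0, 0.1), ((0.0, 0.0, 0.1), (0.1, 0.0, 0.1), (0.1, 0.0, 0.1), (0.1, 0.0, 0.2), (0.0, 0.0, 0.0))),
    },
    "diabetes": {
        "p": ((11.1, 10.9, 11.2), ((0.8, 0.9, 0.6), (2.5, 2.7, 2.3), (12.1, 10.4, 13.8), (31.6, 29.6, 34.1), (34.3, 34.2, 34.5))),
        "i": ((0.7, 0.7, 0.7), ((0.2, 0.3, 0.1), (0.5, 0.6, 0.4), (1.0, 0.9, 1.2), (1.4, 1.3, 1.5), (1.1, 1.0, 1.2))),
        "r": ((0.6, 0.7, 0.5), ((3.4, 4.8, 1.4), (2.1, 3.1, 1.0), (0.7, 0.7, 0.6), (0.4, 0.5, 0.4), (0.2, 0.2, 0.1))),
        "md": ((0.4, 0.4, 0.4), ((0.1, 0.1, 0.2), (0.2, 0.1, 0.3), (0.2, 0.1, 0.3), (0.4, 0.4, 0.4), (0.3, 0.3, 0.3))),
    },
    "dorsal_pain": {
        "p": ((28.3, 31.7, 24.8), ((12.0, 13.8, 10.3), (22.7, 25.3, 20.1), (39.4, 43.3, 35.5), (48.7, 52.1, 44.5), (45.2, 46.5, 42.4))),
        "i": ((2.5, 2.5, 2.4), ((3.0, 3.3, 2.8), (3.3, 3.5, 3.2), (2.8, 2.8, 2.9), (2.1, 2.1, 2.1), (1.6, 1.6, 1.8))),
        "r": ((1.7, 1.6, 1.9), ((3.1, 3.0, 3.1), (2.0, 1.9, 2.2), (1.5, 1.3, 1.7), (1.5, 1.4, 1.6), (1.5, 1.5, 1.3))),
        "md": ((0.0, 0.0, 0.0), ((0.0,) * 3,) * 5),
    },
    "HF": {
        "p": ((4.5, 4.6, 4.4), ((0.0, 0.0, 0.1), (0.2, 0.2, 0.3), (2.5, 1.8, 3.2), (14.4, 13.4, 15.7), (35.3, 35.7, 34.5))),
        "i": ((0.9, 0.9, 0.9), ((0.0, 0.0, 0.0), (0.1, 0.1, 0.1), (0.7, 0.5, 0.9), (2.8, 2.6, 3.1), (4.9, 4.6, 5.4))),
        "r": ((2.6, 2.3, 2.9), ((14.1, 15.3, 13.5), (11.4, 13.3, 10.4), (6.9, 7.1, 6.8), (2.1, 2.2, 2.0), (0.2, 0.2, 0.1))),
        "md": ((4.3, 3.7, 4.9), ((4.1, 5.0, 3.7), (3.3, 3.6, 3.1), (3.1, 2.9, 3.3), (4.5, 3.8, 5.2), (4.7, 4.0, 6.2))),
    },
}

#: diseases whose under-18 rates default to half the 18-29 value instead of 0
UNDER18_HALF_RATE = frozenset({"dorsal_pain", "depression", "COPD"})


def reference_group_values(disease: str, var: str, column: int = 0) -> tuple[float, ...]:
    """Group values for one table column (0 = total, 1 = women, 2 = men),
    with the unpublished 0-17 group filled in per the default policy."""
    _, groups = REFERENCE_RATES_PCT[disease][var]
    adult = tuple(g[column] for g in groups)
    under18 = 0.5 * adult[0] if disease in UNDER18_HALF_RATE else 0.0
    return (under18,) + adult


def reference_national_value(disease: str, var: str = "p") -> float:
    """Published national average (the table's total column), percent."""
    return float(REFERENCE_RATES_PCT[disease][var][0][0])


def reference_national_mean(disease: str, var: str = "p") -> float:
    """Population-share-weighted national mean of the group rates, percent."""
    full = reference_group_values(disease, var, column=0)
    shares = REFERENCE_POPULATION["shares_pct"]
    return float(sum(s * v for s, v in zip(shares, full)) / 100.0)


# ---------------------------------------------------------------------------
# age-group expansion


def expand_agegroup_rates(
    agegroup_table,
    group_bounds=AGE_GROUP_BOUNDS,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Expand group means to a mean-preserving single-age curve.

    The curve is piecewise-linear through the group midpoints (flat beyond
    the outermost midpoints) and then rescaled multiplicatively within each
    group so that the ``weights``-weighted mean over the group reproduces the
    supplied group mean exactly. Uniform weights by default.
    """
    values = np.asarray(agegroup_table, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ScheduleIncompleteError("age-group values must be finite")
    if len(values) != len(group_bounds):
        raise ScheduleIncompleteError("one value per age group required")
    lo = group_bounds[0][0]
    hi = group_bounds[-1][1]
    ages = np.arange(lo, hi + 1, dtype=float)
    if weights is None:
        weights = np.ones_like(ages)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != ages.shape:
        raise ScheduleIncompleteError("weights must cover every single age")

    midpoints = np.array([(a + b) / 2.0 for a, b in group_bounds])
    curve = np.interp(ages, midpoints, values)
    out = np.empty_like(curve)
    for (a, b), target in zip(group_bounds, values):
        sel = slice(a - lo, b - lo + 1)
        w = weights[sel]
        if w.sum() <= 0:
            w = np.ones(b - a + 1)
        group_mean = float(np.average(curve[sel], weights=w))
        if target == 0.0 or group_mean == 0.0:
            out[sel] = target
        else:
            out[sel] = curve[sel] * (target / group_mean)
    return out


# ---------------------------------------------------------------------------
# fixture builders


def build_fixture_population(
    total: float = REFERENCE_POPULATION["total"],
    base_year: int = 2018,
) -> tuple[PopulationPyramid, SurvivalSchedule]:
    """Base-year pyramid and survival slice matching the reference shares.

    The pyramid totals ``total`` persons with the published age-group shares
    (smooth within groups); group-aggregated survival of the emitted schedule
    reproduces the tabulated per-group survival values.
    """
    shares = np.asarray(REFERENCE_POPULATION["shares_pct"], dtype=float)
    widths = np.array([b - a + 1 for a, b in AGE_GROUP_BOUNDS], dtype=float)
    densities = shares / widths  # percent of population per single age
    density_curve = expand_agegroup_rates(densities, AGE_GROUP_BOUNDS)

    K = np.zeros((N_AGES, 2))
    for k, (a, b) in enumerate(AGE_GROUP_BOUNDS):
        f_share, m_share = REFERENCE_POPULATION["gender_split_pct"][k]
        f_frac = f_share / (f_share + m_share)
        group = density_curve[a : b + 1] / 100.0 * total
        K[a : b + 1, 0] = group * f_frac
        K[a : b + 1, 1] = group * (1.0 - f_frac)
    pyramid = PopulationPyramid(K, base_year)

    sr = np.zeros((N_AGES, 2))
    for g in range(2):
        group_vals = [v[g] for v in REFERENCE_SURVIVAL_PCT]
        curve = expand_agegroup_rates(group_vals, AGE_GROUP_BOUNDS, weights=K[:, g])
        # per-group rescaling can lift a group's left edge above its
        # neighbour; iterate isotonic projection (non-increasing above age
        # 30) against the mean-preserving rescale until both hold
        for _ in range(300):
            curve[30:] = np.minimum.accumulate(curve[30:])
            for (a, b), target in zip(AGE_GROUP_BOUNDS, group_vals):
                mean = np.average(curve[a : b + 1], weights=K[a : b + 1, g])
                if mean > 0:
                    curve[a : b + 1] *= target / mean
        sr[:, g] = np.clip(curve / 100.0, 0.0, 1.0)
    return pyramid, SurvivalSchedule(sr, base_year)


def build_fixture_rates(
    disease: str,
    pyramid: PopulationPyramid | None = None,
    base_year: int = 2018,
) -> RateSchedule:
    """Single-age, gender-differentiated base-year rate schedule for one disease.

    Each gender's group values are expanded mean-preservingly against the
    fixture pyramid's per-gender age weights.
    """
    if disease not in REFERENCE_RATES_PCT:
        raise ScheduleIncompleteError(f"no reference rates for disease {disease!r}")
    if pyramid is None:
        pyramid, _ = build_fixture_population(base_year=base_year)

    curves = {}
    for var in ("p", "i", "r", "md"):
        arr = np.zeros((N_AGES, 2))
        for g in range(2):
            full = reference_group_values(disease, var, column=g + 1)
            arr[:, g] = expand_agegroup_rates(
                full, AGE_GROUP_BOUNDS, weights=pyramid.K[:, g, 0]
            ) / 100.0
        curves[var] = arr
    return RateSchedule(
        disease,
        np.clip(curves["p"], 0, 1),
        np.clip(curves["i"], 0, 1),
        np.clip(curves["r"], 0, 1),
        curves["md"],
        base_year,
    )


def build_fixture_bundle(base_year: int = 2018):
    """Pyramid, survival slice and all ten rate schedules in one call."""
    pyramid, survival = build_fixture_population(base_year=base_year)
    rates = {d: build_fixture_rates(d, pyramid, base_year) for d in DISEASES}
    return pyramid, survival, rates


# ---------------------------------------------------------------------------
# microsimulator


@dataclass
class TruthSet:
    """Known true rates driving the microsimulator, single disease."""

    disease_id: str
    p0: np.ndarray  # (101, 2)
    i: np.ndarray
    r: np.ndarray
    md: np.ndarray
    sr: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p0", "i", "r", "md", "sr"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape == (N_AGES,):
                arr = np.repeat(arr[:, None], 2, axis=1)
            if arr.shape != (N_AGES, 2):
                raise ScheduleIncompleteError(f"{name} must have shape (101, 2)")
            setattr(self, name, arr)
        if np.any(self.md > self.sr + 1e-12):
            raise ContractViolationError("truth md exceeds sr")

    def to_rate_schedule(self, base_year: int = 2018) -> RateSchedule:
        return RateSchedule(self.disease_id, self.p0, self.i, self.r, self.md, base_year)

    def to_survival_schedule(self, base_year: int = 2018, horizon: int = 2060) -> SurvivalSchedule:
        return SurvivalSchedule.constant(self.sr, base_year, horizon)


def uniform_truth(
    p0: float = 0.1,
    i: float = 0.05,
    r: float = 0.02,
    md: float = 0.01,
    sr: float = 0.99,
    disease_id: str = "synthetic",
    seed: int = 0,
) -> TruthSet:
    """Age- and gender-constant truth set, handy for calibration tests."""
    ones = np.ones((N_AGES, 2))
    return TruthSet(disease_id, p0 * ones, i * ones, r * ones, md * ones, sr * ones, seed)


_QUARTER_COMBOS = {
    n: np.array(
        [";".join(str(q + 1) for q in range(4) if (mask >> q) & 1)
         for mask in range(16) if bin(mask).count("1") == n]
    )
    for n in (1, 2, 3, 4)
}

#: distribution of the number of diagnosed quarters for a diseased year
_N_QUARTER_P = {2: 0.6, 3: 0.3, 4: 0.1}


def _emit_quarters(n_rows: int, miscoding_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Quarter-pattern strings for diseased person-years.

    By default every diseased year carries >= 2 diagnosed quarters (so the
    two-quarter validation rule is met); with probability ``miscoding_rate``
    only a single quarter is coded, exercising the single-year gap-fill.
    """
    nq = rng.choice(
        list(_N_QUARTER_P), size=n_rows, p=list(_N_QUARTER_P.values())
    )
    if miscoding_rate > 0:
        nq = np.where(rng.random(n_rows) < miscoding_rate, 1, nq)
    out = np.empty(n_rows, dtype=object)
    for n in (1, 2, 3, 4):
        sel = nq == n
        if sel.any():
            combos = _QUARTER_COMBOS[n]
            out[sel] = combos[rng.integers(0, len(combos), sel.sum())]
    return out


def generate_microsim_panel(
    truth: TruthSet,
    n_persons: int,
    years: int | tuple[int, int] = (2018, 2032),
    seed: int | None = None,
    start_ages: tuple[int, int] | np.ndarray = (0, 100),
    miscoding_rate: float = 0.0,
    inpatient_rate: float = 0.0,
) -> pd.DataFrame:
    """Simulate person-year claims records under a known truth set.

    Each person is advanced yearly with events ordered exactly as the
    deterministic engine: survival (patient survival ``sr - md``), then
    recovery, then ageing and incidence at the new age. Diseased years emit
    outpatient quarter patterns; deaths occur at year end and are flagged on
    the last lived year. Deterministic under a fixed seed.
    """
    if n_persons <= 0:
        raise ValueError("n_persons must be positive")
    if isinstance(years, int):
        year_list = list(range(2018, 2018 + years))
    else:
        year_list = list(range(years[0], years[1] + 1))
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    if isinstance(start_ages, tuple):
        age = rng.integers(start_ages[0], start_ages[1] + 1, n_persons)
    else:
        probs = np.asarray(start_ages, dtype=float)
        age = rng.choice(N_AGES, size=n_persons, p=probs / probs.sum())
    gender = rng.integers(0, 2, n_persons)
    person_id = np.arange(n_persons)
    diseased = rng.random(n_persons) < truth.p0[age, gender]
    alive = np.ones(n_persons, dtype=bool)

    chunks = []
    for year in year_list:
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        a, g, sick = age[idx], gender[idx], diseased[idx]
        quarters = np.full(idx.size, "", dtype=object)
        if sick.any():
            quarters[sick] = _emit_quarters(int(sick.sum()), miscoding_rate, rng)
        inpatient = np.zeros(idx.size, dtype=bool)
        if inpatient_rate > 0:
            inpatient = sick & (rng.random(idx.size) < inpatient_rate)

        # transition to next year: survival -> recovery -> ageing -> incidence
        sr_eff = truth.sr[a, g] - np.where(sick, truth.md[a, g], 0.0)
        survive = rng.random(idx.size) < np.clip(sr_eff, 0.0, 1.0)
        survive &= a < 100  # survivors of the terminal age exit
        recover = sick & survive & (rng.random(idx.size) < truth.r[a, g])
        new_age = a + 1
        still_sick = sick & ~recover
        at_risk = survive & ~still_sick
        becomes = np.zeros(idx.size, dtype=bool)
        if at_risk.any():
            becomes[at_risk] = (
                rng.random(int(at_risk.sum()))
                < truth.i[np.minimum(new_age[at_risk], 100), g[at_risk]]
            )

        chunks.append(
            pd.DataFrame(
                {
                    "person_id": person_id[idx],
                    "year": year,
                    "age": a,
                    "gender": np.array(GENDERS)[g],
                    "insured_days": 365,
                    "death_flag": (~survive).astype(int),
                    "quarters": quarters,
                    "inpatient": inpatient.astype(int),
                }
            )
        )
        alive[idx] = survive
        age[idx] = new_age
        diseased[idx] = still_sick | becomes

    panel = pd.concat(chunks, ignore_index=True)
    panel.attrs["disease"] = truth.disease_id
    return panel
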