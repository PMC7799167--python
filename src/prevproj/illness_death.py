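"""Time-discrete Markov illness-death engine with recovery.

The yearly cohort update, per age ``a``, gender ``g`` and year ``t`` (all
quantities referring to the cohort aged ``a-1`` in ``t-1``):

    D  = P_prev * (sr - md) * (1 - r)      surviving prior patients
    ND = K_prev * sr - D                   surviving non-diseased
    I  = ND * i_next                       newly diseased
    P  = D + I                             all patients

and the equivalent cohort-size-free prevalence recursion

    p_next = (p * (1 - i) * (1 - r) * (sr - md) + i * sr) / sr

Events are ordered survival -> recovery -> incidence within each yearly
step; this discrete composition is the documented source of the model's
upward bias relative to a continuous-time formulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import (
    AGES,
    GENDERS,
    N_AGES,
    PopulationPyramid,
    SurvivalSchedule,
    _check_grid,
)
from .exceptions import (
    ContractViolationError,
    DivisionUndefinedError,
    ScheduleIncompleteError,
)

logger = logging.getLogger(__name__)


@dataclass
class RateSchedule:
    """Disease-specific rates on the age x gender (x year) grid.

    ``p0`` is the base-year prevalence; ``i``, ``r`` and ``md`` may carry a
    year axis (time-varying scenarios) or be a single slice (constant rates).
    """

    disease_id: str
    p0: np.ndarray  # (101, 2)
    i: np.ndarray  # (101, 2, n_years) or (101, 2)
    r: np.ndarray
    md: np.ndarray
    base_year: int

    def __post_init__(self) -> None:
        self.p0 = _check_grid(self.p0, "p0")[:, :, 0]
        self.i = _check_grid(self.i, "i")
        self.r = _check_grid(self.r, "r")
        self.md = _check_grid(self.md, "md")
        for name, arr in (("p0", self.p0), ("i", self.i), ("r", self.r)):
            if np.any(arr < 0) or np.any(arr > 1):
                raise ContractViolationError(f"{name} must lie in [0, 1]")
        if np.any(self.md < 0):
            raise ContractViolationError("md must be non-negative")
        n = max(self.i.shape[2], self.r.shape[2], self.md.shape[2])
        for name in ("i", "r", "md"):
            arr = getattr(self, name)
            if arr.shape[2] == 1 and n > 1:
                setattr(self, name, np.repeat(arr, n, axis=2))
            elif arr.shape[2] not in (1, n):
                raise ScheduleIncompleteError(f"{name} year axis inconsistent")

    @property
    def n_years(self) -> int:
        return self.i.shape[2]

    def year_index(self, year: int) -> int:
        idx = int(year) - self.base_year
        if self.n_years == 1:
            return 0
        if not 0 <= idx < self.n_years:
            raise ScheduleIncompleteError(f"year {year} outside rate schedule")
        return idx

    def at(self, year: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(i, r, md) slices for a calendar year."""
        t = self.year_index(year)
        return self.i[:, :, t], self.r[:, :, t], self.md[:, :, t]

    def validate_against(self, schedule: SurvivalSchedule, horizon: int) -> None:
        """Check md <= sr over the projection span."""
        for year in range(self.base_year, horizon):
            sr = schedule.at(year)
            _, _, md = self.at(year)
            if np.any(md > sr + 1e-12):
                raise ContractViolationError(
                    f"md exceeds sr for disease {self.disease_id!r} in year {year}"
                )

    def to_frame(self) -> pd.DataFrame:
        n = self.n_years
        frames = []
        for t in range(n):
            year = self.base_year + t
            df = pd.DataFrame(
                {
                    "disease": self.disease_id,
                    "age": np.repeat(AGES, 2),
                    "gender": np.tile(GENDERS, N_AGES),
                    "year": year,
                    "p": np.where(t == 0, self.p0.reshape(-1), np.nan),
                    "i": self.i[:, :, t].reshape(-1),
                    "r": self.r[:, :, t].reshape(-1),
                    "md": self.md[:, :, t].reshape(-1),
                }
            )
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, disease_id: str | None = None) -> "RateSchedule":
        if disease_id is not None:
            df = df[df["disease"] == disease_id]
        else:
            ids = df["disease"].unique()
            if len(ids) != 1:
                raise ScheduleIncompleteError("frame holds multiple diseases; pass disease_id")
            disease_id = str(ids[0])
        years = np.sort(df["year"].unique())
        base_year = int(years[0])
        n = len(years)
        g_idx = df["gender"].map({g: k for k, g in enumerate(GENDERS)}).to_numpy(int)
        a_idx = df["age"].to_numpy(int)
        t_idx = df["year"].to_numpy(int) - base_year
        grids = {}
        for col in ("i", "r", "md"):
            arr = np.full((N_AGES, 2, n), np.nan)
            arr[a_idx, g_idx, t_idx] = df[col].to_numpy(float)
            grids[col] = arr
        p0 = np.full((N_AGES, 2), np.nan)
        base = df[df["year"] == base_year]
        p0[base["age"].to_numpy(int), base["gender"].map(
            {g: k for k, g in enumerate(GENDERS)}
        ).to_numpy(int)] = base["p"].to_numpy(float)
        return cls(disease_id, p0, grids["i"], grids["r"], grids["md"], base_year)


@dataclass
class CohortLedger:
    """Person counts by age, gender, year: D + I = P and D + ND = K_prev*sr."""

    D: np.ndarray
    ND: np.ndarray
    I: np.ndarray
    P: np.ndarray


@dataclass
class ProjectionResult:
    disease_id: str
    base_year: int
    total_patients: np.ndarray  # (n_years,)
    apr: np.ndarray  # (n_years,)
    p: np.ndarray  # (101, 2, n_years) age-specific prevalence
    population_total: np.ndarray  # (n_years,)
    ledger: CohortLedger | None = None

    @property
    def years(self) -> np.ndarray:
        return self.base_year + np.arange(len(self.total_patients))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "disease": self.disease_id,
                "year": self.years,
                "total_patients": self.total_patients,
                "apr": self.apr,
                "population": self.population_total,
            }
        )


def initialize_patients(pyramid_slice: np.ndarray, rates: RateSchedule) -> np.ndarray:
    """Base-year patient counts P = K * p0, elementwise on the age grid."""
    K = _check_grid(pyramid_slice, "K")[:, :, 0]
    return K * rates.p0


def step_cohort(P_prev, K_prev, sr_prev, md_prev, r_prev, i_next):
    """One yearly cohort update; returns (D, ND, I, P_next).

    Scalar or elementwise on broadcastable arrays. Raises
    :class:`ContractViolationError` if md exceeds sr anywhere.
    """
    P_prev, K_prev, sr_prev, md_prev, r_prev, i_next = map(
        np.asarray, (P_prev, K_prev, sr_prev, md_prev, r_prev, i_next)
    )
    if np.any(md_prev > sr_prev + 1e-12):
        raise ContractViolationError("mortality difference md exceeds survival rate sr")
    D = P_prev * (sr_prev - md_prev) * (1.0 - r_prev)
    ND = K_prev * sr_prev - D
    I = ND * i_next
    P_next = D + I
    return D, ND, I, P_next


def prevalence_step(p_T, i, r, sr, md):
    """Cohort-size-free prevalence recursion; see module docstring."""
    p_T, i, r, sr, md = map(np.asarray, (p_T, i, r, sr, md))
    if np.any(sr == 0):
        raise DivisionUndefinedError("prevalence recursion undefined where sr == 0")
    if np.any(md > sr + 1e-12):
        raise ContractViolationError("mortality difference md exceeds survival rate sr")
    out = (p_T * (1.0 - i) * (1.0 - r) * (sr - md) + i * sr) / sr
    return out if out.ndim else float(out)


def fixed_point_prevalence(i, r, sr, md):
    """Stationary prevalence of the recursion under time-constant rates.

    NaN where i = r = md = 0 (the recursion degenerates to the identity and
    every prevalence is stationary).
    """
    i, r, sr, md = map(np.asarray, (i, r, sr, md))
    denom = sr - (1.0 - i) * (1.0 - r) * (sr - md)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = i * sr / denom
    return out if out.ndim else float(out)


def sensitivity_decomposition(p_T, i, r, sr, md) -> dict[str, float]:
    """Partial derivatives of the prevalence recursion w.r.t. its inputs.

    Returns the coefficients of d(p_T), d(sr), d(md), d(r), d(i) in the total
    differential of ``prevalence_step``.
    """
    if np.any(np.asarray(sr) == 0):
        raise DivisionUndefinedError("sensitivity undefined where sr == 0")
    if np.any(np.asarray(md) > np.asarray(sr) + 1e-12):
        raise ContractViolationError("mortality difference md exceeds survival rate sr")
    p_next = prevalence_step(p_T, i, r, sr, md)
    surv_ratio = (sr - md) / sr
    return {
        "p_T": (1.0 - i) * (1.0 - r) * surv_ratio,
        "sr": (p_T * (1.0 - i) * (1.0 - r) + i - p_next) / sr,
        "md": -p_T * (1.0 - i) * (1.0 - r) / sr,
        "r": -p_T * (1.0 - i) * surv_ratio,
        "i": 1.0 - p_T * surv_ratio + p_T * r * surv_ratio,
    }


def project(
    pyramid: PopulationPyramid,
    schedule: SurvivalSchedule,
    rates: RateSchedule,
    horizon: int | None = None,
    keep_ledger: bool = True,
) -> ProjectionResult:
    """Run the illness-death projection along Lexis diagonals.

    Newborn cohorts enter non-diseased and are exposed to the age-0 incidence
    in their first year. Patient counts per cell are ``p * K`` where ``p``
    follows the prevalence recursion; for migration-free pyramids this equals
    the cohort-ledger count D + I exactly (asserted by the test suite), while
    net in-migrants are assigned the prevalence of their host cohort.
    """
    base_year = pyramid.base_year
    if horizon is None:
        horizon = base_year + pyramid.n_years - 1
    n = horizon - base_year + 1
    if n > pyramid.n_years:
        raise ScheduleIncompleteError("inputs do not cover the projection horizon")
    schedule.year_index(horizon - 1)  # raises if the schedule stops short
    rates.validate_against(schedule, horizon)

    p = np.zeros((N_AGES, 2, n))
    D = np.zeros((N_AGES, 2, n))
    ND = np.zeros((N_AGES, 2, n))
    I = np.zeros((N_AGES, 2, n))
    p[:, :, 0] = rates.p0
    for t in range(1, n):
        year_prev = base_year + t - 1
        sr = schedule.at(year_prev)
        _, r_prev, md_prev = rates.at(year_prev)
        i_next = rates.at(year_prev + 1)[0]
        K_prev = pyramid.K[:, :, t - 1]
        P_prev = p[:, :, t - 1] * K_prev
        d, nd, inew, _ = step_cohort(
            P_prev[:-1], K_prev[:-1], sr[:-1], md_prev[:-1], r_prev[:-1], i_next[1:]
        )
        D[1:, :, t], ND[1:, :, t], I[1:, :, t] = d, nd, inew
        # prevalence recursion (independent of cohort sizes)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_next = (
                p[:-1, :, t - 1]
                * (1.0 - i_next[1:])
                * (1.0 - r_prev[:-1])
                * (sr[:-1] - md_prev[:-1])
                + i_next[1:] * sr[:-1]
            ) / sr[:-1]
        p[1:, :, t] = np.where(sr[:-1] > 0, p_next, 0.0)
        # newborns: enter non-diseased, exposed to first-year incidence
        ND[0, :, t] = pyramid.K[0, :, t]
        I[0, :, t] = ND[0, :, t] * i_next[0]
        p[0, :, t] = i_next[0]

    P_cells = p * pyramid.K[:, :, :n]
    total_patients = P_cells.sum(axis=(0, 1))
    population_total = pyramid.K[:, :, :n].sum(axis=(0, 1))
    apr = np.where(population_total > 0, total_patients / population_total, 0.0)
    ledger = CohortLedger(D, ND, I, D + I) if keep_ledger else None
    return ProjectionResult(
        rates.disease_id, base_year, total_patients, apr, p, population_total, ledger
    )


def status_quo_projection(pyramid: PopulationPyramid, p0: np.ndarray,
                          disease_id: str = "") -> ProjectionResult:
    """Hold age-/gender-specific prevalence fixed and reweight by cohort sizes."""
    p0 = _check_grid(p0, "p0")[:, :, 0]
    n = pyramid.n_years
    p = np.repeat(p0[:, :, None], n, axis=2)
    P_cells = p * pyramid.K
    total_patients = P_cells.sum(axis=(0, 1))
    population_total = pyramid.K.sum(axis=(0, 1))
    apr = np.where(population_total > 0, total_patients / population_total, 0.0)
    return ProjectionResult(
        disease_id, pyramid.base_year, total_patients, apr, p, population_total
    )
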