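"""Estimate p, i, r, md by age and gender from person-level claims panels.

A panel is a tidy frame with one row per person-year (single disease):
``person_id, year, age, gender, insured_days, death_flag, quarters,
inpatient``. ``quarters`` holds the calendar quarters with a confirmed
outpatient diagnosis as a ``;``-separated string ("1;3"), empty when none.
``death_flag`` marks the last lived year (death at year end). Age is the
age at the end of the calendar year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import GENDERS
from .exceptions import ConfigurationError, DataIntegrityError

logger = logging.getLogger(__name__)

PANEL_COLUMNS = (
    "person_id",
    "year",
    "age",
    "gender",
    "insured_days",
    "death_flag",
    "quarters",
    "inpatient",
)


@dataclass
class ValidationCriteria:
    """Per-disease claims-validation rules.

    ``outpatient_rule`` requires a confirmed outpatient diagnosis in at least
    two (M2Q) or three (M3Q) of the year's four quarters; inpatient diagnoses
    count without further validation. ``recovery_followup_years`` of None
    disables recovery estimation (irreversible disease).
    """

    outpatient_rule: str = "M2Q"
    incidence_lookback_years: int = 4
    recovery_followup_years: int | None = 8
    special_depression_rules: bool = False

    def __post_init__(self) -> None:
        if self.outpatient_rule not in ("M2Q", "M3Q"):
            raise ConfigurationError("outpatient_rule must be 'M2Q' or 'M3Q'")
        if self.incidence_lookback_years < 1:
            raise ConfigurationError("incidence_lookback_years must be >= 1")
        if self.recovery_followup_years is not None and self.recovery_followup_years < 1:
            raise ConfigurationError("recovery_followup_years must be >= 1 or None")

    @property
    def min_quarters(self) -> int:
        return 2 if self.outpatient_rule == "M2Q" else 3


#: default rules for the ten reference diseases: 4-year incidence lookback
#: (5 for pulmonary cancer); recovery follow-up 4 years for diseases with
#: realistic cure probabilities, 5 for pulmonary cancer, 8 otherwise, none
#: for dementia. Depression's extra selection criteria are a pluggable hook
#: (the generic rules by default).
DEFAULT_CRITERIA: dict[str, ValidationCriteria] = {
    "arthrosis": ValidationCriteria(),
    "CA": ValidationCriteria(incidence_lookback_years=5, recovery_followup_years=5),
    "CHD": ValidationCriteria(),
    "COPD": ValidationCriteria(),
    "CVD": ValidationCriteria(recovery_followup_years=4),
    "dementia": ValidationCriteria(recovery_followup_years=None),
    "depression": ValidationCriteria(recovery_followup_years=4, special_depression_rules=True),
    "diabetes": ValidationCriteria(),
    "dorsal_pain": ValidationCriteria(recovery_followup_years=4),
    "HF": ValidationCriteria(),
}


def criteria_for(disease: str) -> ValidationCriteria:
    return DEFAULT_CRITERIA.get(disease, ValidationCriteria())


def _count_quarters(quarters: pd.Series) -> np.ndarray:
    q = quarters.fillna("").astype(str)
    return np.where(q == "", 0, q.str.count(";") + 1)


def _check_panel(panel: pd.DataFrame) -> pd.DataFrame:
    missing = set(PANEL_COLUMNS) - set(panel.columns)
    if missing:
        raise DataIntegrityError(f"panel missing columns {sorted(missing)}")
    if panel.duplicated(subset=["person_id", "year"]).any():
        raise DataIntegrityError("panel contains duplicate person-years")
    days = panel["insured_days"]
    if ((days < 0) | (days > 365)).any():
        raise DataIntegrityError("insured_days must lie in [0, 365]")
    df = panel.sort_values(["person_id", "year"], kind="stable").reset_index(drop=True)
    # no records after the death year
    death_years = df.loc[df["death_flag"] == 1].groupby("person_id")["year"].min()
    dy = df["person_id"].map(death_years)
    if (df["year"] > dy.fillna(np.inf)).any():
        raise DataIntegrityError("panel contains records after a person's death year")
    return df


def classify_prevalent_years(
    panel: pd.DataFrame,
    criteria: ValidationCriteria,
    disease: str | None = None,
) -> pd.DataFrame:
    """Flag prevalent person-years.

    A year is prevalent iff the outpatient quarter rule is met, or an
    inpatient diagnosis is present, or (gap-fill, applied once) the criteria
    are satisfied in both the directly adjacent years.

    Returns the sorted panel with ``criteria_met`` (before gap-fill) and
    ``prevalent`` columns added.
    """
    df = _check_panel(panel)
    nq = _count_quarters(df["quarters"])
    met = (nq >= criteria.min_quarters) | (df["inpatient"].to_numpy(bool))
    df = df.assign(criteria_met=met)

    same_prev = (df["person_id"].shift(1) == df["person_id"]) & (
        df["year"].shift(1) == df["year"] - 1
    )
    same_next = (df["person_id"].shift(-1) == df["person_id"]) & (
        df["year"].shift(-1) == df["year"] + 1
    )
    met_prev = df["criteria_met"].shift(1, fill_value=False) & same_prev
    met_next = df["criteria_met"].shift(-1, fill_value=False) & same_next
    df["prevalent"] = df["criteria_met"] | (met_prev & met_next)
    return df


def prevalent_year_sets(classified: pd.DataFrame) -> pd.Series:
    """Per person: the set of prevalent years (index: person_id)."""
    sel = classified[classified["prevalent"]]
    return sel.groupby("person_id")["year"].agg(set)


def detect_incident_cases(
    classified: pd.DataFrame,
    criteria: ValidationCriteria,
) -> pd.DataFrame:
    """Flag incident and at-risk person-years.

    Year ``y`` is *eligible* when the person is observed in every year of the
    lookback window ``y-L..y-1`` and prevalent in none of them; an eligible
    year that is itself prevalent is *incident*. Person-years without a full
    observed lookback enter neither numerator nor denominator.
    """
    L = criteria.incidence_lookback_years
    df = classified.copy()
    observed_ok = np.ones(len(df), dtype=bool)
    clean = np.ones(len(df), dtype=bool)
    pid = df["person_id"].to_numpy()
    yr = df["year"].to_numpy()
    prev = df["prevalent"].to_numpy(bool)
    for lag in range(1, L + 1):
        obs_l = (np.roll(pid, lag) == pid) & (np.roll(yr, lag) == yr - lag)
        obs_l[:lag] = False
        observed_ok &= obs_l
        clean &= ~(obs_l & np.roll(prev, lag))
    df["at_risk"] = observed_ok & clean
    df["incident"] = df["at_risk"] & prev
    return df


def incident_year_sets(with_incidence: pd.DataFrame) -> pd.Series:
    sel = with_incidence[with_incidence["incident"]]
    return sel.groupby("person_id")["year"].agg(set)


def _flag_recovery(df: pd.DataFrame, criteria: ValidationCriteria) -> pd.DataFrame:
    """Mark patient-years followed by a diagnosis-free, fully observed window.

    ``recovery_eligible``: prevalent in ``y``, observed (alive) in every year
    ``y+1..y+F``. ``recovered``: additionally no coded diagnosis (neither
    outpatient quarters nor inpatient) anywhere in the window. Censored
    persons are excluded via the observation requirement.
    """
    F = criteria.recovery_followup_years
    df = df.copy()
    if F is None:
        df["recovery_eligible"] = False
        df["recovered"] = False
        return df
    pid = df["person_id"].to_numpy()
    yr = df["year"].to_numpy()
    any_dx = (_count_quarters(df["quarters"]) > 0) | df["inpatient"].to_numpy(bool)
    observed = np.ones(len(df), dtype=bool)
    clear = np.ones(len(df), dtype=bool)
    n = len(df)
    for lead in range(1, F + 1):
        obs_l = np.zeros(n, dtype=bool)
        if n > lead:
            obs_l[:-lead] = (pid[lead:] == pid[:-lead]) & (yr[lead:] == yr[:-lead] + lead)
        observed &= obs_l
        dx_ahead = np.zeros(n, dtype=bool)
        if n > lead:
            dx_ahead[:-lead] = any_dx[lead:]
        clear &= ~(obs_l & dx_ahead)
    df["recovery_eligible"] = df["prevalent"].to_numpy(bool) & observed
    df["recovered"] = df["recovery_eligible"] & clear
    return df


def estimate_rates(
    panel: pd.DataFrame,
    criteria: ValidationCriteria | None = None,
    disease: str | None = None,
    smooth_md_window: int | None = None,
) -> pd.DataFrame:
    """Estimate p, i, r, md per (age, gender) cell from a claims panel.

    - ``p``: insured days of prevalent person-years over all insured days.
    - ``i``: incident persons over at-risk persons (full disease-free
      lookback observed).
    - ``r``: patients whose entire follow-up window is observed and
      diagnosis-free, over all such observed surviving patients.
    - ``md``: one-year survival of all insureds minus one-year survival of
      the prevalent, floored at 0 (flooring logged).

    Cells without any exposure are emitted as NaN (missing). Returns a tidy
    frame keyed by (age, gender) with the estimates and their denominators.
    An optional centred moving-average smoother over age can be applied to
    ``md``.
    """
    if disease is None:
        disease = panel.attrs.get("disease", "")
    if criteria is None:
        criteria = criteria_for(disease)
    df = classify_prevalent_years(panel, criteria, disease)
    df = detect_incident_cases(df, criteria)
    df = _flag_recovery(df, criteria)

    # one-year survival: died == death_flag on this row (death at year end)
    pid = df["person_id"].to_numpy()
    yr = df["year"].to_numpy()
    observed_next = np.zeros(len(df), dtype=bool)
    observed_next[:-1] = (pid[1:] == pid[:-1]) & (yr[1:] == yr[:-1] + 1)
    died = df["death_flag"].to_numpy(bool)
    df["survival_known"] = observed_next | died
    df["survived"] = observed_next & ~died

    grp = df.groupby(["age", "gender"], observed=True)
    out = grp.apply(
        lambda s: pd.Series(
            {
                "days_total": s["insured_days"].sum(),
                "days_prevalent": s.loc[s["prevalent"], "insured_days"].sum(),
                "n_at_risk": int(s["at_risk"].sum()),
                "n_incident": int(s["incident"].sum()),
                "n_recovery_eligible": int(s["recovery_eligible"].sum()),
                "n_recovered": int(s["recovered"].sum()),
                "n_survival_known": int(s["survival_known"].sum()),
                "n_survived": int(s["survived"].sum()),
                "n_prev_survival_known": int((s["prevalent"] & s["survival_known"]).sum()),
                "n_prev_survived": int((s["prevalent"] & s["survived"]).sum()),
            }
        ),
        include_groups=False,
    ).reset_index()

    with np.errstate(invalid="ignore", divide="ignore"):
        out["p"] = out["days_prevalent"] / out["days_total"].replace(0, np.nan)
        out["i"] = out["n_incident"] / out["n_at_risk"].replace(0, np.nan)
        out["r"] = out["n_recovered"] / out["n_recovery_eligible"].replace(0, np.nan)
        surv_all = out["n_survived"] / out["n_survival_known"].replace(0, np.nan)
        surv_dis = out["n_prev_survived"] / out["n_prev_survival_known"].replace(0, np.nan)
        md_raw = surv_all - surv_dis
    floored = int((md_raw < 0).sum())
    if floored:
        logger.info("floored %d negative md cells at 0", floored)
    out["md"] = md_raw.clip(lower=0.0)
    out["survival_all"] = surv_all
    out["survival_diseased"] = surv_dis
    if criteria.recovery_followup_years is None:
        out["r"] = 0.0

    if smooth_md_window and smooth_md_window > 1:
        out = out.sort_values(["gender", "age"])
        out["md"] = (
            out.groupby("gender", observed=True)["md"]
            .transform(lambda s: s.rolling(smooth_md_window, center=True, min_periods=1).mean())
        )
    out["disease"] = disease
    return out.reset_index(drop=True)


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, sep="\t", index=False)


def read_panel(path, disease: str = "") -> pd.DataFrame:
    panel = pd.read_csv(path, sep="\t", dtype={"quarters": str}, keep_default_na=False,
                        na_values=[])
    for col in ("person_id", "year", "age", "insured_days", "death_flag", "inpatient"):
        panel[col] = panel[col].astype(int)
    panel.attrs["disease"] = disease
    return panel
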