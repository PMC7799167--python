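import numpy as np
import pandas as pd
import pytest

from prevproj import claims_estimation as ce
from prevproj import synthetic_data as sd
from prevproj.exceptions import ConfigurationError, DataIntegrityError
from prevproj.illness_death import fixed_point_prevalence


def make_panel(rows):
    """rows: (person_id, year, quarters, inpatient[, death_flag, age, gender])."""
    records = []
    for row in rows:
        pid, year, quarters, inpatient = row[:4]
        death = row[4] if len(row) > 4 else 0
        age = row[5] if len(row) > 5 else 50
        gender = row[6] if len(row) > 6 else "women"
        records.append(
            dict(
                person_id=pid,
                year=year,
                age=age,
                gender=gender,
                insured_days=365,
                death_flag=death,
                quarters=quarters,
                inpatient=inpatient,
            )
        )
    return pd.DataFrame(records)


M2Q = ce.ValidationCriteria()


class TestValidationCriteria:
    def test_rule_names(self):
        assert ce.ValidationCriteria("M3Q").min_quarters == 3
        with pytest.raises(ConfigurationError):
            ce.ValidationCriteria("M4Q")
        with pytest.raises(ConfigurationError):
            ce.ValidationCriteria(incidence_lookback_years=0)

    def test_disease_defaults(self):
        assert ce.criteria_for("CA").incidence_lookback_years == 5
        assert ce.criteria_for("CA").recovery_followup_years == 5
        assert ce.criteria_for("dementia").recovery_followup_years is None
        assert ce.criteria_for("dorsal_pain").recovery_followup_years == 4
        assert ce.criteria_for("diabetes").recovery_followup_years == 8


class TestClassifyPrevalentYears:
    def test_two_quarters_prevalent(self):
        panel = make_panel([(1, 2016, "1;3", 0)])
        out = ce.classify_prevalent_years(panel, M2Q)
        assert out["prevalent"].tolist() == [True]

    def test_single_quarter_not_prevalent(self):
        panel = make_panel([(1, 2016, "1", 0)])
        out = ce.classify_prevalent_years(panel, M2Q)
        assert out["prevalent"].tolist() == [False]

    def test_m3q_needs_three(self):
        panel = make_panel([(1, 2016, "1;3", 0), (2, 2016, "1;2;4", 0)])
        out = ce.classify_prevalent_years(panel, ce.ValidationCriteria("M3Q"))
        assert out.set_index("person_id")["prevalent"].to_dict() == {1: False, 2: True}

    def test_inpatient_counts_without_validation(self):
        panel = make_panel([(1, 2016, "", 1)])
        out = ce.classify_prevalent_years(panel, M2Q)
        assert out["prevalent"].all()

    def test_gap_fill_single_year(self):
        panel = make_panel([(1, 2015, "1;2", 0), (1, 2016, "3", 0), (1, 2017, "2;4", 0)])
        out = ce.classify_prevalent_years(panel, M2Q)
        assert out["prevalent"].tolist() == [True, True, True]

    def test_gap_fill_not_applied_to_two_year_gaps(self):
        panel = make_panel(
            [(1, 2014, "1;2", 0), (1, 2015, "", 0), (1, 2016, "", 0), (1, 2017, "2;4", 0)]
        )
        out = ce.classify_prevalent_years(panel, M2Q)
        assert out["prevalent"].tolist() == [True, False, False, True]

    def test_gap_fill_requires_both_neighbours(self):
        panel = make_panel([(1, 2015, "1;2", 0), (1, 2016, "", 0)])
        out = ce.classify_prevalent_years(panel, M2Q)
        assert out["prevalent"].tolist() == [True, False]

    def test_duplicate_person_years_rejected(self):
        panel = make_panel([(1, 2016, "1;3", 0), (1, 2016, "", 0)])
        with pytest.raises(DataIntegrityError):
            ce.classify_prevalent_years(panel, M2Q)

    def test_records_after_death_rejected(self):
        panel = make_panel([(1, 2016, "", 0, 1), (1, 2017, "", 0)])
        with pytest.raises(DataIntegrityError):
            ce.classify_prevalent_years(panel, M2Q)

    def test_prevalent_year_sets(self):
        panel = make_panel([(1, 2015, "1;2", 0), (1, 2016, "", 0), (2, 2015, "1;2", 0)])
        out = ce.classify_prevalent_years(panel, M2Q)
        sets = ce.prevalent_year_sets(out)
        assert sets.loc[1] == {2015} and sets.loc[2] == {2015}


class TestDetectIncidentCases:
    def observe(self, pid, years, prevalent_years, L=4):
        rows = [(pid, y, "1;2" if y in prevalent_years else "", 0) for y in years]
        panel = make_panel(rows)
        crit = ce.ValidationCriteria(incidence_lookback_years=L)
        return ce.detect_incident_cases(ce.classify_prevalent_years(panel, crit), crit)

    def test_clean_lookback_incident(self):
        out = self.observe(1, range(2013, 2018), {2017})
        assert out.loc[out["year"] == 2017, "incident"].item()

    def test_lookback_hit_not_incident(self):
        out = self.observe(1, range(2013, 2018), {2014, 2017})
        assert not out.loc[out["year"] == 2017, "incident"].item()

    def test_five_year_lookback_for_cancer(self):
        out = self.observe(1, range(2012, 2018), {2012, 2017}, L=5)
        assert not out.loc[out["year"] == 2017, "incident"].item()
        # with only the generic 4-year lookback the 2012 episode is forgotten
        out4 = self.observe(1, range(2012, 2018), {2012, 2017}, L=4)
        assert out4.loc[out4["year"] == 2017, "incident"].item()

    def test_insufficient_observation_excluded(self):
        out = self.observe(1, range(2015, 2018), {2017})
        row = out[out["year"] == 2017]
        assert not row["at_risk"].item() and not row["incident"].item()


class TestEstimateRates:
    def test_period_prevalence_days_ratio(self):
        rows = []
        for pid in range(10):
            quarters = "1;2" if pid < 2 else ""
            rows.append((pid, 2016, quarters, 0))
        panel = make_panel(rows)
        est = ce.estimate_rates(panel, M2Q, disease="test")
        assert est["p"].item() == pytest.approx(0.2)

    def test_prevalence_weighted_by_insured_days(self):
        panel = make_panel([(1, 2016, "1;2", 0), (2, 2016, "", 0)])
        panel.loc[panel["person_id"] == 1, "insured_days"] = 100
        panel.loc[panel["person_id"] == 2, "insured_days"] = 300
        est = ce.estimate_rates(panel, M2Q, disease="test")
        assert est["p"].item() == pytest.approx(100 / 400)

    def test_mortality_difference_subtraction(self):
        # diseased survival 0.90 (9/10), overall 0.95 (19/20) -> md = 0.05
        rows = []
        for pid in range(10):  # diseased, one dies
            rows.append((pid, 2016, "1;2", 0, 1 if pid == 0 else 0))
            if pid != 0:
                rows.append((pid, 2017, "1;2", 0))
        for pid in range(10, 20):  # healthy, none die
            rows.append((pid, 2016, "", 0))
            rows.append((pid, 2017, "", 0))
        est = ce.estimate_rates(make_panel(rows), M2Q, disease="test")
        cell = est[est["age"] == 50].iloc[0]
        assert cell["survival_diseased"] == pytest.approx(0.90)
        assert cell["survival_all"] == pytest.approx(0.95)
        assert cell["md"] == pytest.approx(0.05)

    def test_negative_md_floored(self, caplog):
        rows = []
        for pid in range(5):  # diseased, all survive
            rows.append((pid, 2016, "1;2", 0))
            rows.append((pid, 2017, "1;2", 0))
        for pid in range(5, 10):  # healthy, one dies
            rows.append((pid, 2016, "", 0, 1 if pid == 5 else 0))
            if pid != 5:
                rows.append((pid, 2017, "", 0))
        with caplog.at_level("INFO", logger="prevproj.claims_estimation"):
            est = ce.estimate_rates(make_panel(rows), M2Q, disease="test")
        assert (est["md"] >= 0).all()

    def test_dementia_recovery_zero_by_construction(self):
        panel = make_panel([(1, y, "1;2", 0) for y in range(2010, 2018)])
        est = ce.estimate_rates(panel, ce.criteria_for("dementia"), disease="dementia")
        assert (est["r"] == 0.0).all()

    def test_recovery_requires_full_followup(self):
        crit = ce.ValidationCriteria(recovery_followup_years=2)
        rows = [
            (1, 2014, "1;2", 0), (1, 2015, "", 0), (1, 2016, "", 0),  # recovered
            (2, 2014, "1;2", 0), (2, 2015, "", 0),                    # censored
            (3, 2014, "1;2", 0), (3, 2015, "", 0), (3, 2016, "1;2", 0),  # relapsed
        ]
        est = ce.estimate_rates(make_panel(rows), crit, disease="test")
        cell = est[est["age"] == 50].iloc[0]
        assert cell["n_recovery_eligible"] == 2  # persons 1 and 3
        assert cell["n_recovered"] == 1

    def test_empty_cells_missing(self):
        panel = make_panel([(1, 2016, "", 0)])
        est = ce.estimate_rates(panel, M2Q, disease="test")
        assert np.isnan(est["i"].item())  # no lookback coverage at all

    def test_md_smoother(self):
        rows = []
        for age in (40, 41, 42):
            for pid in range(20):
                base = age * 1000 + pid
                diseased = pid < 5
                dies = diseased and pid == 0 and age == 41
                rows.append((base, 2016, "1;2" if diseased else "", 0, int(dies), age))
                if not dies:
                    rows.append((base, 2017, "1;2" if diseased else "", 0, 0, age + 1))
        est_raw = ce.estimate_rates(make_panel(rows), M2Q, disease="test")
        est_smooth = ce.estimate_rates(
            make_panel(rows), M2Q, disease="test", smooth_md_window=3
        )
        assert est_smooth["md"].max() <= est_raw["md"].max() + 1e-12

    def test_panel_roundtrip(self, tmp_path):
        truth = sd.uniform_truth(seed=5)
        panel = sd.generate_microsim_panel(truth, 200, (2018, 2021), start_ages=(40, 60))
        path = tmp_path / "panel.tsv"
        ce.write_panel(panel, path)
        back = ce.read_panel(path, disease="synthetic")
        pd.testing.assert_frame_equal(
            back, panel.astype({"inpatient": int}), check_dtype=False
        )


class TestGapFillProperty:
    def test_removing_gap_fill_never_increases_prevalence(self):
        truth = sd.uniform_truth(p0=0.3, i=0.05, r=0.1, md=0.0, sr=0.995, seed=11)
        panel = sd.generate_microsim_panel(
            truth, 3000, (2018, 2025), start_ages=(30, 60), miscoding_rate=0.3
        )
        out = ce.classify_prevalent_years(panel, M2Q)
        assert out["prevalent"].sum() >= out["criteria_met"].sum()
        # and gap-fill fires on this miscoded panel
        assert out["prevalent"].sum() > out["criteria_met"].sum()


TRUE_I, TRUE_R, TRUE_MD, TRUE_SR = 0.01, 0.05, 0.01, 0.97


@pytest.fixture(scope="module")
def recovered():
    p_star = fixed_point_prevalence(TRUE_I, TRUE_R, TRUE_SR, TRUE_MD)
    truth = sd.uniform_truth(p0=p_star, i=TRUE_I, r=TRUE_R, md=TRUE_MD, sr=TRUE_SR, seed=17)
    panel = sd.generate_microsim_panel(truth, 60_000, (2018, 2031), start_ages=(25, 45))
    est = ce.estimate_rates(panel, ce.ValidationCriteria(), disease="synthetic")
    return p_star, est


class TestParameterRecovery:
    """Estimates converge to the generating truth on synthetic panels."""

    I, R, MD, SR = TRUE_I, TRUE_R, TRUE_MD, TRUE_SR

    def test_end_to_end_closure(self, recovered):
        # estimated rates fed to project() reproduce the panel's observed
        # patient counts within Monte-Carlo error
        from prevproj.demography import GENDERS, N_AGES, PopulationPyramid, SurvivalSchedule
        from prevproj.illness_death import RateSchedule, project

        p_star, est = recovered
        truth = sd.uniform_truth(p0=p_star, i=TRUE_I, r=TRUE_R, md=TRUE_MD, sr=TRUE_SR, seed=17)
        panel = sd.generate_microsim_panel(truth, 60_000, (2018, 2031), start_ages=(25, 45))

        grids = {v: np.zeros((N_AGES, 2)) for v in ("p", "i", "r", "md")}
        for _, c in est.iterrows():
            g = GENDERS.index(c["gender"])
            for v in grids:
                if np.isfinite(c[v]):
                    grids[v][int(c["age"]), g] = c[v]
        # estimates need the lookback years; project a medium horizon — the
        # follow-up-window recovery estimator understates the annual r by
        # ~ x(1-i)^F, a documented bias that compounds beyond a few years
        y0, y1 = 2023, 2028
        sub = panel[(panel["year"] >= y0) & (panel["year"] <= y1)]
        counts = sub.groupby(["age", "gender", "year"]).size()
        K = np.zeros((N_AGES, 2, y1 - y0 + 1))
        for (age, gender, year), c in counts.items():
            K[age, GENDERS.index(gender), year - y0] = c
        rates = RateSchedule("synthetic", grids["p"], grids["i"], grids["r"], grids["md"], y0)
        res = project(
            PopulationPyramid(K, y0),
            SurvivalSchedule.constant(truth.sr, y0, y1),
            rates,
            y1,
            keep_ledger=False,
        )
        observed = (
            sub.assign(diseased=sub["quarters"] != "").groupby("year")["diseased"].sum()
        ).to_numpy(float)
        # MC noise of the realised counts plus estimation noise in p0
        se = np.sqrt((res.p * (1 - res.p) * K).sum(axis=(0, 1)))
        assert np.all(np.abs(observed - res.total_patients) <= 4 * se + 0.01 * observed)

    def test_cells_within_three_binomial_se(self, recovered):
        p_star, est = recovered
        cells = est[(est["n_at_risk"] >= 1000) & (est["n_recovery_eligible"] >= 200)]
        assert len(cells) >= 20
        checks = []
        for _, c in cells.iterrows():
            n_p = c["days_total"] / 365.0
            checks.append(abs(c["p"] - p_star) <= 3 * np.sqrt(p_star * (1 - p_star) / n_p))
            checks.append(
                abs(c["i"] - self.I) <= 3 * np.sqrt(self.I * (1 - self.I) / c["n_at_risk"])
            )
            checks.append(
                abs(c["r"] - self.R)
                <= 3 * np.sqrt(self.R * (1 - self.R) / c["n_recovery_eligible"])
            )
            se_md = np.sqrt(
                self.SR * (1 - self.SR) / c["n_survival_known"]
                + (self.SR - self.MD)
                * (1 - self.SR + self.MD)
                / c["n_prev_survival_known"]
            )
            checks.append(abs(c["md"] - self.MD) <= 3 * se_md)
        assert np.mean(checks) >= 0.95
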