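import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_events
from phenotyper import synthetic
from phenotyper.cohort import (
    DEFAULT_RULES,
    OutcomeRules,
    apply_prospective_design,
    build_censor_table,
    build_initial_tte,
    classify_diabetes,
    compute_censor_date,
    incidence_rate,
    refine_tte,
)

TYPE_CODES = synthetic.TYPE_SPECIFIC_CODES


def dm_events(rows):
    frame = make_events(rows)
    frame["outcome_id"] = "DM"
    return frame


class TestClassifyDiabetes:
    def test_t1d_only(self):
        ev = dm_events([("P1", "PRIMARY_CARE", "READ_V2", "C10E.", "2005-01-01",
                         True, "DEFINING")])
        out = classify_diabetes(ev, TYPE_CODES)
        assert out["dm_type"].iloc[0] == "T1D"

    def test_conflicting_types_uncertain(self):
        ev = dm_events([
            ("P1", "PRIMARY_CARE", "READ_V2", "C10E.", "2005-01-01", True, "DEFINING"),
            ("P1", "HOSPITAL", "ICD10", "E11", "2006-01-01", True, "DEFINING"),
        ])
        assert classify_diabetes(ev, TYPE_CODES)["dm_type"].iloc[0] == "UNCERTAIN"

    def test_generic_only_uncertain(self):
        ev = dm_events([("P1", "PRIMARY_CARE", "READ_V2", "C10..", "2005-01-01",
                         True, "DEFINING")])
        assert classify_diabetes(ev, TYPE_CODES)["dm_type"].iloc[0] == "UNCERTAIN"

    def test_date_only_alone_not_assigned(self):
        ev = dm_events([("P1", "PRIMARY_CARE", "READ_V2", "66A..", "2005-01-01",
                         True, "DATE_ONLY")])
        assert classify_diabetes(ev, TYPE_CODES).empty

    def test_first_evidence_uses_date_only_when_gated(self):
        ev = dm_events([
            ("P1", "PRIMARY_CARE", "READ_V2", "66A..", "1999-01-01", True, "DATE_ONLY"),
            ("P1", "PRIMARY_CARE", "READ_V2", "C10F.", "2001-01-01", True, "DEFINING"),
        ])
        out = classify_diabetes(ev, TYPE_CODES)
        assert out["first_evidence_date"].iloc[0] == pd.Timestamp("1999-01-01")
        assert out["dm_type"].iloc[0] == "T2D"


class TestCensorDate:
    def test_death_earliest(self):
        assert compute_censor_date(None, "2016-05-01", "2017-12-31") == \
            pd.Timestamp("2016-05-01")

    def test_lost_earliest(self):
        assert compute_censor_date("2015-01-01", None, "2017-12-31") == \
            pd.Timestamp("2015-01-01")

    def test_showcase_only(self):
        assert compute_censor_date(None, None, "2017-12-31") == pd.Timestamp("2017-12-31")

    def test_missing_showcase_errors(self):
        with pytest.raises(ValueError):
            compute_censor_date("2015-01-01", None, None)

    def test_table_matches_rowwise(self):
        info = pd.DataFrame({
            "participant_id": ["P1", "P2"],
            "lost_to_followup_date": [None, "2015-01-01"],
            "death_date": ["2016-05-01", None],
            "showcase_censor_date": ["2017-12-31", "2017-12-31"],
        })
        table = build_censor_table(info)
        assert list(table["censor_date"]) == [pd.Timestamp("2016-05-01"),
                                              pd.Timestamp("2015-01-01")]


def simple_inputs(event_date=None, index="2008-01-01", censor="2018-01-01",
                  dm="2000-01-01"):
    dm_assign = pd.DataFrame({"participant_id": ["P1"], "dm_type": ["T2D"],
                              "first_evidence_date": [pd.Timestamp(dm)]})
    firsts = pd.DataFrame(columns=["participant_id", "date"])
    if event_date:
        firsts = pd.DataFrame({"participant_id": ["P1"],
                               "date": [pd.Timestamp(event_date)]})
    censor_table = pd.DataFrame({"participant_id": ["P1"],
                                 "censor_date": [pd.Timestamp(censor)]})
    index_dates = pd.Series({"P1": pd.Timestamp(index) if index else pd.NaT})
    return dm_assign, firsts, censor_table, index_dates


class TestBuildInitialTte:
    def test_event_time_four_years(self):
        tte = build_initial_tte(*simple_inputs(event_date="2012-01-01"), "CVD")
        assert tte["status"].iloc[0] == 1
        assert tte["time_years"].iloc[0] == pytest.approx(4.0, abs=0.01)

    def test_censored_time_ten_years(self):
        tte = build_initial_tte(*simple_inputs(), "CVD")
        assert tte["status"].iloc[0] == 0
        assert tte["time_years"].iloc[0] == pytest.approx(10.0, abs=0.01)

    def test_event_after_censor_left_for_refine(self):
        tte = build_initial_tte(*simple_inputs(event_date="2019-06-01"), "CVD")
        assert tte["status"].iloc[0] == 0
        assert tte["event_date"].iloc[0] == pd.Timestamp("2019-06-01")
        assert not tte["excluded"].iloc[0]

    def test_missing_index_excluded_missing_admin(self):
        tte = build_initial_tte(*simple_inputs(index=None), "CVD")
        assert tte["excluded"].iloc[0]
        assert tte["exclusion_reason"].iloc[0] == "missing_admin"


class TestRefineTte:
    def test_event_before_dm(self):
        tte = build_initial_tte(*simple_inputs(event_date="2005-01-01", dm="2007-01-01"),
                                "CVD")
        out = refine_tte(tte)
        assert out["exclusion_reason"].iloc[0] == "event_before_dm"

    def test_event_after_censor(self):
        tte = build_initial_tte(*simple_inputs(event_date="2019-01-01", censor="2017-12-31"),
                                "CVD")
        assert refine_tte(tte)["exclusion_reason"].iloc[0] == "event_after_censor"

    def test_exclusion_condition(self):
        tte = build_initial_tte(*simple_inputs(event_date="2012-01-01"), "CVD")
        out = refine_tte(tte, exclusion_event_ids={"P1"})
        assert out["exclusion_reason"].iloc[0] == "exclusion_condition"


class TestProspectiveDesign:
    def test_index_before_dm_excluded(self):
        tte = build_initial_tte(*simple_inputs(event_date="2012-01-01", dm="2010-01-01"),
                                "CVD")
        tte = refine_tte(tte)
        out = apply_prospective_design(tte, DEFAULT_RULES["CVD"])
        assert out["exclusion_reason"].iloc[0] == "index_not_between"

    def test_dkd_five_year_rule(self):
        tte = build_initial_tte(
            *simple_inputs(event_date="2013-01-01", dm="2010-01-01", index="2010-06-01"),
            "DKD")
        tte["has_primary_care"] = True
        out = apply_prospective_design(refine_tte(tte), DEFAULT_RULES["DKD"])
        assert out["exclusion_reason"].iloc[0] == "short_dm_to_event"

    def test_dm_within_six_months_after_index_retained(self):
        tte = build_initial_tte(*simple_inputs(dm="2009-03-01", index="2009-01-01"), "CVD")
        out = apply_prospective_design(refine_tte(tte), DEFAULT_RULES["CVD"])
        assert not out["excluded"].iloc[0]

    def test_dm_beyond_six_months_excluded(self):
        tte = build_initial_tte(*simple_inputs(dm="2009-08-01", index="2009-01-01"), "CVD")
        out = apply_prospective_design(refine_tte(tte), DEFAULT_RULES["CVD"])
        assert out["exclusion_reason"].iloc[0] == "dm_after_landmark"

    def test_unknown_outcome_without_rules_errors(self):
        tte = build_initial_tte(*simple_inputs(), "NOT_AN_OUTCOME")
        with pytest.raises(ValueError, match="unknown outcome"):
            apply_prospective_design(tte, None)

    def test_every_excluded_row_has_exactly_one_reason(self):
        inputs, _ = synthetic.generate_rule_fixture()
        tte = build_initial_tte(
            inputs["dm_assignments"], inputs["outcome_first_occurrence"],
            inputs["censor_table"], inputs["index_dates"], inputs["outcome_id"],
            has_primary_care=inputs["has_primary_care"],
            hospital_death_event_ids=inputs["hospital_death_event_ids"])
        tte = refine_tte(tte, inputs["exclusion_event_ids"])
        out = apply_prospective_design(tte, DEFAULT_RULES["DKD"])
        excluded = out[out["excluded"]]
        assert excluded["exclusion_reason"].notna().all()
        assert out.loc[~out["excluded"], "exclusion_reason"].isna().all()

    def test_weakening_thresholds_never_shrinks_retained_set(self):
        inputs, _ = synthetic.generate_rule_fixture()
        tte = build_initial_tte(
            inputs["dm_assignments"], inputs["outcome_first_occurrence"],
            inputs["censor_table"], inputs["index_dates"], inputs["outcome_id"],
            has_primary_care=inputs["has_primary_care"],
            hospital_death_event_ids=inputs["hospital_death_event_ids"])
        tte = refine_tte(tte, inputs["exclusion_event_ids"])
        strict = apply_prospective_design(tte, DEFAULT_RULES["DKD"])
        weak = apply_prospective_design(tte, OutcomeRules(
            require_primary_care=False, min_years_dm_to_event=0,
            min_years_dm_followup=0, dm_window_after_index_months=240))
        kept_strict = set(strict.loc[~strict["excluded"], "participant_id"])
        kept_weak = set(weak.loc[~weak["excluded"], "participant_id"])
        assert kept_strict <= kept_weak

    def test_retained_rows_satisfy_invariants(self):
        inputs, _ = synthetic.generate_rule_fixture()
        tte = build_initial_tte(
            inputs["dm_assignments"], inputs["outcome_first_occurrence"],
            inputs["censor_table"], inputs["index_dates"], inputs["outcome_id"],
            has_primary_care=inputs["has_primary_care"],
            hospital_death_event_ids=inputs["hospital_death_event_ids"])
        out = apply_prospective_design(refine_tte(tte, inputs["exclusion_event_ids"]),
                                       DEFAULT_RULES["DKD"])
        kept = out[~out["excluded"]]
        limit = kept["index_date"] + pd.Timedelta(days=182.625)
        assert (kept["dm_first_evidence_date"] <= limit).all()
        events = kept[kept["status"] == 1]
        assert (events["index_date"] <= events["event_date"]).all()
        assert (events["event_date"] <= events["censor_date"]).all()
        assert (kept["time_years"] > 0).all()


class TestIncidenceRate:
    def make_cohort(self, n_events, person_years, n_rows=10):
        times = np.full(n_rows, person_years / n_rows)
        status = np.zeros(n_rows, dtype=int)
        status[:n_events] = 1
        return pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(n_rows)],
            "outcome_id": "CVD", "time_years": times, "status": status,
            "excluded": False,
        })

    def test_rate_arithmetic(self):
        out = incidence_rate(self.make_cohort(2, 100.0))
        assert out["rate_per_1000"] == pytest.approx(20.0)

    def test_zero_events(self):
        out = incidence_rate(self.make_cohort(0, 100.0))
        assert out["rate_per_1000"] == 0.0
        assert out["ci_low"] == 0.0
        assert out["ci_high"] > 0.0

    def test_exact_poisson_ci_matches_gamma_oracle(self):
        out = incidence_rate(self.make_cohort(50, 2000.0, n_rows=100))
        # independent oracle via gamma quantiles (chi2(2k)/2 == Gamma(k, 1))
        lo = stats.gamma.ppf(0.025, 50) / 2000.0 * 1000
        hi = stats.gamma.ppf(0.975, 51) / 2000.0 * 1000
        assert out["ci_low"] == pytest.approx(lo, rel=1e-12)
        assert out["ci_high"] == pytest.approx(hi, rel=1e-12)

    def test_zero_person_years_errors(self):
        cohort = self.make_cohort(0, 0.0)
        with pytest.raises(ValueError):
            incidence_rate(cohort)


class TestRuleFixtureExactness:
    def test_retained_ids_and_reasons_match_expected(self):
        inputs, expected = synthetic.generate_rule_fixture()
        tte = build_initial_tte(
            inputs["dm_assignments"], inputs["outcome_first_occurrence"],
            inputs["censor_table"], inputs["index_dates"], inputs["outcome_id"],
            has_primary_care=inputs["has_primary_care"],
            hospital_death_event_ids=inputs["hospital_death_event_ids"])
        tte = refine_tte(tte, inputs["exclusion_event_ids"])
        out = apply_prospective_design(tte, DEFAULT_RULES["DKD"])
        merged = out.merge(expected, on="participant_id")
        assert (merged["excluded"] == ~merged["retained"]).all()
        for row in merged.itertuples():
            assert (row.exclusion_reason or None) == row.reason
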