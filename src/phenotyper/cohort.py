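"""Diabetes typing, censoring, time-to-event construction, and incidence rates.

The time-to-event table is built in three passes: an initial table from
first occurrences and censoring information, a refinement pass applying the
hard date-logic and exclusion-condition rules, and a prospective-design pass
applying landmark and follow-up requirements. Every excluded row carries
exactly one reason — the first matching rule in a fixed order — so exclusion
counts form a deterministic audit trail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codelist import Role
from .events import first_occurrence

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
SIX_MONTHS_DAYS = 182.625

#: Fixed precedence of exclusion reasons.
EXCLUSION_REASONS = (
    "missing_admin",
    "event_before_dm",
    "event_after_censor",
    "exclusion_condition",
    "index_not_between",
    "dm_after_landmark",
    "no_primary_care",
    "short_dm_to_event",
    "short_followup",
    "non_positive_followup",
)


@dataclass(frozen=True)
class OutcomeRules:
    """Per-outcome prospective-design configuration."""

    require_primary_care: bool = False
    min_years_dm_to_event: float = 0.0
    min_years_dm_followup: float = 0.0
    dm_window_after_index_months: float = 6.0


#: Paper-motivated defaults: kidney disease gets the 5-year rules; the
#: retinopathy cohort requires primary-care linkage but not the 5-year rules.
DEFAULT_RULES = {
    "CVD": OutcomeRules(require_primary_care=False),
    "DKD": OutcomeRules(require_primary_care=True, min_years_dm_to_event=5.0,
                        min_years_dm_followup=5.0),
    "DR": OutcomeRules(require_primary_care=True),
}


def classify_diabetes(
    dm_events: pd.DataFrame,
    type_specific_codes: dict[tuple[str, str], str],
) -> pd.DataFrame:
    """Assign T1D / T2D / UNCERTAIN from code specificity.

    ``dm_events`` is an outcome event table restricted to DEFINING/DATE_ONLY
    diabetes codes; ``type_specific_codes`` tags (system, code) keys as
    ``"T1D"``, ``"T2D"``, or ``"GENERIC"`` (untagged keys count as generic).
    Only participants with at least one DEFINING event are assigned; type is
    T1D/T2D when only that type's specific codes appear, UNCERTAIN when both
    or neither do. ``first_evidence_date`` follows the first-occurrence rule
    (DATE_ONLY dates count once a DEFINING event exists).
    """
    firsts = first_occurrence(dm_events, outcome_id="DM")
    if firsts.empty:
        return pd.DataFrame(columns=["participant_id", "dm_type", "first_evidence_date"])

    ev = dm_events[dm_events["valid"]].copy()
    ev["_type"] = [
        type_specific_codes.get((s, c), "GENERIC") for s, c in zip(ev["system"], ev["code"])
    ]
    type_sets = ev.groupby("participant_id")["_type"].agg(set)

    rows = []
    for row in firsts.itertuples(index=False):
        seen = type_sets.get(row.participant_id, set())
        has_t1 = "T1D" in seen
        has_t2 = "T2D" in seen
        if has_t1 and not has_t2:
            dm_type = "T1D"
        elif has_t2 and not has_t1:
            dm_type = "T2D"
        else:
            dm_type = "UNCERTAIN"
        rows.append((row.participant_id, dm_type, row.date))
    return pd.DataFrame(rows, columns=["participant_id", "dm_type", "first_evidence_date"])


def compute_censor_date(lost_to_followup, death_date, showcase_censor_date):
    """Earliest of loss-to-follow-up, death, and showcase censoring dates."""
    if pd.isna(showcase_censor_date):
        raise ValueError("showcase censoring date must always be present")
    candidates = [
        pd.to_datetime(d)
        for d in (lost_to_followup, death_date, showcase_censor_date)
        if not pd.isna(d)
    ]
    return min(candidates)


def build_censor_table(censor_info: pd.DataFrame) -> pd.DataFrame:
    """Row-wise :func:`compute_censor_date` over a censoring-info table.

    Expects columns participant_id, lost_to_followup_date, death_date,
    showcase_censor_date (the first two may be missing/NaT).
    """
    out = censor_info.copy()
    for col in ("lost_to_followup_date", "death_date", "showcase_censor_date"):
        out[col] = pd.to_datetime(out[col], errors="coerce")
    out["censor_date"] = out[
        ["lost_to_followup_date", "death_date", "showcase_censor_date"]
    ].min(axis=1)
    if out["showcase_censor_date"].isna().any():
        raise ValueError("showcase censoring date must always be present")
    return out


TTE_COLUMNS = [
    "participant_id", "outcome_id", "index_date", "dm_first_evidence_date",
    "event_date", "censor_date", "status", "time_years", "has_primary_care",
    "excluded", "exclusion_reason",
]


def build_initial_tte(
    dm_assignments: pd.DataFrame,
    outcome_first_occurrence: pd.DataFrame,
    censor_table: pd.DataFrame,
    index_dates: pd.Series | dict,
    outcome_id: str,
    has_primary_care: pd.Series | dict | None = None,
    hospital_death_event_ids: set[str] | None = None,
) -> pd.DataFrame:
    """One time-to-event row per diabetes participant.

    Status is 1 when the outcome's first occurrence is on or before the
    censoring date (the raw event date is kept either way so later passes
    can exclude post-censoring events); time runs from the index date in
    365.25-day years. Participants lacking an index date or censoring info
    are flagged excluded with reason ``missing_admin``.
    """
    index_map = pd.Series(index_dates)
    index_map = pd.to_datetime(index_map)
    pc_map = pd.Series(has_primary_care) if has_primary_care is not None else pd.Series(dtype=bool)
    hosp_ids = hospital_death_event_ids or set()

    event_map = dict(zip(outcome_first_occurrence["participant_id"],
                         pd.to_datetime(outcome_first_occurrence["date"])))
    censor_map = dict(zip(censor_table["participant_id"], censor_table["censor_date"]))

    rows = []
    for row in dm_assignments.itertuples(index=False):
        pid = row.participant_id
        index_date = index_map.get(pid, pd.NaT)
        censor_date = censor_map.get(pid, pd.NaT)
        event_date = event_map.get(pid, pd.NaT)
        excluded, reason = False, None
        if pd.isna(index_date) or pd.isna(censor_date):
            excluded, reason = True, "missing_admin"
            status, time_years = 0, np.nan
        else:
            status = int(not pd.isna(event_date) and event_date <= censor_date)
            end = event_date if status == 1 else censor_date
            time_years = (end - index_date).days / DAYS_PER_YEAR
        rows.append({
            "participant_id": pid,
            "outcome_id": outcome_id,
            "index_date": index_date,
            "dm_first_evidence_date": pd.to_datetime(row.first_evidence_date),
            "event_date": event_date,
            "censor_date": censor_date,
            "status": status,
            "time_years": time_years,
            "has_primary_care": bool(pc_map.get(pid, False)),
            "excluded": excluded,
            "exclusion_reason": reason,
        })
    out = pd.DataFrame(rows, columns=TTE_COLUMNS)
    out["_hosp_death_event"] = out["participant_id"].isin(hosp_ids)
    return out


def refine_tte(
    records: pd.DataFrame,
    exclusion_event_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Apply the hard exclusion rules, first matching reason wins.

    Order: event before first DM evidence; event after the censoring date;
    any exclusion-condition event on record. Rows already excluded are left
    untouched.
    """
    out = records.copy()
    exclusion_event_ids = exclusion_event_ids or set()
    open_rows = ~out["excluded"]

    before_dm = (
        open_rows
        & out["event_date"].notna()
        & (out["event_date"] < out["dm_first_evidence_date"])
    )
    _flag(out, before_dm, "event_before_dm")
    open_rows &= ~before_dm

    after_censor = (
        open_rows
        & out["event_date"].notna()
        & (out["event_date"] > out["censor_date"])
    )
    _flag(out, after_censor, "event_after_censor")
    open_rows &= ~after_censor

    has_exclusion = open_rows & out["participant_id"].isin(exclusion_event_ids)
    _flag(out, has_exclusion, "exclusion_condition")
    return out


def _flag(frame: pd.DataFrame, mask: pd.Series, reason: str) -> None:
    if mask.any():
        frame.loc[mask, "excluded"] = True
        frame.loc[mask, "exclusion_reason"] = reason


def apply_prospective_design(
    records: pd.DataFrame,
    rules: OutcomeRules | None = None,
) -> pd.DataFrame:
    """Apply the landmark prospective-design exclusions, in fixed order.

    (a) event rows must have DM first evidence <= index <= event date;
    (b) non-event rows must have DM first evidence within 6 months after
        the index date;
    (c) with ``require_primary_care``, rows without primary-care linkage are
        excluded unless the outcome event came from hospital/death records;
    (d) event rows need >= ``min_years_dm_to_event`` between DM evidence and
        the event; non-event rows need >= ``min_years_dm_followup`` between
        DM evidence and censoring;
    (e) non-positive follow-up time is excluded.
    """
    if rules is None:
        outcome = records["outcome_id"].iloc[0] if len(records) else None
        if outcome not in DEFAULT_RULES:
            raise ValueError(f"unknown outcome {outcome!r}: supply OutcomeRules explicitly")
        rules = DEFAULT_RULES[outcome]

    out = records.copy()
    window_days = rules.dm_window_after_index_months * (SIX_MONTHS_DAYS / 6.0)
    is_event = out["status"] == 1
    open_rows = ~out["excluded"]

    bad_order = open_rows & is_event & ~(
        (out["dm_first_evidence_date"] <= out["index_date"])
        & (out["index_date"] <= out["event_date"])
    )
    _flag(out, bad_order, "index_not_between")
    open_rows &= ~bad_order

    landmark_limit = out["index_date"] + pd.to_timedelta(window_days, unit="D")
    late_dm = open_rows & ~is_event & ~(out["dm_first_evidence_date"] <= landmark_limit)
    _flag(out, late_dm, "dm_after_landmark")
    open_rows &= ~late_dm

    if rules.require_primary_care:
        hosp = out.get("_hosp_death_event", pd.Series(False, index=out.index))
        no_pc = open_rows & ~out["has_primary_care"] & ~(is_event & hosp)
        _flag(out, no_pc, "no_primary_care")
        open_rows &= ~no_pc

    if rules.min_years_dm_to_event > 0:
        span = (out["event_date"] - out["dm_first_evidence_date"]).dt.days / DAYS_PER_YEAR
        short = open_rows & is_event & (span < rules.min_years_dm_to_event)
        _flag(out, short, "short_dm_to_event")
        open_rows &= ~short
    if rules.min_years_dm_followup > 0:
        span = (out["censor_date"] - out["dm_first_evidence_date"]).dt.days / DAYS_PER_YEAR
        short = open_rows & ~is_event & (span < rules.min_years_dm_followup)
        _flag(out, short, "short_followup")
        open_rows &= ~short

    nonpos = open_rows & ~(out["time_years"] > 0)
    _flag(out, nonpos, "non_positive_followup")

    counts = out.loc[out["excluded"], "exclusion_reason"].value_counts()
    if len(counts):
        logger.info("prospective design exclusions: %s", counts.to_dict())
    return out


def incidence_rate(cohort: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Events per 1,000 person-years with an exact Poisson CI.

    The CI uses the chi-square relation: lower = χ²(α/2; 2k)/2,
    upper = χ²(1−α/2; 2k+2)/2 on the event count k, scaled by person-years.
    """
    kept = cohort[~cohort["excluded"]]
    if kept.empty:
        raise ValueError("cohort has no unexcluded rows")
    person_years = float(kept["time_years"].sum())
    if person_years <= 0:
        raise ValueError("zero person-years")
    n_events = int(kept["status"].sum())
    rate = 1000.0 * n_events / person_years
    lower_count = stats.chi2.ppf(alpha / 2, 2 * n_events) / 2 if n_events > 0 else 0.0
    upper_count = stats.chi2.ppf(1 - alpha / 2, 2 * n_events + 2) / 2
    return {
        "outcome_id": cohort["outcome_id"].iloc[0] if len(cohort) else None,
        "n_events": n_events,
        "person_years": person_years,
        "rate_per_1000": rate,
        "ci_low": 1000.0 * lower_count / person_years,
        "ci_high": 1000.0 * upper_count / person_years,
    }
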