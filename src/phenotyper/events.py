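"""Master event table construction, date cleaning, and first occurrences.

Raw rows are never deleted: date problems set ``valid=False`` with a reason
tag so the audit trail survives every step. All dates are day-resolution
ISO-8601 calendar dates held as pandas datetime64 values.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import pandas as pd

from .codelist import Codelist, Role, SchemaError

logger = logging.getLogger(__name__)

EVENT_COLUMNS = [
    "participant_id", "source", "system", "code", "event_date", "valid", "invalid_reason",
]

#: Default placeholder dates observed in UKB-style extracts (configurable).
DEFAULT_PLACEHOLDER_DATES = (
    "1900-01-01", "1901-01-01", "1902-02-02", "1903-03-03", "2037-07-07",
)

#: Tie-break priority for the reported source of a first occurrence when two
#: sources share the minimal date (the date itself is unaffected).
SOURCE_PRIORITY = (
    "PRIMARY_CARE", "HOSPITAL", "DEATH", "SELF_REPORT", "FIRST_OCC_FIELD",
    "ALGO_FIELD", "CUSTOM_FIELD", "BIOMARKER_DERIVED",
)


class EventSource(str, enum.Enum):
    FIRST_OCC_FIELD = "FIRST_OCC_FIELD"
    ALGO_FIELD = "ALGO_FIELD"
    HOSPITAL = "HOSPITAL"
    DEATH = "DEATH"
    SELF_REPORT = "SELF_REPORT"
    PRIMARY_CARE = "PRIMARY_CARE"
    CUSTOM_FIELD = "CUSTOM_FIELD"
    BIOMARKER_DERIVED = "BIOMARKER_DERIVED"


@dataclass(frozen=True)
class FieldSpec:
    """Binding of assessment-table columns to an event source.

    Either ``code_col`` names a column holding the clinical code, or
    ``fixed_code`` supplies a constant code (used for date-only fields such
    as first-occurrence or algorithmically-defined outcome fields).
    """

    date_col: str
    source: str
    system: str
    code_col: str | None = None
    fixed_code: str | None = None

    def __post_init__(self) -> None:
        if (self.code_col is None) == (self.fixed_code is None):
            raise ValueError("exactly one of code_col / fixed_code must be set")
        EventSource(self.source)


def _empty_events() -> pd.DataFrame:
    frame = pd.DataFrame(columns=EVENT_COLUMNS)
    frame["event_date"] = pd.to_datetime(frame["event_date"])
    frame["valid"] = frame["valid"].astype(bool)
    return frame


def _finalize(rows: list[dict]) -> pd.DataFrame:
    if not rows:
        return _empty_events()
    frame = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    frame["event_date"] = pd.to_datetime(frame["event_date"], errors="coerce")
    missing = frame["event_date"].isna() & frame["valid"]
    frame.loc[missing, "valid"] = False
    frame.loc[missing, "invalid_reason"] = "missing_date"
    return frame


def build_master_event_table(
    assessment_table: pd.DataFrame,
    hospital_table: pd.DataFrame,
    death_table: pd.DataFrame,
    field_map: list[FieldSpec],
) -> pd.DataFrame:
    """Unpivot wide assessment fields and append long hospital/death rows.

    One EventRecord is emitted per non-missing (participant, code, date)
    cell. A present code with a missing date still yields a row, flagged
    ``valid=False`` / ``missing_date``.
    """
    rows: list[dict] = []

    if "participant_id" not in assessment_table.columns:
        raise SchemaError("missing required column(s): participant_id")
    for spec in field_map:
        needed = [spec.date_col] + ([spec.code_col] if spec.code_col else [])
        absent = [c for c in needed if c not in assessment_table.columns]
        if absent:
            raise SchemaError(
                f"field_map references column(s) absent from assessment table: {', '.join(absent)}"
            )
        for row in assessment_table.itertuples(index=False):
            raw_date = getattr(row, spec.date_col)
            if spec.code_col is not None:
                code = getattr(row, spec.code_col)
                if pd.isna(code) or str(code) == "":
                    continue
                code = str(code)
            else:
                code = spec.fixed_code
                if pd.isna(raw_date) or str(raw_date) == "":
                    continue  # date-only field: missing date means no event
            has_date = not (pd.isna(raw_date) or str(raw_date) == "")
            rows.append({
                "participant_id": str(row.participant_id),
                "source": spec.source,
                "system": spec.system,
                "code": code,
                "event_date": raw_date if has_date else pd.NaT,
                "valid": has_date,
                "invalid_reason": "" if has_date else "missing_date",
            })

    for table, source in ((hospital_table, "HOSPITAL"), (death_table, "DEATH")):
        if table is None or table.empty:
            continue
        needed = ("participant_id", "date", "system", "code")
        absent = [c for c in needed if c not in table.columns]
        if absent:
            raise SchemaError(f"missing required column(s): {', '.join(absent)}")
        for row in table.itertuples(index=False):
            if pd.isna(row.code) or str(row.code) == "":
                continue
            has_date = not (pd.isna(row.date) or str(row.date) == "")
            rows.append({
                "participant_id": str(row.participant_id),
                "source": source,
                "system": str(row.system),
                "code": str(row.code),
                "event_date": row.date if has_date else pd.NaT,
                "valid": has_date,
                "invalid_reason": "" if has_date else "missing_date",
            })

    return _finalize(rows)


def gp_to_events(gp_table: pd.DataFrame) -> pd.DataFrame:
    """Primary-care clinical rows (participant, date, system, code) as events."""
    needed = ("participant_id", "date", "system", "code")
    absent = [c for c in needed if c not in gp_table.columns]
    if absent:
        raise SchemaError(f"missing required column(s): {', '.join(absent)}")
    rows = []
    for row in gp_table.itertuples(index=False):
        if pd.isna(row.code) or str(row.code) == "":
            continue
        has_date = not (pd.isna(row.date) or str(row.date) == "")
        rows.append({
            "participant_id": str(row.participant_id),
            "source": "PRIMARY_CARE",
            "system": str(row.system),
            "code": str(row.code),
            "event_date": row.date if has_date else pd.NaT,
            "valid": has_date,
            "invalid_reason": "" if has_date else "missing_date",
        })
    return _finalize(rows)


def clean_dates(
    records: pd.DataFrame,
    plausibility_window: tuple[str, str] = ("1930-01-01", "2025-12-31"),
    placeholder_dates: tuple[str, ...] = DEFAULT_PLACEHOLDER_DATES,
    birth_dates: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Flag placeholder, pre-birth, and out-of-window dates invalid.

    Nothing is deleted; the returned copy has ``valid=False`` plus a reason
    tag (``placeholder`` / ``pre_birth`` / ``out_of_window``) on offending
    rows. Placeholder takes precedence, then pre-birth, then window.
    """
    out = records.copy()
    dates = out["event_date"]
    has_date = dates.notna()

    placeholders = pd.to_datetime(list(placeholder_dates))
    is_placeholder = has_date & dates.isin(placeholders)

    if birth_dates is not None:
        births = pd.Series(birth_dates)
        births = pd.to_datetime(births)
        born = out["participant_id"].map(births)
        is_pre_birth = has_date & born.notna() & (dates < born) & ~is_placeholder
    else:
        is_pre_birth = pd.Series(False, index=out.index)

    lo, hi = pd.to_datetime(plausibility_window[0]), pd.to_datetime(plausibility_window[1])
    out_of_window = has_date & ((dates < lo) | (dates > hi)) & ~is_placeholder & ~is_pre_birth

    for mask, reason in (
        (is_placeholder, "placeholder"),
        (is_pre_birth, "pre_birth"),
        (out_of_window, "out_of_window"),
    ):
        newly = mask & out["valid"]
        out.loc[mask, "valid"] = False
        out.loc[newly, "invalid_reason"] = reason
    return out


def extract_outcome_events(
    records: pd.DataFrame,
    codelist: Codelist,
    roles: set[Role] | frozenset[Role] = frozenset({Role.DEFINING, Role.DATE_ONLY}),
) -> pd.DataFrame:
    """Valid records whose (system, code) is in the codelist with a wanted role."""
    if len(codelist) == 0:
        raise ValueError(f"empty codelist for outcome {codelist.outcome_id!r}")
    roles = {Role(r) for r in roles}
    wanted = {key: role for key, (_, role) in codelist.entries.items() if role in roles}
    out = records[records["valid"]].copy()
    keys = list(zip(out["system"], out["code"]))
    keep = [k in wanted for k in keys]
    out = out[keep].copy()
    out["role"] = [wanted[k].value for k, kept in zip(keys, keep) if kept]
    out["outcome_id"] = codelist.outcome_id
    return out.reset_index(drop=True)


def merge_outcome_events(*tables: pd.DataFrame) -> pd.DataFrame:
    """Concatenate per-source outcome event tables, collapsing exact duplicates.

    All inputs must carry the same ``outcome_id``. Duplicates are exact
    (participant, date, system, code) matches; the surviving row's source is
    chosen by :data:`SOURCE_PRIORITY` so the merge is order-independent.
    """
    frames = [t for t in tables if t is not None and not t.empty]
    if not frames:
        out = _empty_events()
        out["role"] = pd.Series(dtype=str)
        out["outcome_id"] = pd.Series(dtype=str)
        return out
    outcome_ids = {t["outcome_id"].iloc[0] for t in frames}
    if len(outcome_ids) > 1:
        raise ValueError(f"outcome_id mismatch across merged tables: {sorted(outcome_ids)}")
    merged = pd.concat(frames, ignore_index=True)
    rank = {s: i for i, s in enumerate(SOURCE_PRIORITY)}
    merged["_rank"] = merged["source"].map(rank).fillna(len(rank)).astype(int)
    merged = merged.sort_values(
        ["participant_id", "event_date", "system", "code", "_rank"], kind="mergesort"
    )
    merged = merged.drop_duplicates(
        subset=["participant_id", "event_date", "system", "code"], keep="first"
    )
    return merged.drop(columns="_rank").reset_index(drop=True)


def first_occurrence(
    merged_events: pd.DataFrame,
    outcome_id: str,
    role_filter: set[Role] | frozenset[Role] = frozenset({Role.DEFINING, Role.DATE_ONLY}),
) -> pd.DataFrame:
    """Earliest valid event date per participant for one outcome.

    DATE_ONLY events may supply the date only for participants who also have
    at least one DEFINING event (two-category rule); participants with no
    qualifying events are simply absent. The reported source follows
    :data:`SOURCE_PRIORITY` on date ties.
    """
    roles = {Role(r).value for r in role_filter}
    ev = merged_events[merged_events["valid"] & merged_events["event_date"].notna()].copy()
    if "role" not in ev.columns:
        ev["role"] = Role.DEFINING.value
    ev = ev[ev["role"].isin(roles)]
    if ev.empty:
        return pd.DataFrame(columns=["participant_id", "outcome_id", "date", "source"])

    if Role.DATE_ONLY.value in roles:
        has_defining = set(ev.loc[ev["role"] == Role.DEFINING.value, "participant_id"])
        ev = ev[(ev["role"] != Role.DATE_ONLY.value) | ev["participant_id"].isin(has_defining)]

    rank = {s: i for i, s in enumerate(SOURCE_PRIORITY)}
    ev["_rank"] = ev["source"].map(rank).fillna(len(rank)).astype(int)
    ev = ev.sort_values(["participant_id", "event_date", "_rank"], kind="mergesort")
    firsts = ev.groupby("participant_id", sort=True).head(1)
    out = firsts[["participant_id", "event_date", "source"]].rename(columns={"event_date": "date"})
    out.insert(1, "outcome_id", outcome_id)
    return out.reset_index(drop=True)
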