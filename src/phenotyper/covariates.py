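"""Baseline covariate panel: ethnicity recode, Charlson index, MET, ISCED.

Mapping tables (Quan ICD-10 Charlson prefixes with original weights, the
qualification-to-ISCED map, and the four-group ethnicity recode) ship as
editable TSV data files alongside the package.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _data_path(name: str):
    return resources.files("phenotyper.data").joinpath(name)


@lru_cache(maxsize=None)
def load_charlson_mapping() -> dict[str, tuple[str, int]]:
    """ICD-10 prefix -> (category, weight), Quan mapping / original weights."""
    table = pd.read_csv(_data_path("charlson_icd10.tsv"), sep="\t", dtype=str)
    return {row.prefix: (row.category, int(row.weight)) for row in table.itertuples(index=False)}


@lru_cache(maxsize=None)
def load_isced_mapping() -> dict[str, int]:
    table = pd.read_csv(_data_path("isced_map.tsv"), sep="\t", dtype=str)
    return {row.qualification: int(row.isced_level) for row in table.itertuples(index=False)}


@lru_cache(maxsize=None)
def load_ethnicity_mapping() -> dict[str, str]:
    table = pd.read_csv(_data_path("ethnicity_map.tsv"), sep="\t", dtype=str)
    return {row.top_level_digit: row.ethnicity4 for row in table.itertuples(index=False)}


def recode_ethnicity(raw_code, mapping: dict[str, str] | None = None):
    """Collapse a hierarchical self-report ethnicity code to four groups.

    The top-level digit decides: 1 -> White, 3 -> Asian, 4 -> Black, all
    other digits (mixed, Chinese, other) -> Other. Missing or negative
    (declined/unknown) codes stay missing for imputation to handle.
    """
    if raw_code is None or (isinstance(raw_code, float) and np.isnan(raw_code)):
        return np.nan
    try:
        code = int(raw_code)
    except (TypeError, ValueError):
        return np.nan
    if code < 0:
        return np.nan
    mapping = mapping or load_ethnicity_mapping()
    return mapping.get(str(code)[0], "Other")


def _normalize_icd10(code: str) -> str:
    return str(code).replace(".", "").strip().upper()


def map_charlson_category(icd10_code: str,
                          mapping: dict[str, tuple[str, int]] | None = None):
    """Longest-prefix Charlson category lookup; None when unmappable."""
    mapping = mapping or load_charlson_mapping()
    code = _normalize_icd10(icd10_code)
    for length in range(min(len(code), 4), 2, -1):
        hit = mapping.get(code[:length])
        if hit is not None:
            return hit
    return None


def compute_cci(
    diagnoses: pd.DataFrame,
    index_date,
    mapping: dict[str, tuple[str, int]] | None = None,
) -> int:
    """Charlson Comorbidity Index for one participant.

    ``diagnoses`` carries (code, date) ICD-10 rows; only rows dated strictly
    before ``index_date`` count, each Charlson category at most once.
    Unmappable codes are ignored (logged at debug level).
    """
    if diagnoses is None or diagnoses.empty:
        return 0
    mapping = mapping or load_charlson_mapping()
    index_date = pd.to_datetime(index_date)
    dates = pd.to_datetime(diagnoses["date"])
    prior = diagnoses[dates < index_date]
    seen: dict[str, int] = {}
    for code in prior["code"]:
        hit = map_charlson_category(code, mapping)
        if hit is None:
            logger.debug("unmappable ICD-10 code %r ignored in CCI", code)
            continue
        category, weight = hit
        seen[category] = weight
    return int(sum(seen.values()))


def compute_cci_table(
    hospital_diagnoses: pd.DataFrame,
    index_dates: pd.Series | dict,
    mapping: dict[str, tuple[str, int]] | None = None,
) -> pd.Series:
    """CCI per participant; participants without admissions score 0."""
    index_map = pd.to_datetime(pd.Series(index_dates))
    out = {}
    groups = dict(tuple(hospital_diagnoses.groupby("participant_id"))) if len(hospital_diagnoses) else {}
    for pid, idx in index_map.items():
        out[pid] = compute_cci(groups.get(pid), idx, mapping)
    return pd.Series(out, name="cci")


def compute_met(
    walk_days=0, walk_min=0,
    moderate_days=0, moderate_min=0,
    vigorous_days=0, vigorous_min=0,
) -> float:
    """IPAQ total activity in MET-hours/week.

    MET-minutes/week = 3.3×walk + 4.0×moderate + 8.0×vigorous (days ×
    minutes per day each); divided by 60 for hours.
    """
    met_minutes = (
        3.3 * float(walk_days) * float(walk_min)
        + 4.0 * float(moderate_days) * float(moderate_min)
        + 8.0 * float(vigorous_days) * float(vigorous_min)
    )
    return met_minutes / 60.0


def compute_isced(
    highest_qualification,
    mapping: dict[str, int] | None = None,
) -> tuple[float, float]:
    """(ISCED level, level>2 flag); both NaN when unmapped or missing."""
    if highest_qualification is None or (
        isinstance(highest_qualification, float) and np.isnan(highest_qualification)
    ):
        return (np.nan, np.nan)
    mapping = mapping or load_isced_mapping()
    level = mapping.get(str(highest_qualification))
    if level is None:
        return (np.nan, np.nan)
    return (float(level), float(level > 2))


def assemble_panel(
    cohort: pd.DataFrame,
    demographics: pd.DataFrame,
    covariate_pieces: dict[str, pd.DataFrame] | None = None,
    biomarker_summaries: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Left-join covariate pieces onto the retained cohort rows.

    ``demographics`` must carry participant_id, sex and birth_date (used for
    age at index). Each covariate piece is keyed by participant_id; duplicate
    keys raise. Biomarker summaries in long form pivot to ``mean_<biomarker>``
    and ``cv_<biomarker>`` columns. Missingness is preserved for imputation.
    """
    panel = cohort.loc[~cohort["excluded"],
                       ["participant_id", "outcome_id", "index_date", "time_years", "status"]].copy()

    pieces = dict(covariate_pieces or {})
    pieces["demographics"] = demographics
    for name, piece in pieces.items():
        if piece is None or piece.empty:
            continue
        if piece["participant_id"].duplicated().any():
            raise ValueError(f"duplicate participant rows in covariate piece {name!r}")
        panel = panel.merge(piece, on="participant_id", how="left")

    if "birth_date" in panel.columns:
        birth = pd.to_datetime(panel["birth_date"])
        panel["age_at_index"] = (pd.to_datetime(panel["index_date"]) - birth).dt.days / 365.25
        panel = panel.drop(columns=["birth_date"])

    if biomarker_summaries is not None and not biomarker_summaries.empty:
        wide = biomarker_summaries.pivot(
            index="participant_id", columns="biomarker", values=["mean", "cv"]
        )
        wide.columns = [f"{stat}_{biomarker}" for stat, biomarker in wide.columns]
        panel = panel.merge(wide.reset_index(), on="participant_id", how="left")

    return panel.reset_index(drop=True)
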