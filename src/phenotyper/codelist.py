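"""Terminology dictionaries and curated, role-tagged outcome codelists.

The curation workflow is: build a master dictionary from several terminology
tables, search descriptions by keyword, expand Read v2 children by code
prefix, forward-map between Read v2 and CTV3, drop codes never used in the
primary-care event table, then apply reviewer annotations that keep/drop
codes and assign roles.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

DICT_COLUMNS = ("system", "code", "description")


class CodeSystem(str, enum.Enum):
    READ_V2 = "READ_V2"
    CTV3 = "CTV3"
    ICD10 = "ICD10"
    OPCS4 = "OPCS4"
    SELF_REPORT_ILLNESS = "SELF_REPORT_ILLNESS"
    SELF_REPORT_OPERATION = "SELF_REPORT_OPERATION"
    TPP_LOCAL = "TPP_LOCAL"
    UKB_FIELD = "UKB_FIELD"


class Role(str, enum.Enum):
    DEFINING = "DEFINING"
    DATE_ONLY = "DATE_ONLY"
    EXCLUSION = "EXCLUSION"


@dataclass(frozen=True, order=True)
class ClinicalCode:
    """A (system, code) terminology entry; description is informative only."""

    system: str
    code: str
    description: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("code must be non-empty")
        system = CodeSystem(self.system).value  # validates
        object.__setattr__(self, "system", system)
        if not self.description and system != CodeSystem.UKB_FIELD.value:
            # Empty descriptions are tolerated but noted; only UKB_FIELD is
            # allowed to be nameless by contract.
            logger.debug("empty description for %s %s", system, self.code)

    @property
    def key(self) -> tuple[str, str]:
        return (self.system, self.code)


class SchemaError(ValueError):
    """An input table is missing a required column."""


def _require_columns(table: pd.DataFrame, columns: tuple[str, ...]) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")


@dataclass
class MasterDictionary:
    """Union of terminology tables, unique on (system, code)."""

    entries: dict[tuple[str, str], ClinicalCode] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.entries

    def get(self, system: str, code: str) -> ClinicalCode | None:
        return self.entries.get((system, code))

    def codes(self) -> list[ClinicalCode]:
        return list(self.entries.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [(c.system, c.code, c.description) for c in self.entries.values()]
        return pd.DataFrame(rows, columns=list(DICT_COLUMNS))


@dataclass
class Codelist:
    """Role-tagged code set for one outcome."""

    outcome_id: str
    entries: dict[tuple[str, str], tuple[ClinicalCode, Role]] = field(default_factory=dict)

    def add(self, code: ClinicalCode, role: Role) -> None:
        if code.key in self.entries:
            raise ValueError(f"code {code.key} appears twice in codelist {self.outcome_id}")
        self.entries[code.key] = (code, Role(role))

    def codes_with_role(self, roles: set[Role] | frozenset[Role]) -> set[tuple[str, str]]:
        roles = {Role(r) for r in roles}
        return {k for k, (_, role) in self.entries.items() if role in roles}

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (c.system, c.code, c.description, role.value)
            for c, role in sorted(self.entries.values(), key=lambda e: (e[0].system, e[0].code))
        ]
        return pd.DataFrame(rows, columns=["system", "code", "description", "role"])


@dataclass
class MappingTable:
    """Undirected READ_V2 <-> CTV3 code pairs."""

    pairs: set[tuple[tuple[str, str], tuple[str, str]]] = field(default_factory=set)

    def add(self, a: ClinicalCode | tuple[str, str], b: ClinicalCode | tuple[str, str]) -> None:
        ka = a.key if isinstance(a, ClinicalCode) else tuple(a)
        kb = b.key if isinstance(b, ClinicalCode) else tuple(b)
        self.pairs.add((ka, kb))

    def partners(self, key: tuple[str, str]) -> set[tuple[str, str]]:
        out = set()
        for a, b in self.pairs:
            if a == key:
                out.add(b)
            elif b == key:
                out.add(a)
        return out


def build_master_dictionary(dictionaries: list[pd.DataFrame]) -> MasterDictionary:
    """Union terminology tables into one dictionary.

    Duplicate (system, code) rows collapse keeping the first description seen;
    the number of collapsed duplicates is logged. Conflicting descriptions for
    the same key produce a warning, not an error.
    """
    master = MasterDictionary()
    n_dup = 0
    for table in dictionaries:
        _require_columns(table, DICT_COLUMNS)
        for row in table.itertuples(index=False):
            system = str(row.system)
            code = str(row.code)
            desc = "" if pd.isna(row.description) else str(row.description)
            key = (system, code)
            if key in master.entries:
                n_dup += 1
                kept = master.entries[key].description
                if desc and kept and desc != kept:
                    logger.warning(
                        "conflicting descriptions for %s %s: kept %r, ignored %r",
                        system, code, kept, desc,
                    )
                continue
            master.entries[key] = ClinicalCode(system, code, desc)
    if n_dup:
        logger.info("collapsed %d duplicate dictionary rows", n_dup)
    return master


def search_terms(
    dictionary: MasterDictionary,
    include_keywords: list[str],
    exclude_keywords: list[str] | None = None,
    seed_codes: set[ClinicalCode] | None = None,
    regex: bool = False,
) -> set[ClinicalCode]:
    """Keyword search over descriptions; exclusion keywords take precedence.

    Matching is case-insensitive substring by default; ``regex=True`` treats
    keywords as case-insensitive regular expressions. Seed codes pass through
    untouched (they are not subject to exclusion keywords).
    """
    seed_codes = set(seed_codes or ())
    exclude_keywords = exclude_keywords or []
    if not include_keywords and not seed_codes:
        raise ValueError("nothing to search: empty include keywords and no seed codes")

    if regex:
        inc = [re.compile(k, re.IGNORECASE) for k in include_keywords]
        exc = [re.compile(k, re.IGNORECASE) for k in exclude_keywords]

        def matches(desc: str, pats) -> bool:
            return any(p.search(desc) for p in pats)
    else:
        inc = [k.lower() for k in include_keywords]
        exc = [k.lower() for k in exclude_keywords]

        def matches(desc: str, pats) -> bool:
            low = desc.lower()
            return any(p in low for p in pats)

    hits = {
        entry
        for entry in dictionary.entries.values()
        if matches(entry.description, inc) and not matches(entry.description, exc)
    }
    return seed_codes | hits


def _strip_dots(code: str) -> str:
    return code.rstrip(".")


def expand_children(
    dictionary: MasterDictionary, parent_codes: set[str] | list[str]
) -> set[ClinicalCode]:
    """All READ_V2 entries whose dot-stripped code has a parent as prefix.

    Read v2 is a 5-character prefix hierarchy padded with trailing dots; the
    parent itself is included when present. Parents absent from the
    dictionary only warn — expansion is purely prefix-based.
    """
    prefixes = []
    for parent in parent_codes:
        stripped = _strip_dots(parent)
        if (CodeSystem.READ_V2.value, parent) not in dictionary and not any(
            e.system == CodeSystem.READ_V2.value and _strip_dots(e.code) == stripped
            for e in dictionary.entries.values()
        ):
            logger.warning("parent code %r not in dictionary; expanding by prefix anyway", parent)
        prefixes.append(stripped)
    return {
        entry
        for entry in dictionary.entries.values()
        if entry.system == CodeSystem.READ_V2.value
        and any(_strip_dots(entry.code).startswith(p) for p in prefixes)
    }


def forward_map(codes: set[ClinicalCode], mapping: MappingTable,
                dictionary: MasterDictionary | None = None) -> set[ClinicalCode]:
    """Augment a code set with its one-step map partners.

    Partners found in ``dictionary`` keep their dictionary description;
    otherwise a bare entry is created. The number of additions is logged.
    """
    out = set(codes)
    keys = {c.key for c in codes}
    added = 0
    for code in codes:
        for partner in mapping.partners(code.key):
            if partner in keys:
                continue
            entry = dictionary.entries.get(partner) if dictionary else None
            if entry is None:
                entry = ClinicalCode(partner[0], partner[1], "")
            if entry not in out:
                out.add(entry)
                keys.add(partner)
                added += 1
    logger.info("forward mapping added %d code(s)", added)
    return out


def filter_by_usage(codes: set[ClinicalCode], primary_care_events: pd.DataFrame) -> set[ClinicalCode]:
    """Retain only codes occurring at least once in the event table."""
    if primary_care_events.empty:
        return set()
    _require_columns(primary_care_events, ("system", "code"))
    used = set(
        zip(primary_care_events["system"].astype(str), primary_care_events["code"].astype(str))
    )
    return {c for c in codes if c.key in used}


def apply_review_annotations(
    codes: set[ClinicalCode],
    annotations: dict[tuple[str, str] | str, str],
    outcome_id: str,
) -> Codelist:
    """Build the final codelist from reviewer annotations.

    ``annotations`` maps a (system, code) key — or a bare code string when
    unambiguous — to one of ``keep``/``drop``/``date_only``/``exclusion``.
    Unannotated candidates default to DEFINING with a logged warning.
    """
    by_key = {c.key: c for c in codes}
    by_code: dict[str, list[tuple[str, str]]] = {}
    for key in by_key:
        by_code.setdefault(key[1], []).append(key)

    resolved: dict[tuple[str, str], str] = {}
    unknown = []
    for ref, action in annotations.items():
        if isinstance(ref, str):
            keys = by_code.get(ref, [])
            if not keys:
                unknown.append(ref)
                continue
            for key in keys:
                resolved[key] = action
        else:
            key = tuple(ref)
            if key not in by_key:
                unknown.append(f"{key[0]}:{key[1]}")
                continue
            resolved[key] = action
    if unknown:
        raise ValueError(f"annotations reference unknown code(s): {', '.join(sorted(unknown))}")

    action_to_role = {
        "keep": Role.DEFINING,
        "date_only": Role.DATE_ONLY,
        "exclusion": Role.EXCLUSION,
    }
    result = Codelist(outcome_id=outcome_id)
    n_default = 0
    for key in sorted(by_key):
        action = resolved.get(key)
        if action is None:
            n_default += 1
            result.add(by_key[key], Role.DEFINING)
            continue
        if action == "drop":
            continue
        if action not in action_to_role:
            raise ValueError(f"unknown annotation action {action!r} for {key}")
        result.add(by_key[key], action_to_role[action])
    if n_default:
        logger.warning("%d unannotated candidate(s) defaulted to DEFINING", n_default)
    return result


# ---------------------------------------------------------------------------
# File I/O — UTF-8 TSV with header system\tcode\tdescription[\trole]

def read_dictionary_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(table, DICT_COLUMNS)
    return table


def read_codelist_tsv(path, outcome_id: str) -> Codelist:
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(table, ("system", "code", "role"))
    cl = Codelist(outcome_id=outcome_id)
    for row in table.itertuples(index=False):
        desc = getattr(row, "description", "")
        cl.add(ClinicalCode(row.system, row.code, desc), Role(row.role))
    return cl


def write_codelist_tsv(codelist: Codelist, path) -> None:
    codelist.to_frame().to_csv(path, sep="\t", index=False)


def read_annotations_tsv(path) -> dict[str, str]:
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(table, ("code", "action"))
    return dict(zip(table["code"], table["action"]))
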