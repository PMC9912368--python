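"""Longitudinal biomarker curation, eGFR/uACR derivation, and landmark summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical units per biomarker.
CANONICAL_UNITS = {
    "GLUCOSE": "mmol/L",
    "HBA1C": "mmol/mol",
    "URINE_ALBUMIN": "mg/L",
    "URINE_CREATININE": "mmol/L",
    "UACR": "mg/mmol",
    "SERUM_CREATININE": "umol/L",
    "SBP": "mmHg",
    "DBP": "mmHg",
    "TOTAL_CHOL": "mmol/L",
    "HDL": "mmol/L",
    "LDL": "mmol/L",
    "TRIG": "mmol/L",
    "EGFR": "ml/min/1.73m2",
}

#: Plausibility bounds (canonical units); values outside are flagged invalid.
DEFAULT_BOUNDS = {
    "GLUCOSE": (0.5, 60.0),
    "HBA1C": (10.0, 200.0),
    "URINE_ALBUMIN": (0.0, 5000.0),
    "URINE_CREATININE": (0.1, 100.0),
    "UACR": (0.0, 3000.0),
    "SERUM_CREATININE": (10.0, 3000.0),
    "SBP": (40.0, 300.0),
    "DBP": (20.0, 200.0),
    "TOTAL_CHOL": (0.5, 30.0),
    "HDL": (0.1, 10.0),
    "LDL": (0.1, 20.0),
    "TRIG": (0.1, 50.0),
    "EGFR": (1.0, 250.0),
}

MEASUREMENT_COLUMNS = [
    "participant_id", "date", "biomarker", "value", "unit_original", "valid",
]


def extract_trajectories(
    primary_care_values: pd.DataFrame,
    assessment_measures: pd.DataFrame,
    biomarker_code_map: dict[tuple[str, str], str],
    unit_rules: dict[tuple[str, str], float],
    bounds: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Combine value-bearing GP rows and assessment measures into trajectories.

    ``primary_care_values`` rows carry (participant_id, date, system, code,
    value, unit); ``biomarker_code_map`` binds (system, code) to a biomarker
    name; ``unit_rules`` maps (biomarker, unit_string) to the multiplicative
    factor converting to the canonical unit. ``assessment_measures`` rows
    already carry (participant_id, date, biomarker, value, unit).

    Output is unit-harmonized, per-participant date-sorted, with implausible
    values flagged ``valid=False``. Unmapped unit strings raise, listing the
    offenders.
    """
    bounds = DEFAULT_BOUNDS if bounds is None else bounds
    rows = []
    bad_units: set[tuple[str, str]] = set()

    if primary_care_values is not None and not primary_care_values.empty:
        for row in primary_care_values.itertuples(index=False):
            biomarker = biomarker_code_map.get((str(row.system), str(row.code)))
            if biomarker is None or pd.isna(row.value):
                continue
            unit = "" if pd.isna(row.unit) else str(row.unit)
            factor = _unit_factor(biomarker, unit, unit_rules, bad_units)
            rows.append((str(row.participant_id), row.date, biomarker,
                         float(row.value) * (factor or 1.0), unit))

    if assessment_measures is not None and not assessment_measures.empty:
        for row in assessment_measures.itertuples(index=False):
            if pd.isna(row.value):
                continue
            biomarker = str(row.biomarker)
            unit = "" if pd.isna(row.unit) else str(row.unit)
            factor = _unit_factor(biomarker, unit, unit_rules, bad_units)
            rows.append((str(row.participant_id), row.date, biomarker,
                         float(row.value) * (factor or 1.0), unit))

    if bad_units:
        listing = ", ".join(f"{b}:{u!r}" for b, u in sorted(bad_units))
        raise ValueError(f"unmapped unit string(s): {listing}")

    frame = pd.DataFrame(rows, columns=["participant_id", "date", "biomarker", "value", "unit_original"])
    frame["date"] = pd.to_datetime(frame["date"])
    lo = frame["biomarker"].map({k: v[0] for k, v in bounds.items()})
    hi = frame["biomarker"].map({k: v[1] for k, v in bounds.items()})
    frame["valid"] = ~((frame["value"] < lo) | (frame["value"] > hi)).fillna(False)
    frame = frame.sort_values(["participant_id", "biomarker", "date"], kind="mergesort")
    return frame.reset_index(drop=True)


def _unit_factor(biomarker, unit, unit_rules, bad_units):
    canonical = CANONICAL_UNITS.get(biomarker)
    if unit == "" or unit == canonical:
        return 1.0
    factor = unit_rules.get((biomarker, unit))
    if factor is None:
        bad_units.add((biomarker, unit))
        return None
    return factor


def compute_egfr(
    serum_creatinine,
    age,
    sex,
    black_race=False,
    creatinine_unit: str = "mg/dL",
    race_term: bool = True,
):
    """CKD-EPI 2009 creatinine eGFR in ml/min/1.73 m².

    eGFR = 141 × min(Scr/κ, 1)^α × max(Scr/κ, 1)^(−1.209) × 0.993^age
             × 1.018 [if female] × 1.159 [if black and race term enabled]
    with κ = 0.7 (female) / 0.9 (male) and α = −0.329 / −0.411. Creatinine
    in µmol/L is divided by 88.4 first. ``sex`` is "F"/"M" (or 0/1 with 0 =
    female). Vectorized over numpy arrays.
    """
    scr = np.asarray(serum_creatinine, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(scr <= 0) or np.any(age <= 0):
        raise ValueError("serum creatinine and age must be positive")
    if creatinine_unit in ("umol/L", "µmol/L"):
        scr = scr / 88.4
    elif creatinine_unit != "mg/dL":
        raise ValueError(f"unsupported creatinine unit {creatinine_unit!r}")

    sex_arr = np.asarray(sex)
    if sex_arr.dtype.kind in "US":
        female = np.char.upper(sex_arr.astype(str)) == "F"
    else:
        female = sex_arr == 0
    black = np.asarray(black_race, dtype=bool)

    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.329, -0.411)
    ratio = scr / kappa
    egfr = (
        141.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.209
        * 0.993 ** age
    )
    egfr = egfr * np.where(female, 1.018, 1.0)
    if race_term:
        egfr = egfr * np.where(black, 1.159, 1.0)
    return egfr if egfr.shape else float(egfr)


def compute_uacr(
    albumin: pd.DataFrame,
    creatinine: pd.DataFrame,
    pairing_window_days: int = 7,
) -> pd.DataFrame:
    """Pair urine albumin (mg/L) with urine creatinine (mmol/L) into uACR.

    Each albumin measurement is paired with the nearest-dated creatinine
    measurement for the same participant within the window; date-distance
    ties resolve to the earlier creatinine. Unpaired albumin rows and pairs
    with zero creatinine are skipped (counts logged).

    Both inputs carry (participant_id, date, value); output rows carry
    (participant_id, date, biomarker="UACR", value in mg/mmol).
    """
    alb = albumin.copy()
    cre = creatinine.copy()
    alb["date"] = pd.to_datetime(alb["date"])
    cre["date"] = pd.to_datetime(cre["date"])
    cre_by_pid: dict[str, pd.DataFrame] = {
        pid: grp.sort_values("date", kind="mergesort") for pid, grp in cre.groupby("participant_id")
    }
    rows = []
    n_unpaired = 0
    n_zero = 0
    for row in alb.sort_values(["participant_id", "date"], kind="mergesort").itertuples(index=False):
        pool = cre_by_pid.get(row.participant_id)
        if pool is None or pool.empty:
            n_unpaired += 1
            continue
        deltas = (pool["date"] - row.date).abs().dt.days
        eligible = pool[deltas <= pairing_window_days]
        if eligible.empty:
            n_unpaired += 1
            continue
        d = deltas[eligible.index]
        best = eligible.loc[d == d.min()].sort_values("date", kind="mergesort").iloc[0]
        if best["value"] == 0:
            n_zero += 1
            continue
        rows.append((row.participant_id, row.date, "UACR", row.value / best["value"]))
    if n_unpaired:
        logger.info("compute_uacr: %d albumin measurement(s) had no creatinine partner", n_unpaired)
    if n_zero:
        logger.info("compute_uacr: %d pair(s) skipped for zero creatinine", n_zero)
    return pd.DataFrame(rows, columns=["participant_id", "date", "biomarker", "value"])


def detect_albuminuria_events(
    uacr: pd.DataFrame,
    micro_threshold: float = 3.0,
    macro_threshold: float = 30.0,
) -> pd.DataFrame:
    """First threshold crossings of the uACR trajectory (mg/mmol).

    MICROALBUMINURIA fires at the first date with uACR >= micro threshold,
    MACROALBUMINURIA at the first date with uACR >= macro threshold; both may
    fire (possibly on the same date).
    """
    if micro_threshold >= macro_threshold:
        raise ValueError("micro threshold must be below macro threshold")
    rows = []
    traj = uacr.copy()
    traj["date"] = pd.to_datetime(traj["date"])
    for pid, grp in traj.sort_values("date", kind="mergesort").groupby("participant_id"):
        for kind, threshold in (("MICROALBUMINURIA", micro_threshold),
                                ("MACROALBUMINURIA", macro_threshold)):
            hit = grp[grp["value"] >= threshold]
            if not hit.empty:
                rows.append((pid, kind, hit["date"].iloc[0]))
    return pd.DataFrame(rows, columns=["participant_id", "kind", "date"])


def detect_prolonged_low_egfr(
    egfr: pd.DataFrame,
    threshold: float = 60.0,
    min_span_days: int = 90,
) -> pd.DataFrame:
    """Sustained low-eGFR events.

    An event fires at the first measurement M2 such that some earlier
    measurement M1 satisfies date(M2) − date(M1) >= ``min_span_days`` and
    every measurement in [M1, M2] is below ``threshold``; the event date is
    date(M2). Re-running on the same trajectory is idempotent.
    """
    rows = []
    traj = egfr.copy()
    traj["date"] = pd.to_datetime(traj["date"])
    for pid, grp in traj.sort_values("date", kind="mergesort").groupby("participant_id"):
        dates = grp["date"].to_numpy()
        values = grp["value"].to_numpy()
        run_start = None  # start date of current uninterrupted low run
        event_date = None
        for d, v in zip(dates, values):
            if v < threshold:
                if run_start is None:
                    run_start = d
                elif (d - run_start) / np.timedelta64(1, "D") >= min_span_days:
                    event_date = d
                    break
            else:
                run_start = None
        if event_date is not None:
            rows.append((pid, "LOW_EGFR_PROLONGED", event_date))
    return pd.DataFrame(rows, columns=["participant_id", "kind", "date"])


def summarize_landmark(
    trajectory: pd.DataFrame,
    window_start,
    window_end,
    cv_min_n: int = 2,
) -> pd.DataFrame:
    """Per-(participant, biomarker) mean and CV within a landmark window.

    CV = sample sd / mean, reported as NaN when fewer than ``cv_min_n``
    in-window measurements exist or the mean is non-positive. Windows may be
    per-participant (pass dict/Series keyed by participant) or global dates.
    """
    window_start_map = window_start if isinstance(window_start, (dict, pd.Series)) else None
    window_end_map = window_end if isinstance(window_end, (dict, pd.Series)) else None
    if window_start_map is None and pd.to_datetime(window_start) > pd.to_datetime(window_end):
        raise ValueError("window_start must not be after window_end")

    traj = trajectory.copy()
    traj["date"] = pd.to_datetime(traj["date"])
    if "valid" in traj.columns:
        traj = traj[traj["valid"]]

    if window_start_map is not None:
        lo = traj["participant_id"].map(pd.Series(window_start_map))
    else:
        lo = pd.Series(pd.to_datetime(window_start), index=traj.index)
    if window_end_map is not None:
        hi = traj["participant_id"].map(pd.Series(window_end_map))
    else:
        hi = pd.Series(pd.to_datetime(window_end), index=traj.index)
    traj = traj[(traj["date"] >= pd.to_datetime(lo)) & (traj["date"] <= pd.to_datetime(hi))]

    rows = []
    for (pid, biomarker), grp in traj.groupby(["participant_id", "biomarker"]):
        values = grp["value"].to_numpy(dtype=float)
        n = len(values)
        mean = float(np.mean(values))
        if n >= cv_min_n and mean > 0:
            cv = float(np.std(values, ddof=1) / mean)
        else:
            cv = np.nan
        rows.append((pid, biomarker, n, mean, cv))
    return pd.DataFrame(rows, columns=["participant_id", "biomarker", "n_measurements", "mean", "cv"])
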