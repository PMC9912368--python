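"""Synthetic EHR-shaped inputs with planted ground truth.

Generates the six input tables the pipeline consumes — terminology
dictionaries, a primary-care clinical event table, hospital and death
records, a baseline assessment table, and seed codelists — plus a ground
truth object sufficient to predict what every pipeline stage should
produce. Everything is deterministic given the config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

# ---------------------------------------------------------------------------
# Fixture terminology: a miniature dictionary with Read-v2-style prefixes so
# hierarchy expansion, forward mapping and keyword search are all exercised.

_READ_V2_ROWS = [
    ("C10..", "Diabetes mellitus"),
    ("C100.", "Diabetes mellitus with no mention of complication"),
    ("C1000", "Diabetes mellitus, juvenile type, no mention of complication"),
    ("C1001", "Diabetes mellitus, adult onset, no mention of complication"),
    ("C104.", "Diabetes mellitus with renal manifestation"),
    ("C108.", "Insulin dependent diabetes mellitus"),
    ("C109.", "Non-insulin dependent diabetes mellitus"),
    ("C10E.", "Type 1 diabetes mellitus"),
    ("C10F.", "Type 2 diabetes mellitus"),
    ("C10N.", "Secondary diabetes mellitus"),
    ("L1808", "Gestational diabetes mellitus"),
    ("66A..", "Diabetic monitoring"),
    ("66A2.", "Diabetic annual review"),
    ("9OL..", "Diabetes monitoring administration"),
    ("F420.", "Diabetic retinopathy"),
    ("F4200", "Background diabetic retinopathy"),
    ("K01..", "Nephrotic syndrome"),
    ("K05..", "Chronic renal failure"),
    ("G3...", "Ischaemic heart disease"),
    ("G30..", "Acute myocardial infarction"),
    ("H33..", "Asthma"),
    ("42W5.", "Haemoglobin A1c level - diabetic control"),
    ("44g..", "Plasma glucose level"),
    ("44J3.", "Serum creatinine"),
    ("46TC.", "Urine microalbumin"),
    ("46M7.", "Urine creatinine"),
    ("2469.", "O/E - systolic blood pressure reading"),
    ("246A.", "O/E - diastolic blood pressure reading"),
    ("44P..", "Serum cholesterol"),
]

_CTV3_ROWS = [
    ("X40J4", "Type 1 diabetes mellitus"),
    ("X40J5", "Type 2 diabetes mellitus"),
    ("XE10F", "Diabetes mellitus"),
    ("XE10G", "Diabetic retinopathy"),
    ("XE10H", "Diabetic nephropathy"),
    ("XE2q5", "Chronic renal impairment"),
    ("XaELQ", "Asthma annual review"),
]

_TPP_ROWS = [
    ("Y1234", "Local diabetes clinic attendance"),
    ("Y5678", "Local podiatry referral"),
]

#: (READ_V2, CTV3) forward-mapping pairs in the fixture terminology.
FIXTURE_MAP_PAIRS = [
    (("READ_V2", "C10E."), ("CTV3", "X40J4")),
    (("READ_V2", "C10F."), ("CTV3", "X40J5")),
    (("READ_V2", "C10.."), ("CTV3", "XE10F")),
    (("READ_V2", "F420."), ("CTV3", "XE10G")),
]

#: DM codes considered type-specific for diabetes classification.
TYPE_SPECIFIC_CODES = {
    ("READ_V2", "C10E."): "T1D",
    ("READ_V2", "C1000"): "T1D",
    ("READ_V2", "C108."): "T1D",
    ("CTV3", "X40J4"): "T1D",
    ("ICD10", "E10"): "T1D",
    ("READ_V2", "C10F."): "T2D",
    ("READ_V2", "C1001"): "T2D",
    ("READ_V2", "C109."): "T2D",
    ("CTV3", "X40J5"): "T2D",
    ("ICD10", "E11"): "T2D",
}

#: Role-tagged fixture codelists per outcome (system, code, role).
FIXTURE_CODELISTS = {
    "DM": [
        ("READ_V2", "C10..", "DEFINING"),
        ("READ_V2", "C100.", "DEFINING"),
        ("READ_V2", "C1000", "DEFINING"),
        ("READ_V2", "C1001", "DEFINING"),
        ("READ_V2", "C108.", "DEFINING"),
        ("READ_V2", "C109.", "DEFINING"),
        ("READ_V2", "C10E.", "DEFINING"),
        ("READ_V2", "C10F.", "DEFINING"),
        ("CTV3", "X40J4", "DEFINING"),
        ("CTV3", "X40J5", "DEFINING"),
        ("CTV3", "XE10F", "DEFINING"),
        ("ICD10", "E10", "DEFINING"),
        ("ICD10", "E11", "DEFINING"),
        ("SELF_REPORT_ILLNESS", "1220", "DEFINING"),
        ("READ_V2", "66A..", "DATE_ONLY"),
        ("READ_V2", "66A2.", "DATE_ONLY"),
        ("READ_V2", "9OL..", "DATE_ONLY"),
    ],
    "DKD": [
        ("READ_V2", "C104.", "DEFINING"),
        ("CTV3", "XE10H", "DEFINING"),
        ("ICD10", "N18", "DEFINING"),
        ("READ_V2", "K01..", "EXCLUSION"),
        ("READ_V2", "K05..", "EXCLUSION"),
        ("CTV3", "XE2q5", "EXCLUSION"),
    ],
    "CVD": [
        ("READ_V2", "G30..", "DEFINING"),
        ("ICD10", "I21", "DEFINING"),
        ("ICD10", "I63", "DEFINING"),
        ("OPCS4", "K49", "DEFINING"),
    ],
    "DR": [
        ("READ_V2", "F420.", "DEFINING"),
        ("READ_V2", "F4200", "DEFINING"),
        ("CTV3", "XE10G", "DEFINING"),
        ("ICD10", "H360", "DEFINING"),
    ],
}

#: Primary-care biomarker code bindings used by the generator.
BIOMARKER_CODES = {
    ("READ_V2", "44g.."): "GLUCOSE",
    ("READ_V2", "42W5."): "HBA1C",
    ("READ_V2", "44J3."): "SERUM_CREATININE",
    ("READ_V2", "46TC."): "URINE_ALBUMIN",
    ("READ_V2", "46M7."): "URINE_CREATININE",
    ("READ_V2", "2469."): "SBP",
    ("READ_V2", "246A."): "DBP",
    ("READ_V2", "44P.."): "TOTAL_CHOL",
}

_BIOMARKER_MODELS = {
    # biomarker: (mu, between-sd, slope-sd per year, noise-sd, visits/year)
    "GLUCOSE": (7.5, 1.5, 0.10, 0.8, 1.5),
    "HBA1C": (52.0, 8.0, 0.50, 3.0, 1.5),
    "SBP": (138.0, 12.0, 0.30, 8.0, 2.0),
    "DBP": (82.0, 8.0, 0.10, 6.0, 2.0),
    "SERUM_CREATININE": (80.0, 15.0, 1.00, 6.0, 1.0),
    "URINE_ALBUMIN": (20.0, 10.0, 1.00, 5.0, 0.8),
    "URINE_CREATININE": (10.0, 3.0, 0.05, 1.5, 0.8),
    "TOTAL_CHOL": (4.8, 0.8, 0.02, 0.4, 1.0),
}


def fixture_dictionaries() -> list[pd.DataFrame]:
    """The three fixture terminology tables (Read v2, CTV3, TPP local)."""
    frames = []
    for system, rows in (("READ_V2", _READ_V2_ROWS), ("CTV3", _CTV3_ROWS),
                         ("TPP_LOCAL", _TPP_ROWS)):
        frames.append(pd.DataFrame(
            [(system, code, desc) for code, desc in rows],
            columns=["system", "code", "description"],
        ))
    return frames


def fixture_codelist_frames() -> dict[str, pd.DataFrame]:
    out = {}
    for outcome, rows in FIXTURE_CODELISTS.items():
        out[outcome] = pd.DataFrame(rows, columns=["system", "code", "role"])
    return out


# ---------------------------------------------------------------------------
# Simulation config and full-cohort generator

@dataclass
class SimulationConfig:
    n_participants: int
    seed: int
    primary_care_linkage_prob: float = 0.45
    dm_prevalence: float = 0.55
    t1d_fraction: float = 0.08
    # complication log-hazard-ratios over named covariates
    beta: dict = field(default_factory=lambda: {
        "age_c10": 0.5, "sex_male": 0.5, "bmi_c": 0.04,
    })
    baseline_hazard: float = 0.035  # events / person-year at covariate zero
    index_date: str = "2008-06-01"
    showcase_censor_date: str = "2017-12-31"
    death_prob: float = 0.05
    lost_prob: float = 0.03
    missingness_rate: float = 0.10
    placeholder_rate: float = 0.01
    outcomes: tuple = ("CVD", "DKD")

    def __post_init__(self) -> None:
        for name in ("primary_care_linkage_prob", "dm_prevalence", "t1d_fraction",
                     "death_prob", "lost_prob", "missingness_rate", "placeholder_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class GroundTruth:
    participants: pd.DataFrame  # per-participant latent quantities
    beta: dict
    baseline_hazard: float
    n_placeholder_rows: int
    config: SimulationConfig


_QUALIFICATIONS = [
    "College or University degree", "A levels/AS levels or equivalent",
    "O levels/GCSEs or equivalent", "CSEs or equivalent",
    "NVQ or HND or HNC or equivalent",
    "Other professional qualifications eg: nursing, teaching",
    "None of the above",
]

_ETHNICITY_CODES = [1001, 1002, 1003, 2001, 3001, 3002, 4001, 4002, 5, 6, -1, -3]


def generate_cohort(config: SimulationConfig) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Generate all six input tables plus ground truth.

    Complication times for each outcome are drawn from an exponential
    proportional-hazards model h(t) = h0·exp(x'β) measured from the index
    date; the linear predictor uses (age−60)/10, male sex, and centered BMI.
    DM onsets precede the index date for most diabetics so landmark rules
    are exercised in both directions.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    pids = np.array([f"P{i:05d}" for i in range(1, n + 1)])
    index_date = pd.Timestamp(config.index_date)
    showcase = pd.Timestamp(config.showcase_censor_date)

    sex = np.where(rng.random(n) < 0.55, "M", "F")
    age_at_index = rng.uniform(40, 70, n)
    birth_dates = index_date - pd.to_timedelta((age_at_index * DAYS_PER_YEAR).round(), unit="D")
    bmi = rng.normal(30, 4, n).clip(17, 55)
    linked = rng.random(n) < config.primary_care_linkage_prob
    gp_first_date = index_date - pd.to_timedelta(rng.uniform(8, 18, n) * DAYS_PER_YEAR, unit="D")

    is_dm = rng.random(n) < config.dm_prevalence
    dm_type = np.where(rng.random(n) < config.t1d_fraction, "T1D", "T2D")
    # DM onset: mostly before index, occasionally up to 2y after (trips landmark rule)
    onset_offset_years = rng.exponential(6.0, n) - rng.uniform(0, 2.0, n)
    dm_onset = index_date - pd.to_timedelta(onset_offset_years * DAYS_PER_YEAR, unit="D")
    dm_onset = pd.Series(dm_onset).dt.floor("D")

    died = rng.random(n) < config.death_prob
    death_dates = index_date + pd.to_timedelta(rng.uniform(0.5, 9.0, n) * DAYS_PER_YEAR, unit="D")
    lost = rng.random(n) < config.lost_prob
    lost_dates = index_date + pd.to_timedelta(rng.uniform(0.5, 8.0, n) * DAYS_PER_YEAR, unit="D")

    censor = pd.Series(showcase, index=range(n))
    censor = censor.where(~died, pd.Series(death_dates).dt.floor("D").clip(upper=showcase))
    censor = pd.concat(
        [censor, pd.Series(lost_dates).dt.floor("D").where(lost, pd.NaT)], axis=1
    ).min(axis=1)

    # complication latent times per outcome (years from index)
    x_lin = (
        config.beta.get("age_c10", 0.0) * (age_at_index - 60) / 10
        + config.beta.get("sex_male", 0.0) * (sex == "M")
        + config.beta.get("bmi_c", 0.0) * (bmi - 30)
    )
    hazards = config.baseline_hazard * np.exp(x_lin)
    latent_times = {
        outcome: rng.exponential(1.0 / hazards) for outcome in config.outcomes
    }
    if all((latent > 50).all() for latent in latent_times.values()):
        logger.warning("hazard configuration produced essentially no events")

    truth = pd.DataFrame({
        "participant_id": pids,
        "sex": sex,
        "age_at_index": age_at_index,
        "bmi": bmi,
        "is_dm": is_dm,
        "dm_type": np.where(is_dm, dm_type, ""),
        "dm_onset_date": dm_onset.where(pd.Series(is_dm), pd.NaT),
        "has_primary_care": linked,
        "gp_first_date": pd.Series(gp_first_date).dt.floor("D"),
        "censor_date": censor,
        "death_date": pd.Series(death_dates).dt.floor("D").where(pd.Series(died), pd.NaT),
        "lost_date": pd.Series(lost_dates).dt.floor("D").where(pd.Series(lost), pd.NaT),
        "linear_predictor": x_lin,
        "hazard": hazards,
    })
    for outcome in config.outcomes:
        # cap far-future latent times so dates stay within pandas' range
        times = np.minimum(latent_times[outcome], 200.0)
        event_date = index_date + pd.to_timedelta(times * DAYS_PER_YEAR, unit="D")
        truth[f"latent_years_{outcome}"] = times
        truth[f"latent_date_{outcome}"] = pd.Series(event_date).dt.floor("D")

    gp_rows: list[tuple] = []
    hosp_rows: list[tuple] = []
    death_rows: list[tuple] = []

    for i in range(n):
        pid = pids[i]
        if is_dm[i]:
            onset = dm_onset.iloc[i]
            defining = ("C10E." if dm_type[i] == "T1D" else "C10F.")
            if linked[i]:
                gp_rows.append((pid, onset, "READ_V2", defining, np.nan, ""))
                # date-only monitoring codes after onset
                for k in range(rng.poisson(2)):
                    gp_rows.append((pid, onset + pd.Timedelta(days=int(rng.integers(30, 2000))),
                                    "READ_V2", "66A..", np.nan, ""))
            if rng.random() < 0.6 or not linked[i]:
                hosp_rows.append((pid, onset + pd.Timedelta(days=int(rng.integers(0, 365))),
                                  "ICD10", "E10" if dm_type[i] == "T1D" else "E11"))
        # unrelated admissions so the comorbidity index varies
        for _ in range(rng.poisson(0.7)):
            admit = index_date + pd.Timedelta(days=int(rng.integers(-4000, 3000)))
            hosp_rows.append((pid, admit, "ICD10",
                              str(rng.choice(["J44", "I50", "C50", "K26", "M06", "S72"]))))
        for outcome in config.outcomes:
            event_date = truth.loc[i, f"latent_date_{outcome}"]
            if event_date > showcase + pd.Timedelta(days=int(3 * DAYS_PER_YEAR)):
                continue  # far latent events leave no record anywhere
            if outcome == "CVD":
                hosp_rows.append((pid, event_date, "ICD10", "I21"))
            else:  # DKD: coded in GP when linked, hospital for a fraction otherwise
                if linked[i]:
                    gp_rows.append((pid, event_date, "READ_V2", "C104.", np.nan, ""))
                elif rng.random() < 0.5:
                    hosp_rows.append((pid, event_date, "ICD10", "N18"))
        if died[i]:
            death_rows.append((pid, truth.loc[i, "death_date"], "ICD10",
                               "I21" if rng.random() < 0.3 else "C349"))

    # biomarker trajectories for linked participants
    for i in range(n):
        if not linked[i]:
            continue
        pid = pids[i]
        start = truth.loc[i, "gp_first_date"]
        span_years = (showcase - start).days / DAYS_PER_YEAR
        for (system, code), biomarker in BIOMARKER_CODES.items():
            mu, sd_b, sd_s, sd_e, rate = _BIOMARKER_MODELS[biomarker]
            subject_mean = rng.normal(mu, sd_b)
            slope = rng.normal(0.0, sd_s)
            n_visits = rng.poisson(rate * span_years)
            if n_visits == 0:
                continue
            ts = np.sort(rng.uniform(0, span_years, n_visits))
            values = subject_mean + slope * ts + rng.normal(0, sd_e, n_visits)
            values = np.maximum(values, 0.1)
            for t, v in zip(ts, values):
                date = start + pd.Timedelta(days=int(t * DAYS_PER_YEAR))
                gp_rows.append((pid, date, system, code, round(float(v), 2), ""))

    gp = pd.DataFrame(gp_rows, columns=["participant_id", "date", "system", "code", "value", "unit"])
    hospital = pd.DataFrame(hosp_rows, columns=["participant_id", "date", "system", "code"])
    death = pd.DataFrame(death_rows, columns=["participant_id", "date", "system", "code"])

    # placeholder-date injection into GP diagnosis rows
    n_placeholder = 0
    if len(gp) and config.placeholder_rate > 0:
        candidates = gp.index[gp["value"].isna()]
        inject = candidates[rng.random(len(candidates)) < config.placeholder_rate]
        gp.loc[inject, "date"] = pd.Timestamp("1901-01-01")
        n_placeholder = len(inject)

    ethnicity = rng.choice(_ETHNICITY_CODES, n)
    qualification = rng.choice(_QUALIFICATIONS, n)
    assessment = pd.DataFrame({
        "participant_id": pids,
        "birth_date": birth_dates.floor("D"),
        "sex": sex,
        "index_date": index_date,
        "ethnicity_code": ethnicity,
        "qualification": qualification,
        "ever_smoked": (rng.random(n) < 0.5).astype(int),
        "pack_years": np.round(rng.exponential(15, n), 1),
        "bmi": np.round(bmi, 1),
        "insulin": (rng.random(n) < 0.2).astype(int),
        "bp_med": (rng.random(n) < 0.6).astype(int),
        "chol_med": (rng.random(n) < 0.7).astype(int),
        "walk_days": rng.integers(0, 8, n),
        "walk_min": rng.integers(0, 61, n),
        "moderate_days": rng.integers(0, 8, n),
        "moderate_min": rng.integers(0, 61, n),
        "vigorous_days": rng.integers(0, 8, n),
        "vigorous_min": rng.integers(0, 61, n),
        "sr_dm_code": np.where(is_dm & (rng.random(n) < 0.6), "1220", ""),
        "lost_to_followup_date": truth["lost_date"].to_numpy(),
        "death_date": truth["death_date"].to_numpy(),
        "showcase_censor_date": showcase,
        "has_primary_care": linked.astype(int),
        "gp_first_date": truth["gp_first_date"].to_numpy(),
    })
    assessment["sr_dm_date"] = np.where(
        assessment["sr_dm_code"] != "", truth["dm_onset_date"].to_numpy(), np.datetime64("NaT"))

    if config.missingness_rate > 0:
        for col in ("bmi", "pack_years", "qualification", "ethnicity_code"):
            mask = rng.random(n) < config.missingness_rate
            assessment.loc[mask, col] = np.nan

    tables = {
        "dictionaries": fixture_dictionaries(),
        "gp_clinical": gp.reset_index(drop=True),
        "hospital": hospital,
        "death": death,
        "assessment": assessment,
        "codelists": fixture_codelist_frames(),
    }
    ground_truth = GroundTruth(
        participants=truth, beta=dict(config.beta),
        baseline_hazard=config.baseline_hazard,
        n_placeholder_rows=n_placeholder, config=config,
    )
    return tables, ground_truth


# ---------------------------------------------------------------------------
# Hand-constructed rule fixture: one participant per cohort exclusion rule

def generate_rule_fixture() -> tuple[dict, pd.DataFrame]:
    """Cohort-module inputs with one participant per exclusion rule.

    Returns ``(inputs, expected)`` where ``inputs`` feeds
    ``build_initial_tte`` → ``refine_tte`` → ``apply_prospective_design``
    (outcome DKD: primary care required, 5-year rules on), and ``expected``
    lists the designed retention flag and exclusion reason per participant.
    """
    showcase = "2017-12-31"
    index = "2008-01-01"
    # pid: (dm_onset, index, event, has_pc, hosp_event, in_exclusion, lost, retained, reason)
    rows = {
        "S01": ("2000-01-01", index, "2010-01-01", True, False, False, None, True, None),
        "S02": ("2005-06-01", index, None, True, False, False, None, True, None),
        "S03": ("2001-01-01", index, "2011-05-01", False, True, False, None, True, None),
        "S04": ("2008-03-01", index, None, True, False, False, None, True, None),
        "V01": ("2007-01-01", index, "2005-01-01", True, False, False, None, False, "event_before_dm"),
        "V02": ("2000-01-01", index, "2019-06-01", True, False, False, None, False, "event_after_censor"),
        "V03": ("2002-01-01", index, "2012-01-01", True, False, True, None, False, "exclusion_condition"),
        "V04": ("2010-01-01", index, "2012-01-01", True, False, False, None, False, "index_not_between"),
        "V05": ("2009-03-01", index, None, True, False, False, None, False, "dm_after_landmark"),
        "V06": ("2003-01-01", index, None, False, False, False, None, False, "no_primary_care"),
        "V07": ("2007-06-01", index, "2011-01-01", True, False, False, None, False, "short_dm_to_event"),
        "V08": ("2014-01-01", "2014-01-01", None, True, False, False, None, False, "short_followup"),
        "V09": ("2003-01-01", "2010-01-01", "2010-01-01", True, False, False, None, False, "non_positive_followup"),
        "V10": ("2002-01-01", None, None, True, False, False, None, False, "missing_admin"),
    }

    dm_assignments = pd.DataFrame({
        "participant_id": list(rows),
        "dm_type": "T2D",
        "first_evidence_date": pd.to_datetime([r[0] for r in rows.values()]),
    })
    outcome_firsts = pd.DataFrame(
        [(pid, r[2]) for pid, r in rows.items() if r[2] is not None],
        columns=["participant_id", "date"],
    )
    outcome_firsts["date"] = pd.to_datetime(outcome_firsts["date"])
    censor_table = pd.DataFrame({
        "participant_id": list(rows),
        "lost_to_followup_date": pd.to_datetime([r[6] for r in rows.values()]),
        "death_date": pd.NaT,
        "showcase_censor_date": pd.Timestamp(showcase),
    })
    censor_table["censor_date"] = censor_table[
        ["lost_to_followup_date", "death_date", "showcase_censor_date"]].min(axis=1)
    index_dates = pd.Series(
        {pid: (pd.Timestamp(r[1]) if r[1] else pd.NaT) for pid, r in rows.items()})
    has_primary_care = pd.Series({pid: r[3] for pid, r in rows.items()})
    hospital_death_event_ids = {pid for pid, r in rows.items() if r[4]}
    exclusion_event_ids = {pid for pid, r in rows.items() if r[5]}

    inputs = {
        "dm_assignments": dm_assignments,
        "outcome_first_occurrence": outcome_firsts,
        "censor_table": censor_table,
        "index_dates": index_dates,
        "has_primary_care": has_primary_care,
        "hospital_death_event_ids": hospital_death_event_ids,
        "exclusion_event_ids": exclusion_event_ids,
        "outcome_id": "DKD",
    }
    expected = pd.DataFrame({
        "participant_id": list(rows),
        "retained": [r[7] for r in rows.values()],
        "reason": [r[8] for r in rows.values()],
    })
    return inputs, expected


# ---------------------------------------------------------------------------
# Small generators for analysis-module oracles

def simulate_survival_panel(
    n: int,
    beta: dict[str, float],
    seed: int,
    baseline_hazard: float = 0.1,
    censor_years: float = 10.0,
    n_noise: int = 0,
) -> pd.DataFrame:
    """Exponential proportional-hazards panel with known coefficients.

    Covariates named in ``beta`` are standard normal except names containing
    "bin", which are Bernoulli(0.5); ``n_noise`` extra null covariates
    ``noise_i`` are appended. Administrative censoring at ``censor_years``.
    """
    rng = np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {}
    lp = np.zeros(n)
    for name, coef in beta.items():
        x = (rng.random(n) < 0.5).astype(float) if "bin" in name else rng.normal(0, 1, n)
        data[name] = x
        lp += coef * x
    for i in range(n_noise):
        data[f"noise_{i}"] = rng.normal(0, 1, n)
    times = rng.exponential(1.0 / (baseline_hazard * np.exp(lp)))
    status = (times <= censor_years).astype(int)
    data["time_years"] = np.minimum(times, censor_years)
    data["status"] = status
    frame = pd.DataFrame(data)
    frame.insert(0, "participant_id", [f"S{i:06d}" for i in range(n)])
    return frame


def generate_random_outcome_events(
    n_participants: int,
    seed: int,
    mean_events: float = 3.0,
    outcome_id: str = "DM",
) -> pd.DataFrame:
    """Random merged-format outcome event table for first-occurrence oracles.

    Events carry random dates, sources, DEFINING/DATE_ONLY roles and an
    occasional invalid flag, so the gating and min-date rules are both
    exercised.
    """
    rng = np.random.default_rng(seed)
    sources = ["PRIMARY_CARE", "HOSPITAL", "DEATH", "SELF_REPORT", "FIRST_OCC_FIELD"]
    base = pd.Timestamp("1995-01-01")
    rows = []
    for i in range(n_participants):
        pid = f"R{i:05d}"
        for _ in range(rng.poisson(mean_events)):
            date = base + pd.Timedelta(days=int(rng.integers(0, 8000)))
            role = "DEFINING" if rng.random() < 0.6 else "DATE_ONLY"
            valid = rng.random() > 0.1
            rows.append((pid, str(rng.choice(sources)), "READ_V2",
                         "C10.." if role == "DEFINING" else "66A..",
                         date, valid, "" if valid else "placeholder", role, outcome_id))
    return pd.DataFrame(rows, columns=[
        "participant_id", "source", "system", "code", "event_date",
        "valid", "invalid_reason", "role", "outcome_id",
    ])


def inject_missingness(
    panel: pd.DataFrame,
    rate: float,
    seed: int,
    columns: list[str] | None = None,
    mechanism: str = "MCAR",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blank eligible cells independently with probability ``rate`` (MCAR).

    Returns the blanked copy and the boolean mask of blanked cells. Raises
    if any targeted column would lose every value.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if mechanism != "MCAR":
        raise ValueError(f"unsupported missingness mechanism {mechanism!r}")
    columns = columns or [c for c in panel.columns if c != "participant_id"]
    rng = np.random.default_rng(seed)
    out = panel.copy()
    mask = pd.DataFrame(False, index=panel.index, columns=columns)
    for col in columns:
        hit = rng.random(len(panel)) < rate
        if hit.all() and len(panel):
            raise ValueError(f"rate {rate} would blank the entire column {col!r}")
        mask[col] = hit
        out.loc[hit, col] = np.nan
    return out, mask
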