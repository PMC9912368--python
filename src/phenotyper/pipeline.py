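"""End-to-end orchestration: simulate -> curate -> events -> biomarkers ->
cohort -> covariates -> analysis.

Primarily exercised on synthetic inputs; every step is deterministic given
the seed, so two runs with the same configuration produce byte-identical
outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, biomarkers, codelist, cohort, covariates, events, synthetic

logger = logging.getLogger(__name__)


def curate_dm_codelist(dictionaries, gp_clinical) -> codelist.Codelist:
    """Run the full curation chain for the diabetes codelist on fixture data."""
    master = codelist.build_master_dictionary(dictionaries)
    hits = codelist.search_terms(master, ["diabet"], ["gestational"])
    hits |= codelist.expand_children(master, ["C10.."])
    mapping = codelist.MappingTable()
    for a, b in synthetic.FIXTURE_MAP_PAIRS:
        mapping.add(a, b)
    hits = codelist.forward_map(hits, mapping, master)
    hits = codelist.filter_by_usage(hits, gp_clinical)
    annotations = {
        (system, code): {"DEFINING": "keep", "DATE_ONLY": "date_only",
                         "EXCLUSION": "exclusion"}[role]
        for system, code, role in synthetic.FIXTURE_CODELISTS["DM"]
        if any(c.key == (system, code) for c in hits)
    }
    # reviewer drops: complication codes match "diabet" but define other
    # outcomes; measurement and local-admin codes are not diagnoses
    droppable = {key for key in synthetic.BIOMARKER_CODES}
    droppable |= {("TPP_LOCAL", "Y1234"), ("TPP_LOCAL", "Y5678")}
    for outcome in ("DKD", "DR"):
        droppable |= {(s, c) for s, c, _ in synthetic.FIXTURE_CODELISTS[outcome]}
    for c in hits:
        if c.key in droppable:
            annotations[c.key] = "drop"
    return codelist.apply_review_annotations(hits, annotations, "DM")


def _codelist_from_frame(outcome: str, frame: pd.DataFrame) -> codelist.Codelist:
    cl = codelist.Codelist(outcome_id=outcome)
    for row in frame.itertuples(index=False):
        cl.add(codelist.ClinicalCode(row.system, row.code, getattr(row, "description", "")),
               codelist.Role(row.role))
    return cl


def run_full(
    seed: int,
    n_participants: int = 500,
    m_imputations: int = 5,
    outdir: str | Path | None = None,
) -> dict:
    """Run the whole pipeline on synthetic data; optionally write outputs.

    Returns a dict with the generated tables, first occurrences, cohorts,
    incidence rates, the covariate panel, and the analysis results for the
    CVD outcome.
    """
    config = synthetic.SimulationConfig(n_participants=n_participants, seed=seed)
    tables, truth = synthetic.generate_cohort(config)
    gp = tables["gp_clinical"]
    assessment = tables["assessment"]

    # UKB-side events match the seed (field-based) codelists; primary-care
    # events match the curated primary-care codelist for DM.
    dm_codelist = curate_dm_codelist(tables["dictionaries"], gp)
    outcome_codelists = {
        name: _codelist_from_frame(name, frame)
        for name, frame in tables["codelists"].items()
    }
    gp_codelists = dict(outcome_codelists)
    gp_codelists["DM"] = dm_codelist

    # --- events ---------------------------------------------------------
    field_map = [
        events.FieldSpec(date_col="sr_dm_date", code_col="sr_dm_code",
                         source="SELF_REPORT", system="SELF_REPORT_ILLNESS"),
    ]
    ukb_events = events.build_master_event_table(
        assessment, tables["hospital"], tables["death"], field_map)
    gp_diag = gp[gp["value"].isna()][["participant_id", "date", "system", "code"]]
    gp_events = events.gp_to_events(gp_diag)
    birth = pd.Series(assessment["birth_date"].values, index=assessment["participant_id"])
    ukb_events = events.clean_dates(ukb_events, birth_dates=birth)
    gp_events = events.clean_dates(gp_events, birth_dates=birth)

    firsts = {}
    merged_by_outcome = {}
    for outcome in ("DM", "CVD", "DKD"):
        roles = {codelist.Role.DEFINING, codelist.Role.DATE_ONLY}
        merged = events.merge_outcome_events(
            events.extract_outcome_events(ukb_events, outcome_codelists[outcome], roles),
            events.extract_outcome_events(gp_events, gp_codelists[outcome], roles),
        )
        merged_by_outcome[outcome] = merged
        firsts[outcome] = events.first_occurrence(merged, outcome)

    # --- biomarkers -----------------------------------------------------
    gp_values = gp[gp["value"].notna()]
    trajectories = biomarkers.extract_trajectories(
        gp_values, None, synthetic.BIOMARKER_CODES, unit_rules={})
    demo = assessment.set_index("participant_id")
    scr = trajectories[(trajectories["biomarker"] == "SERUM_CREATININE") & trajectories["valid"]]
    egfr_rows = scr.copy()
    if len(scr):
        age_at_meas = (
            (pd.to_datetime(scr["date"]).to_numpy()
             - demo.loc[scr["participant_id"], "birth_date"].to_numpy())
            / np.timedelta64(1, "D") / 365.25
        )
        egfr_rows["value"] = biomarkers.compute_egfr(
            scr["value"].to_numpy(), age_at_meas,
            demo.loc[scr["participant_id"], "sex"].to_numpy(),
            creatinine_unit="umol/L")
        egfr_rows["biomarker"] = "EGFR"
    alb = trajectories[trajectories["biomarker"] == "URINE_ALBUMIN"]
    ucr = trajectories[trajectories["biomarker"] == "URINE_CREATININE"]
    uacr = biomarkers.compute_uacr(alb, ucr)
    derived = pd.concat([
        biomarkers.detect_albuminuria_events(uacr),
        biomarkers.detect_prolonged_low_egfr(egfr_rows),
    ], ignore_index=True)

    window_start = pd.Series(assessment["gp_first_date"].values, index=assessment["participant_id"])
    window_end = (pd.to_datetime(assessment["index_date"])
                  + pd.to_timedelta(182.625, unit="D"))
    window_end = pd.Series(window_end.values, index=assessment["participant_id"])
    summaries = biomarkers.summarize_landmark(
        pd.concat([trajectories, egfr_rows, uacr.assign(valid=True, unit_original="")],
                  ignore_index=True),
        window_start, window_end)

    # --- cohort ---------------------------------------------------------
    dm_assign = cohort.classify_diabetes(merged_by_outcome["DM"], synthetic.TYPE_SPECIFIC_CODES)
    censor_table = cohort.build_censor_table(
        assessment[["participant_id", "lost_to_followup_date", "death_date",
                    "showcase_censor_date"]])
    index_dates = pd.Series(pd.to_datetime(assessment["index_date"]).values,
                            index=assessment["participant_id"])
    has_pc = pd.Series(assessment["has_primary_care"].astype(bool).values,
                       index=assessment["participant_id"])

    cohorts, rates = {}, {}
    for outcome in ("CVD", "DKD"):
        merged = merged_by_outcome[outcome]
        hosp_ids = set(merged.loc[
            merged["valid"] & merged["source"].isin(["HOSPITAL", "DEATH"]), "participant_id"])
        exclusion_ids: set = set()
        if outcome == "DKD":
            excl_events = events.merge_outcome_events(
                events.extract_outcome_events(
                    ukb_events, outcome_codelists["DKD"], {codelist.Role.EXCLUSION}),
                events.extract_outcome_events(
                    gp_events, outcome_codelists["DKD"], {codelist.Role.EXCLUSION}),
            )
            exclusion_ids = set(excl_events["participant_id"])
        tte = cohort.build_initial_tte(
            dm_assign, firsts[outcome], censor_table, index_dates, outcome,
            has_primary_care=has_pc, hospital_death_event_ids=hosp_ids)
        tte = cohort.refine_tte(tte, exclusion_ids)
        tte = cohort.apply_prospective_design(tte, cohort.DEFAULT_RULES[outcome])
        cohorts[outcome] = tte
        if (~tte["excluded"]).any() and tte.loc[~tte["excluded"], "time_years"].sum() > 0:
            rates[outcome] = cohort.incidence_rate(tte)

    # --- covariates -----------------------------------------------------
    demographics = assessment[["participant_id", "sex", "birth_date"]].copy()
    demographics["sex_male"] = (demographics["sex"] == "M").astype(float)
    demographics = demographics.drop(columns="sex")
    base_cov = assessment[["participant_id", "bmi", "ever_smoked", "pack_years",
                           "insulin", "bp_med", "chol_med"]].copy()
    base_cov["ethnicity4"] = [covariates.recode_ethnicity(c)
                              for c in assessment["ethnicity_code"]]
    base_cov["met_hours_week"] = [
        covariates.compute_met(r.walk_days, r.walk_min, r.moderate_days,
                               r.moderate_min, r.vigorous_days, r.vigorous_min)
        for r in assessment.itertuples(index=False)
    ]
    base_cov["isced_gt2"] = [covariates.compute_isced(q)[1]
                             for q in assessment["qualification"]]
    cci = covariates.compute_cci_table(
        tables["hospital"], index_dates).rename_axis("participant_id").reset_index()

    panel = covariates.assemble_panel(
        cohorts["CVD"], demographics,
        {"base": base_cov, "cci": cci},
        summaries[summaries["biomarker"].isin(["GLUCOSE", "HBA1C", "SBP"])],
    )

    # --- analysis (CVD outcome) -----------------------------------------
    result = None
    candidate_vars = [c for c in [
        "bmi", "ever_smoked", "insulin", "bp_med", "chol_med", "cci",
        "isced_gt2", "met_hours_week", "mean_GLUCOSE", "mean_SBP", "cv_SBP",
    ] if c in panel.columns]
    if panel["status"].sum() >= 10 and len(panel) >= 50:
        impute_vars = ["time_years", "status", "age_at_index", "sex_male"] + candidate_vars
        imp = analysis.impute(panel, m=m_imputations, seed=seed, variables=impute_vars)
        std_cols = [c for c in candidate_vars if c.startswith(("mean_", "cv_"))
                    or c == "met_hours_week"]
        panels = analysis.standardize(imp.panels, std_cols)
        selection = analysis.pooled_stepwise_select(
            panels, candidates=candidate_vars, forced=["age_at_index", "sex_male"])

        train_ids, valid_ids = analysis.train_validate_split(
            panel["participant_id"].to_numpy(), seed=seed)
        fits = []
        valid_panels = []
        final_vars = selection.forced_vars + selection.selected_vars
        for p in panels:
            tr = p[p["participant_id"].isin(train_ids)]
            va = p[p["participant_id"].isin(valid_ids)]
            beta, _ = analysis.fit_cox(tr, final_vars)
            fits.append((beta, tr[final_vars].mean()))
            valid_panels.append(va.reset_index(drop=True))
        scores = analysis.compute_risk_scores(fits, valid_panels)
        valid_status = panel.set_index("participant_id").loc[scores.index, "status"]
        auc, auc_ci = analysis.evaluate_auc(scores.to_numpy(), valid_status.to_numpy())
        km = analysis.km_by_median(scores, panel)
        result = {
            "selection": selection, "scores": scores, "auc": auc, "auc_ci": auc_ci,
            "km": km, "train_ids": train_ids, "valid_ids": valid_ids,
        }

    out = {
        "config": config, "tables": tables, "truth": truth,
        "dm_codelist": dm_codelist, "first_occurrences": firsts,
        "trajectories": trajectories, "derived_events": derived,
        "summaries": summaries, "dm_assignments": dm_assign,
        "cohorts": cohorts, "incidence_rates": rates,
        "panel": panel, "analysis": result,
    }
    if outdir is not None:
        write_outputs(out, Path(outdir))
    return out


def write_outputs(results: dict, outdir: Path) -> None:
    """Write the pipeline's principal outputs as deterministic text files."""
    outdir.mkdir(parents=True, exist_ok=True)
    codelist.write_codelist_tsv(results["dm_codelist"], outdir / "dm_codelist.tsv")
    for outcome, firsts in results["first_occurrences"].items():
        firsts.to_csv(outdir / f"first_occurrence_{outcome}.tsv", sep="\t", index=False)
    for outcome, tte in results["cohorts"].items():
        cols = ["participant_id", "outcome_id", "index_date", "time_years",
                "status", "excluded", "exclusion_reason"]
        tte[cols].to_csv(outdir / f"cohort_{outcome}.tsv", sep="\t", index=False)
    results["summaries"].to_csv(outdir / "biomarker_summaries.tsv", sep="\t",
                                index=False, float_format="%.10g")
    results["panel"].to_csv(outdir / "panel.tsv", sep="\t", index=False,
                            float_format="%.10g")
    with open(outdir / "incidence.json", "w") as fh:
        json.dump({k: {kk: (round(vv, 10) if isinstance(vv, float) else vv)
                       for kk, vv in v.items()}
                   for k, v in results["incidence_rates"].items()}, fh, indent=2, sort_keys=True)
    if results["analysis"] is not None:
        sel = results["analysis"]["selection"]
        sel.summary.round(10).to_csv(outdir / "pooled_hr.tsv", sep="\t")
        pd.DataFrame(sel.selection_trace,
                     columns=["step", "action", "variable", "pooled_p"]).round(10).to_csv(
            outdir / "selection_trace.tsv", sep="\t", index=False)
        with open(outdir / "auc.json", "w") as fh:
            json.dump({"auc": round(results["analysis"]["auc"], 10),
                       "ci": [round(x, 10) for x in results["analysis"]["auc_ci"]],
                       "logrank_p": round(results["analysis"]["km"]["logrank_p"], 10)},
                      fh, indent=2, sort_keys=True)
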