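# phenotyper

A pipeline for phenotyping disease incidence and progression from
multi-source, EHR-shaped tables, exercised end to end on synthetic
UK-Biobank-shaped data. It covers:

- **codelist** — master terminology dictionaries (Read v2 / CTV3 / ICD-10 /
  OPCS4 / TPP local) and curated, role-tagged outcome codelists via keyword
  search, Read v2 prefix-hierarchy expansion, Read↔CTV3 forward mapping,
  usage filtering, and reviewer annotations.
- **events** — a master clinical event table from assessment fields,
  hospital admissions, death records and primary care; flag-based date
  cleaning (placeholders, pre-birth, implausible); outcome event extraction;
  cross-source merging; per-participant first occurrences with a
  DEFINING/DATE_ONLY gating rule.
- **biomarkers** — longitudinal trajectory curation with unit harmonization,
  CKD-EPI (2009) eGFR, urine albumin-to-creatinine pairing, derived
  micro/macroalbuminuria and prolonged-low-eGFR events, and landmark-window
  mean/CV summaries.
- **cohort** — diabetes type assignment, censoring dates, initial and
  refined time-to-event tables, prospective landmark-design exclusions
  (primary-care representation, 5-year rules, 6-month landmark window), and
  incidence rates with exact Poisson CIs.
- **covariates** — ethnicity recode, Charlson Comorbidity Index (Quan
  ICD-10 mapping, shipped as editable TSV), IPAQ MET hours/week, ISCED
  education levels, and panel assembly.
- **analysis** — chained-equations multiple imputation (PMM / stochastic
  model prediction chosen per variable), Cox fits with Efron ties, Rubin's
  rules pooling with Barnard–Rubin degrees of freedom, pooled stepwise
  variable selection with forced base covariates, 2:1 train/validation risk
  prediction with averaged risk scores, Mann–Whitney AUC with DeLong CIs,
  and median-split Kaplan–Meier curves.
- **synthetic** — a generator for all six input tables (terminology,
  primary care, hospital, death, assessment, seed codelists) with planted
  proportional-hazards ground truth, partial primary-care linkage,
  placeholder dates and MCAR missingness, plus a hand-built rule fixture
  with one participant per exclusion rule.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria; the two
stochastic ones (Cox CI coverage over 200 replicates, stepwise selection
operating characteristics over 100 replicates) take a few minutes.

## CLI

```bash
phenotyper simulate --n 500 --seed 1 --out data/          # synthetic inputs
phenotyper curate --dict data/dictionary_0.tsv --dict data/dictionary_1.tsv \
    --include diabet --exclude gestational --parents "C10.." \
    --events data/gp_clinical.tsv --outcome DM --out dm_codelist.tsv
phenotyper events --gp data/gp_clinical.tsv --codelist dm_codelist.tsv \
    --outcome DM --out first_occurrence.tsv
phenotyper cohort --outcome DKD --dm-assignments dm.tsv \
    --first-occurrence fo.tsv --censor censor.tsv --out cohort.tsv
phenotyper analyze --panel panel.tsv --m 5 --seed 42 \
    --candidates bmi,cci,ever_smoked --out results/
phenotyper pipeline --n 500 --seed 1 --out results/       # everything
```

All input/output tables are UTF-8 TSV; dates are ISO-8601 calendar dates.

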