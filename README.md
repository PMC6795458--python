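# nbarti

Measurement of antibiotic prescribing at non-bacterial acute respiratory
tract infection (NB-ARTI) consultations from outpatient claims data.

The package builds an analysis cohort from five flat claims tables
(patients, facilities, consultations, diagnoses, prescriptions), classifies
diagnosis appropriateness and antibiotic classes, and computes monthly
prescribing rates, trend regressions, and crude/adjusted logistic odds
ratios. A synthetic claims generator with exact ground truth makes every
stage testable without any external data.

## Pipeline

1. **claims_model** — table schemas, readers/writers, and covariate
   conventions: nine age bins (0–3 … 60–, ages < 75), in/out-of-hours visit
   classification ([08:00, 18:00) on non-holiday weekdays is in-hours),
   April-to-March fiscal years, and five facility categories (clinics
   without/with beds, other/university/public hospitals).
2. **appropriateness** — diagnosis-code → requires-antibiotics lookup
   (exact match, then 3-character ICD-10 class prefix; strict or lenient
   mode) and the ATC class map (J01DD/J01FA/J01MA are broad-spectrum,
   J01C is penicillin, anything else J01 is other).
   The packaged `data/appropriateness_default.csv` is a clearly-labelled
   stand-in covering the J00–J22 classes; supply your own adjudicated table
   for real analyses.
3. **cohort_builder** — links each consultation to same-patient diagnoses
   within a lookback window (default 30 days, endpoints and same day
   inclusive), keeps consultations with an active ARTI code (J00–J06,
   J20–J22), drops those with any active antibiotic-requiring code, labels
   the diagnosis category, and links same-date J01 prescriptions.
4. **analytics** — monthly rates per 100 cohort consultations (overall or
   stratified by age group, diagnosis category, specialty, or antibiotic
   class), composition tables, OLS trend fits, the prescribing-rate vs
   diagnosis-rate regression, and the linkage-window sensitivity sweep.
5. **regression** — crude and adjusted logistic odds ratios with Wald 95%
   CIs, and specialty-stratified yearly adjusted ORs.
6. **synthetic_data** — claims bundles drawn from a logistic prescribing
   model with known coefficients; `ground_truth(config)` returns the exact
   ORs and expected monthly rate curve by enumeration over the covariate
   grid.
7. **cli** — `nbarti` command-line entry point.

## CLI

```sh
# write a synthetic claims bundle + ground truth
nbarti simulate --out sim/ --seed 1

# cohort from claims tables
nbarti build --inputs sim/ --out out/ --window 30

# all-in-one from a YAML run config
nbarti run --config run.yaml --out out/ --seed 1 --window 0 --window 30
nbarti validate run.yaml
```

A run config contains exactly one of `inputs:` (directory or table→path
mapping) or `simulate:` (generator settings), plus optional
`appropriateness_table`, `appropriateness_mode` (strict/lenient), `window`
(int or list), and `stratifiers`. `run` writes `cohort.csv`,
`attrition.json`, `rates.csv`, `composition.csv`, `trend.json`,
`or_table.csv`, `stratified_aor.csv`, optional `sensitivity.csv`, and a
`manifest.json` with checksums; reruns with the same config and seed are
byte-identical.

## Data formats

Five UTF-8 delimited tables with header rows (comma by default):
`patients.csv` (patient_id, sex, birth_year_month YYYY-MM, insured_status),
`facilities.csv` (facility_id, bed_count, is_university, is_public,
specialty), `consultations.csv` (patient_id, facility_id, date YYYY-MM-DD,
visit_slot as HH:MM or a pre-coded in_hours/out_of_hours flag),
`diagnoses.csv` (patient_id, facility_id, code, diagnosis_date), and
`prescriptions.csv` (patient_id, facility_id optional, date, atc_code).
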