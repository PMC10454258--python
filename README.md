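# claimscohort

Claims-based cohort phenotyping and suicide-specific mortality analysis for
depression populations, exercised end-to-end on a seeded synthetic
administrative-claims generator.

The package implements:

* **codesets** — ICD-10(-CM) prefix code lists (dot-insensitive matching,
  range expansion), drug-ingredient classification, and three nested
  cause-of-death suicide definitions (broad ⊇ probable ⊇ strict), loaded
  from a validated YAML config with a packaged default.
* **synthetic** — a deterministic, seeded claims generator: enrollment
  spans with optional gaps, diagnosis claims with positions and settings,
  ingredient-level pharmacy fills, and death records drawn from competing
  exponential hazards (suicide / other death / disenrollment) per planted
  cohort, with administrative censoring.
* **phenotyping** — cohort algorithms: established depression (claim pair
  within 365 days or an inpatient stay), treatment-resistance (≥3 distinct
  antidepressant ingredients or antidepressant + atypical antipsychotic in
  an inclusive 365-day window), ideation/attempt with attribution rules,
  depression-alone fallback, exclusions, the 183-day baseline-history
  requirement, and a stepwise attrition log.
* **characterization** — baseline and last-year indicator variables
  (comorbidity categories via a miniature, user-replaceable code→category
  map; medication classes; ideation/attempt flags) and summary tables.
* **linkage** — deterministic death-record linkage restricted to patients
  not enrolled past the death-index search cutoff, classifying every death
  under every definition (underlying and multiple-cause codes).
* **rates** — censored person-time (index → earliest of disenrollment,
  administrative end, death), the recent ideation/attempt stratifier, and
  incidence rates per 100 person-years by cohort × stratum.
* **adjustment** — misclassification arithmetic: expected true suicides
  from nested definition counts with reclassification weights, PPV of the
  broad definition and sensitivity of the strict one.
* **pipeline / cli** — table I/O schema, orchestration, and a CLI.

## CLI

```sh
# generate synthetic tables (+ a separate truth file for testing)
claimscohort simulate --n-patients 5000 --seed 7 --out scratch/tables

# run everything: phenotyping, characterization, linkage, rates per
# definition, adjustment; writes report CSVs + manifest.json
claimscohort run --input scratch/tables --out scratch/report
# or simulate inline:
claimscohort run --simulate 5000 --seed 7 --out scratch/report

# individual stages
claimscohort phenotype --input scratch/tables --out scratch/pheno
claimscohort rates --input scratch/tables --out scratch/rates.csv --definition strict
claimscohort adjust --broad 261 --probable 248 --strict 130
```

Input tables are plain CSV (`patients`, `enrollment`, `medical_claims`,
`pharmacy_claims`, optional `deaths`) with ISO-8601 dates; see
`claimscohort/io.py` for the column schema. Identification-period and
observation-end dates are flags on every subcommand.

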