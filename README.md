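# hivpheno

Rule-based computable phenotyping of **people with HIV (PWH)** and **PrEP
users** from OMOP CDM-shaped electronic health record (EHR) and survey data.

Observational research programs that pool EHRs from many institutions need an
executable, auditable definition of "this participant has HIV" before any
downstream epidemiology can happen. `hivpheno` implements such a definition as
a deterministic rule engine over four evidence domains — diagnosis codes
(ICD-10 / SNOMED conditions), antiretroviral drug exposures, HIV laboratory
results (LOINC-coded screens and viral loads), and a self-reported survey
item — together with the machinery around it: concept-set management, date
windowing and duplicate-id consolidation, disclosure-controlled reporting,
and a synthetic-cohort generator with per-person ground-truth labels so the
whole pipeline is testable without access-restricted patient data.

## The classification rules

Each person is assigned exactly one label, with precedence
`CONFIRMED_PWH > PROBABLE_PWH > PREP_USER > NONE`:

* **Confirmed PWH** — any of:
  1. affirmative answer to the HIV personal-medical-history survey item
     (OMOP concept 1384391);
  2. a confirming lab: positive screening result (whole-string match on
     "detected", "HIV-1 positive", "positive", "reactive", "abnormal",
     "high"), **or** a viral load strictly above 200 copies/mL on its own
     scale (linear v > 200; log₁₀ v > log₁₀ 200; ln v > ln 200), **or**
     virologic suppression on treatment (ART drug pattern plus undetectable
     viral loads, < 200 copies/mL, on ≥ 2 distinct dates);
  3. an HIV diagnosis code **and** a non-PrEP ART drug history.
* **Probable PWH** — unconfirmed EHR evidence: an HIV diagnosis code *or* an
  ART drug pattern, with nothing confirming.
* **PrEP user** — every drug combination in the person's history is exactly
  FTC+TDF or FTC+TAF (two ingredients, any dose or form; one drug alone or
  three or more drugs together never count), plus a negative screening
  result, no HIV diagnosis code, and no affirmative survey answer.
  HCV-only regimens are excluded from ART evidence throughout (several
  agents are dual-purpose), and PrEP users carrying hepatitis-B codes
  (B180/B181/B191) are flagged — not relabeled — as possible HBV
  misclassification.
* **None** — everything else.

The assignment also records *which* clauses confirmed (`confirm_basis`) and
which domains contributed positive evidence (`evidence_sources`), enabling a
Venn decomposition of the cohort by evidence source.

## Worked example

Generate a synthetic 1000-person cohort (30% confirmed, 20% probable, 4%
PrEP, 46% background, with messy lab scales, duplicate ids and decoy records
planted), then classify it:

```bash
phenotype synth --n 1000 --seed 42 --out demo/data
# wrote 1028 persons ({'NONE': 460, 'CONFIRMED_PWH': 300,
#                      'PROBABLE_PWH': 200, 'PREP_USER': 40}) -> demo/data

phenotype run --omop-dir demo/data --out demo/results
# classified 1000 persons -> demo/results
#   CONFIRMED_PWH: 300
#   PROBABLE_PWH: 200
#   PREP_USER: 40
#   NONE: 460
```

(1028 person *rows* collapse to 1000 persons: the generator plants duplicate
ids that `phenotype run` consolidates via `aliases.csv`.) The output
directory contains `assignments.csv`:

```text
person_id,label,confirm_basis,evidence_sources,hbv_flag
P000001,NONE,,,False
P000005,CONFIRMED_PWH,condition_and_drug,condition+drug,False
...
```

plus `report.json`, `venn.tsv` and `demographics.tsv`. Rendered counts below
20 are suppressed (`<20`) for disclosure control; zeros and counts ≥ 20 pass
through:

```text
cohort  sources                     count
total   condition                   62
total   condition+drug              150
total   condition+drug+lab          30
total   condition+drug+lab+survey   <20
```

Every number above is recomputed by the classifier at run time; comparing
`assignments.csv` against the generator's `truth.csv` reproduces the labels
exactly.

The same functionality is available as a library:

```python
from hivpheno import (GroundTruthSpec, RunConfig, demo_registry,
                      generate_cohort, run_cohort,
                      filter_by_date_window, consolidate_person_ids)

lb = generate_cohort(GroundTruthSpec(n_persons=1000, seed=42))
bundle = consolidate_person_ids(filter_by_date_window(lb.bundle))
assignments = run_cohort(bundle, demo_registry(), RunConfig())
```

## Configuration

* **Concept sets** (`--concepts`): a YAML/JSON file mapping roles
  (`hiv_condition`, `art_drug`, `prep_component_*`, `hcv_drug`,
  `hbv_condition`, `hiv_screen_lab`, `hiv_vl_lab`, `survey_hiv_question`,
  `survey_hiv_positive_answers`) to code lists. A small demonstration
  registry ships with the package; production deployments supply their own
  pre-expanded lists.
* **Run config** (`--config`): date windows (EHR 1981-01-01 … 2022-07-01,
  survey 2018-10-01 … 2022-06-30, both closed intervals), the viral-load
  threshold, lab string sets, scale-inference bound, drug-combination
  tolerance window, masking threshold, strict/lenient orphan handling, and
  the drug-concept → ingredient map.

See `docs/methods.md` for the full account of the model, its parameters and
its limitations.
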