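# Methods

## The phenotyping model

`hivpheno` implements a deterministic, rule-based computable phenotype: a
person's HIV status is a pure function of their records in four OMOP CDM
domains (condition_occurrence, drug_exposure, measurement, observation/survey)
and of a role-tagged concept registry. There is no probabilistic scoring, no
visit-count criterion, and no free-text processing; those are explicit
non-goals. The rules and their precedence are stated in the README; this note
records the modeling choices, parameters, and what the test evidence does and
does not establish.

### Assumptions

* Structured codes are trustworthy evidence: a mapped HIV diagnosis code, an
  ingredient-resolved drug exposure, a LOINC-coded lab. Diagnoses recorded
  only in clinical notes are invisible, so false negatives from
  narrative-only documentation are out of scope by design.
* One label per person. Tier precedence (confirmed > probable > PrEP > none)
  resolves all overlaps; in particular an affirmative survey answer vetoes a
  PrEP-user label (a self-reported PWH on FTC/TDF is a confirmed PWH, not a
  PrEP user) — the tiers would otherwise be contradictory.
* The probable tier means *unconfirmed EHR evidence*: an HIV diagnosis code
  or a non-PrEP ART drug history on its own. Treating drug-only histories as
  probable (not just diagnosis-only) is a deliberate design choice: an ART
  regimen without a coded diagnosis is exactly the incomplete-metadata case
  the probable tier exists for.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| viral-load threshold | 200 | copies/mL | conservative detectability cut; strict `>` so exactly 200 is undetectable |
| suppression rule | ≥ 2 undetectable VLs | distinct dates | distinct *dates*, not rows, so duplicated records cannot inflate the count; requires an ART pattern |
| EHR window | 1981-01-01 … 2022-07-01 | closed dates | HIV-era records up to the data-release cut; closed on both ends (the conservative reading of "from … to …") |
| survey window | 2018-10-01 … 2022-06-30 | closed dates | lifetime of the survey instrument |
| log₁₀ plausibility bound | 8.0 | log₁₀ copies/mL | scale heuristic for unit-less numeric VLs: no real linear result sits ≤ 8 copies/mL in these data, while log-transformed values almost never exceed 8 |
| combo tolerance | 0 | days | drug records on the same calendar date form one combination; fixed-dose products already resolve to co-dated ingredients, and a tolerance > 0 is available for split prescriptions |
| masking threshold | 20 | persons | rendered counts in [1, 19] are suppressed |
| anchor date | 2022-07-01 | date | age computation (adult cohort, age bands) |

Screening strings: the positive set is {detected, hiv-1 positive,
hiv-positive, positive, reactive, abnormal, high}; the negative set
{negative, nonreactive, non-reactive, not detected, undetected, normal}.
Matching is whole-string after trim/casefold — never substring — so
"not detected" can never hit "detected". The negative set is a package
choice (configurable): source systems vary and only the positive vocabulary
is standardized in practice.

## Numerical and edge-case choices

* **Threshold boundary.** The detectable/undetectable pair is printed as
  ">200" / "<200", leaving exactly 200 unspecified; we resolve it to
  undetectable (strict `>` for detectability) and test the boundary on every
  scale.
* **Scale inference order.** Unit metadata → per-run override → heuristic.
  A bare "log" unit maps to log₁₀, the clinical convention for viral loads;
  "ln" must appear as its own token to mean natural log.
* **Low numeric viral loads** (e.g. 26 or 1.95 on a log scale) are routed to
  *undetectable*: on their own they confer no label and feed only the
  suppression rule. A lone undetectable VL without ART is deliberately
  inert.
* **ICD normalization** strips dots (B18.1 ≡ B181) and casefolds; dots are
  meaningless in every vocabulary used here (LOINC uses hyphens, SNOMED is
  numeric).
* **HCV exclusion.** A drug combination composed entirely of HCV-role
  ingredients is excluded from ART evidence; a mixed combination with any
  ART-role ingredient still counts. Dual-use agents are surfaced by registry
  validation as informational flags.
* **Rounding.** Percentages use round-half-up at one decimal (`Decimal`
  arithmetic, not float), matching how epidemiological tables are
  conventionally printed; banker's rounding would diverge on .x5 shares.
* **Masking is render-only.** Internal counts stay exact (sums reconcile,
  percentages are computed before masking); only rendered cells are
  suppressed, a masked count's percentage is suppressed with it, and zero
  renders as 0 — zero reveals no individual. Disclosure control applies to
  person-count cells; level names, test statistics and run metadata are not
  counts.
* **Chi-square comparisons** (confirmed vs probable, per characteristic) use
  the standard test of independence without continuity correction, with
  unknown/skip levels kept as categories and zero-margin levels dropped;
  degenerate single-level tables are skipped with a note.
* **Duplicate ids** are consolidated by following the alias map to a fixed
  point (cycles fatal); the persons table keeps the canonical row and the
  record multiset is otherwise preserved. Filtering and consolidation
  commute, and date filtering is idempotent — both property-tested.
* **Orphan records** (child rows whose person_id lacks a persons row)
  default to fatal: silently dropping them changes cohort counts. A lenient
  mode drops and counts them. Persons under 18 at the anchor date are
  dropped with a provenance count — a cohort-definition filter, not an
  error.

## The synthetic-cohort generator

The generator **plants records that satisfy each intended label's rule by
construction** rather than sampling a disease model: the artifact under test
is classification logic, not epidemiology. Defaults: 30% confirmed / 20%
probable / 4% PrEP / 46% none; within confirmed, an evidence-subset mix
dominated by condition+drug and drug-alone sources; within probable, 31%
condition-only vs 69% drug-only. These mirror the internal ratios of a large
US research-program HIV cohort while adding a background of unlabeled
persons.

Messiness channels (defaults in parentheses) are each designed to be
non-confounding, so 100% label recovery is the *correct* outcome and any
miss indicates a real bug: log₁₀-scale viral-load rows (30%) and ln-scale
rows (10%); missing units (20%) — only where the plausibility heuristic
provably recovers the scale (linear undetectables are planted at ≥ 9
copies/mL, ln rows always keep their unit); duplicate person ids with an
alias file (2%); HCV-only drug decoys (5%, never to PrEP users, whose
pattern any extra combination would legitimately break); HBV diagnosis
decoys on PrEP users (30%, driving the flag, never the label); and
out-of-window records (5%) that the date filter must remove, including
records that would change the label if left in.

What passing therefore shows: the engine implements the rules exactly, on
data whose difficulty is adversarial but *known*. What it does not show:
performance on real EHR data, where concept lists are incomplete, lab
strings are wilder, co-exposure dates drift, and the truth is unknown —
the generator emulates structure, not clinical reality. Demographics are
sampled independently of evidence from configurable categorical margins and
exist only to exercise the reporting module; they carry no epidemiological
signal.

The handcrafted edge-case bundle covers one person per classifier branch and
boundary: viral load exactly 200 (and exactly log₁₀ 200), single-drug and
three-drug non-PrEP patterns, the extra-combination PrEP violation, the
survey-positive PrEP candidate, a duplicate-id pair, the "Not detected"
superstring trap, ln-scale values either side of the threshold, and the
HBV-flagged PrEP user.

## Problem sizes

The default verification cohort is 5000 persons (≈ 10 000 clinical records),
classified in a few seconds; the scale-equivariance check uses 10 000 random
viral-load values over (10⁻⁶, 10⁷); the rule-table equivalence check
enumerates all 864 consistent evidence profiles. These sizes fully exercise
every branch and allocation edge of the algorithm — the logic is per-person
and has no asymptotic behavior that larger cohorts would reveal.

## Known limitations

* Concept coverage is the user's responsibility: the bundled registry is a
  demonstration subset, and cohort counts on real data depend on the
  supplied lists, not on the logic tested here.
* No vocabulary traversal: code lists must be pre-expanded
  (ancestor/descendant expansion is out of scope).
* PEP (post-exposure prophylaxis) courses are indistinguishable from PrEP in
  structured drug data; the HBV flag covers the hepatitis-B confusion but
  PEP misclassification remains possible, as it does in any
  structured-data-only definition.
* Survey "negative" answers and missing answers are distinguished in the
  evidence profile but treated identically by the tier rules; the
  distinction is kept for reporting.
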