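"""Synthetic OMOP-shaped cohorts with per-person ground-truth labels.

The generator does not simulate an epidemic: it plants records that satisfy
each person's intended classification rule *by construction*, so that running
the engine over the bundle and comparing against the planted truth exercises
every rule branch. Messiness knobs add the failure modes real extracts show —
log-scale viral loads, missing units, duplicate person ids, HCV-drug and
HBV-code decoys, out-of-window records — all designed to be non-confounding:
a correct pipeline recovers 100% of planted labels, so any disagreement is a
bug in either generator or engine.

Safety constraints that keep decoys non-confounding:

* linear-scale undetectable viral loads are planted at >= 9 copies/mL so a
  dropped unit can never push them under the log10-plausibility bound;
* ln-scale values always keep their unit (unit-less ln values are not
  distinguishable from log10 by any heuristic);
* HCV decoy combinations are never given to PrEP users (any non-PrEP combo
  disqualifies the PrEP pattern — by design);
* planted ART histories are never a bare FTC+TDF/FTC+TAF pair.
"""
from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .engine import CONFIRMED_PWH, NONE, PREP_USER, PROBABLE_PWH
from .omop_io import OmopBundle, resolve_ingredients
from .reporting import subset_key

HIV_CONDITION_CODES = ("B20", "Z21", "86406008")
HBV_CODES = ("B180", "B181", "B191")
SCREEN_CONCEPT = "75622-1"
VL_CONCEPT = "20447-9"
SURVEY_QUESTION = "1384391"
SURVEY_POSITIVE_ANSWER = "Infectious Disease Condition: HIV/AIDS"

POSITIVE_SCREEN_VALUES = ("Reactive", "Positive", "DETECTED", "HIV-1 Positive",
                          "Abnormal", "High")
NEGATIVE_SCREEN_VALUES = ("Not detected", "Negative", "NONREACTIVE", "Non-reactive")

#: Demographic sampling distributions, loosely shaped like a US HIV cohort's
#: margins; they exist purely to exercise the reporting module.
DEMOGRAPHIC_DISTRIBUTIONS: dict[str, dict[str, float]] = {
    "gender": {"Female": 0.36, "Male": 0.60, "Other or skipped": 0.04},
    "race": {"Asian/other/unknown": 0.21, "Black or African American": 0.41,
             "White": 0.38},
    "ethnicity": {"Hispanic or Latino": 0.15, "Not Hispanic or Latino": 0.81,
                  "Unknown": 0.04},
    "marital_status": {"Divorced/separated/widowed": 0.23,
                       "Married/living with partner": 0.32,
                       "Never married": 0.40, "Unknown": 0.05},
    "sexual_orientation": {"Bisexual": 0.07, "Gay": 0.29, "Lesbian": 0.01,
                           "None": 0.02, "Straight": 0.56,
                           "Prefer not to answer": 0.05},
    "education": {"High school degree or more": 0.92,
                  "Less than a high school degree": 0.035, "Unknown": 0.045},
    "income_band": {"Greater than 35000 USD": 0.30, "Less than 35000 USD": 0.50,
                    "Unknown": 0.20},
    "insurance": {"Yes": 0.91, "No": 0.05, "Unknown": 0.04},
    "disability": {"Yes": 0.125, "No": 0.875},
    "chronic_conditions": {"0": 0.62, "1": 0.21, "2+": 0.17},
}

DEFAULT_TIER_MIX = {
    CONFIRMED_PWH: 0.30,
    PROBABLE_PWH: 0.20,
    PREP_USER: 0.04,
    NONE: 0.46,
}

#: Per-tier distribution over evidence-source subsets (keys are sorted
#: "+"-joined source names). Confirmed subsets must contain a confirming
#: mechanism (survey, lab, or condition+drug); probable subsets are the two
#: unconfirmed single-domain cases.
DEFAULT_CONFIRMED_COMPOSITION = {
    "condition+drug": 0.50,
    "drug+lab": 0.08,
    "survey": 0.13,
    "lab": 0.02,
    "condition+drug+lab": 0.10,
    "condition+drug+survey": 0.07,
    "condition+drug+lab+survey": 0.05,
    "lab+survey": 0.02,
    "condition+lab": 0.02,
    "drug+survey": 0.01,
}
DEFAULT_PROBABLE_COMPOSITION = {"condition": 0.31, "drug": 0.69}


class SpecError(ValueError):
    """Infeasible or inconsistent ground-truth specification."""


@dataclass(frozen=True)
class Messiness:
    """Rates (per eligible person/row, all in [0, 1]) of realistic noise."""

    log_scale_vl: float = 0.30
    ln_scale_vl: float = 0.10
    missing_unit: float = 0.20
    duplicate_id: float = 0.02
    hcv_decoy: float = 0.05
    hbv_decoy: float = 0.30
    out_of_window: float = 0.05

    def __post_init__(self) -> None:
        for name, rate in self.__dict__.items():
            if not 0.0 <= rate <= 1.0:
                raise SpecError(f"messiness rate {name}={rate} outside [0, 1]")

    @classmethod
    def none(cls) -> "Messiness":
        return cls(0, 0, 0, 0, 0, 0, 0)


@dataclass(frozen=True)
class GroundTruthSpec:
    n_persons: int = 1000
    tier_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TIER_MIX))
    confirmed_composition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONFIRMED_COMPOSITION))
    probable_composition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROBABLE_COMPOSITION))
    messiness: Messiness = field(default_factory=Messiness)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 0:
            raise SpecError("n_persons must be >= 0")
        for name, dist in (("tier_mix", self.tier_mix),
                           ("confirmed_composition", self.confirmed_composition),
                           ("probable_composition", self.probable_composition)):
            total = sum(dist.values())
            if dist and not math.isclose(total, 1.0, abs_tol=1e-9):
                raise SpecError(f"{name} proportions sum to {total}, not 1")
        for key in self.tier_mix:
            if key not in (CONFIRMED_PWH, PROBABLE_PWH, PREP_USER, NONE):
                raise SpecError(f"unknown tier in tier_mix: {key}")
        for subset in self.confirmed_composition:
            s = frozenset(subset.split("+"))
            if not ("survey" in s or "lab" in s or {"condition", "drug"} <= s):
                raise SpecError(
                    f"confirmed subset {subset!r} carries no confirming mechanism"
                )
        for subset in self.probable_composition:
            if subset not in ("condition", "drug"):
                raise SpecError(
                    f"probable subset {subset!r} must be 'condition' or 'drug'"
                )


@dataclass
class LabeledBundle:
    """A generated bundle plus the truth table it must classify back to."""

    bundle: OmopBundle
    truth: pd.DataFrame  # person_id, label, evidence_sources, hbv_flag
    spec: GroundTruthSpec | None = None


def _allocate(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Deterministic largest-remainder allocation of n among categories."""
    keys = sorted(proportions)
    raw = {k: n * proportions[k] for k in keys}
    alloc = {k: int(math.floor(raw[k])) for k in keys}
    short = n - sum(alloc.values())
    by_rem = sorted(keys, key=lambda k: (-(raw[k] - alloc[k]), k))
    for k in by_rem[:short]:
        alloc[k] += 1
    return alloc


def _rand_date(rng: np.random.Generator,
               window: tuple[datetime.date, datetime.date]) -> datetime.date:
    span = (window[1] - window[0]).days
    return window[0] + datetime.timedelta(days=int(rng.integers(0, span + 1)))


class _Builder:
    """Accumulates rows for the five tables plus truth/aliases."""

    def __init__(self, rng: np.random.Generator, config: RunConfig) -> None:
        self.rng = rng
        self.config = config
        self.messiness = Messiness.none()
        self.persons: list[dict] = []
        self.conditions: list[dict] = []
        self.drugs: list[dict] = []
        self.measurements: list[dict] = []
        self.surveys: list[dict] = []
        self.truth: list[dict] = []
        self.alias_map: dict[str, str] = {}

    # -- person & demographics -------------------------------------------
    def add_person(self, pid: str) -> None:
        rng = self.rng
        age = int(np.clip(round(rng.normal(52, 15)), 18, 90))
        row = {"person_id": pid,
               "birth_year": self.config.anchor_date.year - age}
        for col, dist in DEMOGRAPHIC_DISTRIBUTIONS.items():
            levels = sorted(dist)
            probs = np.array([dist[l] for l in levels])
            row[col] = str(rng.choice(levels, p=probs / probs.sum()))
        self.persons.append(row)

    # -- evidence planting -----------------------------------------------
    def plant_condition(self, pid: str, code: str | None = None) -> None:
        code = code or str(self.rng.choice(HIV_CONDITION_CODES))
        snomed = code.isdigit()
        self.conditions.append({
            "person_id": pid,
            "concept_id": code if snomed else "",
            "source_code": "" if snomed else code,
            "date": _rand_date(self.rng, self.config.ehr_window),
        })

    def plant_art(self, pid: str) -> None:
        """A non-PrEP ART history: single agent or a 3-ingredient regimen."""
        rng = self.rng
        variant = rng.choice(["single", "triple_product", "triple_rows"])
        n_days = int(rng.integers(1, 4))
        for _ in range(n_days):
            date = _rand_date(rng, self.config.ehr_window)
            if variant == "single":
                self._drug_row(pid, str(rng.choice(["dolutegravir", "darunavir",
                                                    "raltegravir"])), date)
            elif variant == "triple_product":
                self._drug_row(pid, str(rng.choice(["biktarvy", "atripla"])), date)
            else:
                for ing in ("dolutegravir", "emtricitabine", "tenofovir_disoproxil"):
                    self._drug_row(pid, ing, date)

    def plant_prep(self, pid: str) -> None:
        # distinct fill dates: two fills with different backbones on one day
        # would form a 3-ingredient combo and break the PrEP pattern
        rng = self.rng
        n_fills = int(rng.integers(1, 4))
        dates: set[datetime.date] = set()
        while len(dates) < n_fills:
            dates.add(_rand_date(rng, self.config.ehr_window))
        for date in sorted(dates):
            form = rng.choice(["truvada", "descovy", "split_tdf", "split_taf"])
            if form == "split_tdf":
                self._drug_row(pid, "emtricitabine", date)
                self._drug_row(pid, "tenofovir_disoproxil", date)
            elif form == "split_taf":
                self._drug_row(pid, "emtricitabine", date)
                self._drug_row(pid, "tenofovir_alafenamide", date)
            else:
                self._drug_row(pid, str(form), date)

    def plant_screen(self, pid: str, positive: bool,
                     date: datetime.date | None = None) -> None:
        values = POSITIVE_SCREEN_VALUES if positive else NEGATIVE_SCREEN_VALUES
        self.measurements.append({
            "person_id": pid,
            "concept_id": SCREEN_CONCEPT,
            "value_string": str(self.rng.choice(values)),
            "value_number": np.nan,
            "unit_string": "",
            "date": date or _rand_date(self.rng, self.config.ehr_window),
        })

    def plant_vl(self, pid: str, detectable: bool,
                 date: datetime.date | None = None) -> None:
        """One numeric viral-load row, possibly log-scaled / unit-less.

        Undetectable linear values start at 9 copies/mL: below the log10
        plausibility bound a unit-less value would be reread as log10, so the
        generator never emits one there.
        """
        rng = self.rng
        m = self.messiness
        copies = int(rng.integers(300, 1_000_000)) if detectable \
            else int(rng.integers(9, 181))
        value, unit = float(copies), "copies/mL"
        if rng.random() < m.ln_scale_vl:
            value, unit = round(math.log(copies), 3), "ln copies/mL"
        elif rng.random() < m.log_scale_vl:
            value, unit = round(math.log10(copies), 3), "log10 copies/mL"
            if rng.random() < m.missing_unit:
                unit = ""
        elif rng.random() < m.missing_unit:
            unit = ""  # linear values are all > the log10 bound, heuristic-safe
        self.measurements.append({
            "person_id": pid, "concept_id": VL_CONCEPT, "value_string": "",
            "value_number": value, "unit_string": unit,
            "date": date or _rand_date(rng, self.config.ehr_window),
        })

    def plant_survey(self, pid: str, positive: bool) -> None:
        self.surveys.append({
            "person_id": pid,
            "question_concept_id": SURVEY_QUESTION,
            "answer_value": SURVEY_POSITIVE_ANSWER if positive else "No",
            "date": _rand_date(self.rng, self.config.survey_window),
        })

    def _drug_row(self, pid: str, concept: str, date: datetime.date) -> None:
        self.drugs.append({
            "person_id": pid, "drug_concept_id": concept, "date": date,
        })

    # -- decoys -----------------------------------------------------------
    def plant_hcv_decoy(self, pid: str) -> None:
        self._drug_row(pid, str(self.rng.choice(["harvoni", "epclusa", "sofosbuvir"])),
                       _rand_date(self.rng, self.config.ehr_window))

    def plant_hbv_decoy(self, pid: str) -> None:
        code = str(self.rng.choice(HBV_CODES))
        self.conditions.append({
            "person_id": pid, "concept_id": "", "source_code": code,
            "date": _rand_date(self.rng, self.config.ehr_window),
        })

    def plant_other_drug(self, pid: str) -> None:
        self._drug_row(pid, str(self.rng.choice(["metformin", "lisinopril",
                                                 "atorvastatin"])),
                       _rand_date(self.rng, self.config.ehr_window))

    def plant_out_of_window(self, pid: str) -> None:
        rng = self.rng
        kind = rng.choice(["condition", "drug", "survey", "measurement"])
        before = self.config.ehr_window[0] - datetime.timedelta(
            days=int(rng.integers(30, 2000)))
        if kind == "condition":
            self.conditions.append({
                "person_id": pid, "concept_id": "", "source_code": "B20",
                "date": before,
            })
        elif kind == "drug":
            self._drug_row(pid, "atripla", before)
        elif kind == "survey":
            self.surveys.append({
                "person_id": pid, "question_concept_id": SURVEY_QUESTION,
                "answer_value": SURVEY_POSITIVE_ANSWER,
                "date": self.config.survey_window[0] - datetime.timedelta(
                    days=int(rng.integers(1, 400))),
            })
        else:
            after = self.config.ehr_window[1] + datetime.timedelta(
                days=int(rng.integers(1, 400)))
            self.measurements.append({
                "person_id": pid, "concept_id": VL_CONCEPT, "value_string": "",
                "value_number": float(int(rng.integers(300, 100000))),
                "unit_string": "copies/mL", "date": after,
            })

    # -- assembly ---------------------------------------------------------
    def to_bundle(self) -> OmopBundle:
        persons = pd.DataFrame(
            self.persons,
            columns=["person_id", "birth_year", *DEMOGRAPHIC_DISTRIBUTIONS],
        )
        conditions = pd.DataFrame(
            self.conditions, columns=["person_id", "concept_id", "source_code", "date"])
        drugs = pd.DataFrame(
            self.drugs, columns=["person_id", "drug_concept_id", "date"])
        drugs["ingredients"] = [
            resolve_ingredients(c, self.config.ingredient_map)
            for c in drugs["drug_concept_id"]
        ]
        measurements = pd.DataFrame(
            self.measurements,
            columns=["person_id", "concept_id", "value_string", "value_number",
                     "unit_string", "date"])
        measurements["value_number"] = pd.to_numeric(measurements["value_number"])
        surveys = pd.DataFrame(
            self.surveys,
            columns=["person_id", "question_concept_id", "answer_value", "date"])
        bundle = OmopBundle(
            persons=persons, conditions=conditions, drugs=drugs,
            measurements=measurements, surveys=surveys,
            alias_map=dict(self.alias_map),
            provenance={"source": "synthetic", "row_counts": {}},
        )
        bundle.provenance["row_counts"] = bundle.counts()
        return bundle


def _plant_confirmed(b: _Builder, pid: str, subset: frozenset[str]) -> None:
    rng = b.rng
    if "condition" in subset:
        b.plant_condition(pid)
    if "drug" in subset:
        b.plant_art(pid)
    if "survey" in subset:
        b.plant_survey(pid, positive=True)
    if "lab" in subset:
        mechanisms = ["screen_pos", "vl_detectable"]
        if "drug" in subset:
            mechanisms.append("suppressed")
        mech = str(rng.choice(mechanisms))
        if mech == "screen_pos":
            b.plant_screen(pid, positive=True)
        elif mech == "vl_detectable":
            for _ in range(int(rng.integers(1, 3))):
                b.plant_vl(pid, detectable=True)
        else:
            d1 = _rand_date(rng, b.config.ehr_window)
            d2 = d1 + datetime.timedelta(days=int(rng.integers(30, 200)))
            d2 = min(d2, b.config.ehr_window[1])
            if d2 == d1:
                d1 = d1 - datetime.timedelta(days=40)
            b.plant_vl(pid, detectable=False, date=d1)
            b.plant_vl(pid, detectable=False, date=d2)


def generate_cohort(spec: GroundTruthSpec,
                    config: RunConfig | None = None) -> LabeledBundle:
    """Deterministically generate a labeled bundle realizing ``spec``.

    Each person's planted records realize the intended label and
    evidence-source subset exactly; decoys never change intended labels.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(spec.seed)
    b = _Builder(rng, config)
    b.messiness = spec.messiness
    m = spec.messiness

    tier_alloc = _allocate(spec.n_persons, dict(spec.tier_mix))
    plan: list[tuple[str, str]] = []  # (label, subset_key)
    conf_alloc = _allocate(tier_alloc.get(CONFIRMED_PWH, 0),
                           dict(spec.confirmed_composition))
    for subset, k in sorted(conf_alloc.items()):
        plan += [(CONFIRMED_PWH, subset)] * k
    prob_alloc = _allocate(tier_alloc.get(PROBABLE_PWH, 0),
                           dict(spec.probable_composition))
    for subset, k in sorted(prob_alloc.items()):
        plan += [(PROBABLE_PWH, subset)] * k
    plan += [(PREP_USER, "drug+lab")] * tier_alloc.get(PREP_USER, 0)
    plan += [(NONE, "")] * tier_alloc.get(NONE, 0)

    order = rng.permutation(len(plan))
    for i, idx in enumerate(order):
        label, skey = plan[idx]
        pid = f"P{i + 1:06d}"
        b.add_person(pid)
        subset = frozenset(skey.split("+")) if skey else frozenset()
        hbv = False
        if label == CONFIRMED_PWH:
            _plant_confirmed(b, pid, subset)
        elif label == PROBABLE_PWH:
            if skey == "condition":
                b.plant_condition(pid)
            else:
                b.plant_art(pid)
            if rng.random() < 0.2:
                b.plant_survey(pid, positive=False)
        elif label == PREP_USER:
            b.plant_prep(pid)
            b.plant_screen(pid, positive=False)
            if rng.random() < m.hbv_decoy:
                b.plant_hbv_decoy(pid)
                hbv = True
        else:
            background = rng.choice(["empty", "other_drug", "neg_screen",
                                     "hcv_only", "neg_survey"])
            if background == "other_drug":
                b.plant_other_drug(pid)
            elif background == "neg_screen":
                b.plant_screen(pid, positive=False)
            elif background == "hcv_only":
                b.plant_hcv_decoy(pid)
            elif background == "neg_survey":
                b.plant_survey(pid, positive=False)

        if label != PREP_USER and rng.random() < m.hcv_decoy:
            b.plant_hcv_decoy(pid)
        if rng.random() < m.out_of_window:
            b.plant_out_of_window(pid)

        b.truth.append({
            "person_id": pid, "label": label,
            "evidence_sources": skey, "hbv_flag": hbv,
        })

    _split_duplicate_ids(b, m.duplicate_id)

    truth = pd.DataFrame(
        b.truth, columns=["person_id", "label", "evidence_sources", "hbv_flag"]
    ).sort_values("person_id", kind="mergesort").reset_index(drop=True)
    return LabeledBundle(bundle=b.to_bundle(), truth=truth, spec=spec)


def _split_duplicate_ids(b: _Builder, rate: float) -> None:
    """Move some of a person's records under an alias id, recording the
    alias -> canonical mapping that consolidation must undo."""
    if rate <= 0 or not b.persons:
        return
    rng = b.rng
    originals = [p["person_id"] for p in b.persons]
    chosen = [pid for pid in originals if rng.random() < rate]
    person_rows = {p["person_id"]: p for p in b.persons}
    for pid in chosen:
        alias = f"D{pid}"
        moved = 0
        for rows in (b.conditions, b.drugs, b.measurements, b.surveys):
            for row in rows:
                if row["person_id"] == pid and rng.random() < 0.5:
                    row["person_id"] = alias
                    moved += 1
        # alias person row shares demographics with the canonical row
        alias_row = dict(person_rows[pid])
        alias_row["person_id"] = alias
        b.persons.append(alias_row)
        b.alias_map[alias] = pid


def generate_edge_cases(config: RunConfig | None = None) -> LabeledBundle:
    """One handcrafted person per boundary/branch of the classifier."""
    config = config or RunConfig()
    rng = np.random.default_rng(20220701)
    b = _Builder(rng, config)
    b.messiness = Messiness.none()
    mid = datetime.date(2020, 6, 15)
    later = datetime.date(2021, 3, 1)

    def vl_row(pid: str, value: float, unit: str, date=mid) -> None:
        b.measurements.append({
            "person_id": pid, "concept_id": VL_CONCEPT, "value_string": "",
            "value_number": value, "unit_string": unit, "date": date,
        })

    def person(pid: str, label: str, sources: str, hbv: bool = False) -> str:
        b.add_person(pid)
        b.truth.append({"person_id": pid, "label": label,
                        "evidence_sources": sources, "hbv_flag": hbv})
        return pid

    # boundary: VL exactly at threshold is undetectable -> no label
    vl_row(person("E01", NONE, ""), 200.0, "copies/mL")
    # boundary: log10 value exactly log10(200)
    vl_row(person("E02", NONE, ""), math.log10(200.0), "log10 copies/mL")
    # single PrEP component alone is ART evidence, not PrEP
    p = person("E03", PROBABLE_PWH, "drug")
    b._drug_row(p, "emtricitabine", mid)
    # three ingredients together are not PrEP
    p = person("E04", PROBABLE_PWH, "drug")
    b._drug_row(p, "biktarvy", mid)
    # FTC+TDF days plus any other combination disqualify PrEP
    p = person("E05", PROBABLE_PWH, "drug")
    b._drug_row(p, "truvada", mid)
    b._drug_row(p, "darunavir", later)
    # survey-positive PrEP candidate is a confirmed PWH
    p = person("E06", CONFIRMED_PWH, "survey")
    b._drug_row(p, "truvada", mid)
    b.plant_screen(p, positive=False, date=mid)
    b.surveys.append({"person_id": p, "question_concept_id": SURVEY_QUESTION,
                      "answer_value": SURVEY_POSITIVE_ANSWER,
                      "date": datetime.date(2020, 1, 15)})
    # duplicate-id pair: condition under canonical, ART under alias
    p = person("E07", CONFIRMED_PWH, "condition+drug")
    b.conditions.append({"person_id": p, "concept_id": "86406008",
                         "source_code": "", "date": mid})
    b._drug_row("DE07", "biktarvy", later)
    alias_row = dict(b.persons[-1])
    alias_row["person_id"] = "DE07"
    b.persons.append(alias_row)
    b.alias_map["DE07"] = p
    # negative screening string must not substring-match "detected"
    b.plant_screen(person("E08", NONE, ""), positive=False, date=mid)
    # canonical PrEP user
    p = person("E09", PREP_USER, "drug+lab")
    b._drug_row(p, "truvada", mid)
    b._drug_row(p, "descovy", later)
    b.plant_screen(p, positive=False, date=mid)
    # PrEP-pattern drugs plus an HIV condition code: probable, not PrEP
    p = person("E10", PROBABLE_PWH, "condition")
    b._drug_row(p, "truvada", mid)
    b.conditions.append({"person_id": p, "concept_id": "", "source_code": "B20",
                         "date": mid})
    # survey alone confirms
    p = person("E11", CONFIRMED_PWH, "survey")
    b.surveys.append({"person_id": p, "question_concept_id": SURVEY_QUESTION,
                      "answer_value": SURVEY_POSITIVE_ANSWER,
                      "date": datetime.date(2019, 7, 1)})
    # condition alone is probable
    p = person("E12", PROBABLE_PWH, "condition")
    b.conditions.append({"person_id": p, "concept_id": "", "source_code": "Z21",
                         "date": mid})
    # suppressed on ART: two undetectable VLs on distinct dates
    p = person("E13", CONFIRMED_PWH, "drug+lab")
    b._drug_row(p, "atripla", mid)
    vl_row(p, 50.0, "copies/mL", mid)
    vl_row(p, 40.0, "copies/mL", later)
    # one undetectable VL is not suppression
    p = person("E14", PROBABLE_PWH, "drug")
    b._drug_row(p, "atripla", mid)
    vl_row(p, 50.0, "copies/mL", mid)
    # positive screen alone confirms
    b.plant_screen(person("E15", CONFIRMED_PWH, "lab"), positive=True, date=mid)
    # HCV-only drug history is excluded from ART evidence
    p = person("E16", NONE, "")
    b._drug_row(p, "harvoni", mid)
    # VL just above threshold confirms
    vl_row(person("E17", CONFIRMED_PWH, "lab"), 201.0, "copies/mL")
    # PrEP user with an HBV code: label unchanged, flag set
    p = person("E18", PREP_USER, "drug+lab", hbv=True)
    b._drug_row(p, "truvada", mid)
    b.plant_screen(p, positive=False, date=mid)
    b.conditions.append({"person_id": p, "concept_id": "", "source_code": "B18.1",
                         "date": mid})
    # natural-log scale below / above threshold (ln 200 ~ 5.298)
    vl_row(person("E19", NONE, ""), 5.2, "ln copies/mL")
    vl_row(person("E20", CONFIRMED_PWH, "lab"), 5.4, "ln copies/mL")

    truth = pd.DataFrame(
        b.truth, columns=["person_id", "label", "evidence_sources", "hbv_flag"]
    ).sort_values("person_id", kind="mergesort").reset_index(drop=True)
    return LabeledBundle(bundle=b.to_bundle(), truth=truth, spec=None)
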