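"""Per-person evidence aggregation and tier assignment.

The classifier partitions every person into exactly one of four labels:

``CONFIRMED_PWH``
    Any of: an affirmative answer to the HIV survey item; a positive
    screening result; a detectable viral load (>200 copies/mL or its log
    equivalent); virologic suppression on ART (>=2 undetectable viral loads
    while on an ART drug pattern); or an HIV diagnosis code together with a
    non-PrEP ART drug history.
``PROBABLE_PWH``
    Unconfirmed EHR evidence: an HIV diagnosis code or an ART drug pattern,
    with nothing confirming. (Diagnosis-only records are the classic
    incomplete-metadata case; drug-only records are ART regimens with no
    coded diagnosis.)
``PREP_USER``
    A strictly FTC+TDF / FTC+TAF two-drug history, a negative screening
    result, no HIV diagnosis code, and no affirmative survey answer.
``NONE``
    Everything else.

Precedence is CONFIRMED > PROBABLE > PREP_USER > NONE, evaluated in that
order; the assignment records which confirming clauses fired and which data
domains contributed positive evidence (for the Venn decomposition).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from . import evidence as ev
from .concept_sets import ConceptSetRegistry, normalize_code
from .config import RunConfig
from .omop_io import OmopBundle

CONFIRMED_PWH = "CONFIRMED_PWH"
PROBABLE_PWH = "PROBABLE_PWH"
PREP_USER = "PREP_USER"
NONE = "NONE"
LABELS = (CONFIRMED_PWH, PROBABLE_PWH, PREP_USER, NONE)

MISSING = "missing"


@dataclass(frozen=True)
class EvidenceProfile:
    """Boolean/enum summary of one person's evidence across the four domains."""

    person_id: str
    condition_pos: bool = False
    survey_status: str = MISSING       # positive | negative | missing
    screening_status: str = MISSING    # positive | negative | missing
    vl_detectable_count: int = 0
    vl_undetectable_count: int = 0
    drug_pattern: str = ev.NO_PATTERN  # PREP_ONLY | ART | HCV_ONLY | NONE
    suppressed_on_art: bool = False

    def __post_init__(self) -> None:
        if self.vl_detectable_count < 0 or self.vl_undetectable_count < 0:
            raise ValueError("viral-load counts must be non-negative")
        if self.suppressed_on_art and not (
            self.drug_pattern == ev.ART and self.vl_undetectable_count >= 2
        ):
            raise ValueError(
                "suppressed_on_art requires ART pattern and >=2 undetectable VLs"
            )


@dataclass(frozen=True)
class PhenotypeAssignment:
    person_id: str
    label: str
    confirm_basis: frozenset[str] = frozenset()      # subset of {survey, lab, condition_and_drug}
    evidence_sources: frozenset[str] = frozenset()   # subset of {condition, drug, lab, survey}
    hbv_flag: bool = False


def build_evidence_profile(
    person_id: str,
    conditions: pd.DataFrame,
    drugs: pd.DataFrame,
    measurements: pd.DataFrame,
    surveys: pd.DataFrame,
    registry: ConceptSetRegistry,
    config: RunConfig | None = None,
) -> EvidenceProfile:
    """Collapse one person's record slices into an :class:`EvidenceProfile`.

    Empty slices yield an all-missing profile; classification is total.
    """
    config = config or RunConfig()

    condition_pos = False
    if conditions is not None and len(conditions):
        for row in conditions.itertuples(index=False):
            roles = registry.classify(row.source_code) | registry.classify(row.concept_id)
            if "hiv_condition" in roles:
                condition_pos = True
                break

    survey_status = MISSING
    if surveys is not None and len(surveys):
        question_ids = {c for c in registry.codes("survey_hiv_question")}
        saw_negative = False
        for row in surveys.itertuples(index=False):
            if normalize_code(row.question_concept_id) not in question_ids:
                continue
            if registry.answer_is_positive(row.answer_value):
                survey_status = "positive"
                break
            if str(row.answer_value).strip().casefold() in config.survey_negative_answers:
                saw_negative = True
        if survey_status != "positive" and saw_negative:
            survey_status = "negative"

    interps = ev.interpret_measurements(measurements, registry, config)
    screen = [i for i in interps if i.kind == "screening"]
    vls = [i for i in interps if i.kind == "viral_load"]
    if any(i.verdict == ev.POSITIVE for i in screen):
        screening_status = "positive"
    elif any(i.verdict == ev.NEGATIVE for i in screen):
        screening_status = "negative"
    else:
        screening_status = MISSING
    vl_detectable = len({i.date for i in vls if i.verdict == ev.DETECTABLE})
    vl_undetectable = len({i.date for i in vls if i.verdict == ev.UNDETECTABLE})

    combos = ev.group_drug_records_into_combos(
        drugs, registry, tolerance_days=config.combo_tolerance_days
    )
    pattern = ev.classify_drug_pattern(combos)
    suppressed = ev.detect_suppressed_on_art(vls, pattern)

    return EvidenceProfile(
        person_id=person_id,
        condition_pos=condition_pos,
        survey_status=survey_status,
        screening_status=screening_status,
        vl_detectable_count=vl_detectable,
        vl_undetectable_count=vl_undetectable,
        drug_pattern=pattern,
        suppressed_on_art=suppressed,
    )


def assign_phenotype(profile: EvidenceProfile) -> PhenotypeAssignment:
    """Apply the tier rules to one evidence profile. Total and deterministic."""
    confirm_basis: set[str] = set()
    if profile.survey_status == "positive":
        confirm_basis.add("survey")
    if (
        profile.screening_status == "positive"
        or profile.vl_detectable_count >= 1
        or profile.suppressed_on_art
    ):
        confirm_basis.add("lab")
    if profile.condition_pos and profile.drug_pattern == ev.ART:
        confirm_basis.add("condition_and_drug")

    lab_positive = (
        profile.screening_status == "positive"
        or profile.vl_detectable_count >= 1
        or profile.suppressed_on_art
    )
    positive_sources = frozenset(
        s for s, hit in (
            ("condition", profile.condition_pos),
            ("drug", profile.drug_pattern == ev.ART),
            ("lab", lab_positive),
            ("survey", profile.survey_status == "positive"),
        ) if hit
    )

    if confirm_basis:
        return PhenotypeAssignment(
            profile.person_id, CONFIRMED_PWH,
            confirm_basis=frozenset(confirm_basis),
            evidence_sources=positive_sources,
        )
    if profile.condition_pos or profile.drug_pattern == ev.ART:
        return PhenotypeAssignment(
            profile.person_id, PROBABLE_PWH, evidence_sources=positive_sources
        )
    if (
        profile.drug_pattern == ev.PREP_ONLY
        and profile.screening_status == "negative"
        and not profile.condition_pos
        and profile.survey_status != "positive"
    ):
        # the PrEP definition itself requires the drug pattern plus the
        # negative lab, so both domains contributed
        return PhenotypeAssignment(
            profile.person_id, PREP_USER,
            evidence_sources=frozenset({"drug", "lab"}),
        )
    return PhenotypeAssignment(profile.person_id, NONE)


def _person_slices(bundle: OmopBundle):
    groups = {}
    for table, df in bundle.child_tables().items():
        groups[table] = (
            {pid: g for pid, g in df.groupby("person_id", sort=False)}
            if len(df) else {}
        )
    empty = {table: df.iloc[0:0] for table, df in bundle.child_tables().items()}
    for pid in sorted(bundle.persons["person_id"]):
        yield pid, {
            table: groups[table].get(pid, empty[table])
            for table in ("conditions", "drugs", "measurements", "surveys")
        }


def classify_bundle(
    bundle: OmopBundle,
    registry: ConceptSetRegistry,
    config: RunConfig | None = None,
) -> list[PhenotypeAssignment]:
    """One assignment per person, sorted by person_id; HBV flags applied."""
    config = config or RunConfig()
    assignments = []
    for pid, slices in _person_slices(bundle):
        profile = build_evidence_profile(
            pid, slices["conditions"], slices["drugs"], slices["measurements"],
            slices["surveys"], registry, config,
        )
        assignments.append(assign_phenotype(profile))
    return hbv_flag_prep_users(assignments, bundle.conditions, registry)


def hbv_flag_prep_users(
    assignments: Sequence[PhenotypeAssignment],
    conditions: pd.DataFrame,
    registry: ConceptSetRegistry,
) -> list[PhenotypeAssignment]:
    """Diagnostic flag for possible hepatitis-B misclassification.

    FTC/TDF/TAF also treat HBV, so a PrEP-user label can mask an HBV patient.
    PrEP users carrying any hbv_condition-role diagnosis code get
    ``hbv_flag=True``; labels are never changed by this check.
    """
    hbv_persons: set[str] = set()
    if conditions is not None and len(conditions):
        for row in conditions.itertuples(index=False):
            roles = registry.classify(row.source_code) | registry.classify(row.concept_id)
            if "hbv_condition" in roles:
                hbv_persons.add(row.person_id)
    out = []
    for a in assignments:
        if a.label == PREP_USER and a.person_id in hbv_persons:
            out.append(replace(a, hbv_flag=True))
        else:
            out.append(a)
    return out


def assignments_to_frame(assignments: Iterable[PhenotypeAssignment]) -> pd.DataFrame:
    rows = [
        {
            "person_id": a.person_id,
            "label": a.label,
            "confirm_basis": "+".join(sorted(a.confirm_basis)),
            "evidence_sources": "+".join(sorted(a.evidence_sources)),
            "hbv_flag": a.hbv_flag,
        }
        for a in assignments
    ]
    df = pd.DataFrame(
        rows, columns=["person_id", "label", "confirm_basis", "evidence_sources", "hbv_flag"]
    )
    return df.sort_values("person_id", kind="mergesort").reset_index(drop=True)


def run_cohort(
    bundle: OmopBundle,
    registry: ConceptSetRegistry,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Classify a prepared bundle; returns the assignment table sorted by
    person_id (deterministic given inputs, invariant to record order)."""
    return assignments_to_frame(classify_bundle(bundle, registry, config))
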