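"""Role-tagged concept sets: what counts as HIV condition, ART drug, PrEP
component, HCV drug, HBV condition, HIV lab test, or the HIV survey item.

The classification algorithm is driven entirely by this registry, so swapping
in a site's full production code lists requires no code change. The bundled
demo registry holds a small, representative subset of ICD-10 / SNOMED / LOINC
codes and readable ingredient tokens; it exists to exercise the algorithm,
not to be clinically exhaustive.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

#: Closed role vocabulary. prep_component_* identify the individual PrEP
#: ingredients; survey_hiv_positive_answers hold the affirmative answer
#: strings to the HIV survey question.
ROLES = (
    "hiv_condition",
    "art_drug",
    "prep_component_ftc",
    "prep_component_tdf",
    "prep_component_taf",
    "hcv_drug",
    "hbv_condition",
    "hiv_screen_lab",
    "hiv_vl_lab",
    "survey_hiv_question",
    "survey_hiv_positive_answers",
)

#: Roles that may legitimately be empty (sites without HCV/HBV exclusion lists).
OPTIONAL_ROLES = frozenset({"hcv_drug", "hbv_condition"})


class ConceptConfigError(ValueError):
    """Malformed or incomplete concept-set configuration."""


def normalize_code(code: object) -> str:
    """Normalize a code for matching: trim, casefold, strip ICD dots.

    ``B18.1`` and ``B181`` refer to the same ICD-10 code; undotted forms are
    canonical here. The dot never carries meaning in the vocabularies used
    (LOINC uses hyphens, SNOMED is numeric), so stripping is safe globally.
    """
    return str(code).strip().casefold().replace(".", "")


def _normalize_answer(answer: object) -> str:
    # Survey answers are free-ish text; dots are meaningful, so only
    # trim/casefold.
    return str(answer).strip().casefold()


@dataclass(frozen=True)
class ConceptSetRegistry:
    """Immutable mapping of role -> normalized code set."""

    roles: Mapping[str, frozenset[str]]
    version: str = "demo-0"
    source_note: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.roles) - set(ROLES)
        if unknown:
            raise ConceptConfigError(f"unknown roles: {sorted(unknown)}")
        missing = [r for r in ROLES if r not in self.roles]
        if missing:
            raise ConceptConfigError(
                f"role {missing[0]} absent (missing roles: {missing})"
            )

    def codes(self, role: str) -> frozenset[str]:
        return self.roles[role]

    def classify(self, code: object) -> frozenset[str]:
        """All roles containing ``code`` (empty set if none)."""
        norm = normalize_code(code)
        return frozenset(r for r in ROLES if norm in self.roles[r])

    def answer_is_positive(self, answer: object) -> bool:
        return _normalize_answer(answer) in {
            _normalize_answer(a) for a in self.roles["survey_hiv_positive_answers"]
        }

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "source_note": self.source_note,
            "roles": {r: sorted(self.roles[r]) for r in ROLES},
        }


def classify_code(code: object, registry: ConceptSetRegistry) -> frozenset[str]:
    """Pure function of (normalized code, registry contents)."""
    return registry.classify(code)


def _build_registry(raw_roles: Mapping, version: str, source_note: str,
                    warnings: list[str] | None = None) -> ConceptSetRegistry:
    roles: dict[str, frozenset[str]] = {}
    for role, codes in raw_roles.items():
        if role not in ROLES:
            raise ConceptConfigError(f"unknown role name: {role}")
        if role == "survey_hiv_positive_answers":
            normed = [_normalize_answer(c) for c in (codes or [])]
        else:
            normed = [normalize_code(c) for c in (codes or [])]
        if warnings is not None and len(normed) != len(set(normed)):
            dupes = sorted({c for c in normed if normed.count(c) > 1})
            warnings.append(f"duplicate codes in role {role}: {dupes}")
        roles[role] = frozenset(normed)
    for role in OPTIONAL_ROLES:
        roles.setdefault(role, frozenset())
    return ConceptSetRegistry(roles=roles, version=version, source_note=source_note)


def load_concept_config(path: str | Path) -> ConceptSetRegistry:
    """Load a registry from YAML/JSON with a top-level ``roles`` mapping.

    Missing mandatory roles are fatal; duplicate codes within a role are
    deduplicated (frozenset semantics).
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "roles" not in data:
        raise ConceptConfigError(f"{path}: missing top-level 'roles' section")
    raw = dict(data["roles"])
    for role in ROLES:
        if role not in raw:
            if role in OPTIONAL_ROLES:
                raw[role] = []
            else:
                raise ConceptConfigError(f"role {role} absent from {path}")
    return _build_registry(
        raw,
        version=str(data.get("version", "unversioned")),
        source_note=str(data.get("source_note", "")),
    )


def save_concept_config(registry: ConceptSetRegistry, path: str | Path) -> None:
    path = Path(path)
    payload = registry.to_dict()
    with open(path, "w", encoding="utf-8") as fh:
        if path.suffix == ".json":
            json.dump(payload, fh, indent=2, sort_keys=True)
        else:
            yaml.safe_dump(payload, fh, sort_keys=True)


@dataclass
class ValidationReport:
    """Outcome of registry consistency checks.

    ``forbidden_overlaps`` — codes tagged both hiv_condition and
    hbv_condition (a code cannot simultaneously assert and confound HIV).
    ``flagged`` — informational: hcv_drug codes, split by whether they also
    hold art_drug (dual-use agents) or are HCV-only (the exclusion set).
    """

    forbidden_overlaps: list[str] = field(default_factory=list)
    flagged: list[str] = field(default_factory=list)
    empty_roles: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.forbidden_overlaps and not self.empty_roles

    @property
    def empty(self) -> bool:
        return not (self.forbidden_overlaps or self.flagged or self.empty_roles)


def validate_registry(registry: ConceptSetRegistry, strict: bool = True) -> ValidationReport:
    report = ValidationReport()
    overlap = registry.codes("hiv_condition") & registry.codes("hbv_condition")
    report.forbidden_overlaps = sorted(overlap)
    for code in sorted(registry.codes("hcv_drug")):
        if code in registry.codes("art_drug"):
            report.flagged.append(f"dual-use HCV/ART agent: {code}")
        else:
            report.flagged.append(f"hcv-only exclusion: {code}")
    for role in ROLES:
        if role in OPTIONAL_ROLES:
            continue
        if not registry.codes(role):
            report.empty_roles.append(role)
    if strict and report.forbidden_overlaps:
        raise ConceptConfigError(
            "codes in both hiv_condition and hbv_condition: "
            + ", ".join(report.forbidden_overlaps)
        )
    return report


#: Demo concept sets. ICD-10 (undotted) + SNOMED for conditions, LOINC for
#: labs, readable ingredient tokens for drugs, the OMOP concept id for the
#: personal-medical-history HIV survey item.
DEMO_CONCEPTS: dict[str, list[str]] = {
    "hiv_condition": ["B20", "Z21", "B97.35", "86406008", "62479008"],
    "art_drug": [
        "emtricitabine", "tenofovir_disoproxil", "tenofovir_alafenamide",
        "dolutegravir", "bictegravir", "darunavir", "efavirenz",
        "lamivudine", "zidovudine", "raltegravir", "ritonavir",
    ],
    "prep_component_ftc": ["emtricitabine"],
    "prep_component_tdf": ["tenofovir_disoproxil"],
    "prep_component_taf": ["tenofovir_alafenamide"],
    "hcv_drug": ["sofosbuvir", "ledipasvir", "velpatasvir", "glecaprevir"],
    "hbv_condition": ["B180", "B181", "B191"],
    "hiv_screen_lab": ["75622-1", "56888-1", "7918-1"],
    "hiv_vl_lab": ["20447-9", "25836-8", "10351-5"],
    "survey_hiv_question": ["1384391"],
    "survey_hiv_positive_answers": ["Infectious Disease Condition: HIV/AIDS"],
}


def demo_registry() -> ConceptSetRegistry:
    """The bundled demonstration registry (see module docstring)."""
    return _build_registry(DEMO_CONCEPTS, version="demo-1",
                           source_note="bundled demonstration concept sets")
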