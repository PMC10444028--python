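"""Run configuration: date windows, lab-interpretation rules, schema mapping.

All tunables that govern a phenotyping run live in one :class:`RunConfig`
object, loadable from YAML so a run is fully described by (OMOP directory,
concept config, run config).
"""
from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

# EHR records are considered from the start of the HIV epidemic era to the
# data-release cut; survey responses from the survey instrument's launch.
DEFAULT_EHR_WINDOW = (datetime.date(1981, 1, 1), datetime.date(2022, 7, 1))
DEFAULT_SURVEY_WINDOW = (datetime.date(2018, 10, 1), datetime.date(2022, 6, 30))
DEFAULT_ANCHOR_DATE = datetime.date(2022, 7, 1)

# Result strings that count as a positive HIV screen (case-insensitive,
# whole-string after trimming). Both "hiv-1 positive" and "hiv-positive"
# spellings occur in source data.
DEFAULT_POSITIVE_STRINGS = frozenset(
    {"detected", "hiv-1 positive", "hiv-positive", "positive", "reactive",
     "abnormal", "high"}
)
DEFAULT_NEGATIVE_STRINGS = frozenset(
    {"negative", "nonreactive", "non-reactive", "not detected", "undetected",
     "normal"}
)

# Explicit "no" answers to the HIV survey item (anything else non-positive is
# treated as missing).
DEFAULT_SURVEY_NEGATIVE_ANSWERS = frozenset({"no", "none of these"})

# Demo drug-concept -> ingredient resolution. Fixed-dose combination products
# resolve to their component ingredients; anything absent from the map is its
# own single ingredient. A production deployment supplies its own map.
DEMO_INGREDIENT_MAP: dict[str, tuple[str, ...]] = {
    "truvada": ("emtricitabine", "tenofovir_disoproxil"),
    "descovy": ("emtricitabine", "tenofovir_alafenamide"),
    "atripla": ("efavirenz", "emtricitabine", "tenofovir_disoproxil"),
    "biktarvy": ("bictegravir", "emtricitabine", "tenofovir_alafenamide"),
    "harvoni": ("ledipasvir", "sofosbuvir"),
    "epclusa": ("sofosbuvir", "velpatasvir"),
}

TABLE_FILES = {
    "persons": "person.csv",
    "conditions": "condition_occurrence.csv",
    "drugs": "drug_exposure.csv",
    "measurements": "measurement.csv",
    "surveys": "observation.csv",
}

# Canonical field -> CSV column defaults; overridable via RunConfig.columns.
DEFAULT_COLUMNS: dict[str, dict[str, str]] = {
    "persons": {"person_id": "person_id", "birth_year": "birth_year"},
    "conditions": {
        "person_id": "person_id",
        "concept_id": "concept_id",
        "source_code": "source_code",
        "date": "date",
    },
    "drugs": {
        "person_id": "person_id",
        "drug_concept_id": "drug_concept_id",
        "date": "date",
    },
    "measurements": {
        "person_id": "person_id",
        "concept_id": "concept_id",
        "value_string": "value_string",
        "value_number": "value_number",
        "unit_string": "unit_string",
        "date": "date",
    },
    "surveys": {
        "person_id": "person_id",
        "question_concept_id": "question_concept_id",
        "answer_value": "answer_value",
        "date": "date",
    },
}


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


def _parse_date(value) -> datetime.date:
    if isinstance(value, datetime.datetime):
        return value.date()
    if isinstance(value, datetime.date):
        return value
    return datetime.date.fromisoformat(str(value))


@dataclass(frozen=True)
class RunConfig:
    """Every tunable of a phenotyping run.

    Parameters
    ----------
    ehr_window, survey_window
        Closed calendar-date intervals; records dated outside are dropped
        before classification.
    anchor_date
        Reference date for age computation (adult-cohort check, age bands).
    strict
        Orphan child records (person_id absent from the person table) are
        fatal when True, dropped-and-counted when False.
    vl_threshold_copies
        Viral-load detectability threshold in copies/mL; strictly greater
        counts as detectable.
    log10_plausibility_bound
        Heuristic bound for scale inference on unit-less numeric viral loads:
        values at or below it are read as log10 copies/mL.
    combo_tolerance_days
        Drug records within this many days of each other are grouped into one
        combination (0 = same calendar date only).
    mask_threshold
        Rendered counts in [1, mask_threshold-1] are suppressed.
    """

    ehr_window: tuple[datetime.date, datetime.date] = DEFAULT_EHR_WINDOW
    survey_window: tuple[datetime.date, datetime.date] = DEFAULT_SURVEY_WINDOW
    anchor_date: datetime.date = DEFAULT_ANCHOR_DATE
    strict: bool = True
    vl_threshold_copies: float = 200.0
    log10_plausibility_bound: float = 8.0
    positive_strings: frozenset[str] = DEFAULT_POSITIVE_STRINGS
    negative_strings: frozenset[str] = DEFAULT_NEGATIVE_STRINGS
    survey_negative_answers: frozenset[str] = DEFAULT_SURVEY_NEGATIVE_ANSWERS
    combo_tolerance_days: int = 0
    mask_threshold: int = 20
    ingredient_map: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEMO_INGREDIENT_MAP)
    )
    columns: Mapping[str, Mapping[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (start, end) in (
            ("ehr_window", self.ehr_window),
            ("survey_window", self.survey_window),
        ):
            if start > end:
                raise ConfigError(f"{name} is inverted: {start} > {end}")
        if self.mask_threshold < 1:
            raise ConfigError("mask_threshold must be >= 1")
        if self.combo_tolerance_days < 0:
            raise ConfigError("combo_tolerance_days must be >= 0")

    def column_map(self, table: str) -> dict[str, str]:
        """Canonical-field -> CSV-column mapping for one table."""
        base = dict(DEFAULT_COLUMNS[table])
        base.update(self.columns.get(table, {}))
        return base

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("ehr_window", "survey_window"):
            d[key] = [v.isoformat() for v in d[key]]
        d["anchor_date"] = self.anchor_date.isoformat()
        d["positive_strings"] = sorted(self.positive_strings)
        d["negative_strings"] = sorted(self.negative_strings)
        d["survey_negative_answers"] = sorted(self.survey_negative_answers)
        d["ingredient_map"] = {k: list(v) for k, v in sorted(self.ingredient_map.items())}
        d["columns"] = {t: dict(m) for t, m in self.columns.items()}
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        kwargs: dict = {}
        for key in ("ehr_window", "survey_window"):
            if key in data:
                start, end = data[key]
                kwargs[key] = (_parse_date(start), _parse_date(end))
        if "anchor_date" in data:
            kwargs["anchor_date"] = _parse_date(data["anchor_date"])
        for key in ("strict", "vl_threshold_copies", "log10_plausibility_bound",
                    "combo_tolerance_days", "mask_threshold"):
            if key in data:
                kwargs[key] = data[key]
        for key in ("positive_strings", "negative_strings", "survey_negative_answers"):
            if key in data:
                kwargs[key] = frozenset(str(s).strip().casefold() for s in data[key])
        if "ingredient_map" in data:
            kwargs["ingredient_map"] = {
                str(k): tuple(str(i) for i in v) for k, v in data["ingredient_map"].items()
            }
        if "columns" in data:
            kwargs["columns"] = {t: dict(m) for t, m in data["columns"].items()}
        unknown = set(data) - {
            "ehr_window", "survey_window", "anchor_date", "strict",
            "vl_threshold_copies", "log10_plausibility_bound",
            "positive_strings", "negative_strings", "survey_negative_answers",
            "combo_tolerance_days", "mask_threshold", "ingredient_map", "columns",
        }
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
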