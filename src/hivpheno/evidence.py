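"""Turn raw lab values and drug histories into the evidence atoms the
classifier consumes.

Two kinds of HIV lab results are handled separately. Screening tests carry
categorical result strings ("Reactive", "Not detected", ...); they are matched
whole-string, case-insensitively, against configured positive/negative sets —
substring matching is deliberately avoided so "not detected" can never hit
"detected". Viral loads carry numbers whose scale may be linear copies/mL or a
log transform; the detectability threshold (default 200 copies/mL, strict
inequality) is compared on whichever scale the value lives on.

Drug histories are grouped into same-day combinations; the per-person pattern
over all combinations decides PrEP-only vs ART vs HCV-only status.
"""
from __future__ import annotations

import datetime
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .concept_sets import ConceptSetRegistry, normalize_code
from .config import RunConfig

# Lab verdicts
POSITIVE = "positive"
NEGATIVE = "negative"
UNKNOWN = "unknown"
DETECTABLE = "detectable"
UNDETECTABLE = "undetectable"

# Drug pattern classes
PREP_ONLY = "PREP_ONLY"
ART = "ART"
HCV_ONLY = "HCV_ONLY"
NO_PATTERN = "NONE"

LINEAR = "linear"
LOG10 = "log10"
LN = "ln"

OTHER_DRUG = "other_drug"


@dataclass(frozen=True)
class VlScale:
    """Resolved scale of a numeric viral-load value and how it was decided."""

    scale: str  # linear | log10 | ln
    source: str  # unit_metadata | config_override | heuristic


@dataclass(frozen=True)
class LabInterpretation:
    """One interpreted lab record.

    ``kind`` is ``screening`` (verdict positive/negative/unknown) or
    ``viral_load`` (verdict detectable/undetectable/unknown).
    """

    kind: str
    verdict: str
    date: datetime.date | None
    raw_value: str


@dataclass(frozen=True)
class DrugDayCombo:
    """Union of role-tagged ingredients one person was exposed to on one day
    (or within the configured tolerance window)."""

    person_id: str
    date: datetime.date
    ingredients: frozenset[str]
    roles: Mapping[str, frozenset[str]]  # ingredient -> roles (OTHER_DRUG if none)


def interpret_screening_value(
    value_string: str,
    positive_strings: Iterable[str] = None,
    negative_strings: Iterable[str] = None,
) -> str:
    """Classify a categorical screening result string.

    Whole-string match after trim/casefold; anything outside both configured
    sets is ``unknown``. Total function — never raises.
    """
    cfg = RunConfig()
    pos = frozenset(positive_strings) if positive_strings is not None else cfg.positive_strings
    neg = frozenset(negative_strings) if negative_strings is not None else cfg.negative_strings
    token = str(value_string or "").strip().casefold()
    if not token:
        return UNKNOWN
    if token in neg:
        return NEGATIVE
    if token in pos:
        return POSITIVE
    return UNKNOWN


_LOG10_TOKENS = ("log10", "log 10", "log_10")
_LN_TOKENS = ("ln",)


def infer_vl_scale(
    value_number: float,
    unit_string: str = "",
    log10_bound: float = 8.0,
    override: str | None = None,
) -> VlScale:
    """Decide whether a numeric viral load is linear, log10 or ln scale.

    Unit metadata wins when present; a per-run override beats everything; with
    neither, a plausibility heuristic applies: no real linear copies/mL value
    sits at or below ``log10_bound`` (default 8.0 ~ 10^8 copies/mL ceiling on
    the log side), so small unit-less values are read as log10.
    """
    if value_number is None or (isinstance(value_number, float) and math.isnan(value_number)):
        raise ValueError("viral-load scale inference requires a numeric value")
    if value_number < 0:
        raise ValueError(f"negative viral-load value: {value_number}")
    if override is not None:
        if override not in (LINEAR, LOG10, LN):
            raise ValueError(f"unknown scale override: {override}")
        return VlScale(override, "config_override")
    unit = str(unit_string or "").strip().casefold()
    if unit:
        if any(tok in unit for tok in _LOG10_TOKENS):
            return VlScale(LOG10, "unit_metadata")
        words = unit.replace("/", " ").split()
        if any(tok in words for tok in _LN_TOKENS):
            return VlScale(LN, "unit_metadata")
        if "log" in unit:
            # bare "log" on a clinical viral load conventionally means log10
            return VlScale(LOG10, "unit_metadata")
        return VlScale(LINEAR, "unit_metadata")
    if value_number <= log10_bound:
        return VlScale(LOG10, "heuristic")
    return VlScale(LINEAR, "heuristic")


def interpret_viral_load(
    value_number: float | None,
    scale: VlScale | str,
    threshold_copies: float = 200.0,
) -> str:
    """Detectable iff the value strictly exceeds the threshold on its own
    scale (linear: v > t; log10: v > log10 t; ln: v > ln t).

    Exactly the threshold is undetectable (strict inequality). Missing value
    is ``unknown``.
    """
    if value_number is None or (isinstance(value_number, float) and math.isnan(value_number)):
        return UNKNOWN
    name = scale.scale if isinstance(scale, VlScale) else scale
    if name == LINEAR:
        cut = threshold_copies
    elif name == LOG10:
        cut = math.log10(threshold_copies)
    elif name == LN:
        cut = math.log(threshold_copies)
    else:
        raise ValueError(f"unknown viral-load scale: {name}")
    return DETECTABLE if value_number > cut else UNDETECTABLE


def interpret_measurements(
    measurements: pd.DataFrame,
    registry: ConceptSetRegistry,
    config: RunConfig | None = None,
) -> list[LabInterpretation]:
    """Interpret every HIV-relevant measurement row.

    Rows route by the concept's registry role: hiv_screen_lab rows through the
    string matcher, hiv_vl_lab rows through scale inference + threshold (a
    categorical string on a VL row maps positive->detectable,
    negative->undetectable). Rows whose concept holds neither role are skipped.
    """
    config = config or RunConfig()
    out: list[LabInterpretation] = []
    if measurements is None or len(measurements) == 0:
        return out
    for row in measurements.itertuples(index=False):
        roles = registry.classify(row.concept_id)
        date = row.date
        value_string = getattr(row, "value_string", "") or ""
        value_number = getattr(row, "value_number", float("nan"))
        if "hiv_screen_lab" in roles:
            verdict = interpret_screening_value(
                value_string, config.positive_strings, config.negative_strings
            )
            out.append(LabInterpretation("screening", verdict, date, str(value_string)))
        if "hiv_vl_lab" in roles:
            verdict = UNKNOWN
            raw = str(value_string)
            if value_number is not None and not (
                isinstance(value_number, float) and math.isnan(value_number)
            ):
                raw = str(value_number)
                try:
                    scale = infer_vl_scale(
                        float(value_number),
                        getattr(row, "unit_string", "") or "",
                        log10_bound=config.log10_plausibility_bound,
                    )
                    verdict = interpret_viral_load(
                        float(value_number), scale, config.vl_threshold_copies
                    )
                except ValueError:
                    verdict = UNKNOWN
            elif value_string:
                s = interpret_screening_value(
                    value_string, config.positive_strings, config.negative_strings
                )
                verdict = {POSITIVE: DETECTABLE, NEGATIVE: UNDETECTABLE}.get(s, UNKNOWN)
            out.append(LabInterpretation("viral_load", verdict, date, raw))
    return out


def _ingredient_roles(ingredient: str, registry: ConceptSetRegistry) -> frozenset[str]:
    roles = registry.classify(ingredient)
    return roles if roles else frozenset({OTHER_DRUG})


def group_drug_records_into_combos(
    drugs: pd.DataFrame,
    registry: ConceptSetRegistry,
    tolerance_days: int = 0,
) -> list[DrugDayCombo]:
    """Group ingredient-resolved drug records into per-(person, day) combos.

    Records on the same date — or whose dates chain within ``tolerance_days``
    of each other — form one combination holding the union of ingredients.
    Ingredients with no registry role are tagged ``other_drug``.
    """
    combos: list[DrugDayCombo] = []
    if drugs is None or len(drugs) == 0:
        return combos
    for person_id, group in drugs.groupby("person_id", sort=True):
        by_date: dict[datetime.date, set[str]] = {}
        for row in group.itertuples(index=False):
            by_date.setdefault(row.date, set()).update(
                normalize_code(i) for i in row.ingredients
            )
        dates = sorted(by_date)
        cluster_dates: list[datetime.date] = []
        cluster_ing: set[str] = set()
        for d in dates:
            if cluster_dates and (d - cluster_dates[-1]).days > tolerance_days:
                combos.append(_make_combo(person_id, cluster_dates[0], cluster_ing, registry))
                cluster_dates, cluster_ing = [], set()
            cluster_dates.append(d)
            cluster_ing.update(by_date[d])
        if cluster_dates:
            combos.append(_make_combo(person_id, cluster_dates[0], cluster_ing, registry))
    return combos


def _make_combo(person_id: str, date: datetime.date, ingredients: set[str],
                registry: ConceptSetRegistry) -> DrugDayCombo:
    return DrugDayCombo(
        person_id=person_id,
        date=date,
        ingredients=frozenset(ingredients),
        roles={i: _ingredient_roles(i, registry) for i in sorted(ingredients)},
    )


def _combo_is_prep(combo: DrugDayCombo) -> bool:
    # exactly two ingredients: FTC plus TDF or TAF, any dose/form
    if len(combo.ingredients) != 2:
        return False
    has_ftc = any("prep_component_ftc" in r for r in combo.roles.values())
    has_backbone = any(
        ("prep_component_tdf" in r) or ("prep_component_taf" in r)
        for r in combo.roles.values()
    )
    ftc = {i for i, r in combo.roles.items() if "prep_component_ftc" in r}
    backbone = {
        i for i, r in combo.roles.items()
        if "prep_component_tdf" in r or "prep_component_taf" in r
    }
    return has_ftc and has_backbone and bool(ftc) and bool(backbone - ftc)


def _combo_is_hcv_only(combo: DrugDayCombo) -> bool:
    # every ingredient is an HCV agent with no ART role
    return bool(combo.ingredients) and all(
        "hcv_drug" in r and "art_drug" not in r for r in combo.roles.values()
    )


def _combo_counts_as_art(combo: DrugDayCombo) -> bool:
    # HCV-only regimens are excluded from ART evidence; mixed regimens with
    # any ART-role ingredient still count
    if _combo_is_hcv_only(combo):
        return False
    return any("art_drug" in r for r in combo.roles.values())


def classify_drug_pattern(combos: Sequence[DrugDayCombo]) -> str:
    """Summarize one person's whole drug history into a pattern class.

    PREP_ONLY: every combination is exactly FTC+TDF or FTC+TAF (and at least
    one exists) — one drug alone or three or more drugs together is not PrEP,
    and any other combination anywhere in the history disqualifies it.
    ART: any combination carries an ART-role ingredient outside an HCV-only
    regimen (and the pattern is not PREP_ONLY). HCV_ONLY: role-bearing
    combinations are exclusively HCV agents. NONE otherwise.
    """
    if not combos:
        return NO_PATTERN
    persons = {c.person_id for c in combos}
    if len(persons) > 1:
        raise ValueError(f"combos span multiple persons: {sorted(persons)}")
    if all(_combo_is_prep(c) for c in combos):
        return PREP_ONLY
    if any(_combo_counts_as_art(c) for c in combos):
        return ART
    hcv = [c for c in combos if _combo_is_hcv_only(c)]
    role_bearing = [
        c for c in combos
        if any(r - {OTHER_DRUG} for r in c.roles.values())
    ]
    if hcv and len(hcv) == len(role_bearing):
        return HCV_ONLY
    return NO_PATTERN


def detect_suppressed_on_art(
    vl_history: Iterable[LabInterpretation], pattern: str
) -> bool:
    """Virologically suppressed on treatment: ART pattern plus undetectable
    viral loads on at least two distinct dates (distinct dates, not rows, so
    duplicated records cannot inflate the count)."""
    if pattern != ART:
        return False
    dates = {
        i.date for i in vl_history
        if i.kind == "viral_load" and i.verdict == UNDETECTABLE
    }
    return len(dates) >= 2
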