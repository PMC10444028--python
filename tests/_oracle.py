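"""Independent brute-force rule table for the tier assignment.

Written separately from the engine: virologic suppression is recomputed here
from the pattern and the undetectable count (the engine carries it as a
precomputed flag), and the rules are expressed as a flat reason list rather
than the engine's staged control flow. Used as the ground-truth oracle in
equivalence tests over the enumerated profile space.
"""
from itertools import product

from hivpheno.engine import (CONFIRMED_PWH, NONE, PREP_USER, PROBABLE_PWH,
                             EvidenceProfile)


def oracle_assign(profile: EvidenceProfile):
    """(label, confirm_basis, evidence_sources) by an independent route."""
    cond = profile.condition_pos
    on_art = profile.drug_pattern == "ART"
    prep_pattern = profile.drug_pattern == "PREP_ONLY"
    survey_pos = profile.survey_status == "positive"
    suppressed = on_art and profile.vl_undetectable_count >= 2
    lab_pos = (profile.screening_status == "positive"
               or profile.vl_detectable_count > 0
               or suppressed)

    reasons = set()
    if survey_pos:
        reasons.add("survey")
    if lab_pos:
        reasons.add("lab")
    if cond and on_art:
        reasons.add("condition_and_drug")

    sources = set()
    if cond:
        sources.add("condition")
    if on_art:
        sources.add("drug")
    if lab_pos:
        sources.add("lab")
    if survey_pos:
        sources.add("survey")

    if reasons:
        return CONFIRMED_PWH, frozenset(reasons), frozenset(sources)
    if cond or on_art:
        return PROBABLE_PWH, frozenset(), frozenset(sources)
    if (prep_pattern and profile.screening_status == "negative"
            and not cond and not survey_pos):
        return PREP_USER, frozenset(), frozenset({"drug", "lab"})
    return NONE, frozenset(), frozenset()


def enumerate_profiles():
    """The full finite profile space (suppression flag kept consistent)."""
    profiles = []
    for (cond, survey, screen, vl_det, vl_undet, pattern) in product(
        (False, True),
        ("positive", "negative", "missing"),
        ("positive", "negative", "missing"),
        (0, 1, 2),
        (0, 1, 2, 3),
        ("PREP_ONLY", "ART", "HCV_ONLY", "NONE"),
    ):
        profiles.append(EvidenceProfile(
            person_id="X",
            condition_pos=cond,
            survey_status=survey,
            screening_status=screen,
            vl_detectable_count=vl_det,
            vl_undetectable_count=vl_undet,
            drug_pattern=pattern,
            suppressed_on_art=(pattern == "ART" and vl_undet >= 2),
        ))
    return profiles
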