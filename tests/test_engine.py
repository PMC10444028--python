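import dataclasses

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hivpheno.engine import (CONFIRMED_PWH, NONE, PREP_USER, PROBABLE_PWH,
                             EvidenceProfile, assign_phenotype,
                             build_evidence_profile, classify_bundle,
                             hbv_flag_prep_users, run_cohort)

from _oracle import enumerate_profiles, oracle_assign
from conftest import d, make_bundle, make_persons


def profile(**kwargs) -> EvidenceProfile:
    return EvidenceProfile(person_id="X", **kwargs)


class TestAssignPhenotype:
    def test_survey_positive_alone_confirms(self):
        a = assign_phenotype(profile(survey_status="positive"))
        assert a.label == CONFIRMED_PWH
        assert a.confirm_basis == {"survey"}
        assert a.evidence_sources == {"survey"}

    def test_condition_alone_is_probable(self):
        a = assign_phenotype(profile(condition_pos=True))
        assert a.label == PROBABLE_PWH
        assert a.evidence_sources == {"condition"}

    def test_condition_plus_art_confirms(self):
        a = assign_phenotype(profile(condition_pos=True, drug_pattern="ART"))
        assert a.label == CONFIRMED_PWH
        assert a.confirm_basis == {"condition_and_drug"}
        assert a.evidence_sources == {"condition", "drug"}

    def test_art_alone_is_probable(self):
        a = assign_phenotype(profile(drug_pattern="ART"))
        assert a.label == PROBABLE_PWH
        assert a.evidence_sources == {"drug"}

    def test_prep_pattern_with_negative_screen_is_prep_user(self):
        a = assign_phenotype(profile(drug_pattern="PREP_ONLY",
                                     screening_status="negative"))
        assert a.label == PREP_USER
        assert a.evidence_sources == {"drug", "lab"}

    def test_prep_pattern_without_negative_screen_is_none(self):
        a = assign_phenotype(profile(drug_pattern="PREP_ONLY"))
        assert a.label == NONE

    def test_no_evidence_is_none(self):
        a = assign_phenotype(profile())
        assert a.label == NONE
        assert a.evidence_sources == frozenset()

    def test_prep_pattern_with_condition_is_probable(self):
        a = assign_phenotype(profile(drug_pattern="PREP_ONLY",
                                     screening_status="negative",
                                     condition_pos=True))
        assert a.label == PROBABLE_PWH

    def test_survey_positive_vetoes_prep(self):
        a = assign_phenotype(profile(drug_pattern="PREP_ONLY",
                                     screening_status="negative",
                                     survey_status="positive"))
        assert a.label == CONFIRMED_PWH

    def test_detectable_vl_confirms_via_lab(self):
        a = assign_phenotype(profile(vl_detectable_count=1))
        assert a.label == CONFIRMED_PWH
        assert a.confirm_basis == {"lab"}

    def test_suppressed_on_art_confirms(self):
        a = assign_phenotype(profile(drug_pattern="ART",
                                     vl_undetectable_count=2,
                                     suppressed_on_art=True))
        assert a.label == CONFIRMED_PWH
        assert a.confirm_basis == {"lab"}
        assert a.evidence_sources == {"drug", "lab"}

    def test_lone_undetectable_without_art_confers_nothing(self):
        a = assign_phenotype(profile(vl_undetectable_count=1))
        assert a.label == NONE

    def test_inconsistent_suppression_flag_rejected(self):
        with pytest.raises(ValueError, match="suppressed_on_art"):
            profile(suppressed_on_art=True)


class TestOracleEquivalence:
    def test_full_profile_space_agrees_with_rule_table(self):
        profiles = enumerate_profiles()
        assert len(profiles) == 864
        for p in profiles:
            got = assign_phenotype(p)
            label, basis, sources = oracle_assign(p)
            assert got.label == label, p
            assert got.confirm_basis == basis, p
            assert got.evidence_sources == sources, p

    def test_partition_is_total_and_single_label(self):
        labels = {assign_phenotype(p).label for p in enumerate_profiles()}
        assert labels == {CONFIRMED_PWH, PROBABLE_PWH, PREP_USER, NONE}

    def test_prep_user_incompatible_with_positive_hiv_evidence(self):
        for p in enumerate_profiles():
            a = assign_phenotype(p)
            if a.label == PREP_USER:
                assert not p.condition_pos
                assert p.survey_status != "positive"
                assert p.screening_status != "positive"
                assert p.vl_detectable_count == 0
                assert p.drug_pattern == "PREP_ONLY"


_CONFIRMING_UPGRADES = [
    {"survey_status": "positive"},
    {"screening_status": "positive"},
    {"vl_detectable_count": 1},
]


@settings(max_examples=200, derandomize=True)
@given(st.sampled_from(enumerate_profiles()), st.integers(0, 2))
def test_adding_confirming_evidence_never_demotes(base, which):
    upgraded = dataclasses.replace(base, **_CONFIRMING_UPGRADES[which])
    after = assign_phenotype(upgraded)
    assert after.label == CONFIRMED_PWH


class TestBuildEvidenceProfile:
    def test_condition_only_person(self, registry, config):
        bundle = make_bundle(
            conditions=[("A", "86406008", "", d("2020-01-01"))])
        p = build_evidence_profile("A", bundle.conditions, bundle.drugs,
                                   bundle.measurements, bundle.surveys,
                                   registry, config)
        assert p.condition_pos is True
        assert p.survey_status == "missing"
        assert p.screening_status == "missing"
        assert p.drug_pattern == "NONE"

    def test_survey_answer_detected(self, registry, config):
        bundle = make_bundle(surveys=[
            ("A", "1384391", "Infectious Disease Condition: HIV/AIDS",
             d("2020-01-01"))])
        p = build_evidence_profile("A", bundle.conditions, bundle.drugs,
                                   bundle.measurements, bundle.surveys,
                                   registry, config)
        assert p.survey_status == "positive"

    def test_other_question_ignored(self, registry, config):
        bundle = make_bundle(surveys=[
            ("A", "999", "Infectious Disease Condition: HIV/AIDS",
             d("2020-01-01"))])
        p = build_evidence_profile("A", bundle.conditions, bundle.drugs,
                                   bundle.measurements, bundle.surveys,
                                   registry, config)
        assert p.survey_status == "missing"

    def test_suppressed_on_art_detected(self, registry, config):
        bundle = make_bundle(
            drugs=[("A", ("biktarvy",), d("2020-01-01"))],
            measurements=[
                ("A", "20447-9", "", 50.0, "copies/mL", d("2020-02-01")),
                ("A", "20447-9", "", 40.0, "copies/mL", d("2020-08-01")),
            ])
        bundle.drugs["ingredients"] = [
            ("bictegravir", "emtricitabine", "tenofovir_alafenamide")]
        p = build_evidence_profile("A", bundle.conditions, bundle.drugs,
                                   bundle.measurements, bundle.surveys,
                                   registry, config)
        assert p.drug_pattern == "ART"
        assert p.vl_undetectable_count == 2
        assert p.suppressed_on_art is True

    def test_empty_slices_all_missing(self, registry, config):
        bundle = make_bundle()
        p = build_evidence_profile("A", bundle.conditions, bundle.drugs,
                                   bundle.measurements, bundle.surveys,
                                   registry, config)
        assert p == EvidenceProfile(person_id="A")


class TestRunCohort:
    def test_empty_bundle_yields_empty_table(self, registry, config):
        bundle = make_bundle(persons=make_persons())
        out = run_cohort(bundle, registry, config)
        assert len(out) == 0

    def test_everyone_gets_exactly_one_label(self, registry, config):
        from hivpheno import GroundTruthSpec, generate_cohort
        lb = generate_cohort(GroundTruthSpec(n_persons=300, seed=2))
        out = run_cohort(lb.bundle, registry, config)
        assert len(out) == len(lb.bundle.persons)
        assert out["person_id"].is_unique
        assert set(out["label"]) <= {CONFIRMED_PWH, PROBABLE_PWH, PREP_USER, NONE}

    def test_record_order_invariance(self, registry, config):
        from hivpheno import GroundTruthSpec, generate_cohort
        lb = generate_cohort(GroundTruthSpec(n_persons=200, seed=4))
        base = run_cohort(lb.bundle, registry, config)
        shuffled = lb.bundle.copy()
        for table in ("conditions", "drugs", "measurements", "surveys"):
            df = getattr(shuffled, table)
            setattr(shuffled, table,
                    df.sample(frac=1.0, random_state=99).reset_index(drop=True))
        shuffled.persons = shuffled.persons.sample(
            frac=1.0, random_state=99).reset_index(drop=True)
        again = run_cohort(shuffled, registry, config)
        pd.testing.assert_frame_equal(base, again)


class TestHbvFlag:
    def _assignments(self, registry, conditions):
        bundle = make_bundle(
            persons=make_persons("PREP1", "PREP2", "CONF1"),
            conditions=conditions,
            drugs=[("PREP1", ("emtricitabine", "tenofovir_disoproxil"), d("2020-01-01")),
                   ("PREP2", ("emtricitabine", "tenofovir_disoproxil"), d("2020-01-01")),
                   ("CONF1", ("dolutegravir",), d("2020-01-01"))],
            measurements=[
                ("PREP1", "75622-1", "Negative", float("nan"), "", d("2020-01-01")),
                ("PREP2", "75622-1", "Negative", float("nan"), "", d("2020-01-01")),
                ("CONF1", "75622-1", "Reactive", float("nan"), "", d("2020-01-01"))],
        )
        return classify_bundle(bundle, registry), bundle

    def test_prep_user_with_hbv_code_flagged_label_unchanged(self, registry):
        conditions = [("PREP1", "", "B181", d("2020-01-01")),
                      ("CONF1", "", "B180", d("2020-01-01"))]
        assignments, bundle = self._assignments(registry, conditions)
        by_id = {a.person_id: a for a in assignments}
        assert by_id["PREP1"].label == PREP_USER
        assert by_id["PREP1"].hbv_flag is True
        assert by_id["PREP2"].hbv_flag is False
        # check applies to PrEP users only
        assert by_id["CONF1"].label == CONFIRMED_PWH
        assert by_id["CONF1"].hbv_flag is False

    def test_flag_idempotent(self, registry):
        conditions = [("PREP1", "", "B191", d("2020-01-01"))]
        assignments, bundle = self._assignments(registry, conditions)
        again = hbv_flag_prep_users(assignments, bundle.conditions, registry)
        assert assignments == again
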