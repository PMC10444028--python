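import datetime
import math

import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from hivpheno import evidence as ev
from hivpheno.config import RunConfig

from conftest import d


class TestScreeningInterpretation:
    @pytest.mark.parametrize("value", [
        "Reactive", "reactive", "  Positive  ", "HIV-1 positive",
        "HIV-positive", "Detected", "Abnormal", "High",
    ])
    def test_positive_strings(self, value):
        assert ev.interpret_screening_value(value) == ev.POSITIVE

    @pytest.mark.parametrize("value", [
        "Not detected", "NONREACTIVE", "non-reactive", "Negative",
        "undetected", "normal",
    ])
    def test_negative_strings_never_positive(self, value):
        # superstring traps: "not detected" contains "detected"
        assert ev.interpret_screening_value(value) == ev.NEGATIVE

    @pytest.mark.parametrize("value", ["", None, "pending", "see note", "1.5"])
    def test_everything_else_unknown(self, value):
        assert ev.interpret_screening_value(value) == ev.UNKNOWN

    @given(st.sampled_from(sorted(RunConfig().negative_strings)),
           st.sampled_from(["", " ", "  "]), st.booleans())
    def test_negative_set_immune_to_case_and_padding(self, s, pad, upper):
        probe = pad + (s.upper() if upper else s) + pad
        assert ev.interpret_screening_value(probe) == ev.NEGATIVE


class TestScaleInference:
    @pytest.mark.parametrize("value,unit,scale,source", [
        (350.0, "copies/mL", ev.LINEAR, "unit_metadata"),
        (2.5, "log10 copies/mL", ev.LOG10, "unit_metadata"),
        (5.0, "ln copies/mL", ev.LN, "unit_metadata"),
        (2.5, "log copies/mL", ev.LOG10, "unit_metadata"),  # clinical log = log10
        (2.5, "", ev.LOG10, "heuristic"),   # 2.5 <= bound 8.0
        (350.0, "", ev.LINEAR, "heuristic"),
        (8.0, "", ev.LOG10, "heuristic"),   # bound is inclusive on the log side
    ])
    def test_unit_then_heuristic(self, value, unit, scale, source):
        got = ev.infer_vl_scale(value, unit)
        assert (got.scale, got.source) == (scale, source)

    def test_override_beats_unit(self):
        got = ev.infer_vl_scale(2.5, "copies/mL", override=ev.LOG10)
        assert (got.scale, got.source) == (ev.LOG10, "config_override")

    def test_negative_value_is_error(self):
        with pytest.raises(ValueError, match="negative"):
            ev.infer_vl_scale(-1.0, "copies/mL")


class TestViralLoadThreshold:
    @pytest.mark.parametrize("value,scale,expected", [
        (1000.0, ev.LINEAR, ev.DETECTABLE),
        (201.0, ev.LINEAR, ev.DETECTABLE),
        (200.0, ev.LINEAR, ev.UNDETECTABLE),   # strict ">" boundary
        (26.0, ev.LINEAR, ev.UNDETECTABLE),
        (2.5, ev.LOG10, ev.DETECTABLE),        # 10**2.5 ~ 316 > 200
        (math.log10(200.0), ev.LOG10, ev.UNDETECTABLE),
        (5.2, ev.LN, ev.UNDETECTABLE),         # e**5.2 ~ 181 < 200
        (5.4, ev.LN, ev.DETECTABLE),           # e**5.4 ~ 221 > 200
    ])
    def test_threshold_on_each_scale(self, value, scale, expected):
        assert ev.interpret_viral_load(value, scale) == expected
        # independent oracle: exponentiate back to copies, compare linearly
        if scale == ev.LINEAR:
            copies = value
        elif scale == ev.LOG10:
            copies = 10 ** value
        else:
            copies = math.exp(value)
        linear_verdict = ev.DETECTABLE if copies > 200 * (1 + 1e-12) \
            else ev.UNDETECTABLE
        assert ev.interpret_viral_load(value, scale) == linear_verdict

    def test_missing_value_unknown(self):
        assert ev.interpret_viral_load(None, ev.LINEAR) == ev.UNKNOWN
        assert ev.interpret_viral_load(float("nan"), ev.LINEAR) == ev.UNKNOWN

    @settings(max_examples=300, derandomize=True)
    @given(st.floats(min_value=1e-3, max_value=1e7,
                     allow_nan=False, allow_infinity=False))
    def test_scale_equivariance(self, v):
        # within an ulp of the threshold the float log is not order-preserving
        assume(abs(v - 200.0) > 1e-9)
        lin = ev.interpret_viral_load(v, ev.LINEAR)
        assert ev.interpret_viral_load(math.log10(v), ev.LOG10) == lin
        assert ev.interpret_viral_load(math.log(v), ev.LN) == lin


def drugs_frame(rows):
    df = pd.DataFrame(rows, columns=["person_id", "ingredients", "date"])
    df["drug_concept_id"] = ["+".join(i) for i in df["ingredients"]]
    return df


class TestDrugCombos:
    def test_same_day_records_union(self, registry):
        df = drugs_frame([
            ("A", ("emtricitabine",), d("2020-01-01")),
            ("A", ("tenofovir_disoproxil",), d("2020-01-01")),
        ])
        combos = ev.group_drug_records_into_combos(df, registry)
        assert len(combos) == 1
        assert combos[0].ingredients == {"emtricitabine", "tenofovir_disoproxil"}

    def test_different_days_stay_separate(self, registry):
        df = drugs_frame([
            ("A", ("emtricitabine",), d("2020-01-01")),
            ("A", ("tenofovir_disoproxil",), d("2020-01-02")),
        ])
        combos = ev.group_drug_records_into_combos(df, registry)
        assert [c.ingredients for c in combos] == [
            frozenset({"emtricitabine"}), frozenset({"tenofovir_disoproxil"})]

    def test_tolerance_window_merges_split_prescriptions(self, registry):
        df = drugs_frame([
            ("A", ("emtricitabine",), d("2020-01-01")),
            ("A", ("tenofovir_disoproxil",), d("2020-01-02")),
        ])
        combos = ev.group_drug_records_into_combos(df, registry, tolerance_days=1)
        assert len(combos) == 1
        assert len(combos[0].ingredients) == 2

    def test_fixed_dose_product_yields_two_ingredient_combo(self, registry):
        df = drugs_frame([
            ("A", ("emtricitabine", "tenofovir_disoproxil"), d("2020-01-01")),
        ])
        combos = ev.group_drug_records_into_combos(df, registry)
        assert combos[0].ingredients == {"emtricitabine", "tenofovir_disoproxil"}

    def test_unknown_ingredient_tagged_other(self, registry):
        df = drugs_frame([("A", ("metformin",), d("2020-01-01"))])
        combos = ev.group_drug_records_into_combos(df, registry)
        assert combos[0].roles["metformin"] == {ev.OTHER_DRUG}


def combo(ingredients, registry, date="2020-01-01", pid="A"):
    df = drugs_frame([(pid, tuple(ingredients), d(date))])
    return ev.group_drug_records_into_combos(df, registry)[0]


class TestDrugPattern:
    def test_ftc_tdf_only_is_prep(self, registry):
        combos = [combo(("emtricitabine", "tenofovir_disoproxil"), registry),
                  combo(("emtricitabine", "tenofovir_disoproxil"), registry,
                        "2020-03-01")]
        assert ev.classify_drug_pattern(combos) == ev.PREP_ONLY

    def test_ftc_taf_only_is_prep(self, registry):
        combos = [combo(("emtricitabine", "tenofovir_alafenamide"), registry)]
        assert ev.classify_drug_pattern(combos) == ev.PREP_ONLY

    def test_single_drug_is_not_prep(self, registry):
        combos = [combo(("emtricitabine",), registry)]
        assert ev.classify_drug_pattern(combos) == ev.ART

    def test_three_ingredients_are_not_prep(self, registry):
        combos = [combo(("emtricitabine", "tenofovir_disoproxil",
                         "dolutegravir"), registry)]
        assert ev.classify_drug_pattern(combos) == ev.ART

    def test_extra_combination_disqualifies_prep(self, registry):
        combos = [combo(("emtricitabine", "tenofovir_disoproxil"), registry),
                  combo(("darunavir",), registry, "2020-05-01")]
        assert ev.classify_drug_pattern(combos) == ev.ART

    def test_hcv_only_regimen_excluded_from_art(self, registry):
        combos = [combo(("sofosbuvir",), registry),
                  combo(("ledipasvir", "sofosbuvir"), registry, "2020-02-01")]
        assert ev.classify_drug_pattern(combos) == ev.HCV_ONLY

    def test_unrecognized_drugs_alone_give_no_pattern(self, registry):
        combos = [combo(("metformin",), registry)]
        assert ev.classify_drug_pattern(combos) == ev.NO_PATTERN
        assert ev.classify_drug_pattern([]) == ev.NO_PATTERN

    def test_order_invariance(self, registry):
        combos = [combo(("emtricitabine", "tenofovir_disoproxil"), registry),
                  combo(("darunavir",), registry, "2020-05-01"),
                  combo(("sofosbuvir",), registry, "2020-06-01")]
        base = ev.classify_drug_pattern(combos)
        assert ev.classify_drug_pattern(list(reversed(combos))) == base
        assert ev.classify_drug_pattern(combos[1:] + combos[:1]) == base

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.sampled_from([
        ("emtricitabine", "tenofovir_disoproxil"),
        ("emtricitabine", "tenofovir_alafenamide"),
        ("dolutegravir",), ("sofosbuvir",), ("metformin",),
        ("emtricitabine", "tenofovir_disoproxil", "dolutegravir"),
    ]), min_size=0, max_size=5))
    def test_prep_and_art_mutually_exclusive(self, registry, ingredient_sets):
        combos = [combo(ings, registry, f"2020-0{i % 9 + 1}-15")
                  for i, ings in enumerate(ingredient_sets)]
        pattern = ev.classify_drug_pattern(combos)
        assert pattern in (ev.PREP_ONLY, ev.ART, ev.HCV_ONLY, ev.NO_PATTERN)
        if pattern == ev.PREP_ONLY:
            assert all(len(c.ingredients) == 2 for c in combos)


def vl(verdict, date):
    return ev.LabInterpretation("viral_load", verdict, d(date), "")


class TestSuppression:
    def test_art_with_two_undetectable_dates(self):
        history = [vl(ev.UNDETECTABLE, "2020-01-01"),
                   vl(ev.UNDETECTABLE, "2020-06-01")]
        assert ev.detect_suppressed_on_art(history, ev.ART) is True

    def test_one_undetectable_is_not_enough(self):
        assert ev.detect_suppressed_on_art(
            [vl(ev.UNDETECTABLE, "2020-01-01")], ev.ART) is False

    def test_requires_art_pattern(self):
        history = [vl(ev.UNDETECTABLE, "2020-01-01"),
                   vl(ev.UNDETECTABLE, "2020-06-01")]
        assert ev.detect_suppressed_on_art(history, ev.PREP_ONLY) is False

    def test_duplicate_rows_on_one_date_do_not_inflate(self):
        history = [vl(ev.UNDETECTABLE, "2020-01-01"),
                   vl(ev.UNDETECTABLE, "2020-01-01")]
        assert ev.detect_suppressed_on_art(history, ev.ART) is False


class TestInterpretMeasurements:
    def test_routes_by_concept_role(self, registry, config):
        df = pd.DataFrame([
            ("A", "75622-1", "Reactive", float("nan"), "", d("2020-01-01")),
            ("A", "20447-9", "", 350.0, "copies/mL", d("2020-02-01")),
            ("A", "20447-9", "Not detected", float("nan"), "", d("2020-03-01")),
            ("A", "9999-9", "Reactive", float("nan"), "", d("2020-04-01")),
        ], columns=["person_id", "concept_id", "value_string", "value_number",
                    "unit_string", "date"])
        interps = ev.interpret_measurements(df, registry, config)
        kinds = [(i.kind, i.verdict) for i in interps]
        assert ("screening", ev.POSITIVE) in kinds
        assert ("viral_load", ev.DETECTABLE) in kinds
        assert ("viral_load", ev.UNDETECTABLE) in kinds  # categorical VL row
        assert len(interps) == 3  # unrelated concept skipped
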