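import datetime

import pandas as pd
import pytest

from hivpheno import RunConfig, demo_registry
from hivpheno.omop_io import OmopBundle


@pytest.fixture(scope="session")
def registry():
    return demo_registry()


@pytest.fixture()
def config():
    return RunConfig()


def d(iso: str) -> datetime.date:
    return datetime.date.fromisoformat(iso)


def make_persons(*person_ids: str, birth_year: int = 1980) -> pd.DataFrame:
    return pd.DataFrame({
        "person_id": list(person_ids),
        "birth_year": [birth_year] * len(person_ids),
    })


def make_bundle(
    persons=None,
    conditions=None,
    drugs=None,
    measurements=None,
    surveys=None,
    alias_map=None,
) -> OmopBundle:
    """In-memory bundle builder for hand-written fixtures.

    ``drugs`` rows are (person_id, ingredients-tuple, date); conditions are
    (person_id, concept_id, source_code, date); measurements are
    (person_id, concept_id, value_string, value_number, unit_string, date);
    surveys are (person_id, question, answer, date).
    """
    persons = persons if persons is not None else make_persons("A")
    cond = pd.DataFrame(
        conditions or [], columns=["person_id", "concept_id", "source_code", "date"])
    drug_rows = [
        {"person_id": p, "drug_concept_id": "+".join(ing), "ingredients": tuple(ing),
         "date": dt}
        for p, ing, dt in (drugs or [])
    ]
    drg = pd.DataFrame(
        drug_rows, columns=["person_id", "drug_concept_id", "ingredients", "date"])
    meas = pd.DataFrame(
        measurements or [],
        columns=["person_id", "concept_id", "value_string", "value_number",
                 "unit_string", "date"])
    if len(meas):
        meas["value_number"] = pd.to_numeric(meas["value_number"])
    srv = pd.DataFrame(
        surveys or [],
        columns=["person_id", "question_concept_id", "answer_value", "date"])
    return OmopBundle(
        persons=persons, conditions=cond, drugs=drg, measurements=meas,
        surveys=srv, alias_map=dict(alias_map or {}),
    )


FORBIDDEN_BAND = range(1, 20)

# JSON keys whose values are person counts subject to disclosure control
# (level names, test statistics and provenance metadata are not counts).
_NON_COUNT_JSON_KEYS = {"characteristic", "level", "chi2", "dof", "p_value",
                        "note", "mask_threshold", "metadata", "comparisons"}


def _walk_json_counts(node, path=""):
    if isinstance(node, dict):
        for k, v in node.items():
            if k in _NON_COUNT_JSON_KEYS:
                continue
            yield from _walk_json_counts(v, f"{path}/{k}")
    elif isinstance(node, list):
        for i, v in enumerate(node):
            yield from _walk_json_counts(v, f"{path}[{i}]")
    elif isinstance(node, bool):
        return
    elif isinstance(node, int):
        yield path, node


def scan_rendered_files(*paths) -> list[str]:
    """Every rendered count cell in [1, 19] across report files.

    Count cells are the `count` column of venn.tsv, the `*_n` columns of
    demographics.tsv, and every integer leaf of report.json outside level
    names, test statistics and metadata.
    """
    import json

    import pandas as pd

    hits = []
    for path in paths:
        if path.suffix == ".json":
            data = json.loads(path.read_text(encoding="utf-8"))
            for where, value in _walk_json_counts(data):
                if value in FORBIDDEN_BAND:
                    hits.append(f"{path.name}{where}: {value}")
        elif path.suffix == ".tsv":
            df = pd.read_csv(path, sep="\t", dtype=str)
            count_cols = [c for c in df.columns
                          if c == "count" or c.endswith("_n")]
            for col in count_cols:
                for value in df[col].fillna(""):
                    if value.isdigit() and int(value) in FORBIDDEN_BAND:
                        hits.append(f"{path.name}:{col}: {value}")
    return hits
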