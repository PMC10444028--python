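"""Read, validate, date-filter and deduplicate OMOP CDM-shaped tables.

Five comma-separated UTF-8 files with a header row make up a bundle:
``person.csv``, ``condition_occurrence.csv``, ``drug_exposure.csv``,
``measurement.csv``, ``observation.csv`` (survey rows). Dates are ISO-8601.
An optional ``aliases.csv`` (``alias_id,canonical_id``) carries duplicate
person-id mappings discovered upstream.

In memory everything is a pandas DataFrame; the bundle is a thin dataclass
around the five frames plus provenance (row counts, rejected rows).
"""
from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .concept_sets import normalize_code
from .config import ConfigError, RunConfig, TABLE_FILES

PERSON_DEMOGRAPHIC_COLUMNS = (
    "gender", "race", "ethnicity", "marital_status", "sexual_orientation",
    "education", "income_band", "insurance", "disability", "chronic_conditions",
)


class OmopIOError(ValueError):
    """Fatal problem with an OMOP bundle (missing table, orphan record, ...)."""


@dataclass
class OmopBundle:
    """The five raw record collections keyed by person_id.

    Child-table person_ids must exist in ``persons`` (enforced at read time;
    strict mode makes violations fatal). ``alias_map`` holds duplicate-id
    mappings not yet applied; :func:`consolidate_person_ids` resolves them.
    """

    persons: pd.DataFrame
    conditions: pd.DataFrame
    drugs: pd.DataFrame
    measurements: pd.DataFrame
    surveys: pd.DataFrame
    alias_map: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "persons": self.persons,
            "conditions": self.conditions,
            "drugs": self.drugs,
            "measurements": self.measurements,
            "surveys": self.surveys,
        }

    def child_tables(self) -> dict[str, pd.DataFrame]:
        t = self.tables()
        t.pop("persons")
        return t

    def counts(self) -> dict[str, int]:
        return {name: len(df) for name, df in self.tables().items()}

    def copy(self) -> "OmopBundle":
        return OmopBundle(
            persons=self.persons.copy(),
            conditions=self.conditions.copy(),
            drugs=self.drugs.copy(),
            measurements=self.measurements.copy(),
            surveys=self.surveys.copy(),
            alias_map=dict(self.alias_map),
            provenance=dict(self.provenance),
        )


def _read_table(path: Path, table: str, colmap: Mapping[str, str]) -> pd.DataFrame:
    fp = path / TABLE_FILES[table]
    if not fp.exists():
        raise OmopIOError(f"missing table file: {fp}")
    df = pd.read_csv(fp, dtype=str, keep_default_na=False)
    missing = [csv_col for csv_col in colmap.values() if csv_col not in df.columns]
    if missing:
        raise OmopIOError(f"{fp}: missing columns {missing}")
    rename = {csv_col: canon for canon, csv_col in colmap.items()}
    return df.rename(columns=rename)


def _parse_dates(df: pd.DataFrame, rejections: list[str], table: str) -> pd.DataFrame:
    parsed = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    bad = parsed.isna()
    for idx in df.index[bad]:
        rejections.append(f"{table}: row {idx}: unparseable date {df.at[idx, 'date']!r}")
    df = df.loc[~bad].copy()
    df["date"] = parsed.loc[~bad].dt.date
    return df


def resolve_ingredients(drug_concept_id: str,
                        ingredient_map: Mapping[str, tuple[str, ...]]) -> tuple[str, ...]:
    """Resolve a drug concept to ingredient-level codes.

    Combination products map to >=2 ingredients via the explicit mapping;
    unmapped concepts are treated as their own single ingredient.
    """
    key = normalize_code(drug_concept_id)
    mapped = {normalize_code(k): v for k, v in ingredient_map.items()}.get(key)
    if mapped:
        return tuple(sorted(normalize_code(i) for i in mapped))
    return (key,)


def read_omop_dir(path: str | Path, config: RunConfig | None = None) -> OmopBundle:
    """Read a directory of OMOP-shaped CSVs into a typed bundle.

    Malformed rows (unparseable dates, blank person ids) are rejected with a
    logged reason; counts land in ``bundle.provenance``. Under-18 persons at
    the anchor date are outside the adult cohort and are dropped together
    with their records (counted, not fatal). Orphan child records are fatal
    in strict mode, dropped-and-counted otherwise.
    """
    config = config or RunConfig()
    path = Path(path)
    rejections: list[str] = []

    frames: dict[str, pd.DataFrame] = {}
    for table in TABLE_FILES:
        df = _read_table(path, table, config.column_map(table))
        if table != "persons":
            df = _parse_dates(df, rejections, table)
        blank = df["person_id"].str.strip() == ""
        for idx in df.index[blank]:
            rejections.append(f"{table}: row {idx}: blank person_id")
        frames[table] = df.loc[~blank].reset_index(drop=True)

    persons = frames["persons"]
    if persons.empty:
        raise OmopIOError(f"{path}: persons table is empty")
    birth_year = pd.to_numeric(persons["birth_year"], errors="coerce")
    bad_by = birth_year.isna()
    for idx in persons.index[bad_by]:
        rejections.append(
            f"persons: row {idx}: unparseable birth_year {persons.at[idx, 'birth_year']!r}"
        )
    persons = persons.loc[~bad_by].copy()
    persons["birth_year"] = birth_year.loc[~bad_by].astype(int)

    # Adult cohort: age at the anchor date must be >= 18.
    age = config.anchor_date.year - persons["birth_year"]
    minors = persons.loc[age < 18, "person_id"]
    n_minors = len(minors)
    persons = persons.loc[age >= 18].reset_index(drop=True)
    if persons.empty:
        raise OmopIOError(f"{path}: no adult persons remain")
    dup = persons["person_id"].duplicated()
    if dup.any():
        raise OmopIOError(
            f"duplicate person rows for ids {sorted(persons.loc[dup, 'person_id'])}; "
            "use aliases.csv for duplicate-id consolidation"
        )

    minor_ids = set(minors)
    known = set(persons["person_id"])
    n_orphans = 0
    for table in ("conditions", "drugs", "measurements", "surveys"):
        df = frames[table]
        is_minor = df["person_id"].isin(minor_ids)
        df = df.loc[~is_minor]
        orphan = ~df["person_id"].isin(known)
        if orphan.any():
            orphan_ids = sorted(df.loc[orphan, "person_id"].unique())
            if config.strict:
                raise OmopIOError(
                    f"{table}: records reference person_ids absent from persons "
                    f"table (orphans): {orphan_ids[:10]}"
                )
            n_orphans += int(orphan.sum())
            for pid in orphan_ids:
                rejections.append(f"{table}: orphan person_id {pid} dropped")
            df = df.loc[~orphan]
        frames[table] = df.reset_index(drop=True)

    drugs = frames["drugs"]
    drugs["ingredients"] = [
        resolve_ingredients(c, config.ingredient_map) for c in drugs["drug_concept_id"]
    ]
    frames["drugs"] = drugs

    meas = frames["measurements"]
    meas["value_number"] = pd.to_numeric(
        meas["value_number"].replace("", np.nan), errors="coerce"
    )
    frames["measurements"] = meas

    alias_map: dict[str, str] = {}
    alias_fp = path / "aliases.csv"
    if alias_fp.exists():
        adf = pd.read_csv(alias_fp, dtype=str)
        alias_map = dict(zip(adf["alias_id"], adf["canonical_id"]))

    bundle = OmopBundle(
        persons=persons,
        conditions=frames["conditions"],
        drugs=frames["drugs"],
        measurements=frames["measurements"],
        surveys=frames["surveys"],
        alias_map=alias_map,
        provenance={
            "source": str(path),
            "row_counts": {},
            "rejected_rows": len(rejections),
            "rejections": rejections,
            "minors_dropped": n_minors,
            "orphans_dropped": n_orphans,
        },
    )
    bundle.provenance["row_counts"] = bundle.counts()
    return bundle


def write_bundle(bundle: OmopBundle, path: str | Path) -> None:
    """Write a bundle back to the five CSVs (plus aliases.csv if any).

    Inverse of :func:`read_omop_dir` up to ingredient resolution (the
    ``ingredients`` column is derived, not written).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for table, df in bundle.tables().items():
        out = df.copy()
        if "ingredients" in out.columns:
            out = out.drop(columns=["ingredients"])
        out.to_csv(path / TABLE_FILES[table], index=False)
    if bundle.alias_map:
        pd.DataFrame(
            {"alias_id": list(bundle.alias_map), "canonical_id": list(bundle.alias_map.values())}
        ).to_csv(path / "aliases.csv", index=False)


def _window_mask(dates: pd.Series, window: tuple[datetime.date, datetime.date]) -> pd.Series:
    start, end = window
    return dates.map(lambda d: start <= d <= end)


def filter_by_date_window(
    bundle: OmopBundle,
    ehr_window: tuple[datetime.date, datetime.date] | None = None,
    survey_window: tuple[datetime.date, datetime.date] | None = None,
    config: RunConfig | None = None,
) -> OmopBundle:
    """Restrict EHR tables and surveys to their closed date windows.

    Conditions/drugs/measurements are kept iff ``start <= date <= end`` of the
    EHR window; surveys use the survey window. Persons are untouched.
    Idempotent by construction.
    """
    config = config or RunConfig()
    ehr_window = ehr_window or config.ehr_window
    survey_window = survey_window or config.survey_window
    for name, (start, end) in (("ehr_window", ehr_window), ("survey_window", survey_window)):
        if start > end:
            raise ConfigError(f"{name} is inverted: {start} > {end}")

    out = bundle.copy()
    removed = {}
    for table in ("conditions", "drugs", "measurements"):
        df = getattr(out, table)
        keep = _window_mask(df["date"], ehr_window) if len(df) else df.index == df.index
        removed[table] = int(len(df) - keep.sum()) if len(df) else 0
        setattr(out, table, df.loc[keep].reset_index(drop=True))
    if len(out.surveys):
        keep = _window_mask(out.surveys["date"], survey_window)
        removed["surveys"] = int(len(out.surveys) - keep.sum())
        out.surveys = out.surveys.loc[keep].reset_index(drop=True)
    else:
        removed["surveys"] = 0
    out.provenance = dict(out.provenance)
    out.provenance["window_removed"] = removed
    return out


def _resolve_alias(pid: str, alias_map: Mapping[str, str]) -> str:
    """Follow an alias chain to its canonical id; cycles are fatal."""
    seen = [pid]
    cur = pid
    while cur in alias_map:
        cur = alias_map[cur]
        if cur in seen:
            raise OmopIOError(f"alias cycle detected: {' -> '.join(seen + [cur])}")
        seen.append(cur)
    return cur


def consolidate_person_ids(
    bundle: OmopBundle, alias_map: Mapping[str, str] | None = None
) -> OmopBundle:
    """Merge duplicate person ids onto canonical ids.

    Every record's person_id is rewritten to the transitive closure of the
    alias map; the persons table keeps one row per canonical id (the
    canonical id's own demographics — a canonical id with no person row is
    fatal). The record multiset is otherwise preserved.
    """
    alias_map = dict(alias_map) if alias_map is not None else dict(bundle.alias_map)
    out = bundle.copy()
    out.alias_map = {}
    if not alias_map:
        return out

    resolved = {pid: _resolve_alias(pid, alias_map) for pid in alias_map}
    present = set(out.persons["person_id"])
    for alias, canonical in resolved.items():
        if canonical not in present:
            raise OmopIOError(
                f"canonical id {canonical} (alias {alias}) has no demographics row"
            )

    def remap(series: pd.Series) -> pd.Series:
        return series.map(lambda pid: resolved.get(pid, pid))

    for table in ("conditions", "drugs", "measurements", "surveys"):
        df = getattr(out, table)
        if len(df):
            df = df.copy()
            df["person_id"] = remap(df["person_id"])
        setattr(out, table, df)

    aliases = {a for a in resolved if resolved[a] != a}
    persons = out.persons.loc[~out.persons["person_id"].isin(aliases)]
    out.persons = persons.reset_index(drop=True)
    out.provenance = dict(out.provenance)
    out.provenance["aliases_consolidated"] = len(aliases)
    return out
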