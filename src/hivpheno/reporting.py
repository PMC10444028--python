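"""Cohort summary outputs: Venn evidence-source decomposition, demographic
table with small-cell suppression, and confirmed-vs-probable comparisons.

Small-cell suppression is a render-layer concern only: internal counts stay
exact (sums reconcile, percentages are computed before masking), but any
rendered count in [1, threshold-1] is replaced by the mask token. Zero is not
a disclosure risk and renders as 0.
"""
from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .config import RunConfig
from .engine import (CONFIRMED_PWH, NONE, PREP_USER, PROBABLE_PWH,
                     PhenotypeAssignment)

MASK_TOKEN = "<20"
PWH_LABELS = (CONFIRMED_PWH, PROBABLE_PWH)

AGE_BANDS = ((18, 29), (30, 39), (40, 49), (50, 64), (65, 200))

#: Person-table columns summarized in the demographic table, in render order.
DEMOGRAPHIC_CHARACTERISTICS = (
    "gender", "age_group", "race", "ethnicity", "marital_status",
    "sexual_orientation", "education", "income_band", "insurance",
    "disability", "chronic_conditions",
)


class ReportError(ValueError):
    """Internal inconsistency while building a report."""


@dataclass(frozen=True)
class MaskedCount:
    """A count that renders masked when in the disclosure-risk band."""

    n: int
    threshold: int = 20

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ReportError(f"negative count: {self.n}")

    @property
    def masked(self) -> bool:
        return 1 <= self.n < self.threshold

    def render(self) -> str:
        return f"<{self.threshold}" if self.masked else str(self.n)


def mask_small_cells(count: int, threshold: int = 20) -> MaskedCount:
    """0 stays 0; 1..threshold-1 masks; >=threshold passes through."""
    return MaskedCount(int(count), threshold)


def category_share(count: int, total: int) -> float:
    """Percentage ``100*count/total`` rounded half-up to one decimal.

    Half-up (not banker's) rounding so 0.05-boundary shares round the way
    conventional epidemiological tables print them.
    """
    if total <= 0:
        raise ReportError("category_share undefined for total <= 0")
    if not 0 <= count <= total:
        raise ReportError(f"count {count} outside [0, {total}]")
    share = Decimal(count) * Decimal(100) / Decimal(total)
    return float(share.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def subset_key(sources: Iterable[str]) -> str:
    return "+".join(sorted(sources))


def venn_decomposition(
    assignments: Sequence[PhenotypeAssignment],
    labels: Sequence[str] = PWH_LABELS,
) -> dict[frozenset[str], int]:
    """Partition labeled persons by their exact evidence-source subset.

    Counts are pairwise disjoint and sum to the number of persons carrying
    the requested labels. A PWH with an empty source set indicates an engine
    bug and is fatal.
    """
    out: dict[frozenset[str], int] = {}
    for a in assignments:
        if a.label not in labels:
            continue
        if a.label in PWH_LABELS and not a.evidence_sources:
            raise ReportError(
                f"person {a.person_id} labeled {a.label} with no evidence sources"
            )
        out[a.evidence_sources] = out.get(a.evidence_sources, 0) + 1
    return out


def age_group(birth_year: int, anchor: datetime.date) -> str:
    age = anchor.year - int(birth_year)
    for lo, hi in AGE_BANDS:
        if lo <= age <= hi:
            return f"{lo}-{hi}" if hi < 200 else f"{lo}+"
    return "unknown"


def demographic_table(
    assignments: Sequence[PhenotypeAssignment],
    persons: pd.DataFrame,
    config: RunConfig | None = None,
    characteristics: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Level counts and within-tier percentages for each characteristic.

    Columns: characteristic, level, then ``{tier}_n`` / ``{tier}_pct`` for
    tiers total (confirmed+probable), confirmed, probable, prep. Unknown /
    skip values are preserved as their own levels. Percentages are computed
    on unmasked counts; masking happens only at render time.
    """
    config = config or RunConfig()
    characteristics = tuple(characteristics or DEMOGRAPHIC_CHARACTERISTICS)

    label_of = {a.person_id: a.label for a in assignments}
    missing = [pid for pid in label_of if pid not in set(persons["person_id"])]
    if missing:
        raise ReportError(f"assigned persons missing from persons table: {missing[:5]}")

    df = persons.copy()
    df["age_group"] = [
        age_group(by, config.anchor_date) for by in df["birth_year"]
    ]
    df["label"] = df["person_id"].map(label_of).fillna(NONE)
    for col in characteristics:
        if col not in df.columns:
            df[col] = "unknown"
        df[col] = df[col].replace("", "unknown").fillna("unknown")

    tiers = {
        "total": df["label"].isin(PWH_LABELS),
        "confirmed": df["label"] == CONFIRMED_PWH,
        "probable": df["label"] == PROBABLE_PWH,
        "prep": df["label"] == PREP_USER,
    }
    tier_totals = {t: int(m.sum()) for t, m in tiers.items()}

    rows = []
    for char in characteristics:
        levels = sorted(df.loc[df["label"] != NONE, char].unique())
        for level in levels:
            row: dict[str, object] = {"characteristic": char, "level": str(level)}
            for tier, mask in tiers.items():
                n = int(((df[char] == level) & mask).sum())
                row[f"{tier}_n"] = n
                row[f"{tier}_pct"] = (
                    category_share(n, tier_totals[tier]) if tier_totals[tier] else None
                )
            rows.append(row)
    return pd.DataFrame(rows)


def compare_tiers(demographics: pd.DataFrame) -> pd.DataFrame:
    """Chi-square test of independence, confirmed vs probable, per
    characteristic (no continuity correction; unknown levels included).

    Levels with zero combined count are dropped; characteristics left with a
    single level are skipped with a note.
    """
    results = []
    for char, group in demographics.groupby("characteristic", sort=False):
        table = group[["confirmed_n", "probable_n"]].to_numpy()
        keep = table.sum(axis=1) > 0
        dropped = int((~keep).sum())
        table = table[keep]
        if len(table) < 2 or table.sum(axis=0).min() == 0:
            results.append({
                "characteristic": char, "chi2": None, "dof": None,
                "p_value": None, "note": "skipped: degenerate table",
            })
            continue
        res = stats.chi2_contingency(table, correction=False)
        results.append({
            "characteristic": char,
            "chi2": float(res.statistic),
            "dof": int(res.dof),
            "p_value": float(res.pvalue),
            "note": f"{dropped} zero-margin level(s) dropped" if dropped else "",
        })
    return pd.DataFrame(results)


@dataclass
class CohortReport:
    """Everything the run summary serializes: tier counts, two Venn
    decompositions (all PWH; confirmed only), demographics, comparisons."""

    tier_counts: dict[str, int]
    venn_total: dict[frozenset[str], int]
    venn_confirmed: dict[frozenset[str], int]
    demographics: pd.DataFrame
    comparisons: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def build_report(
    assignments: Sequence[PhenotypeAssignment],
    persons: pd.DataFrame,
    config: RunConfig | None = None,
    metadata: Mapping | None = None,
) -> CohortReport:
    config = config or RunConfig()
    tier_counts = {label: 0 for label in (CONFIRMED_PWH, PROBABLE_PWH, PREP_USER, NONE)}
    for a in assignments:
        tier_counts[a.label] += 1
    tier_counts["TOTAL_PWH"] = tier_counts[CONFIRMED_PWH] + tier_counts[PROBABLE_PWH]
    demographics = demographic_table(assignments, persons, config)
    return CohortReport(
        tier_counts=tier_counts,
        venn_total=venn_decomposition(assignments, PWH_LABELS),
        venn_confirmed=venn_decomposition(assignments, (CONFIRMED_PWH,)),
        demographics=demographics,
        comparisons=compare_tiers(demographics),
        metadata=dict(metadata or {}),
    )


def _render_count(n: int, threshold: int) -> object:
    mc = mask_small_cells(n, threshold)
    return mc.render() if mc.masked else n


def report_to_json_dict(report: CohortReport, threshold: int = 20) -> dict:
    """Masked, JSON-serializable view of a report."""
    def venn(d: dict[frozenset[str], int]) -> dict[str, object]:
        return {subset_key(k): _render_count(v, threshold) for k, v in sorted(
            d.items(), key=lambda kv: subset_key(kv[0]))}

    demo = []
    for row in report.demographics.to_dict("records"):
        out = {"characteristic": row["characteristic"], "level": row["level"]}
        for tier in ("total", "confirmed", "probable", "prep"):
            mc = mask_small_cells(int(row[f"{tier}_n"]), threshold)
            out[f"{tier}_n"] = mc.render() if mc.masked else mc.n
            # a masked count's percentage would re-identify it; suppress both
            out[f"{tier}_pct"] = mc.render() if mc.masked else row[f"{tier}_pct"]
        demo.append(out)

    return {
        "tier_counts": {
            k: _render_count(v, threshold) for k, v in report.tier_counts.items()
        },
        "venn": {"total": venn(report.venn_total),
                 "confirmed": venn(report.venn_confirmed)},
        "demographics": demo,
        "comparisons": report.comparisons.to_dict("records"),
        "mask_threshold": threshold,
        "metadata": report.metadata,
    }


def write_report(report: CohortReport, outdir: str | Path, threshold: int = 20) -> list[Path]:
    """Write report.json plus human-readable TSVs; all rendered counts masked."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    jpath = outdir / "report.json"
    with open(jpath, "w", encoding="utf-8") as fh:
        json.dump(report_to_json_dict(report, threshold), fh, indent=2)
    written.append(jpath)

    vrows = []
    for which, venn in (("total", report.venn_total), ("confirmed", report.venn_confirmed)):
        for subset, n in sorted(venn.items(), key=lambda kv: subset_key(kv[0])):
            vrows.append({
                "cohort": which, "sources": subset_key(subset),
                "count": str(_render_count(n, threshold)),
            })
    vpath = outdir / "venn.tsv"
    pd.DataFrame(vrows, columns=["cohort", "sources", "count"]).to_csv(
        vpath, sep="\t", index=False
    )
    written.append(vpath)

    drows = []
    for row in report.demographics.to_dict("records"):
        out = {"characteristic": row["characteristic"], "level": row["level"]}
        for tier in ("total", "confirmed", "probable", "prep"):
            mc = mask_small_cells(int(row[f"{tier}_n"]), threshold)
            if mc.masked:
                out[f"{tier}_n"], out[f"{tier}_pct"] = mc.render(), mc.render()
            else:
                pct = row[f"{tier}_pct"]
                out[f"{tier}_n"] = str(mc.n)
                out[f"{tier}_pct"] = "" if pct is None else f"{pct:.1f}"
        drows.append(out)
    dpath = outdir / "demographics.tsv"
    pd.DataFrame(drows).to_csv(dpath, sep="\t", index=False)
    written.append(dpath)
    return written
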