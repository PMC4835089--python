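"""Pairwise genotype concordance in five categories.

Every compared site falls into exactly one category:

* CONCORDANT — identical genotypes, the calls being either both present
  or both missing;
* DISCORDANT_HET_HOMO — one call homozygous (reference or first
  alternate), the other heterozygous (reference / first alternate);
* DISCORDANT_HOMO_HOMO — one homozygous reference, the other homozygous
  for the first alternate;
* DISCORDANT_OTHER — differing genotypes involving alternate alleles
  beyond the first;
* MISSING — a no-call in exactly one of the two samples.

The concordance rate for a variant group is 100 x concordant / total
compared sites in that group.  Because the five categories are exhaustive,
this is the only denominator under which they form a partition; the
both-missing sites it places in the numerator are reported separately so
alternative denominators can be recomputed.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import pandas as pd

from dbsconcord.callset_model import CallSet, GenotypeCall, SampleMeta, ValidationError
from dbsconcord.classify_filter import REPORTING_GROUPS, reporting_group

__all__ = [
    "ConcordanceCategory",
    "ConcordanceTable",
    "classify_genotype_pair",
    "pairwise_concordance",
    "concordance_rate",
    "average_replicate_rates",
    "pilot_concordance_report",
    "category_long_table",
    "PAIRING_PLANS",
]


class ConcordanceCategory(str, Enum):
    CONCORDANT = "concordant"
    DISCORDANT_HET_HOMO = "discordant_het_homo"
    DISCORDANT_HOMO_HOMO = "discordant_homo_homo"
    DISCORDANT_OTHER = "discordant_other"
    MISSING = "missing"


#: Sample-type pairings compared in each pilot design.  DBS-vs-WB pairings
#: probe amplified dried-blood-spot DNA against the whole-blood standard;
#: WB_ref vs WB_ref_replica sets the technical-reproducibility baseline,
#: and WB_ref vs WB_WGA_ref isolates the amplification reaction itself.
PAIRING_PLANS: dict[int, list[tuple[str, str]]] = {
    1: [("DBS_2x3.2", "WB_ref")],
    2: [("DBS_2x3.2", "WB_ref"), ("WB_ref", "WB_ref_replica")],
    3: [
        ("DBS_2x3.2", "WB_ref"),
        ("DBS_2x1.6", "WB_ref"),
        ("DBS_2x3.2", "DBS_2x1.6"),
        ("WB_ref", "WB_WGA_ref"),
    ],
}


@dataclass(slots=True)
class ConcordanceTable:
    """Category counts per reporting group for one ordered sample pair."""

    sample_a: str
    sample_b: str
    counts: dict[str, Counter] = field(default_factory=dict)
    n_sites: dict[str, int] = field(default_factory=dict)
    filter_state: str = "RAW"

    def rate(self, group: str) -> float:
        return concordance_rate(self, group)


def classify_genotype_pair(a: GenotypeCall, b: GenotypeCall) -> ConcordanceCategory:
    """Place one genotype pair into its concordance category.

    Comparison is on unordered allele multisets, so 0/1 and 1/0 agree.
    Identical genotypes are CONCORDANT even when they involve alleles
    beyond the first alternate (identity takes precedence over OTHER);
    both-missing is CONCORDANT by the "either present or missing" rule.
    """
    ga = a.sorted_alleles()
    gb = b.sorted_alleles()
    if ga is None and gb is None:
        return ConcordanceCategory.CONCORDANT
    if ga is None or gb is None:
        return ConcordanceCategory.MISSING
    if ga == gb:
        return ConcordanceCategory.CONCORDANT
    if max(ga[1], gb[1]) >= 2:
        return ConcordanceCategory.DISCORDANT_OTHER
    # remaining genotypes are over {0, 1}: 0/0, 0/1 or 1/1
    if {ga, gb} == {(0, 0), (1, 1)}:
        return ConcordanceCategory.DISCORDANT_HOMO_HOMO
    return ConcordanceCategory.DISCORDANT_HET_HOMO


def pairwise_concordance(
    cs: CallSet,
    a: str,
    b: str,
    filter_state: str = "RAW",
    groups: Optional[Sequence[str]] = None,
) -> ConcordanceTable:
    """Tabulate concordance categories between two samples over a call set.

    ``groups`` optionally supplies precomputed reporting groups (one per
    record, in record order) to avoid re-classifying records when many
    pairs are compared on the same call set.
    """
    roster_ids = set(cs.sample_ids)
    for sid in (a, b):
        if sid not in roster_ids:
            raise ValidationError(f"sample {sid!r} not in call set roster")
    if groups is None:
        groups = [reporting_group(rec) for rec in cs.records]
    table = ConcordanceTable(
        sample_a=a,
        sample_b=b,
        counts={g: Counter() for g in REPORTING_GROUPS},
        n_sites={g: 0 for g in REPORTING_GROUPS},
        filter_state=filter_state,
    )
    for rec, group in zip(cs.records, groups):
        cat = classify_genotype_pair(rec.calls[a], rec.calls[b])
        table.counts[group][cat] += 1
        table.n_sites[group] += 1
    return table


def concordance_rate(t: ConcordanceTable, group: str) -> float:
    """Percent concordant sites in a reporting group; NaN when no sites."""
    n = t.n_sites.get(group, 0)
    if n == 0:
        return float("nan")
    return 100.0 * t.counts[group][ConcordanceCategory.CONCORDANT] / n


def average_replicate_rates(tables: Sequence[ConcordanceTable]) -> dict[str, float]:
    """Arithmetic mean of per-table rates per group (mean of rates, not
    pooled counts).  Tables with no sites in a group are skipped for that
    group; an all-empty group averages to NaN."""
    if not tables:
        raise ValidationError("average_replicate_rates: empty table list")
    states = {t.filter_state for t in tables}
    if len(states) > 1:
        raise ValidationError(f"mixed filter states in replicate averaging: {states}")
    out: dict[str, float] = {}
    for group in REPORTING_GROUPS:
        rates = [concordance_rate(t, group) for t in tables]
        rates = [r for r in rates if not math.isnan(r)]
        out[group] = sum(rates) / len(rates) if rates else float("nan")
    return out


def _subject_pair_tables(
    cs: CallSet,
    manifest: Sequence[SampleMeta],
    type_a: str,
    type_b: str,
    subject: str,
    filter_state: str,
    groups: Sequence[str],
) -> list[ConcordanceTable]:
    """All replicate-cross tables for one subject and one type pairing."""
    a_samples = [
        m
        for m in manifest
        if m.subject_id == subject and m.sample_type == type_a
    ]
    b_samples = [
        m
        for m in manifest
        if m.subject_id == subject and m.sample_type == type_b
    ]
    tables = []
    for ma in sorted(a_samples, key=lambda m: m.replicate):
        for mb in sorted(b_samples, key=lambda m: m.replicate):
            if ma.sample_id == mb.sample_id:
                continue
            tables.append(
                pairwise_concordance(
                    cs, ma.sample_id, mb.sample_id, filter_state, groups
                )
            )
    return tables


def _mean_ignoring_nan(values: Sequence[float]) -> float:
    vals = [v for v in values if not math.isnan(v)]
    return sum(vals) / len(vals) if vals else float("nan")


def pilot_concordance_report(
    raw: CallSet,
    filtered: CallSet,
    manifest: Sequence[SampleMeta],
    pairing_plan: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Mean concordance rate per pairing, group and filter state.

    For each sample-type pairing and each subject owning both types, every
    replicate of type A is compared with every replicate of type B and the
    resulting rates are averaged per subject (replicate pre-averaging);
    the reported rate is the mean of the per-subject rates, computed on
    the raw (pre-filter) and filtered call sets.
    """
    types_present = {m.sample_type for m in manifest}
    for ta, tb in pairing_plan:
        for t in (ta, tb):
            if t not in types_present:
                raise ValidationError(
                    f"pairing references sample type {t!r} absent from manifest"
                )
    subjects = sorted({m.subject_id for m in manifest})
    rows = []
    for state, cs in (("RAW", raw), ("FILTERED", filtered)):
        groups = [reporting_group(rec) for rec in cs.records]
        for ta, tb in pairing_plan:
            per_subject: dict[str, dict[str, float]] = {}
            for subject in subjects:
                tables = _subject_pair_tables(
                    cs, manifest, ta, tb, subject, state, groups
                )
                if not tables:
                    continue
                per_subject[subject] = average_replicate_rates(tables)
            if not per_subject:
                raise ValidationError(
                    f"no subject carries both {ta!r} and {tb!r}"
                )
            for group in REPORTING_GROUPS:
                subj_rates = [r[group] for r in per_subject.values()]
                rows.append(
                    {
                        "sample_type_a": ta,
                        "sample_type_b": tb,
                        "pairing": f"{ta} vs {tb}",
                        "reporting_group": group,
                        "filter_state": state,
                        "mean_rate": _mean_ignoring_nan(subj_rates),
                        "n_subjects": len(subj_rates),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_type_a",
            "sample_type_b",
            "pairing",
            "reporting_group",
            "filter_state",
            "mean_rate",
            "n_subjects",
        ],
    )


def pairing_tables(
    cs: CallSet,
    manifest: Sequence[SampleMeta],
    pairing_plan: Sequence[tuple[str, str]],
    filter_state: str = "RAW",
) -> list[ConcordanceTable]:
    """All within-subject pair tables for a pairing plan, in plan order."""
    groups = [reporting_group(rec) for rec in cs.records]
    subjects = sorted({m.subject_id for m in manifest})
    tables: list[ConcordanceTable] = []
    for ta, tb in pairing_plan:
        for subject in subjects:
            tables.extend(
                _subject_pair_tables(cs, manifest, ta, tb, subject, filter_state, groups)
            )
    return tables


def category_long_table(tables: Sequence[ConcordanceTable]) -> pd.DataFrame:
    """Long-format table of all five category fractions for each pair.

    Emitting every category (including both-missing inside CONCORDANT and
    the MISSING single-no-call class) lets any alternative rate
    denominator be recomputed downstream.
    """
    rows = []
    for t in tables:
        for group in REPORTING_GROUPS:
            n = t.n_sites.get(group, 0)
            for cat in ConcordanceCategory:
                count = t.counts[group][cat] if group in t.counts else 0
                rows.append(
                    {
                        "sample_a": t.sample_a,
                        "sample_b": t.sample_b,
                        "filter_state": t.filter_state,
                        "reporting_group": group,
                        "category": cat.value,
                        "count": count,
                        "fraction": count / n if n else float("nan"),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_a",
            "sample_b",
            "filter_state",
            "reporting_group",
            "category",
            "count",
            "fraction",
        ],
    )
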