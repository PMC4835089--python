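"""Variant-type classification and two-level call-set filtering.

Variants are partitioned into four reporting groups — SNP, insertion,
deletion and multiallelic — the last of which splits into two classes:
MULTIALLELIC_COMPLEX (multiple alternate alleles that are insertions or
deletions of different sizes) and MULTIALLELIC_MIXED (alternate alleles
mixing SNPs, insertions and/or deletions).

Filtering combines a variant-level criterion, average sample depth
(multi-sample depth / roster size) strictly greater than 20, with a
sample-level criterion, the minimum genotype quality across the designated
whole-blood reference samples (minGQ_WB) strictly greater than 30.  A
missing reference genotype forces minGQ_WB to 0, so such sites are always
removed at the default threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import pandas as pd

from dbsconcord.callset_model import (
    CallSet,
    SampleMeta,
    ValidationError,
    VariantRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VariantClass",
    "FilterThresholds",
    "classify_variant",
    "reporting_group",
    "average_sample_depth",
    "min_gq_wb",
    "apply_filters",
    "variant_type_summary",
    "REPORTING_GROUPS",
]

#: Reporting groups in the conventional frequency order (SNPs dominate).
REPORTING_GROUPS = ("SNP", "insertion", "deletion", "multiallelic")


class VariantClass(str, Enum):
    SNP = "SNP"
    INSERTION = "INSERTION"
    DELETION = "DELETION"
    MULTIALLELIC_COMPLEX = "MULTIALLELIC_COMPLEX"
    MULTIALLELIC_MIXED = "MULTIALLELIC_MIXED"

    @property
    def reporting_group(self) -> str:
        if self is VariantClass.SNP:
            return "SNP"
        if self is VariantClass.INSERTION:
            return "insertion"
        if self is VariantClass.DELETION:
            return "deletion"
        return "multiallelic"


@dataclass(frozen=True, slots=True)
class FilterThresholds:
    """Strict lower bounds for the two filter criteria.

    ``min_avg_depth``: average sample depth must exceed this (default 20).
    ``min_gq_wb``: the minimum reference-sample GQ must exceed this
    (default 30).  Boundary values are removed.
    """

    min_avg_depth: float = 20.0
    min_gq_wb: int = 30

    def __post_init__(self) -> None:
        if self.min_avg_depth < 0 or self.min_gq_wb < 0:
            raise ValidationError("filter thresholds must be >= 0")


def _alt_kind(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "snp"
    if len(alt) > len(ref):
        return "ins"
    if len(alt) < len(ref):
        return "del"
    return "complex"  # equal-length multi-base substitution (MNP)


def classify_variant(record: VariantRecord) -> VariantClass:
    """Assign a variant class from the REF/ALT allele lengths.

    Per-alt typing: equal length 1 -> SNP, longer ALT -> insertion, shorter
    ALT -> deletion, equal length > 1 -> complex.  A single-alt record takes
    its alt's type; a multi-alt record whose alts are all SNPs is an SNP,
    all insertions/deletions is MULTIALLELIC_COMPLEX, and any mixture (or
    any complex alt) is MULTIALLELIC_MIXED.  A single-alt complex record
    (an MNP) has no bucket of its own in the four-group taxonomy; it is
    reported under the multiallelic group as MULTIALLELIC_MIXED and logged.
    """
    kinds = [_alt_kind(record.ref, alt) for alt in record.alts]
    if len(kinds) == 1:
        kind = kinds[0]
        if kind == "snp":
            return VariantClass.SNP
        if kind == "ins":
            return VariantClass.INSERTION
        if kind == "del":
            return VariantClass.DELETION
        logger.debug(
            "single-alt MNP/complex record at %s:%d grouped as multiallelic",
            record.chrom,
            record.pos,
        )
        return VariantClass.MULTIALLELIC_MIXED
    kindset = set(kinds)
    if kindset == {"snp"}:
        return VariantClass.SNP
    if kindset <= {"ins", "del"}:
        return VariantClass.MULTIALLELIC_COMPLEX
    return VariantClass.MULTIALLELIC_MIXED


def reporting_group(record: VariantRecord) -> str:
    return classify_variant(record).reporting_group


def average_sample_depth(record: VariantRecord, n_samples: int) -> float:
    """Multi-sample site depth divided by the number of samples called."""
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    return record.site_dp / n_samples


def min_gq_wb(record: VariantRecord, roster: Sequence[SampleMeta]) -> int:
    """Minimum GQ across the reference-standard samples at this site.

    A reference call that is missing, absent or lacks a GQ contributes 0,
    so any gap in the reference standard disqualifies the site at a
    positive threshold.
    """
    ref_ids = [m.sample_id for m in roster if m.is_reference_standard]
    if not ref_ids:
        raise ValidationError("roster has no is_reference_standard samples")
    min_gq = None
    for sid in ref_ids:
        call = record.calls.get(sid)
        if call is None or call.is_missing or call.gq is None:
            gq = 0
        else:
            gq = call.gq
        min_gq = gq if min_gq is None else min(min_gq, gq)
    return int(min_gq)


def apply_filters(
    cs: CallSet, thresholds: FilterThresholds = FilterThresholds()
) -> tuple[CallSet, pd.DataFrame]:
    """Apply the depth and minGQ_WB filters; return kept records + a log.

    The decision table has one row per input record with both statistics
    and the verdict, so filter attrition is auditable.  Filtering is a pure
    subset operation: records are kept unmodified and in order.
    """
    n_samples = len(cs.roster)
    kept: list[VariantRecord] = []
    rows = []
    for rec in cs.records:
        avg_dp = average_sample_depth(rec, n_samples)
        gq = min_gq_wb(rec, cs.roster)
        ok = avg_dp > thresholds.min_avg_depth and gq > thresholds.min_gq_wb
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "avg_sample_depth": avg_dp,
                "min_gq_wb": gq,
                "kept": ok,
            }
        )
        if ok:
            kept.append(rec)
    decisions = pd.DataFrame(
        rows, columns=["chrom", "pos", "avg_sample_depth", "min_gq_wb", "kept"]
    )
    out = cs.with_records(kept, provenance=f"filter({cs.provenance})")
    return out, decisions


def variant_type_summary(cs: CallSet) -> pd.DataFrame:
    """Counts and percentages per reporting group (S1-Table layout)."""
    counts = {g: 0 for g in REPORTING_GROUPS}
    for rec in cs.records:
        counts[reporting_group(rec)] += 1
    total = sum(counts.values())
    rows = []
    for group in REPORTING_GROUPS:
        n = counts[group]
        pct = 100.0 * n / total if total else float("nan")
        rows.append({"reporting_group": group, "n": n, "percent": pct})
    rows.append(
        {
            "reporting_group": "total",
            "n": total,
            "percent": 100.0 if total else float("nan"),
        }
    )
    return pd.DataFrame(rows, columns=["reporting_group", "n", "percent"])
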