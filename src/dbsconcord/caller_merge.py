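"""Priority merge of two callers' call sets.

Both callers genotype the same alignments in multi-sample mode, so a site
is identified by its (chrom, pos) anchor.  The merge keeps, in order of
priority:

* every PASS record of the first caller (HaplotypeCaller-style, "HC");
* every PASS record of the second caller ("UG") at an anchor where the
  first caller has no PASS record — either no record at all, or a record
  that its recalibration filter removed.

All other records are dropped.  Priority is record-level: when both
callers PASS the same anchor with different alleles, the HC record wins
wholesale; no allele normalization or left-alignment is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

from dbsconcord.callset_model import (
    CallSet,
    FilterStatus,
    Source,
    ValidationError,
    VariantRecord,
    copy_record,
)

__all__ = ["MergeReport", "merge_key", "merge_caller_outputs"]


@dataclass(slots=True)
class MergeReport:
    """Counts describing how a merge partitioned the two inputs.

    The merged size equals ``n_hc_pass + n_ug_rescued + n_unique_ug``,
    where ``n_unique_ug`` counts UG-PASS anchors with no HC record at all
    and ``n_ug_rescued`` counts UG-PASS anchors where the HC record was
    FILTERED.
    """

    n_hc_pass: int = 0
    n_ug_pass: int = 0
    n_overlap_hc_wins: int = 0
    n_ug_rescued: int = 0
    n_unique_hc: int = 0
    n_unique_ug: int = 0

    @property
    def n_merged(self) -> int:
        return self.n_hc_pass + self.n_ug_rescued + self.n_unique_ug

    def to_dict(self) -> dict[str, int]:
        return {
            "n_hc_pass": self.n_hc_pass,
            "n_ug_pass": self.n_ug_pass,
            "n_overlap_hc_wins": self.n_overlap_hc_wins,
            "n_ug_rescued": self.n_ug_rescued,
            "n_unique_hc": self.n_unique_hc,
            "n_unique_ug": self.n_unique_ug,
            "n_merged": self.n_merged,
        }


def merge_key(record: VariantRecord) -> tuple[str, int]:
    """Anchor identity of a record: exact contig name and 1-based position."""
    return (record.chrom, record.pos)


def _index_by_key(cs: CallSet, label: str) -> dict[tuple[str, int], VariantRecord]:
    index: dict[tuple[str, int], VariantRecord] = {}
    for rec in cs.records:
        key = merge_key(rec)
        if key in index:
            raise ValidationError(
                f"{label}: duplicate merge key {key[0]}:{key[1]} within one call set"
            )
        index[key] = rec
    return index


def merge_caller_outputs(
    hc: CallSet, ug: CallSet, strict_ref: bool = False
) -> tuple[CallSet, MergeReport]:
    """Merge two callers' outputs by PASS priority.

    Parameters
    ----------
    hc, ug:
        Call sets of the priority caller and the secondary caller.  Must
        share an identical sample roster; each may contain at most one
        record per (chrom, pos) anchor.
    strict_ref:
        When True, reject anchors where the two callers disagree on the
        REF allele instead of silently keeping the winning record.

    Returns the merged call set (source MERGED, per-record ``origin`` tag
    "HC" or "UG") and a :class:`MergeReport`.
    """
    if [m.sample_id for m in hc.roster] != [m.sample_id for m in ug.roster]:
        raise ValidationError("caller call sets have different sample rosters")

    hc_index = _index_by_key(hc, "hc")
    ug_index = _index_by_key(ug, "ug")

    report = MergeReport()
    merged: list[VariantRecord] = []

    for key, rec in hc_index.items():
        other = ug_index.get(key)
        if strict_ref and other is not None and other.ref != rec.ref:
            raise ValidationError(
                f"REF mismatch at {key[0]}:{key[1]}: hc={rec.ref} ug={other.ref}"
            )
        if rec.filter_status is FilterStatus.PASS:
            report.n_hc_pass += 1
            if other is None:
                report.n_unique_hc += 1
            elif other.filter_status is FilterStatus.PASS:
                report.n_overlap_hc_wins += 1
            merged.append(copy_record(rec, source=Source.MERGED, origin="HC"))

    for key, rec in ug_index.items():
        if rec.filter_status is not FilterStatus.PASS:
            continue
        report.n_ug_pass += 1
        hc_rec = hc_index.get(key)
        if hc_rec is None:
            report.n_unique_ug += 1
            merged.append(copy_record(rec, source=Source.MERGED, origin="UG"))
        elif hc_rec.filter_status is not FilterStatus.PASS:
            report.n_ug_rescued += 1
            merged.append(copy_record(rec, source=Source.MERGED, origin="UG"))

    out = hc.with_records(merged, provenance=f"merge({hc.provenance},{ug.provenance})")
    return out, report
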