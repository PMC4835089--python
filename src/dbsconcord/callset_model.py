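"""Core domain types and readers/writers for VCF, BED and manifest files.

The central container is a :class:`CallSet`: a position-sorted list of
:class:`VariantRecord` over a shared sample roster.  Genotypes are stored
per sample as :class:`GenotypeCall`; a no-call (``./.``) or half-call
(``./1``) is represented by ``alleles=None`` (MISSING) — the concordance
categories only distinguish "present" from "no call", so half-calls are
collapsed to MISSING at read time.

Coordinates are VCF-native 1-based.  BED inputs are 0-based half-open and
converted only inside :mod:`dbsconcord.coverage_stats`.  Contig names are
compared by exact string match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: Sample types of the pilot-study design.
SAMPLE_TYPES = ("DBS_2x3.2", "DBS_2x1.6", "WB_ref", "WB_ref_replica", "WB_WGA_ref")

#: Sample types derived from whole-genome-amplified DNA.  Allele dropout is
#: an amplification artifact, so it is confined to these types (including
#: the amplified whole-blood control WB_WGA_ref).
WGA_SAMPLE_TYPES = frozenset({"DBS_2x3.2", "DBS_2x1.6", "WB_WGA_ref"})

_VALID_BASES = frozenset("ACGTN")

MANIFEST_COLUMNS = (
    "sample_id",
    "subject_id",
    "sample_type",
    "replicate",
    "pilot",
    "is_reference_standard",
)


class ValidationError(ValueError):
    """Raised when an input violates a structural contract (exit code 2)."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed (names the offending line)."""


class FilterStatus(str, Enum):
    PASS = "PASS"
    FILTERED = "FILTERED"


class Source(str, Enum):
    HC = "HC"
    UG = "UG"
    MERGED = "MERGED"


@dataclass(frozen=True, slots=True)
class GenotypeCall:
    """One sample's diploid genotype at one site.

    ``alleles`` is an unordered pair of allele indices (0=REF, 1=first ALT,
    ...) stored sorted, or ``None`` for a no-call.  Phase is discarded:
    0|1 and 1/0 are the same genotype here.  ``gq`` and ``dp`` are the
    per-sample genotype quality and read depth, when present.
    """

    sample_id: str
    alleles: Optional[tuple[int, int]] = None
    gq: Optional[int] = None
    dp: Optional[int] = None

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    def sorted_alleles(self) -> Optional[tuple[int, int]]:
        if self.alleles is None:
            return None
        a, b = self.alleles
        return (a, b) if a <= b else (b, a)


@dataclass(slots=True)
class VariantRecord:
    """One variant site with per-sample genotype calls.

    ``site_dp`` is the multi-sample combined depth (the VCF INFO DP field);
    when the INFO field is absent it is reconstructed as the sum of the
    per-sample depths.  ``origin`` records which caller a merged record
    came from.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    filter_status: FilterStatus = FilterStatus.PASS
    site_dp: int = 0
    calls: dict[str, GenotypeCall] = field(default_factory=dict)
    source: Source = Source.HC
    origin: Optional[str] = None

    @property
    def n_alts(self) -> int:
        return len(self.alts)

    def validate(self, roster_ids: Optional[Sequence[str]] = None) -> None:
        if self.pos < 1:
            raise ValidationError(f"{self.chrom}:{self.pos}: pos must be >= 1")
        for allele in (self.ref, *self.alts):
            if not allele or not set(allele.upper()) <= _VALID_BASES:
                raise ValidationError(
                    f"{self.chrom}:{self.pos}: invalid allele {allele!r}"
                )
        n_alleles = 1 + len(self.alts)
        for call in self.calls.values():
            if call.alleles is not None:
                if any(a < 0 or a >= n_alleles for a in call.alleles):
                    raise ValidationError(
                        f"{self.chrom}:{self.pos}: allele index out of range "
                        f"for sample {call.sample_id}"
                    )
        if roster_ids is not None:
            missing = set(roster_ids) - set(self.calls)
            if missing:
                raise ValidationError(
                    f"{self.chrom}:{self.pos}: no call entry for samples "
                    f"{sorted(missing)}"
                )


@dataclass(frozen=True, slots=True)
class SampleMeta:
    """Manifest entry for one sequenced sample.

    ``is_reference_standard`` marks membership in the whole-blood reference
    set over which the minGQ_WB sample-level filter is computed.
    """

    sample_id: str
    subject_id: str
    sample_type: str
    replicate: int = 1
    pilot: int = 1
    is_reference_standard: bool = False

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValidationError(
                f"unknown sample_type {self.sample_type!r}; "
                f"allowed: {', '.join(SAMPLE_TYPES)}"
            )
        if self.replicate < 1:
            raise ValidationError(f"{self.sample_id}: replicate must be >= 1")
        if self.pilot not in (1, 2, 3):
            raise ValidationError(f"{self.sample_id}: pilot must be 1, 2 or 3")


@dataclass(slots=True)
class CallSet:
    """A position-sorted collection of variant records over one roster."""

    records: list[VariantRecord]
    roster: list[SampleMeta]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.sort()

    def sort(self) -> None:
        # stable, so input order is preserved among (chrom, pos) ties
        self.records.sort(key=lambda r: (r.chrom, r.pos))

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.roster]

    def __len__(self) -> int:
        return len(self.records)

    def sample_meta(self, sample_id: str) -> SampleMeta:
        for m in self.roster:
            if m.sample_id == sample_id:
                return m
        raise KeyError(sample_id)

    def with_records(self, records: Iterable[VariantRecord], provenance: str) -> "CallSet":
        return CallSet(records=list(records), roster=list(self.roster), provenance=provenance)


def _normalize_gt(gt: Optional[tuple]) -> Optional[tuple[int, int]]:
    """Map a pysam GT tuple to a sorted allele pair or MISSING.

    Half-calls (one allele missing) and non-diploid tuples collapse to
    MISSING; phased and unphased separators are equivalent.
    """
    if gt is None or len(gt) != 2 or gt[0] is None or gt[1] is None:
        return None
    a, b = int(gt[0]), int(gt[1])
    return (a, b) if a <= b else (b, a)


def read_multisample_vcf(
    path: str | Path,
    manifest: Sequence[SampleMeta],
    source_label: Source | str = Source.HC,
) -> CallSet:
    """Read a multi-sample VCF restricted to the manifest samples.

    FILTER ``PASS`` or ``.`` maps to PASS; any other value (e.g. a VQSR
    tranche label) maps to FILTERED.  Records with symbolic alleles,
    breakends or non-diploid genotypes are skipped with a logged count.
    When INFO/DP is absent, site depth is the sum of per-sample depths.
    """
    source = Source(source_label)
    path = Path(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"{path}: cannot open as VCF: {exc}") from exc

    header_samples = set(vcf.header.samples)
    absent = [m.sample_id for m in manifest if m.sample_id not in header_samples]
    if absent:
        raise ValidationError(
            f"{path}: manifest samples absent from VCF header: {absent}"
        )

    sample_ids = [m.sample_id for m in manifest]
    has_info_dp = "DP" in vcf.header.info
    has_info_src = "SRC" in vcf.header.info
    records: list[VariantRecord] = []
    n_skipped = 0
    lineno = 0
    try:
        for rec in vcf:
            lineno += 1
            alts = rec.alts
            if alts is None:
                n_skipped += 1
                continue
            if any(a is None or not set(a.upper()) <= _VALID_BASES for a in alts):
                n_skipped += 1  # symbolic / breakend / spanning-deletion alleles
                continue
            if not set(rec.ref.upper()) <= _VALID_BASES:
                n_skipped += 1
                continue
            filters = list(rec.filter.keys())
            status = (
                FilterStatus.PASS
                if not filters or filters == ["PASS"]
                else FilterStatus.FILTERED
            )
            calls: dict[str, GenotypeCall] = {}
            diploid = True
            for sid in sample_ids:
                fmt = rec.samples[sid]
                gt = fmt.get("GT")
                if gt is not None and len(gt) not in (1, 2):
                    diploid = False
                    break
                if gt is not None and len(gt) == 1:
                    # haploid call: treat as non-diploid record
                    diploid = False
                    break
                gq = fmt.get("GQ")
                dp = fmt.get("DP")
                calls[sid] = GenotypeCall(
                    sample_id=sid,
                    alleles=_normalize_gt(gt),
                    gq=None if gq is None else int(gq),
                    dp=None if dp is None else int(dp),
                )
            if not diploid:
                n_skipped += 1
                continue
            info_dp = rec.info.get("DP") if has_info_dp else None
            if info_dp is None:
                site_dp = sum(c.dp or 0 for c in calls.values())
            else:
                site_dp = int(info_dp)
            origin = rec.info.get("SRC") if has_info_src else None
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(alts),
                    filter_status=status,
                    site_dp=site_dp,
                    calls=calls,
                    source=source,
                    origin=str(origin) if origin is not None else None,
                )
            )
    except (ValueError, OSError) as exc:
        raise ParseError(f"{path}: malformed VCF near data line {lineno + 1}: {exc}") from exc
    finally:
        vcf.close()

    if n_skipped:
        logger.info("%s: skipped %d unsupported records", path, n_skipped)
    return CallSet(records=records, roster=list(manifest), provenance=f"{source.value}:{path.name}")


def write_callset_vcf(cs: CallSet, path: str | Path) -> None:
    """Write a CallSet as a plain-text VCF v4.2 file.

    The round trip ``read(write(cs))`` preserves every field the pipeline
    consumes: (chrom, pos, ref, alts, filter status, site depth, per-sample
    GT/GQ/DP, merge origin).  MISSING genotypes are written as ``./.``;
    FILTERED records carry the generic ``LOWQ`` filter label.
    """
    header = pysam.VariantHeader()
    header.add_line('##FILTER=<ID=LOWQ,Description="Did not pass the source caller filter">')
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Combined multi-sample depth">')
    header.add_line('##INFO=<ID=SRC,Number=1,Type=String,Description="Origin caller of a merged record">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    seen: list[str] = []
    for rec in cs.records:
        if rec.chrom not in seen:
            seen.append(rec.chrom)
    for chrom in sorted(seen):
        header.add_line(f"##contig=<ID={chrom}>")
    for sid in cs.sample_ids:
        header.add_sample(sid)

    path = Path(path)
    try:
        out = pysam.VariantFile(str(path), "w", header=header)
    except OSError as exc:
        raise OSError(f"cannot write VCF to {path}: {exc}") from exc
    try:
        for rec in cs.records:
            vrec = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref, *rec.alts),
            )
            if rec.filter_status is FilterStatus.PASS:
                vrec.filter.add("PASS")
            else:
                vrec.filter.add("LOWQ")
            vrec.info["DP"] = int(rec.site_dp)
            if rec.origin is not None:
                vrec.info["SRC"] = rec.origin
            for sid in cs.sample_ids:
                call = rec.calls.get(sid)
                fmt = vrec.samples[sid]
                if call is None or call.alleles is None:
                    fmt["GT"] = (None, None)
                else:
                    fmt["GT"] = tuple(call.alleles)
                fmt.phased = False
                if call is not None and call.gq is not None:
                    fmt["GQ"] = int(call.gq)
                if call is not None and call.dp is not None:
                    fmt["DP"] = int(call.dp)
            out.write(vrec)
    finally:
        out.close()


def read_manifest(path: str | Path) -> list[SampleMeta]:
    """Read and validate a sample manifest TSV.

    Required columns: sample_id, subject_id, sample_type, replicate, pilot,
    is_reference_standard.  (subject, type, replicate) must be unique within
    a pilot and every pilot must contain at least one reference-standard
    sample (the minGQ_WB filter is undefined otherwise).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except (OSError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: cannot parse manifest: {exc}") from exc
    missing_cols = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(f"{path}: manifest missing columns {sorted(missing_cols)}")

    metas: list[SampleMeta] = []
    for idx, row in df.iterrows():
        token = str(row["is_reference_standard"]).strip().lower()
        if token in ("true", "1", "yes"):
            is_ref = True
        elif token in ("false", "0", "no"):
            is_ref = False
        else:
            raise ValidationError(
                f"{path}: row {idx + 2}: is_reference_standard must be "
                f"true/false, got {row['is_reference_standard']!r}"
            )
        try:
            metas.append(
                SampleMeta(
                    sample_id=str(row["sample_id"]),
                    subject_id=str(row["subject_id"]),
                    sample_type=str(row["sample_type"]),
                    replicate=int(row["replicate"]),
                    pilot=int(row["pilot"]),
                    is_reference_standard=is_ref,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: row {idx + 2}: {exc}") from exc
    validate_manifest(metas)
    return metas


def validate_manifest(metas: Sequence[SampleMeta]) -> None:
    seen: set[tuple] = set()
    pilots: dict[int, bool] = {}
    ids: set[str] = set()
    for m in metas:
        if m.sample_id in ids:
            raise ValidationError(f"duplicate sample_id {m.sample_id!r}")
        ids.add(m.sample_id)
        key = (m.pilot, m.subject_id, m.sample_type, m.replicate)
        if key in seen:
            raise ValidationError(
                f"duplicate manifest entry for (subject={m.subject_id}, "
                f"type={m.sample_type}, replicate={m.replicate}, pilot={m.pilot})"
            )
        seen.add(key)
        pilots[m.pilot] = pilots.get(m.pilot, False) or m.is_reference_standard
    for pilot, has_ref in pilots.items():
        if not has_ref:
            raise ValidationError(
                f"pilot {pilot}: no sample flagged is_reference_standard; "
                "the minGQ_WB filter needs at least one"
            )


def write_manifest(metas: Sequence[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "subject_id": m.subject_id,
                "sample_type": m.sample_type,
                "replicate": m.replicate,
                "pilot": m.pilot,
                "is_reference_standard": "true" if m.is_reference_standard else "false",
            }
            for m in metas
        ],
        columns=list(MANIFEST_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def copy_record(rec: VariantRecord, **changes) -> VariantRecord:
    """Shallow copy of a record with field overrides (calls dict shared)."""
    return replace(rec, **changes)
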