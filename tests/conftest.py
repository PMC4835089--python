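"""Shared builders for small hand-constructed call sets."""

from __future__ import annotations

import pytest

from dbsconcord.callset_model import (
    CallSet,
    FilterStatus,
    GenotypeCall,
    SampleMeta,
    VariantRecord,
)


def make_roster(n_wb: int = 2, n_dbs: int = 2, pilot: int = 2) -> list[SampleMeta]:
    """Small roster: n_wb whole-blood reference samples + n_dbs DBS samples."""
    roster = []
    for i in range(n_wb):
        roster.append(
            SampleMeta(
                sample_id=f"WB{i + 1}",
                subject_id=f"SUBJ{i + 1:02d}",
                sample_type="WB_ref",
                replicate=1,
                pilot=pilot,
                is_reference_standard=True,
            )
        )
    for i in range(n_dbs):
        roster.append(
            SampleMeta(
                sample_id=f"DBS{i + 1}",
                subject_id=f"SUBJ{i + 1:02d}",
                sample_type="DBS_2x3.2",
                replicate=1,
                pilot=pilot,
                is_reference_standard=False,
            )
        )
    return roster


def make_record(
    roster,
    pos,
    ref="A",
    alts=("G",),
    genotypes=None,
    gq=99,
    dp=50,
    filter_status=FilterStatus.PASS,
    site_dp=None,
    chrom="chr1",
):
    """Record with one genotype per roster sample.

    ``genotypes`` maps sample_id -> allele pair or None (missing); samples
    not listed default to 0/0.
    """
    genotypes = genotypes or {}
    calls = {}
    for m in roster:
        gt = genotypes.get(m.sample_id, (0, 0))
        calls[m.sample_id] = GenotypeCall(
            sample_id=m.sample_id,
            alleles=gt,
            gq=gq if gt is not None else None,
            dp=dp,
        )
    if site_dp is None:
        site_dp = dp * len(roster)
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alts=tuple(alts),
        filter_status=filter_status,
        site_dp=site_dp,
        calls=calls,
    )


def make_callset(roster, records, provenance="test"):
    return CallSet(records=list(records), roster=list(roster), provenance=provenance)


@pytest.fixture
def roster():
    return make_roster()
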