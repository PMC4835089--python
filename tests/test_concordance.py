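"""Five-category genotype comparison, rates and replicate averaging."""

from __future__ import annotations

import itertools
import math
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from dbsconcord.callset_model import GenotypeCall, ValidationError
from dbsconcord.concordance import (
    ConcordanceCategory as C,
    ConcordanceTable,
    average_replicate_rates,
    classify_genotype_pair,
    concordance_rate,
    pairwise_concordance,
    pilot_concordance_report,
)
from dbsconcord.classify_filter import REPORTING_GROUPS
from dbsconcord.caller_merge import merge_caller_outputs
from dbsconcord.classify_filter import apply_filters
from dbsconcord.synthetic_data import SimulationConfig, simulate_cohort

from conftest import make_callset, make_record, make_roster


def oracle_category(ga, gb):
    """Independent brute-force restatement of the five category definitions.

    Works on ordered allele tuples or None; compares allele multisets.
    """
    if ga is None and gb is None:
        return C.CONCORDANT  # identical: both "missing"
    if ga is None or gb is None:
        return C.MISSING  # no call in exactly one sample
    if Counter(ga) == Counter(gb):
        return C.CONCORDANT  # identical genotypes
    if any(allele >= 2 for allele in (*ga, *gb)):
        return C.DISCORDANT_OTHER  # involves alternates beyond the first
    homs = {(0, 0), (1, 1)}
    sa, sb = tuple(sorted(ga)), tuple(sorted(gb))
    if sa in homs and sb in homs:
        return C.DISCORDANT_HOMO_HOMO
    return C.DISCORDANT_HET_HOMO


def _call(gt):
    return GenotypeCall("S", alleles=gt)


ALL_GENOTYPES = [None] + [(i, j) for i in range(4) for j in range(i, 4)]


class TestClassifyGenotypePair:
    def test_matches_bruteforce_oracle_on_all_pairs(self):
        """Exhaustive agreement over every ordered diploid pair with allele
        indices up to 3 plus MISSING."""
        ordered = [None] + [(i, j) for i in range(4) for j in range(4)]
        for ga, gb in itertools.product(ordered, repeat=2):
            got = classify_genotype_pair(_call(ga), _call(gb))
            assert got is oracle_category(ga, gb), (ga, gb, got)

    @pytest.mark.parametrize(
        "ga,gb,expected",
        [
            ((0, 1), (1, 0), C.CONCORDANT),
            (None, None, C.CONCORDANT),
            ((0, 0), (0, 1), C.DISCORDANT_HET_HOMO),
            ((1, 1), (0, 1), C.DISCORDANT_HET_HOMO),
            ((0, 0), (1, 1), C.DISCORDANT_HOMO_HOMO),
            ((0, 1), (1, 2), C.DISCORDANT_OTHER),
            ((2, 2), (0, 0), C.DISCORDANT_OTHER),
            ((0, 1), None, C.MISSING),
            # identical genotypes take precedence over OTHER
            ((1, 2), (1, 2), C.CONCORDANT),
        ],
    )
    def test_category_examples(self, ga, gb, expected):
        assert classify_genotype_pair(_call(ga), _call(gb)) is expected

    @settings(max_examples=300, derandomize=True)
    @given(
        ga=st.sampled_from(ALL_GENOTYPES),
        gb=st.sampled_from(ALL_GENOTYPES),
    )
    def test_symmetry(self, ga, gb):
        assert classify_genotype_pair(_call(ga), _call(gb)) is classify_genotype_pair(
            _call(gb), _call(ga)
        )


class TestPairwiseConcordance:
    def test_identical_genotypes_all_concordant(self):
        roster = make_roster()
        records = [
            make_record(roster, p, genotypes={"WB1": (0, 1), "DBS1": (0, 1)})
            for p in (10, 20, 30)
        ]
        t = pairwise_concordance(make_callset(roster, records), "WB1", "DBS1")
        assert t.counts["SNP"][C.CONCORDANT] == 3
        assert t.n_sites["SNP"] == 3

    def test_self_comparison_is_reflexive(self):
        sim = simulate_cohort(SimulationConfig(seed=41, n_sites=300))
        sid = sim.hc.sample_ids[0]
        t = pairwise_concordance(sim.hc, sid, sid)
        for group in REPORTING_GROUPS:
            n = t.n_sites[group]
            assert t.counts[group][C.CONCORDANT] == n

    def test_swap_symmetry(self):
        sim = simulate_cohort(SimulationConfig(seed=42, n_sites=300))
        a, b = sim.hc.sample_ids[0], sim.hc.sample_ids[3]
        t1 = pairwise_concordance(sim.hc, a, b)
        t2 = pairwise_concordance(sim.hc, b, a)
        assert t1.counts == t2.counts

    def test_categories_partition_sites(self):
        sim = simulate_cohort(SimulationConfig(seed=43, n_sites=500))
        ids = sim.hc.sample_ids
        for a, b in [(ids[0], ids[1]), (ids[2], ids[5])]:
            t = pairwise_concordance(sim.hc, a, b)
            for group in REPORTING_GROUPS:
                assert sum(t.counts[group].values()) == t.n_sites[group]
            assert sum(t.n_sites.values()) == len(sim.hc)

    def test_unknown_sample_rejected(self):
        roster = make_roster()
        cs = make_callset(roster, [make_record(roster, 1)])
        with pytest.raises(ValidationError):
            pairwise_concordance(cs, "WB1", "nope")


class TestRates:
    def _table(self, conc, het_homo, missing, n):
        counts = {g: Counter() for g in REPORTING_GROUPS}
        counts["SNP"][C.CONCORDANT] = conc
        counts["SNP"][C.DISCORDANT_HET_HOMO] = het_homo
        counts["SNP"][C.MISSING] = missing
        return ConcordanceTable(
            "a", "b", counts=counts, n_sites={"SNP": n}, filter_state="RAW"
        )

    def test_rate_definition(self):
        assert concordance_rate(self._table(98, 1, 1, 100), "SNP") == 98.0
        assert concordance_rate(self._table(50, 0, 0, 50), "SNP") == 100.0

    def test_zero_sites_is_nan_not_zero(self):
        t = self._table(0, 0, 0, 0)
        t.n_sites["SNP"] = 0
        assert math.isnan(concordance_rate(t, "SNP"))
        assert math.isnan(concordance_rate(t, "deletion"))

    def test_replicate_averaging(self):
        tables = [self._table(int(r), 0, 0, 100) for r in (98, 99, 100)]
        avg = average_replicate_rates(tables)
        assert avg["SNP"] == pytest.approx(99.0)
        single = average_replicate_rates([self._table(97, 3, 0, 100)])
        assert single["SNP"] == 97.0

    def test_averaging_three_identical_tables_is_identity(self):
        t = self._table(95, 5, 0, 100)
        avg = average_replicate_rates([t, t, t])
        assert avg["SNP"] == concordance_rate(t, "SNP")

    def test_averaging_rejects_mixed_filter_states(self):
        a = self._table(98, 1, 1, 100)
        b = self._table(98, 1, 1, 100)
        b.filter_state = "FILTERED"
        with pytest.raises(ValidationError, match="filter state"):
            average_replicate_rates([a, b])
        with pytest.raises(ValidationError, match="empty"):
            average_replicate_rates([])


class TestPilotReport:
    def test_pilot2_report_shape(self):
        sim = simulate_cohort(SimulationConfig(seed=44, n_sites=400, pilot=2))
        merged, _ = merge_caller_outputs(sim.hc, sim.ug)
        filtered, _ = apply_filters(merged)
        plan = [("DBS_2x3.2", "WB_ref"), ("WB_ref", "WB_ref_replica")]
        report = pilot_concordance_report(merged, filtered, sim.manifest, plan)
        assert set(report["pairing"]) == {
            "DBS_2x3.2 vs WB_ref",
            "WB_ref vs WB_ref_replica",
        }
        # 2 pairings x 4 groups x 2 filter states
        assert len(report) == 16
        assert set(report["filter_state"]) == {"RAW", "FILTERED"}
        assert (report["n_subjects"] == 8).all()

    def test_single_subject_rate_equals_cohort_mean(self):
        sim = simulate_cohort(SimulationConfig(seed=45, n_sites=300, n_subjects=1))
        merged, _ = merge_caller_outputs(sim.hc, sim.ug)
        filtered, _ = apply_filters(merged)
        report = pilot_concordance_report(
            merged, filtered, sim.manifest, [("DBS_2x3.2", "WB_ref")]
        )
        raw = report[(report.filter_state == "RAW") & (report.reporting_group == "SNP")]
        table = pairwise_concordance(
            merged, "S01_DBS_2x3.2_r1", "S01_WB_ref_r1", "RAW"
        )
        assert raw["mean_rate"].iloc[0] == pytest.approx(concordance_rate(table, "SNP"))

    def test_unknown_pairing_type_rejected(self):
        sim = simulate_cohort(SimulationConfig(seed=46, n_sites=100, pilot=1))
        merged, _ = merge_caller_outputs(sim.hc, sim.ug)
        with pytest.raises(ValidationError, match="absent from manifest"):
            pilot_concordance_report(
                merged, merged, sim.manifest, [("WB_WGA_ref", "WB_ref")]
            )
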