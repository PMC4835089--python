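"""Synthetic cohort generator: design, determinism, artifact mechanisms."""

from __future__ import annotations

import math

import numpy as np
import pytest

from dbsconcord.callset_model import FilterStatus, ValidationError, write_callset_vcf
from dbsconcord.caller_merge import merge_caller_outputs
from dbsconcord.classify_filter import apply_filters
from dbsconcord.concordance import pilot_concordance_report
from dbsconcord.synthetic_data import (
    PILOT_DESIGNS,
    SimulationConfig,
    build_manifest,
    observe_genotype,
    simulate_cohort,
)


def artifact_free(seed=0, **kw):
    base = dict(
        seed=seed,
        dropout_prob=0.0,
        error_prob=0.0,
        missing_prob=0.0,
        p_hc_filtered_ug_pass=0.0,
        p_hc_pass_ug_filtered=0.0,
        p_hc_unique=0.0,
        p_ug_unique=0.0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_invalid_fields_are_listed(self):
        cfg = SimulationConfig(n_sites=0, dropout_prob=1.5, depth_mean=-1)
        with pytest.raises(ValidationError) as err:
            cfg.validate()
        msg = str(err.value)
        for name in ("n_sites", "dropout_prob", "depth_mean"):
            assert name in msg

    def test_class_mix_must_sum_to_one(self):
        cfg = SimulationConfig(class_mix={"SNP": 0.9, "insertion": 0.2})
        with pytest.raises(ValidationError, match="class_mix"):
            cfg.validate()

    def test_zero_length_targets_rejected(self):
        with pytest.raises(ValidationError, match="targets"):
            SimulationConfig(n_target_regions=0).validate()


class TestDesign:
    def test_pilot3_manifest_counts(self):
        manifest = build_manifest(SimulationConfig(pilot=3, n_subjects=7))
        assert len(manifest) == 42  # 7 x (1 + 3 + 1 + 1)
        per_type = {}
        for m in manifest:
            per_type[m.sample_type] = per_type.get(m.sample_type, 0) + 1
        assert per_type == {"DBS_2x3.2": 7, "DBS_2x1.6": 21, "WB_ref": 7, "WB_WGA_ref": 7}

    def test_pilot_sample_totals_match_designs(self):
        for pilot, n_subjects, expected in ((1, 7, 14), (2, 8, 24), (3, 7, 42)):
            manifest = build_manifest(SimulationConfig(pilot=pilot, n_subjects=n_subjects))
            assert len(manifest) == expected

    def test_only_wb_ref_is_reference_standard_by_default(self):
        manifest = build_manifest(SimulationConfig(pilot=2, n_subjects=3))
        refs = {m.sample_type for m in manifest if m.is_reference_standard}
        assert refs == {"WB_ref"}
        manifest = build_manifest(
            SimulationConfig(pilot=2, n_subjects=3, replica_is_reference=True)
        )
        refs = {m.sample_type for m in manifest if m.is_reference_standard}
        assert refs == {"WB_ref", "WB_ref_replica"}


class TestDeterminism:
    def test_same_seed_byte_identical_vcfs(self, tmp_path):
        paths = []
        for run in (1, 2):
            sim = simulate_cohort(SimulationConfig(seed=9, n_sites=300))
            p = tmp_path / f"hc{run}.vcf"
            write_callset_vcf(sim.hc, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_cohort(SimulationConfig(seed=1, n_sites=200))
        b = simulate_cohort(SimulationConfig(seed=2, n_sites=200))
        ga = [r.calls[a.hc.sample_ids[0]].alleles for r in a.hc.records]
        gb = [r.calls[b.hc.sample_ids[0]].alleles for r in b.hc.records]
        assert ga != gb


class TestArtifactMechanisms:
    def test_artifact_free_cohort_is_fully_concordant(self):
        sim = simulate_cohort(artifact_free(seed=13, n_sites=1500))
        merged, _ = merge_caller_outputs(sim.hc, sim.ug)
        assert len(merged) == 1500
        assert all(r.filter_status is FilterStatus.PASS for r in sim.hc.records)
        filtered, _ = apply_filters(merged)
        report = pilot_concordance_report(
            merged, filtered, sim.manifest,
            [("DBS_2x3.2", "WB_ref"), ("WB_ref", "WB_ref_replica")],
        )
        assert (report["mean_rate"] == 100.0).all()

    def test_dropout_gated_to_wga_types(self):
        sim = simulate_cohort(
            SimulationConfig(seed=14, n_sites=2000, dropout_prob=0.3,
                             error_prob=0.0, missing_prob=0.0)
        )
        wga_cols = [
            i for i, m in enumerate(sim.manifest) if m.sample_type in
            ("DBS_2x3.2", "DBS_2x1.6", "WB_WGA_ref")
        ]
        wb_cols = [i for i in range(len(sim.manifest)) if i not in wga_cols]
        assert sim.truth.dropout[:, wga_cols].sum() > 0
        assert sim.truth.dropout[:, wb_cols].sum() == 0

    def test_dropout_requires_heterozygous_truth(self):
        sim = simulate_cohort(
            SimulationConfig(seed=15, n_sites=1000, dropout_prob=0.5,
                             error_prob=0.0, missing_prob=0.0)
        )
        truth = sim.truth
        for k, m in enumerate(sim.manifest):
            j = truth.subject_ids.index(m.subject_id)
            het = truth.truth_alleles[:, j, 0] != truth.truth_alleles[:, j, 1]
            fired = truth.dropout[:, k]
            assert not np.any(fired & ~het)

    def test_observe_genotype_dropout_rate_recovers(self):
        """Binomial check of the scalar observation model: at coupling 0 the
        realized het->hom rate matches the nominal dropout probability."""
        cfg = SimulationConfig(
            dropout_prob=0.05, error_prob=0.0, missing_prob=0.0,
            artifact_depth_coupling=0.0,
        )
        rng = np.random.default_rng(16)
        n = 10_000
        n_hom = 0
        for _ in range(n):
            call = observe_genotype((0, 1), "DBS_2x3.2", 60, cfg, rng)
            if call.alleles in ((0, 0), (1, 1)):
                n_hom += 1
        p_hat = n_hom / n
        se = math.sqrt(0.05 * 0.95 / n)
        assert abs(p_hat - 0.05) <= 3 * se

    def test_observe_genotype_dropout_never_fires_for_wb(self):
        cfg = SimulationConfig(dropout_prob=1.0, error_prob=0.0, missing_prob=0.0,
                               artifact_depth_coupling=0.0)
        rng = np.random.default_rng(17)
        for _ in range(50):
            call = observe_genotype((0, 1), "WB_ref", 60, cfg, rng)
            assert call.alleles == (0, 1)

    def test_observe_genotype_dropout_yields_either_homozygote(self):
        cfg = SimulationConfig(dropout_prob=1.0, error_prob=0.0, missing_prob=0.0,
                               artifact_depth_coupling=0.0)
        rng = np.random.default_rng(18)
        seen = {observe_genotype((0, 1), "DBS_2x3.2", 60, cfg, rng).alleles
                for _ in range(200)}
        assert seen == {(0, 0), (1, 1)}

    def test_missingness_concentrates_at_low_depth(self):
        cfg = SimulationConfig(missing_prob=1.0)
        rng = np.random.default_rng(19)
        low = sum(
            observe_genotype((0, 0), "WB_ref", 2, cfg, rng).is_missing
            for _ in range(300)
        )
        high = sum(
            observe_genotype((0, 0), "WB_ref", 60, cfg, rng).is_missing
            for _ in range(300)
        )
        assert low > 250
        assert high == 0  # logistic weight is ~0 at 60x

    def test_subject_truth_shared_across_sample_types(self):
        sim = simulate_cohort(artifact_free(seed=20, n_sites=400, pilot=3, n_subjects=3))
        for rec in sim.hc.records[:50]:
            by_subject = {}
            for m in sim.manifest:
                gt = rec.calls[m.sample_id].sorted_alleles()
                by_subject.setdefault(m.subject_id, set()).add(gt)
            assert all(len(s) == 1 for s in by_subject.values())

    def test_wb_concordance_exceeds_dbs_concordance_prefilter(self):
        """With dropout confined to WGA types, the WB-vs-WB baseline beats
        DBS-vs-WB before filtering."""
        sim = simulate_cohort(SimulationConfig(seed=21, n_sites=8000))
        merged, _ = merge_caller_outputs(sim.hc, sim.ug)
        filtered, _ = apply_filters(merged)
        report = pilot_concordance_report(
            merged, filtered, sim.manifest,
            [("DBS_2x3.2", "WB_ref"), ("WB_ref", "WB_ref_replica")],
        ).set_index(["pairing", "reporting_group", "filter_state"])
        dbs = report.loc[("DBS_2x3.2 vs WB_ref", "SNP", "RAW"), "mean_rate"]
        wb = report.loc[("WB_ref vs WB_ref_replica", "SNP", "RAW"), "mean_rate"]
        assert wb > dbs
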