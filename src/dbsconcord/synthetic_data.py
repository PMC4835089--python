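"""Synthetic exome cohort generator for pipeline testing.

Emulates the pilot-study layout: a handful of subjects, each sequenced as
several sample types (dried-blood-spot wgaDNA at two disc sizes, a
whole-blood reference, a replicated reference, an amplified reference),
with two simulated callers emitting multi-sample call sets over the same
roster.  The generator injects the artifact mechanisms that distinguish
amplified low-input DNA from high-quality whole-blood DNA:

* allele dropout — a truth-heterozygous genotype observed homozygous,
  confined to WGA-derived sample types;
* amplification/sequence error — a genotype perturbed to a random
  different genotype, any sample type;
* depth-dependent missingness — no-calls concentrated at low depth;
* depth attenuation — WGA types draw lower depth than whole blood;
* caller disagreement — sites PASS in only one caller, or filtered by the
  priority caller's recalibration while PASS in the secondary caller.

Dropout and error probabilities can be coupled to per-sample depth
(``artifact_depth_coupling``), concentrating artifacts at poorly covered
sites the way real discordant calls co-locate with low depth and low
quality; genotype quality rises with depth and drops on artifact calls, so
the depth and minGQ_WB filters preferentially remove artifact-bearing
sites.  With the coupling at 0 every artifact rate is the exact marginal
probability, which is what parameter-recovery tests measure.

Everything is driven by one integer seed; the same config and seed give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from dbsconcord.callset_model import (
    CallSet,
    FilterStatus,
    GenotypeCall,
    SampleMeta,
    Source,
    ValidationError,
    VariantRecord,
    WGA_SAMPLE_TYPES,
    SAMPLE_TYPES,
)
from dbsconcord.coverage_stats import DepthTrack

__all__ = [
    "PILOT_DESIGNS",
    "SimulationConfig",
    "SimulationResult",
    "TruthSet",
    "simulate_cohort",
    "observe_genotype",
    "simulate_depth_tracks",
    "make_targets",
]

_BASES = "ACGT"

#: Sample types and replicate counts per pilot, as in the study design:
#: Pilot 1 pairs DBS wgaDNA with the whole-blood reference; Pilot 2 adds a
#: replicated reference; Pilot 3 adds triplicate small-disc DBS and an
#: amplified whole-blood control.
PILOT_DESIGNS: dict[int, dict[str, int]] = {
    1: {"DBS_2x3.2": 1, "WB_ref": 1},
    2: {"DBS_2x3.2": 1, "WB_ref": 1, "WB_ref_replica": 1},
    3: {"DBS_2x3.2": 1, "DBS_2x1.6": 3, "WB_ref": 1, "WB_WGA_ref": 1},
}

_DEFAULT_CLASS_MIX = {
    "SNP": 0.89,
    "insertion": 0.05,
    "deletion": 0.035,
    "multiallelic_complex": 0.010,
    "multiallelic_mixed": 0.015,
}

_DEFAULT_ATTENUATION = {
    "DBS_2x3.2": 0.80,
    "DBS_2x1.6": 0.78,
    "WB_WGA_ref": 0.85,
    "WB_ref": 1.0,
    "WB_ref_replica": 1.0,
}


@dataclass(slots=True)
class SimulationConfig:
    """All generative parameters for a synthetic cohort.

    Defaults describe a Pilot-2-shaped study: 8 subjects, 20,000 exome
    sites dominated by SNPs (89% — inside the observed 84-94% SNP share),
    mean site depth 60X with whole-blood samples at full depth and
    WGA-derived types attenuated to ~80%, 5% allele dropout at
    heterozygous sites in WGA types, 0.5% genotype error and up to 3%
    depth-dependent missingness.
    """

    seed: int = 0
    n_subjects: int = 8
    pilot: int = 2
    pilot_design: Optional[dict[str, int]] = None
    n_sites: int = 20_000
    class_mix: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_MIX)
    )
    #: Beta(a, b) prior for the per-site alternate allele frequency.
    af_beta: tuple[float, float] = (0.8, 0.8)
    #: Negative-binomial depth model: per-sample per-site mean and
    #: dispersion (size) parameter, scaled by a Gamma-distributed per-site
    #: factor shared across samples (capture efficiency of the site).
    depth_mean: float = 60.0
    depth_dispersion: float = 8.0
    site_depth_shape: float = 3.0
    attenuation: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ATTENUATION)
    )
    #: Marginal artifact probabilities.
    dropout_prob: float = 0.05
    error_prob: float = 0.005
    missing_prob: float = 0.03
    #: 0 = artifacts independent of depth (rates are exact marginals);
    #: 1 = artifacts fully concentrated at low-depth sites.
    artifact_depth_coupling: float = 0.8
    artifact_depth_midpoint: float = 15.0
    artifact_depth_scale: float = 4.0
    missing_depth_midpoint: float = 8.0
    missing_depth_scale: float = 2.0
    #: GQ model: correct calls get ~slope*min(depth, 30) + noise (capped at
    #: 99); artifact calls draw low GQ around ``artifact_gq_mean``.
    gq_slope: float = 3.3
    gq_noise_sd: float = 5.0
    artifact_gq_mean: float = 20.0
    artifact_gq_sd: float = 8.0
    #: Caller disagreement: per-site probabilities of HC-filtered/UG-PASS,
    #: HC-PASS/UG-filtered, HC-only and UG-only sites.
    p_hc_filtered_ug_pass: float = 0.02
    p_hc_pass_ug_filtered: float = 0.01
    p_hc_unique: float = 0.02
    p_ug_unique: float = 0.02
    #: WB_ref_replica samples may optionally join the minGQ_WB reference
    #: set; by default only WB_ref samples are the high-quality standard.
    replica_is_reference: bool = False
    #: Coverage-track targets.
    n_target_regions: int = 50
    target_region_length: int = 120

    def effective_design(self) -> dict[str, int]:
        if self.pilot_design is not None:
            return dict(self.pilot_design)
        return dict(PILOT_DESIGNS[self.pilot])

    def validate(self) -> None:
        bad: list[str] = []
        if self.n_subjects < 1:
            bad.append("n_subjects")
        if self.n_sites < 1:
            bad.append("n_sites")
        if self.pilot not in (1, 2, 3):
            bad.append("pilot")
        design = self.pilot_design or PILOT_DESIGNS.get(self.pilot, {})
        if not design:
            bad.append("pilot_design")
        for stype, reps in design.items():
            if stype not in SAMPLE_TYPES or reps < 1:
                bad.append(f"pilot_design[{stype}]")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            bad.append("class_mix")
        if set(self.class_mix) - set(_DEFAULT_CLASS_MIX):
            bad.append("class_mix")
        for name in (
            "dropout_prob",
            "error_prob",
            "missing_prob",
            "artifact_depth_coupling",
            "p_hc_filtered_ug_pass",
            "p_hc_pass_ug_filtered",
            "p_hc_unique",
            "p_ug_unique",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                bad.append(name)
        if (
            self.p_hc_filtered_ug_pass
            + self.p_hc_pass_ug_filtered
            + self.p_hc_unique
            + self.p_ug_unique
            > 1.0
        ):
            bad.append("caller disagreement probabilities (sum > 1)")
        if self.depth_mean <= 0:
            bad.append("depth_mean")
        if self.depth_dispersion <= 0:
            bad.append("depth_dispersion")
        if self.site_depth_shape <= 0:
            bad.append("site_depth_shape")
        if min(self.af_beta) <= 0:
            bad.append("af_beta")
        for stype in design:
            if self.attenuation.get(stype, 0) <= 0:
                bad.append(f"attenuation[{stype}]")
        if self.n_target_regions < 1 or self.target_region_length < 1:
            bad.append("targets")
        if bad:
            raise ValidationError(f"invalid simulation config fields: {bad}")


@dataclass(slots=True)
class TruthSet:
    """Ground truth and artifact provenance for a simulated cohort.

    ``truth_alleles[s, j]`` is the sorted allele pair of subject ``j`` at
    site ``s`` (shared by all of that subject's sample types);
    ``dropout/error/missing[s, k]`` flag which artifact, if any, fired for
    sample ``k`` at site ``s``.
    """

    subject_ids: list[str]
    sample_ids: list[str]
    site_chrom: list[str]
    site_pos: np.ndarray
    site_class: list[str]
    n_alts: np.ndarray
    truth_alleles: np.ndarray  # (n_sites, n_subjects, 2), sorted pairs
    dropout: np.ndarray  # (n_sites, n_samples) bool
    error: np.ndarray
    missing: np.ndarray

    def het_mask(self, subject_id: str) -> np.ndarray:
        j = self.subject_ids.index(subject_id)
        return self.truth_alleles[:, j, 0] != self.truth_alleles[:, j, 1]


@dataclass(slots=True)
class SimulationResult:
    hc: CallSet
    ug: CallSet
    manifest: list[SampleMeta]
    truth: TruthSet
    targets: list[tuple[str, int, int]]
    depth_tracks: dict[str, DepthTrack]
    config: SimulationConfig


# ---------------------------------------------------------------------------
# shared probability model (used by both the scalar reference observer and
# the vectorized cohort path)

def _coupling_weight(depth, midpoint: float, scale: float):
    """Logistic weight in [0, 1], ~1 at low depth, ~0 at high depth."""
    return 1.0 / (1.0 + np.exp((np.asarray(depth, dtype=float) - midpoint) / scale))


def _dropout_p(depth, cfg: SimulationConfig):
    c = cfg.artifact_depth_coupling
    w = _coupling_weight(depth, cfg.artifact_depth_midpoint, cfg.artifact_depth_scale)
    return cfg.dropout_prob * ((1.0 - c) + c * w)


def _error_p(depth, cfg: SimulationConfig):
    c = cfg.artifact_depth_coupling
    w = _coupling_weight(depth, cfg.artifact_depth_midpoint, cfg.artifact_depth_scale)
    return cfg.error_prob * ((1.0 - c) + c * w)


def _missing_p(depth, cfg: SimulationConfig):
    w = _coupling_weight(depth, cfg.missing_depth_midpoint, cfg.missing_depth_scale)
    return cfg.missing_prob * w


def _genotype_space(n_alleles: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n_alleles) for j in range(i, n_alleles)]


def _correct_gq(depth: float, noise: float, cfg: SimulationConfig) -> int:
    gq = cfg.gq_slope * min(depth, 30.0) + noise
    return int(np.clip(round(gq), 0, 99))


def _artifact_gq(noise: float, cfg: SimulationConfig) -> int:
    return int(np.clip(round(cfg.artifact_gq_mean + noise), 0, 99))


def observe_genotype(
    truth_gt: tuple[int, int],
    sample_type: str,
    site_depth: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    n_alleles: int = 2,
) -> GenotypeCall:
    """Scalar reference implementation of the observation model.

    Applies, in this fixed order: allele dropout (heterozygous truth,
    WGA-derived sample types only — dropout is an amplification artifact),
    genotype error, depth-dependent missingness; then assigns GQ.  The
    vectorized cohort simulator follows the same probability model; this
    single-call form is the contract tests exercise.
    """
    a, b = sorted(truth_gt)
    obs = (a, b)
    is_het = a != b
    dropped = False
    if is_het and sample_type in WGA_SAMPLE_TYPES:
        if rng.random() < _dropout_p(site_depth, cfg):
            keep = a if rng.random() < 0.5 else b
            obs = (keep, keep)
            dropped = True
    errored = False
    if rng.random() < _error_p(site_depth, cfg):
        space = [g for g in _genotype_space(n_alleles) if g != obs]
        obs = space[int(rng.integers(len(space)))]
        errored = True
    if rng.random() < _missing_p(site_depth, cfg):
        return GenotypeCall(sample_id="", alleles=None, gq=None, dp=int(site_depth))
    noise = rng.normal(0.0, cfg.gq_noise_sd)
    if dropped or errored:
        gq = _artifact_gq(rng.normal(0.0, cfg.artifact_gq_sd), cfg)
    else:
        gq = _correct_gq(site_depth, noise, cfg)
    return GenotypeCall(sample_id="", alleles=obs, gq=gq, dp=int(site_depth))


# ---------------------------------------------------------------------------
# cohort-level simulation

def build_manifest(cfg: SimulationConfig) -> list[SampleMeta]:
    """Roster for the configured design, in deterministic order."""
    design = cfg.effective_design()
    metas = []
    for j in range(cfg.n_subjects):
        subject = f"SUBJ{j + 1:02d}"
        for stype in SAMPLE_TYPES:  # fixed order
            if stype not in design:
                continue
            for rep in range(1, design[stype] + 1):
                is_ref = stype == "WB_ref" or (
                    cfg.replica_is_reference and stype == "WB_ref_replica"
                )
                metas.append(
                    SampleMeta(
                        sample_id=f"S{j + 1:02d}_{stype}_r{rep}",
                        subject_id=subject,
                        sample_type=stype,
                        replicate=rep,
                        pilot=cfg.pilot,
                        is_reference_standard=is_ref,
                    )
                )
    return metas


def _simulate_sites(cfg: SimulationConfig, rng: np.random.Generator):
    """Draw variant classes and REF/ALT allele strings for every site."""
    classes = list(_DEFAULT_CLASS_MIX)
    probs = np.array([cfg.class_mix.get(c, 0.0) for c in classes])
    site_class_idx = rng.choice(len(classes), size=cfg.n_sites, p=probs)
    chroms: list[str] = []
    positions = np.zeros(cfg.n_sites, dtype=int)
    refs: list[str] = []
    alts_list: list[tuple[str, ...]] = []
    site_classes: list[str] = []
    pos = 100
    for i in range(cfg.n_sites):
        cls = classes[site_class_idx[i]]
        site_classes.append(cls)
        b = _BASES[rng.integers(4)]
        other = _BASES[(_BASES.index(b) + 1 + rng.integers(3)) % 4]
        tail1 = _BASES[rng.integers(4)]
        tail2 = _BASES[rng.integers(4)]
        if cls == "SNP":
            ref, alts = b, (other,)
        elif cls == "insertion":
            ref, alts = b, (b + tail1,)
        elif cls == "deletion":
            ref, alts = b + tail1, (b,)
        elif cls == "multiallelic_complex":
            if rng.random() < 0.5:
                ref, alts = b, (b + tail1, b + tail1 + tail2)  # two insertions
            else:
                ref, alts = b + tail1 + tail2, (b, b + tail1)  # two deletions
        else:  # multiallelic_mixed: SNP + insertion
            ref, alts = b, (other, b + tail1)
        chroms.append("chr1")
        positions[i] = pos
        pos += 25
        refs.append(ref)
        alts_list.append(alts)
    return chroms, positions, refs, alts_list, site_classes


def _simulate_truth(
    cfg: SimulationConfig, n_alts: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Hardy-Weinberg truth genotypes per subject, shared across types.

    The per-site alternate allele frequency is Beta-distributed; at
    two-alt sites it splits 3:1 between the first and second alternates.
    """
    af = rng.beta(cfg.af_beta[0], cfg.af_beta[1], size=cfg.n_sites)
    p_alt2 = np.where(n_alts >= 2, 0.25 * af, 0.0)
    p_alt1 = af - p_alt2
    u = rng.random((cfg.n_sites, cfg.n_subjects, 2))
    alleles = np.zeros((cfg.n_sites, cfg.n_subjects, 2), dtype=np.int8)
    alleles[u < (p_alt1 + p_alt2)[:, None, None]] = 1
    alleles[u < p_alt2[:, None, None]] = 2
    alleles.sort(axis=2)
    return alleles


def simulate_cohort(cfg: SimulationConfig) -> SimulationResult:
    """Generate two caller-style call sets, truth, targets and depth tracks.

    Per-sample observations apply depth, dropout (WGA types only), error,
    missingness and GQ models in that order; caller disagreement then
    assigns per-site PASS/FILTERED status (or absence) to each simulated
    caller.  Deterministic under ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    manifest = build_manifest(cfg)
    subject_ids = sorted({m.subject_id for m in manifest})
    subj_index = {s: i for i, s in enumerate(subject_ids)}
    n_sites = cfg.n_sites
    n_samples = len(manifest)

    chroms, positions, refs, alts_list, site_classes = _simulate_sites(cfg, rng)
    n_alts = np.array([len(a) for a in alts_list])
    truth_alleles = _simulate_truth(cfg, n_alts, rng)

    site_factor = rng.gamma(cfg.site_depth_shape, 1.0 / cfg.site_depth_shape, n_sites)

    # genotype space lookup per n_alts value
    spaces = {k: _genotype_space(k + 1) for k in (1, 2)}

    obs_alleles = np.zeros((n_sites, n_samples, 2), dtype=np.int8)
    dropout_flags = np.zeros((n_sites, n_samples), dtype=bool)
    error_flags = np.zeros((n_sites, n_samples), dtype=bool)
    missing_flags = np.zeros((n_sites, n_samples), dtype=bool)
    depths = np.zeros((n_sites, n_samples), dtype=np.int32)
    gqs = np.zeros((n_sites, n_samples), dtype=np.int16)

    r = cfg.depth_dispersion
    for k, meta in enumerate(manifest):
        j = subj_index[meta.subject_id]
        mean = cfg.depth_mean * cfg.attenuation[meta.sample_type] * site_factor
        p = r / (r + mean)
        d = rng.negative_binomial(r, p).astype(np.int32)
        depths[:, k] = d

        ta = truth_alleles[:, j, 0].copy()
        tb = truth_alleles[:, j, 1].copy()
        het = ta != tb

        # allele dropout: amplification artifact, WGA-derived types only
        drop_u = rng.random(n_sites)
        drop_pick = rng.integers(0, 2, n_sites)
        if meta.sample_type in WGA_SAMPLE_TYPES:
            fire = het & (drop_u < _dropout_p(d, cfg))
        else:
            fire = np.zeros(n_sites, dtype=bool)
        kept = np.where(drop_pick == 0, ta, tb)
        ta = np.where(fire, kept, ta)
        tb = np.where(fire, kept, tb)
        dropout_flags[:, k] = fire

        # genotype error: uniform over the other genotypes at the site
        err_u = rng.random(n_sites)
        err_fire = err_u < _error_p(d, cfg)
        error_flags[:, k] = err_fire
        for i in np.nonzero(err_fire)[0]:
            space = spaces[int(n_alts[i])]
            current = (int(ta[i]), int(tb[i]))
            choices = [g for g in space if g != current]
            g = choices[int(rng.integers(len(choices)))]
            ta[i], tb[i] = g

        # depth-dependent missingness
        miss_u = rng.random(n_sites)
        miss_fire = miss_u < _missing_p(d, cfg)
        missing_flags[:, k] = miss_fire

        obs_alleles[:, k, 0] = ta
        obs_alleles[:, k, 1] = tb

        artifact = fire | err_fire
        gq_noise = rng.normal(0.0, cfg.gq_noise_sd, n_sites)
        art_noise = rng.normal(0.0, cfg.artifact_gq_sd, n_sites)
        gq_correct = np.clip(
            np.round(cfg.gq_slope * np.minimum(d, 30.0) + gq_noise), 0, 99
        )
        gq_art = np.clip(np.round(cfg.artifact_gq_mean + art_noise), 0, 99)
        gqs[:, k] = np.where(artifact, gq_art, gq_correct).astype(np.int16)

    # caller PASS/FILTERED assignment per site
    u = rng.random(n_sites)
    p1 = cfg.p_hc_filtered_ug_pass
    p2 = p1 + cfg.p_hc_pass_ug_filtered
    p3 = p2 + cfg.p_hc_unique
    p4 = p3 + cfg.p_ug_unique
    hc_filtered = u < p1
    ug_filtered = (u >= p1) & (u < p2)
    hc_only = (u >= p2) & (u < p3)
    ug_only = (u >= p3) & (u < p4)

    sample_ids = [m.sample_id for m in manifest]
    hc_records: list[VariantRecord] = []
    ug_records: list[VariantRecord] = []
    for i in range(n_sites):
        calls: dict[str, GenotypeCall] = {}
        for k, sid in enumerate(sample_ids):
            if missing_flags[i, k]:
                calls[sid] = GenotypeCall(
                    sample_id=sid, alleles=None, gq=None, dp=int(depths[i, k])
                )
            else:
                calls[sid] = GenotypeCall(
                    sample_id=sid,
                    alleles=(int(obs_alleles[i, k, 0]), int(obs_alleles[i, k, 1])),
                    gq=int(gqs[i, k]),
                    dp=int(depths[i, k]),
                )
        site_dp = int(depths[i].sum())
        common = dict(
            chrom=chroms[i],
            pos=int(positions[i]),
            ref=refs[i],
            alts=alts_list[i],
            site_dp=site_dp,
            calls=calls,
        )
        if not ug_only[i]:
            hc_records.append(
                VariantRecord(
                    filter_status=(
                        FilterStatus.FILTERED if hc_filtered[i] else FilterStatus.PASS
                    ),
                    source=Source.HC,
                    **common,
                )
            )
        if not hc_only[i]:
            ug_records.append(
                VariantRecord(
                    filter_status=(
                        FilterStatus.FILTERED if ug_filtered[i] else FilterStatus.PASS
                    ),
                    source=Source.UG,
                    **common,
                )
            )

    hc = CallSet(records=hc_records, roster=list(manifest), provenance="sim:HC")
    ug = CallSet(records=ug_records, roster=list(manifest), provenance="sim:UG")

    truth = TruthSet(
        subject_ids=subject_ids,
        sample_ids=sample_ids,
        site_chrom=chroms,
        site_pos=positions,
        site_class=site_classes,
        n_alts=n_alts,
        truth_alleles=truth_alleles,
        dropout=dropout_flags,
        error=error_flags,
        missing=missing_flags,
    )

    targets = make_targets(cfg)
    tracks = simulate_depth_tracks(cfg, manifest, targets, rng=rng)
    return SimulationResult(
        hc=hc,
        ug=ug,
        manifest=manifest,
        truth=truth,
        targets=targets,
        depth_tracks=tracks,
        config=cfg,
    )


def make_targets(cfg: SimulationConfig) -> list[tuple[str, int, int]]:
    """Evenly spaced capture intervals on a synthetic contig (BED coords)."""
    length = cfg.target_region_length
    targets = []
    start = 1000
    for _ in range(cfg.n_target_regions):
        targets.append(("chr1", start, start + length))
        start += length + 200
    return targets


def simulate_depth_tracks(
    cfg: SimulationConfig,
    manifest: Sequence[SampleMeta],
    targets: Sequence[tuple[str, int, int]],
    rng: Optional[np.random.Generator] = None,
) -> dict[str, DepthTrack]:
    """Per-base depth tracks over the targets, one per sample.

    Depth follows the same negative-binomial model as the call sets, with
    a Gamma region factor shared across samples (so the DBS-vs-WB coverage
    deficit is driven purely by the attenuation multipliers).
    """
    if not targets:
        raise ValidationError("simulate_depth_tracks: empty target list")
    if rng is None:
        cfg.validate()
        rng = np.random.default_rng(cfg.seed + 1)
    region_factor = rng.gamma(
        cfg.site_depth_shape, 1.0 / cfg.site_depth_shape, len(targets)
    )
    r = cfg.depth_dispersion
    tracks: dict[str, DepthTrack] = {}
    for meta in manifest:
        atten = cfg.attenuation.get(meta.sample_type, 1.0)
        regions = []
        for (chrom, start, end), factor in zip(targets, region_factor):
            mean = cfg.depth_mean * atten * factor
            p = r / (r + mean)
            depths = rng.negative_binomial(r, p, size=end - start)
            regions.append((chrom, start, end, depths.astype(int)))
        tracks[meta.sample_id] = DepthTrack(sample_id=meta.sample_id, regions=regions)
    return tracks
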