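"""End-to-end orchestration: simulate/load -> merge -> filter -> report.

A run is driven by a :class:`RunConfig` (typically loaded from YAML) and
produces, in the output directory: the merged and filtered VCFs, the merge
report, the per-record filter decision table, a variant-type summary
(counts and percentages before/after filtering), the concordance report
(mean rates per pairing, variant group and filter state, plus a
long-format table of all five category fractions), coverage statistics,
and a machine-readable run manifest with the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from dbsconcord.callset_model import (
    CallSet,
    SampleMeta,
    ValidationError,
    read_manifest,
    read_multisample_vcf,
    write_callset_vcf,
    write_manifest,
)
from dbsconcord.caller_merge import merge_caller_outputs
from dbsconcord.classify_filter import (
    FilterThresholds,
    apply_filters,
    variant_type_summary,
)
from dbsconcord.concordance import (
    PAIRING_PLANS,
    category_long_table,
    pairing_tables,
    pilot_concordance_report,
)
from dbsconcord.coverage_stats import (
    DepthTrack,
    coverage_table,
    read_depth_tsv,
    read_targets_bed,
    sample_type_boxplot,
)
from dbsconcord.synthetic_data import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "write_depth_tsv", "write_targets_bed"]


@dataclass(slots=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulation`` (generate a synthetic cohort) or
    ``inputs`` (paths to real hc/ug VCFs + manifest, optionally targets
    BED and a directory of per-sample depth TSVs) must be provided.
    """

    outdir: Path
    simulation: Optional[SimulationConfig] = None
    inputs: Optional[dict[str, str]] = None
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    pairing_plan: Optional[list[tuple[str, str]]] = None
    coverage_thresholds: tuple[int, ...] = (10, 30)
    coverage_mode: str = "per_base"
    seed: Optional[int] = None

    def validate(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValidationError(
                "exactly one of 'simulation' or 'inputs' must be configured"
            )
        if self.inputs is not None:
            for key in ("hc_vcf", "ug_vcf", "manifest"):
                if key not in self.inputs:
                    raise ValidationError(f"inputs missing required key {key!r}")

    @classmethod
    def from_dict(cls, data: dict, outdir: str | Path) -> "RunConfig":
        sim = None
        if "simulation" in data and data["simulation"] is not None:
            sim_data = dict(data["simulation"])
            unknown = set(sim_data) - {
                f.name for f in dataclasses.fields(SimulationConfig)
            }
            if unknown:
                raise ValidationError(f"unknown simulation fields: {sorted(unknown)}")
            if "pilot_design" in sim_data and sim_data["pilot_design"] is not None:
                sim_data["pilot_design"] = {
                    str(k): int(v) for k, v in sim_data["pilot_design"].items()
                }
            sim = SimulationConfig(**sim_data)
        thresholds = FilterThresholds(**data.get("thresholds", {}))
        plan = None
        if data.get("pairing_plan") is not None:
            plan = [tuple(p) for p in data["pairing_plan"]]
        seed = data.get("seed")
        if sim is not None and seed is not None:
            sim.seed = int(seed)
        return cls(
            outdir=Path(outdir),
            simulation=sim,
            inputs=data.get("inputs"),
            thresholds=thresholds,
            pairing_plan=plan,
            coverage_thresholds=tuple(data.get("coverage_thresholds", (10, 30))),
            coverage_mode=data.get("coverage_mode", "per_base"),
            seed=seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path, outdir: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data, outdir)

    def config_hash(self) -> str:
        payload = {
            "simulation": dataclasses.asdict(self.simulation)
            if self.simulation
            else None,
            "inputs": self.inputs,
            "thresholds": dataclasses.asdict(self.thresholds),
            "pairing_plan": self.pairing_plan,
            "coverage_thresholds": list(self.coverage_thresholds),
            "coverage_mode": self.coverage_mode,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def write_targets_bed(targets: Sequence[tuple[str, int, int]], path: Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in targets:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_depth_tsv(track: DepthTrack, path: Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, depths in track.regions:
            for offset, depth in enumerate(depths):
                fh.write(f"{chrom}\t{start + offset + 1}\t{int(depth)}\n")


def _default_plan(manifest: Sequence[SampleMeta]) -> list[tuple[str, str]]:
    pilots = {m.pilot for m in manifest}
    if len(pilots) != 1:
        raise ValidationError(
            "manifest spans multiple pilots; supply an explicit pairing plan"
        )
    pilot = pilots.pop()
    types = {m.sample_type for m in manifest}
    plan = [
        (a, b) for a, b in PAIRING_PLANS[pilot] if a in types and b in types
    ]
    if not plan:
        raise ValidationError(f"no default pairing applies to pilot {pilot} manifest")
    return plan


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full evaluation and write all tables to ``cfg.outdir``.

    Returns a summary dict holding the in-memory DataFrames and key counts
    so callers (tests, the acceptance script) can assert on results without
    re-reading files.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    tracks: dict[str, DepthTrack] = {}
    targets = None
    if cfg.simulation is not None:
        logger.info("stage simulate: %d subjects, %d sites",
                    cfg.simulation.n_subjects, cfg.simulation.n_sites)
        sim = simulate_cohort(cfg.simulation)
        manifest = sim.manifest
        hc, ug = sim.hc, sim.ug
        targets = sim.targets
        tracks = sim.depth_tracks
        write_manifest(manifest, outdir / "manifest.tsv")
        write_callset_vcf(hc, outdir / "hc.vcf")
        write_callset_vcf(ug, outdir / "ug.vcf")
        write_targets_bed(targets, outdir / "targets.bed")
        depth_dir = outdir / "depths"
        depth_dir.mkdir(exist_ok=True)
        for sid, track in tracks.items():
            write_depth_tsv(track, depth_dir / f"{sid}.tsv")
    else:
        manifest = read_manifest(cfg.inputs["manifest"])
        hc = read_multisample_vcf(cfg.inputs["hc_vcf"], manifest, "HC")
        ug = read_multisample_vcf(cfg.inputs["ug_vcf"], manifest, "UG")
        if cfg.inputs.get("targets_bed"):
            targets = read_targets_bed(cfg.inputs["targets_bed"])
            depth_dir = cfg.inputs.get("depth_dir")
            if depth_dir:
                for m in manifest:
                    tsv = Path(depth_dir) / f"{m.sample_id}.tsv"
                    if tsv.exists():
                        tracks[m.sample_id] = read_depth_tsv(tsv, targets, m.sample_id)

    logger.info("stage merge: hc=%d ug=%d records", len(hc), len(ug))
    merged, merge_report = merge_caller_outputs(hc, ug)
    write_callset_vcf(merged, outdir / "merged.vcf")
    pd.DataFrame([merge_report.to_dict()]).to_csv(
        outdir / "merge_report.tsv", sep="\t", index=False
    )
    logger.info("stage merge: %d merged records", len(merged))

    summary_before = variant_type_summary(merged)
    filtered, decisions = apply_filters(merged, cfg.thresholds)
    logger.info("stage filter: %d -> %d records", len(merged), len(filtered))
    write_callset_vcf(filtered, outdir / "filtered.vcf")
    decisions.to_csv(outdir / "filter_decisions.tsv", sep="\t", index=False)
    summary_after = variant_type_summary(filtered)
    variant_summary = summary_before.merge(
        summary_after, on="reporting_group", suffixes=("_before", "_after")
    )
    variant_summary.to_csv(outdir / "variant_summary.tsv", sep="\t", index=False)

    plan = cfg.pairing_plan or _default_plan(manifest)
    logger.info("stage concordance: plan=%s", plan)
    report = pilot_concordance_report(merged, filtered, manifest, plan)
    report.to_csv(outdir / "concordance_rates.tsv", sep="\t", index=False)
    tables = pairing_tables(merged, manifest, plan, "RAW") + pairing_tables(
        filtered, manifest, plan, "FILTERED"
    )
    categories = category_long_table(tables)
    categories.to_csv(outdir / "concordance_categories.tsv", sep="\t", index=False)

    coverage = None
    boxplots = None
    if tracks:
        coverage = coverage_table(
            tracks, manifest, cfg.coverage_thresholds, mode=cfg.coverage_mode
        )
        coverage.to_csv(outdir / "coverage.tsv", sep="\t", index=False)
        thr = max(cfg.coverage_thresholds)
        by_type = {
            stype: coverage.loc[
                coverage["sample_type"] == stype, f"pct_gt_{thr}x"
            ].tolist()
            for stype in sorted({m.sample_type for m in manifest})
        }
        boxplots = sample_type_boxplot(by_type)
        pd.DataFrame(
            [
                {
                    "sample_type": stype,
                    "threshold": thr,
                    "median": s.median,
                    "q1": s.q1,
                    "q3": s.q3,
                    "whisker_low": s.whisker_low,
                    "whisker_high": s.whisker_high,
                    "n_outliers": len(s.outliers),
                }
                for stype, s in boxplots.items()
            ]
        ).to_csv(outdir / "coverage_boxplot.tsv", sep="\t", index=False)

    run_manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed
        if cfg.seed is not None
        else (cfg.simulation.seed if cfg.simulation else None),
        "n_merged": len(merged),
        "n_filtered": len(filtered),
        "outputs": sorted(
            {p.name for p in outdir.iterdir() if p.is_file()} | {"run_manifest.json"}
        ),
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2, sort_keys=True)

    return {
        "manifest": manifest,
        "merged": merged,
        "filtered": filtered,
        "merge_report": merge_report,
        "variant_summary": variant_summary,
        "decisions": decisions,
        "concordance": report,
        "categories": categories,
        "coverage": coverage,
        "boxplots": boxplots,
        "run_manifest": run_manifest,
    }
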