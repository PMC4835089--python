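"""Exome coverage-by-depth statistics and box-plot summaries.

For each sample the percentage of target bases with depth strictly above a
threshold (conventionally 30X for confident diploid genotype calls, 10X as
a permissive floor) is computed over the capture intervals, and the
per-sample-type distributions are summarised Tukey-style (median,
quartiles by linear interpolation, whiskers at the most extreme points
within 1.5 x IQR of the quartiles, outliers beyond).

BED inputs are 0-based half-open; per-base depth tables are 1-based
(chrom, pos, depth), the dialect of ``samtools depth``.  Target positions
absent from a depth table count as depth 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from dbsconcord.callset_model import ParseError, SampleMeta, ValidationError

__all__ = [
    "DepthTrack",
    "BoxplotSummary",
    "read_targets_bed",
    "read_depth_tsv",
    "fraction_above_depth",
    "boxplot_summary",
    "sample_type_boxplot",
    "coverage_delta",
    "coverage_table",
]


@dataclass(slots=True)
class DepthTrack:
    """Per-base depth over the target intervals for one sample.

    ``regions`` holds (chrom, start, end, depths) with BED coordinates
    (0-based half-open) and ``len(depths) == end - start``.
    """

    sample_id: str
    regions: list[tuple[str, int, int, np.ndarray]]

    def __post_init__(self) -> None:
        for chrom, start, end, depths in self.regions:
            if end <= start:
                raise ValidationError(f"{chrom}:{start}-{end}: empty region")
            if len(depths) != end - start:
                raise ValidationError(
                    f"{chrom}:{start}-{end}: depth vector length {len(depths)} "
                    f"!= region span {end - start}"
                )

    @property
    def n_bases(self) -> int:
        return sum(end - start for _, start, end, _ in self.regions)

    def all_depths(self) -> np.ndarray:
        if not self.regions:
            return np.zeros(0, dtype=int)
        return np.concatenate([d for _, _, _, d in self.regions])


@dataclass(slots=True)
class BoxplotSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]


def read_targets_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a BED3 target file (0-based half-open intervals)."""
    targets = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 BED columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if end <= start or start < 0:
                raise ParseError(f"{path}: line {lineno}: invalid interval {start}-{end}")
            targets.append((chrom, start, end))
    return targets


def read_depth_tsv(
    path: str | Path,
    targets: Sequence[tuple[str, int, int]],
    sample_id: str,
) -> DepthTrack:
    """Build a DepthTrack from a (chrom, 1-based pos, depth) table.

    Positions inside targets that the table omits get depth 0; positions
    outside the targets are ignored.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "pos", "depth"],
            dtype={"chrom": str, "pos": int, "depth": int},
            comment="#",
        )
    except (ValueError, OSError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: cannot parse depth table: {exc}") from exc

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        by_chrom[str(chrom)] = (
            sub["pos"].to_numpy(),
            sub["depth"].to_numpy(),
        )
    regions = []
    for chrom, start, end in targets:
        depths = np.zeros(end - start, dtype=int)
        if chrom in by_chrom:
            pos, dep = by_chrom[chrom]
            # 1-based pos p covers 0-based offset p-1-start
            mask = (pos >= start + 1) & (pos <= end)
            depths[pos[mask] - 1 - start] = dep[mask]
        regions.append((chrom, start, end, depths))
    return DepthTrack(sample_id=sample_id, regions=regions)


def fraction_above_depth(
    track: DepthTrack, threshold: int, mode: str = "per_base"
) -> float:
    """Percent of the target covered at depth strictly above ``threshold``.

    ``mode="per_base"`` (default) counts target bases with depth >
    threshold; ``mode="region_mean"`` counts whole regions whose mean
    depth > threshold.  Both use a strict inequality.
    """
    if not track.regions:
        raise ValidationError(f"{track.sample_id}: empty depth track")
    if mode == "per_base":
        depths = track.all_depths()
        return 100.0 * float(np.count_nonzero(depths > threshold)) / len(depths)
    if mode == "region_mean":
        means = np.array([d.mean() for _, _, _, d in track.regions])
        return 100.0 * float(np.count_nonzero(means > threshold)) / len(means)
    raise ValidationError(f"unknown coverage mode {mode!r}")


def boxplot_summary(values: Sequence[float]) -> BoxplotSummary:
    """Tukey five-number summary with 1.5 x IQR whiskers.

    Quartiles use linear interpolation between order statistics; whiskers
    sit on the most extreme data points within 1.5 x IQR of the quartiles;
    everything beyond is an outlier.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("boxplot_summary: empty group")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    whisker_low = float(inside.min())
    whisker_high = float(inside.max())
    outliers = sorted(float(v) for v in arr[(arr < lo_fence) | (arr > hi_fence)])
    return BoxplotSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=whisker_low,
        whisker_high=whisker_high,
        outliers=outliers,
    )


def sample_type_boxplot(
    values_by_type: Mapping[str, Sequence[float]]
) -> dict[str, BoxplotSummary]:
    """Box-plot summary of coverage percentages per sample type."""
    out = {}
    for sample_type, values in values_by_type.items():
        if len(values) == 0:
            raise ValidationError(f"sample type {sample_type!r}: empty group")
        out[sample_type] = boxplot_summary(values)
    return out


def coverage_delta(summary_a: BoxplotSummary, summary_b: BoxplotSummary) -> float:
    """Signed difference of medians (b minus a), in percentage points."""
    return summary_b.median - summary_a.median


def coverage_table(
    tracks: Mapping[str, DepthTrack],
    manifest: Sequence[SampleMeta],
    thresholds: Sequence[int] = (10, 30),
    mode: str = "per_base",
) -> pd.DataFrame:
    """Per-sample coverage percentages at each depth threshold."""
    rows = []
    for m in manifest:
        track = tracks.get(m.sample_id)
        if track is None:
            raise ValidationError(f"no depth track for sample {m.sample_id!r}")
        row = {
            "sample_id": m.sample_id,
            "subject_id": m.subject_id,
            "sample_type": m.sample_type,
            "pilot": m.pilot,
        }
        for thr in thresholds:
            row[f"pct_gt_{thr}x"] = fraction_above_depth(track, thr, mode=mode)
        rows.append(row)
    return pd.DataFrame(rows)
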