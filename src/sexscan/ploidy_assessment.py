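"""Coverage breadth/means and the depth-ratio hemizygosity check.

A region present in one copy per diploid genome sits at about half the
genome-wide mean depth of the carrying sex; the ratio classifies the region
as absent / haploid / diploid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from sexscan.formats_io import (
    FEMALE,
    MALE,
    DepthTable,
    GenomicInterval,
    SampleSheet,
)

CALL_ABSENT = "absent"
CALL_HAPLOID = "haploid"
CALL_DIPLOID = "diploid"
CALL_AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class PloidyThresholds:
    absent_high: float = 0.05
    haploid_low: float = 0.3
    haploid_high: float = 0.7
    diploid_low: float = 0.8
    diploid_high: float = 1.2


@dataclass
class CoverageSummary:
    samples: list[str]
    breadth: dict[str, float]
    mean_depth: dict[str, float]
    group_mean_depth: dict[str, float]
    breadth_min_depth: int

    def group_breadth_range(self) -> tuple[float, float]:
        values = list(self.breadth.values())
        return min(values), max(values)


@dataclass(frozen=True)
class PloidyCall:
    region: GenomicInterval
    sex: str
    region_mean: float
    genome_mean: float
    ratio: float
    call: str


def coverage_summary(
    tables: Mapping[str, DepthTable],
    sheet: SampleSheet,
    breadth_min_depth: int = 1,
) -> CoverageSummary:
    """Per-sample breadth (fraction of positions at depth >=
    ``breadth_min_depth``) and mean depth, plus per-sex group means.

    Expects dense tables (zero-depth positions explicit) — breadth is
    meaningless on sparse input.
    """
    if not tables or all(t.n_positions == 0 for t in tables.values()):
        raise ValueError("coverage_summary requires a non-empty depth table set")
    samples = next(iter(tables.values())).samples
    total = sum(t.n_positions for t in tables.values())
    covered = np.zeros(len(samples), dtype=np.int64)
    depth_sum = np.zeros(len(samples), dtype=np.float64)
    for table in tables.values():
        if table.samples != samples:
            raise ValueError("inconsistent sample columns across contigs")
        covered += (table.depth >= breadth_min_depth).sum(axis=0)
        depth_sum += table.depth.sum(axis=0)
    breadth = {s: covered[i] / total for i, s in enumerate(samples)}
    means = {s: depth_sum[i] / total for i, s in enumerate(samples)}
    group_means = {}
    for sex in (FEMALE, MALE):
        members = [s for s in samples if sheet.entries.get(s) == sex]
        if members:
            group_means[sex] = float(np.mean([means[s] for s in members]))
    return CoverageSummary(
        samples=list(samples),
        breadth=breadth,
        mean_depth=means,
        group_mean_depth=group_means,
        breadth_min_depth=breadth_min_depth,
    )


def region_depth_ratio(
    region: GenomicInterval,
    tables: Mapping[str, DepthTable],
    sheet: SampleSheet,
    sex: str,
    thresholds: PloidyThresholds | None = None,
) -> PloidyCall:
    """Ratio of region mean depth to genome-wide mean depth in ``sex``, and
    the resulting copy-number call."""
    thresholds = thresholds or PloidyThresholds()
    if region.contig not in tables:
        raise ValueError(f"region contig {region.contig!r} not in depth tables")
    members = sheet.group(sex)
    if not members:
        raise ValueError(f"no samples of sex {sex}")
    summary = coverage_summary(tables, sheet)
    genome_mean = summary.group_mean_depth[sex]
    if genome_mean == 0:
        raise ValueError("genome-wide mean depth is zero; ratio undefined")
    sub = tables[region.contig].subset(region)
    if sub.n_positions == 0:
        raise ValueError("region has no positions in the depth table")
    region_mean = float(sub.sample_columns(members).mean())
    ratio = region_mean / genome_mean
    return PloidyCall(
        region=region,
        sex=sex,
        region_mean=region_mean,
        genome_mean=genome_mean,
        ratio=ratio,
        call=classify_ratio(ratio, thresholds),
    )


def classify_ratio(ratio: float, thresholds: PloidyThresholds | None = None) -> str:
    t = thresholds or PloidyThresholds()
    if ratio <= t.absent_high:
        return CALL_ABSENT
    if t.haploid_low <= ratio <= t.haploid_high:
        return CALL_HAPLOID
    if t.diploid_low <= ratio <= t.diploid_high:
        return CALL_DIPLOID
    return CALL_AMBIGUOUS
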