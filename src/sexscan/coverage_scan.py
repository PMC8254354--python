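"""Per-position sex-differential depth scan.

Each position is classified by comparing female and male depth vectors with
Welch's t-test plus presence/absence rules; maximal runs of sex-specific
positions are merged into regions and filtered by a minimum length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from sexscan.formats_io import (
    FEMALE,
    MALE,
    DepthTable,
    GenomicInterval,
    SampleSheet,
)

STATUS_FEMALE = "female_specific"
STATUS_MALE = "male_specific"
STATUS_SHARED = "shared"
STATUS_LOW = "low_coverage"

_STATUS_CODES = {STATUS_LOW: 0, STATUS_SHARED: 1, STATUS_FEMALE: 2, STATUS_MALE: 3}
_CODE_STATUS = {v: k for k, v in _STATUS_CODES.items()}


@dataclass(frozen=True)
class ScanConfig:
    """Thresholds of the scan; defaults mirror the published procedure."""

    min_group_depth: float = 5.0
    p_threshold: float = 1e-4
    min_region_length_bp: int = 51  # "larger than 50 bp"
    absent_max_depth: int = 0
    # bridge isolated positions whose group mean dips under the coverage
    # gate by sampling noise; 0 restores strict contiguity
    merge_gap_bp: int = 10
    target_sex: str = FEMALE

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0, 1)")
        if min(self.min_group_depth, self.min_region_length_bp, self.absent_max_depth, self.merge_gap_bp) < 0:
            raise ValueError("thresholds must be >= 0")
        if self.target_sex not in {FEMALE, MALE}:
            raise ValueError("target_sex must be F or M")


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class PositionCall:
    position: int
    mean_f: float
    mean_m: float
    var_f: float
    var_m: float
    max_f: int
    max_m: int
    welch: WelchResult | None
    status: str


@dataclass(frozen=True)
class SexSpecificRegion:
    interval: GenomicInterval
    target_sex: str
    mean_depth_present: float
    frac_significant: float
    n_positions: int

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class ContigReport:
    contig: str
    n_positions: int
    status_counts: dict[str, int]
    n_tests: int
    regions: list[SexSpecificRegion] = field(default_factory=list)


def welch_t(values_a: Sequence[float], values_b: Sequence[float]) -> WelchResult:
    """Welch's two-sided t-test with Satterthwaite degrees of freedom.

    Zero-variance-in-both-groups cases are handled explicitly: equal means
    give (t=0, p=1); differing means give a degenerate result with p=nan,
    left to presence/absence rules downstream.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("welch_t requires >= 2 observations per group")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sa, sb = va / len(a), vb / len(b)
    se2 = sa + sb
    if se2 == 0.0:
        if ma == mb:
            return WelchResult(t=0.0, df=float(len(a) + len(b) - 2), p=1.0)
        return WelchResult(t=math.inf if ma > mb else -math.inf, df=math.nan, p=math.nan, degenerate=True)
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t=t, df=df, p=min(p, 1.0))


def classify_position(
    depths_f: Sequence[float],
    depths_m: Sequence[float],
    config: ScanConfig,
    position: int = 0,
) -> PositionCall:
    """Classify one position as female_specific / male_specific / shared /
    low_coverage from the two per-sample depth vectors."""
    f = np.asarray(depths_f, dtype=float)
    m = np.asarray(depths_m, dtype=float)
    mean_f, mean_m = float(f.mean()), float(m.mean())
    var_f, var_m = float(f.var(ddof=1)), float(m.var(ddof=1))
    max_f, max_m = int(f.max()), int(m.max())
    welch = welch_t(f, m)
    status = _status_scalar(mean_f, mean_m, max_f, max_m, welch, config)
    return PositionCall(
        position=position,
        mean_f=mean_f,
        mean_m=mean_m,
        var_f=var_f,
        var_m=var_m,
        max_f=max_f,
        max_m=max_m,
        welch=None if welch.degenerate else welch,
        status=status,
    )


def _status_scalar(
    mean_f: float,
    mean_m: float,
    max_f: int,
    max_m: int,
    welch: WelchResult,
    config: ScanConfig,
) -> str:
    if mean_f < config.min_group_depth and mean_m < config.min_group_depth:
        return STATUS_LOW
    # Sex-specificity requires the absent group identically at or below
    # absent_max_depth; that perfect presence/absence split counts as
    # significant on its own (the t-test is degenerate when the absent group
    # has zero variance, and underpowered at small n), so p does not gate
    # the call. p is still computed and reported per position.
    if mean_f >= config.min_group_depth and max_m <= config.absent_max_depth:
        return STATUS_FEMALE
    if mean_m >= config.min_group_depth and max_f <= config.absent_max_depth:
        return STATUS_MALE
    return STATUS_SHARED


def _classify_matrix(
    depth_f: np.ndarray, depth_m: np.ndarray, config: ScanConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized classifier over a (n_positions, n_samples) pair of depth
    matrices. Returns (status codes, significance mask). Must agree exactly
    with classify_position; tests enforce the equivalence."""
    nf, nm = depth_f.shape[1], depth_m.shape[1]
    mean_f = depth_f.mean(axis=1)
    mean_m = depth_m.mean(axis=1)
    var_f = depth_f.var(axis=1, ddof=1)
    var_m = depth_m.var(axis=1, ddof=1)
    max_f = depth_f.max(axis=1)
    max_m = depth_m.max(axis=1)

    sa, sb = var_f / nf, var_m / nm
    se2 = sa + sb
    defined = se2 > 0.0
    t = np.zeros_like(se2)
    p = np.ones_like(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t[defined] = (mean_f[defined] - mean_m[defined]) / np.sqrt(se2[defined])
        df = se2[defined] ** 2 / (
            sa[defined] ** 2 / (nf - 1) + sb[defined] ** 2 / (nm - 1)
        )
        p[defined] = np.minimum(2.0 * stats.t.sf(np.abs(t[defined]), df), 1.0)
    degenerate = (~defined) & (mean_f != mean_m)
    p[degenerate] = np.nan

    low = (mean_f < config.min_group_depth) & (mean_m < config.min_group_depth)
    female = (
        ~low
        & (mean_f >= config.min_group_depth)
        & (max_m <= config.absent_max_depth)
    )
    male = (
        ~low
        & ~female
        & (mean_m >= config.min_group_depth)
        & (max_f <= config.absent_max_depth)
    )
    codes = np.full(len(mean_f), _STATUS_CODES[STATUS_SHARED], dtype=np.int8)
    codes[low] = _STATUS_CODES[STATUS_LOW]
    codes[female] = _STATUS_CODES[STATUS_FEMALE]
    codes[male] = _STATUS_CODES[STATUS_MALE]
    sig_and_defined = defined & (p < config.p_threshold)
    return codes, sig_and_defined


def merge_calls(calls: Sequence[PositionCall], config: ScanConfig) -> list[SexSpecificRegion]:
    """Merge sorted position calls into maximal target-status runs, allowing
    internal non-target gaps of at most ``merge_gap_bp``; drop runs shorter
    than ``min_region_length_bp``."""
    positions = [c.position for c in calls]
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ValueError("calls must be sorted by strictly increasing position")
    target = STATUS_FEMALE if config.target_sex == FEMALE else STATUS_MALE
    regions: list[SexSpecificRegion] = []
    run: list[PositionCall] = []
    for call in calls:
        if call.status != target:
            continue
        if run and call.position - run[-1].position - 1 > config.merge_gap_bp:
            _flush_run(run, calls, config, target, regions)
            run = []
        run.append(call)
    _flush_run(run, calls, config, target, regions)
    return regions


def _flush_run(
    run: list[PositionCall],
    calls: Sequence[PositionCall],
    config: ScanConfig,
    target: str,
    out: list[SexSpecificRegion],
    contig: str = "",
) -> None:
    if not run:
        return
    start, end = run[0].position, run[-1].position
    if end - start + 1 < config.min_region_length_bp:
        return
    present_means = [c.mean_f if target == STATUS_FEMALE else c.mean_m for c in run]
    n_sig = sum(
        1 for c in run if c.welch is not None and not math.isnan(c.welch.p) and c.welch.p < config.p_threshold
    )
    out.append(
        SexSpecificRegion(
            interval=GenomicInterval(contig or "unknown", start, end),
            target_sex=config.target_sex,
            mean_depth_present=float(np.mean(present_means)),
            frac_significant=n_sig / len(run),
            n_positions=len(run),
        )
    )


def _merge_codes(
    contig: str,
    positions: np.ndarray,
    codes: np.ndarray,
    sig: np.ndarray,
    present_mean: np.ndarray,
    config: ScanConfig,
) -> list[SexSpecificRegion]:
    target_code = _STATUS_CODES[STATUS_FEMALE if config.target_sex == FEMALE else STATUS_MALE]
    idx = np.flatnonzero(codes == target_code)
    regions: list[SexSpecificRegion] = []
    if len(idx) == 0:
        return regions
    pos = positions[idx]
    breaks = np.flatnonzero(np.diff(pos) - 1 > config.merge_gap_bp)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(pos) - 1]))
    for s, e in zip(starts, ends):
        start, end = int(pos[s]), int(pos[e])
        if end - start + 1 < config.min_region_length_bp:
            continue
        members = idx[s : e + 1]
        regions.append(
            SexSpecificRegion(
                interval=GenomicInterval(contig, start, end),
                target_sex=config.target_sex,
                mean_depth_present=float(present_mean[members].mean()),
                frac_significant=float(sig[members].mean()),
                n_positions=len(members),
            )
        )
    return regions


def scan(
    tables: Mapping[str, DepthTable],
    sheet: SampleSheet,
    config: ScanConfig | None = None,
) -> tuple[list[SexSpecificRegion], list[ContigReport]]:
    """Run the full per-contig scan: classify every position, merge runs of
    the target status, and report per-status position counts."""
    config = config or ScanConfig()
    sheet.require_scannable()
    regions: list[SexSpecificRegion] = []
    reports: list[ContigReport] = []
    for contig in sorted(tables):
        table = tables[contig]
        depth_f = table.sample_columns(sheet.females).astype(float)
        depth_m = table.sample_columns(sheet.males).astype(float)
        codes, sig = _classify_matrix(depth_f, depth_m, config)
        present = depth_f if config.target_sex == FEMALE else depth_m
        contig_regions = _merge_codes(
            contig, table.positions, codes, sig, present.mean(axis=1), config
        )
        counts = {
            status: int((codes == code).sum()) for status, code in _STATUS_CODES.items()
        }
        reports.append(
            ContigReport(
                contig=contig,
                n_positions=table.n_positions,
                status_counts={_CODE_STATUS[_STATUS_CODES[k]]: v for k, v in counts.items()},
                n_tests=int((~np.isnan(_p_defined_mask(depth_f, depth_m))).sum()) if table.n_positions else 0,
                regions=contig_regions,
            )
        )
        regions.extend(contig_regions)
    return regions, reports


def _p_defined_mask(depth_f: np.ndarray, depth_m: np.ndarray) -> np.ndarray:
    se2 = depth_f.var(axis=1, ddof=1) / depth_f.shape[1] + depth_m.var(axis=1, ddof=1) / depth_m.shape[1]
    out = np.full(len(se2), np.nan)
    out[se2 > 0] = 1.0
    return out
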