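"""Synthetic genomes and depth matrices with a planted hemizygous region.

A diploid multi-scaffold reference carries a shared locus; a second scaffold
carries a female-limited copy of that locus (copy number 1 in females, 0 in
males) derived from it by a fixed number of deletions plus point
substitutions, both kept out of conserved flank windows so a single primer
pair can bracket the variable core. Per-sample depth is drawn from a Poisson
or negative-binomial model whose mean scales with local copy number.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from sexscan.formats_io import (
    FEMALE,
    MALE,
    DepthTable,
    GenomicInterval,
    SampleSheet,
    write_depth_tsv,
    write_fasta,
    write_sample_sheet,
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimParams:
    """Layout of the simulated genome and its planted structural variant."""

    scaffold_lengths: tuple[int, ...] = (8000, 8000, 5000)
    w_region_length: int = 598
    n_deletions: int = 9
    total_deleted: int = 230
    substitution_rate: float = 0.02
    substitution_buffer: int = 5  # keep substitutions clear of deletion junctions
    conserved_flank: int = 60
    shared_locus_offset: int = 2000
    w_locus_offset: int = 2000

    @property
    def shared_locus_length(self) -> int:
        return self.w_region_length + self.total_deleted


@dataclass(frozen=True)
class GenomeLayout:
    scaffolds: tuple[tuple[str, int], ...]
    shared_locus: GenomicInterval
    w_locus: GenomicInterval

    def copy_number(self, contig: str, position: int, sex: str) -> int:
        """2 everywhere except the W locus: 1 in females, 0 in males."""
        probe = GenomicInterval(contig, position, position)
        if probe.overlaps(self.w_locus):
            return 1 if sex == FEMALE else 0
        return 2

    def swapped(self) -> "GenomeLayout":
        return self  # copy-number rule keys on sex label; swap the sheet instead


@dataclass(frozen=True)
class DepthModel:
    """Per-sample mean depth and dispersion of the count distribution.

    ``dispersion`` 0 gives Poisson; otherwise negative binomial with
    variance mean + dispersion * mean^2.
    """

    mean_depth: dict[str, float]
    dispersion: float = 0.0

    def __post_init__(self) -> None:
        if any(lam <= 0 for lam in self.mean_depth.values()):
            raise ValueError("per-sample mean depth must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    w_region: GenomicInterval
    shared_region: GenomicInterval
    deletions: tuple[tuple[int, int], ...]  # (1-based offset in shared locus, length)
    n_deletions: int
    total_deleted: int
    substitutions: int

    def to_dict(self) -> dict:
        return {
            "w_region": dataclasses.asdict(self.w_region),
            "shared_region": dataclasses.asdict(self.shared_region),
            "deletions": list(self.deletions),
            "n_deletions": self.n_deletions,
            "total_deleted": self.total_deleted,
            "substitutions": self.substitutions,
        }


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _place_deletions(
    rng: np.random.Generator, params: SimParams
) -> list[tuple[int, int]]:
    """Non-overlapping deletions (offset, length) within the shared locus,
    clear of the conserved flanks. Offsets are 1-based within the locus."""
    L = params.shared_locus_length
    usable = L - 2 * params.conserved_flank
    k = params.n_deletions
    if k == 0:
        if params.total_deleted:
            raise ValueError("total_deleted > 0 requires n_deletions >= 1")
        return []
    # k deletion lengths >= 1 summing to total_deleted, plus >= 1 bp spacers
    # between and around them inside the usable window.
    if params.total_deleted < k:
        raise ValueError("total_deleted must be >= n_deletions")
    if usable < params.total_deleted + k + 1:
        raise ValueError(
            "loci too short for the requested deletions plus conserved flanks"
        )
    cuts = np.sort(rng.choice(np.arange(1, params.total_deleted), size=k - 1, replace=False)) if k > 1 else np.array([], dtype=int)
    lengths = np.diff(np.concatenate(([0], cuts, [params.total_deleted])))
    slack = usable - params.total_deleted - (k + 1)
    extra = rng.multinomial(slack, np.full(k + 1, 1 / (k + 1))) if slack > 0 else np.zeros(k + 1, dtype=int)
    gaps = extra + 1
    deletions = []
    cursor = params.conserved_flank
    for length, gap in zip(lengths, gaps[:-1]):
        cursor += int(gap)
        deletions.append((cursor + 1, int(length)))  # 1-based offset
        cursor += int(length)
    assert cursor + int(gaps[-1]) <= L - params.conserved_flank
    return deletions


def simulate_reference(
    seed: int, params: SimParams | None = None
) -> tuple[dict[str, str], GenomeLayout, GroundTruth]:
    """Build the FASTA set, layout, and ground truth for one simulation.

    The W-locus sequence equals the shared-locus sequence with the planted
    deletions applied and substitutions added outside the conserved flanks.
    """
    params = params or SimParams()
    if params.total_deleted >= params.shared_locus_length:
        raise ValueError("total_deleted must be smaller than the shared locus")
    rng = np.random.default_rng(seed)
    names = [f"scaffold{i + 1}_sim" for i in range(len(params.scaffold_lengths))]
    seqs = {n: _random_seq(rng, L) for n, L in zip(names, params.scaffold_lengths)}

    shared_name, w_name = names[0], names[1]
    sL = params.shared_locus_length
    if params.shared_locus_offset + sL > params.scaffold_lengths[0]:
        raise ValueError("shared locus does not fit on its scaffold")
    shared_iv = GenomicInterval(
        shared_name, params.shared_locus_offset + 1, params.shared_locus_offset + sL
    )
    shared_seq = seqs[shared_name][shared_iv.start - 1 : shared_iv.end].copy()

    deletions = _place_deletions(rng, params)
    keep = np.ones(sL, dtype=bool)
    for off, length in deletions:
        keep[off - 1 : off - 1 + length] = False
    w_seq = shared_seq[keep].copy()
    assert len(w_seq) == params.w_region_length

    # substitutions only inside the variable core of the W copy, away from
    # deletion junctions (a substituted base flanking a gap can otherwise
    # split the gap in the optimal alignment and skew the gap count)
    n_subs = 0
    core = np.arange(params.conserved_flank, len(w_seq) - params.conserved_flank)
    if deletions and params.substitution_buffer > 0 and len(core):
        kept_before = np.cumsum(np.concatenate(([0], keep[:-1].astype(int))))
        blocked = np.zeros(len(w_seq), dtype=bool)
        for off, _length in deletions:
            junction = int(kept_before[off - 1])  # W index just right of the gap
            lo = max(0, junction - params.substitution_buffer)
            hi = min(len(w_seq), junction + params.substitution_buffer)
            blocked[lo:hi] = True
        core = core[~blocked[core]]
    if params.substitution_rate > 0 and len(core):
        w_seq, n_subs = _plant_substitutions(rng, shared_seq, w_seq, core, params)

    if params.w_locus_offset + len(w_seq) > params.scaffold_lengths[1]:
        raise ValueError("W locus does not fit on its scaffold")
    w_iv = GenomicInterval(
        w_name, params.w_locus_offset + 1, params.w_locus_offset + len(w_seq)
    )
    seqs[w_name][w_iv.start - 1 : w_iv.end] = w_seq

    fasta = {n: "".join(s) for n, s in seqs.items()}
    layout = GenomeLayout(
        scaffolds=tuple(zip(names, params.scaffold_lengths)),
        shared_locus=shared_iv,
        w_locus=w_iv,
    )
    truth = GroundTruth(
        w_region=w_iv,
        shared_region=shared_iv,
        deletions=tuple(deletions),
        n_deletions=len(deletions),
        total_deleted=sum(l for _, l in deletions),
        substitutions=n_subs,
    )
    return fasta, layout, truth


def _plant_substitutions(
    rng: np.random.Generator,
    shared_seq: np.ndarray,
    w_seq: np.ndarray,
    core: np.ndarray,
    params: SimParams,
    max_tries: int = 20,
) -> tuple[np.ndarray, int]:
    """Draw substitutions and verify the planted structure stays recoverable:
    the optimal global alignment of the pair must show exactly the planted
    gap count and total (a substituted base can otherwise coincidentally
    match deleted content and split a gap). Redraw on failure."""
    from sexscan.paralog_alignment import Scoring, gap_inventory, global_align

    expected_gaps = params.n_deletions
    expected_total = params.total_deleted
    shared_str = "".join(shared_seq)
    for _ in range(max_tries):
        candidate = w_seq.copy()
        hit = core[rng.random(len(core)) < params.substitution_rate]
        for i in hit:
            alternatives = _BASES[_BASES != candidate[i]]
            candidate[i] = rng.choice(alternatives)
        if len(hit) == 0:
            return candidate, 0
        aln = global_align("".join(candidate), shared_str, Scoring(), validate=False)
        inv = gap_inventory(aln)
        if (
            inv.n_gaps == expected_gaps
            and inv.total_gap_length("query") == expected_total
            and inv.total_gap_length("subject") == 0
        ):
            return candidate, len(hit)
    raise RuntimeError(
        "could not place substitutions without obscuring the planted deletions; "
        "lower substitution_rate or deletion density"
    )


def default_sample_sheet(n_f: int = 20, n_m: int = 20) -> SampleSheet:
    entries = {f"F{i + 1:02d}": FEMALE for i in range(n_f)}
    entries.update({f"M{i + 1:02d}": MALE for i in range(n_m)})
    return SampleSheet(entries)


def default_depth_model(sheet: SampleSheet, seed: int, low: float = 12.0, high: float = 15.0, dispersion: float = 0.0) -> DepthModel:
    rng = np.random.default_rng(seed)
    means = {s: float(rng.uniform(low, high)) for s in sheet.samples}
    return DepthModel(mean_depth=means, dispersion=dispersion)


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion == 0.0:
        out[pos] = rng.poisson(mean[pos])
    else:
        r = 1.0 / dispersion
        p = r / (r + mean[pos])
        out[pos] = rng.negative_binomial(r, p)
    return out


def simulate_depth(
    layout: GenomeLayout,
    sheet: SampleSheet,
    model: DepthModel,
    seed: int,
    dropout: float = 0.0,
) -> dict[str, DepthTable]:
    """Independent per-position draws with mean lambda_s * copy_number / 2.

    Copy number 0 (males inside the W locus) yields exact zeros. Optional
    uniform ``dropout`` zeroes each position/sample cell with that
    probability, a stand-in for unmappable sites.
    """
    rng = np.random.default_rng(seed)
    samples = sheet.samples
    lam = np.array([model.mean_depth[s] for s in samples])
    tables: dict[str, DepthTable] = {}
    for contig, length in layout.scaffolds:
        cn = np.full((length, len(samples)), 2.0)
        if layout.w_locus.contig == contig:
            s, e = layout.w_locus.start - 1, layout.w_locus.end
            for j, sample in enumerate(samples):
                cn[s:e, j] = 1.0 if sheet.entries[sample] == FEMALE else 0.0
        mean = lam[None, :] * cn / 2.0
        depth = _draw_counts(rng, mean, model.dispersion)
        if dropout > 0.0:
            depth[rng.random(depth.shape) < dropout] = 0
        tables[contig] = DepthTable(
            contig, np.arange(1, length + 1, dtype=np.int64), list(samples), depth
        )
    return tables


@dataclass
class FixtureBundle:
    fasta: dict[str, str]
    layout: GenomeLayout
    truth: GroundTruth
    sheet: SampleSheet
    model: DepthModel
    tables: dict[str, DepthTable]


def make_fixture(
    seed: int,
    params: SimParams | None = None,
    n_f: int = 20,
    n_m: int = 20,
    dispersion: float = 0.0,
    dropout: float = 0.0,
) -> FixtureBundle:
    """In-memory fixture: reference + cohort + depth, deterministic in seed."""
    params = params or SimParams()
    fasta, layout, truth = simulate_reference(seed, params)
    sheet = default_sample_sheet(n_f, n_m)
    model = default_depth_model(sheet, seed + 1, dispersion=dispersion)
    tables = simulate_depth(layout, sheet, model, seed + 2, dropout=dropout)
    return FixtureBundle(fasta, layout, truth, sheet, model, tables)


def make_fixture_bundle(seed: int, out_dir: str | Path, params: SimParams | None = None, n_f: int = 20, n_m: int = 20) -> Path:
    """Write a complete fixture directory: reference.fasta, depth.tsv,
    samples.tsv, truth.json. Byte-identical for identical seeds."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = make_fixture(seed, params=params, n_f=n_f, n_m=n_m)
    write_fasta(bundle.fasta, out / "reference.fasta")
    write_depth_tsv(
        [bundle.tables[c] for c in sorted(bundle.tables)], out / "depth.tsv"
    )
    write_sample_sheet(bundle.sheet, out / "samples.tsv")
    payload = {
        "seed": seed,
        "truth": bundle.truth.to_dict(),
        "scaffolds": [list(s) for s in bundle.layout.scaffolds],
        "mean_depth": bundle.model.mean_depth,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
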