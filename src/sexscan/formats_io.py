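"""Readers and writers for the plain-text formats the pipeline touches.

Coordinate convention: every interval held in memory is 1-based inclusive
(the samtools-depth dialect).  Conversion to 0-based half-open happens only
at the BED boundary, in :func:`write_bed`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

FEMALE = "F"
MALE = "M"


class FormatError(ValueError):
    """Raised on malformed input files, naming the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive interval on a named contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}: "
                "require 1 <= start <= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.end
            and other.start <= self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        """min(overlap/len(self), overlap/len(other)); 0 on different contigs."""
        ov = self.overlap_length(other)
        return min(ov / self.length, ov / other.length)


@dataclass(frozen=True)
class GenePrediction:
    gene_id: str
    cds: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.cds.length < 3:
            raise ValueError(f"CDS of {self.gene_id} shorter than one codon")


@dataclass
class SampleSheet:
    """Mapping of sample id to phenotypic sex label (F or M)."""

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sample, sex in self.entries.items():
            if sex not in {FEMALE, MALE}:
                raise ValueError(f"sample {sample!r}: sex must be F or M, got {sex!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.entries)

    def group(self, sex: str) -> list[str]:
        return [s for s, x in self.entries.items() if x == sex]

    @property
    def females(self) -> list[str]:
        return self.group(FEMALE)

    @property
    def males(self) -> list[str]:
        return self.group(MALE)

    def require_scannable(self) -> None:
        """Welch's test needs at least two samples per sex."""
        for sex in (FEMALE, MALE):
            n = len(self.group(sex))
            if n < 2:
                raise ValueError(
                    f"need >= 2 samples of sex {sex} for scanning, found {n}"
                )

    def swapped(self) -> "SampleSheet":
        flip = {FEMALE: MALE, MALE: FEMALE}
        return SampleSheet({s: flip[x] for s, x in self.entries.items()})


@dataclass
class DepthTable:
    """Per-position, per-sample read depths for one contig.

    ``depth`` has shape (n_positions, n_samples); ``positions`` are 1-based
    and strictly increasing.
    """

    contig: str
    positions: np.ndarray
    samples: list[str]
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 2 or self.depth.shape != (
            len(self.positions),
            len(self.samples),
        ):
            raise ValueError(
                f"depth shape {self.depth.shape} does not match "
                f"{len(self.positions)} positions x {len(self.samples)} samples"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in depth table")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError(f"positions not strictly increasing on {self.contig}")
        if self.depth.size and self.depth.min() < 0:
            raise ValueError(f"negative depth on {self.contig}")

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def sample_columns(self, sample_ids: Sequence[str]) -> np.ndarray:
        idx = [self.samples.index(s) for s in sample_ids]
        return self.depth[:, idx]

    def subset(self, interval: GenomicInterval) -> "DepthTable":
        if interval.contig != self.contig:
            raise ValueError(f"interval on {interval.contig}, table on {self.contig}")
        mask = (self.positions >= interval.start) & (self.positions <= interval.end)
        return DepthTable(self.contig, self.positions[mask], self.samples, self.depth[mask])

    def densify(self, contig_length: int | None = None) -> "DepthTable":
        """Fill absent positions with zero depth from 1 to contig_length
        (or to the last observed position)."""
        if contig_length is None:
            contig_length = int(self.positions[-1]) if self.n_positions else 0
        full = np.arange(1, contig_length + 1, dtype=np.int64)
        dense = np.zeros((contig_length, len(self.samples)), dtype=np.int64)
        if self.n_positions:
            dense[self.positions - 1] = self.depth
        return DepthTable(self.contig, full, self.samples, dense)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Parse a two-column TSV ``sample<TAB>sex`` with sex in {F, M}
    (case-insensitive). Lines starting with ``#`` are skipped."""
    entries: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            sample, sex = parts[0].strip(), parts[1].strip().upper()
            if sex not in {FEMALE, MALE}:
                raise FormatError(f"{path}:{lineno}: unknown sex label {parts[1]!r}")
            if sample in entries:
                raise FormatError(f"{path}:{lineno}: duplicate sample {sample!r}")
            entries[sample] = sex
    return SampleSheet(entries)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#sample\tsex\n")
        for sample, sex in sheet.entries.items():
            fh.write(f"{sample}\t{sex}\n")


def read_depth_tsv(
    path: str | Path,
    sample_ids: Sequence[str] | None = None,
    dense: bool = True,
    contig_lengths: Mapping[str, int] | None = None,
) -> dict[str, DepthTable]:
    """Parse a samtools-depth style TSV: ``contig  pos  d1 ... dn``.

    Sample column order comes from ``sample_ids`` or, if None, from a
    ``#contig  pos  s1 ... sn`` header line; it is never inferred. With
    ``dense=True`` positions missing from the file become explicit zeros
    (up to ``contig_lengths[contig]`` when provided, else the last
    observed position).
    """
    samples = list(sample_ids) if sample_ids is not None else None
    per_contig: dict[str, tuple[list[int], list[list[int]]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                header = line.lstrip("#").split("\t")
                if samples is None:
                    if len(header) < 3:
                        raise FormatError(f"{path}:{lineno}: header has no sample columns")
                    samples = [h.strip() for h in header[2:]]
                continue
            parts = line.split("\t")
            if samples is None:
                raise FormatError(
                    f"{path}: no sample_ids given and no header line found"
                )
            if len(parts) != 2 + len(samples):
                raise FormatError(
                    f"{path}:{lineno}: expected {2 + len(samples)} columns, "
                    f"got {len(parts)}"
                )
            contig = parts[0]
            try:
                pos = int(parts[1])
                depths = [int(x) for x in parts[2:]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if pos < 1:
                raise FormatError(f"{path}:{lineno}: position {pos} is not 1-based")
            if any(d < 0 for d in depths):
                raise FormatError(f"{path}:{lineno}: negative depth")
            positions, rows = per_contig.setdefault(contig, ([], []))
            if positions and pos <= positions[-1]:
                if pos == positions[-1]:
                    raise FormatError(f"{path}:{lineno}: duplicated position {contig}:{pos}")
                raise FormatError(f"{path}:{lineno}: positions out of order at {contig}:{pos}")
            positions.append(pos)
            rows.append(depths)

    if not per_contig:
        logger.warning("depth file %s is empty", path)
        return {}

    tables: dict[str, DepthTable] = {}
    assert samples is not None
    for contig, (positions, rows) in per_contig.items():
        table = DepthTable(
            contig,
            np.array(positions, dtype=np.int64),
            list(samples),
            np.array(rows, dtype=np.int64),
        )
        if dense:
            length = contig_lengths.get(contig) if contig_lengths else None
            table = table.densify(length)
        tables[contig] = table
    return tables


def write_depth_tsv(tables: Iterable[DepthTable], path: str | Path) -> None:
    """Write tables in the dialect :func:`read_depth_tsv` reads, with a
    header line carrying the sample order."""
    tables = list(tables)
    with open(path, "w") as fh:
        if tables:
            fh.write("#contig\tpos\t" + "\t".join(tables[0].samples) + "\n")
        for table in tables:
            for pos, row in zip(table.positions, table.depth):
                fh.write(f"{table.contig}\t{pos}\t" + "\t".join(map(str, row)) + "\n")


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path, names: Sequence[str] | None = None) -> None:
    """Write BED (0-based half-open): start_bed = start - 1, end_bed = end."""
    intervals = list(intervals)
    if names is None:
        names = [f"region_{i + 1}" for i in range(len(intervals))]
    with open(path, "w") as fh:
        for iv, name in zip(intervals, names):
            fh.write(f"{iv.contig}\t{iv.start - 1}\t{iv.end}\t{name}\n")


def to_bed_coords(interval: GenomicInterval) -> tuple[int, int]:
    return interval.start - 1, interval.end


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by record id, uppercased."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_gene_table(path: str | Path) -> list[GenePrediction]:
    """GFF-like TSV: ``gene_id  contig  start  end  strand`` (1-based inclusive)."""
    genes: list[GenePrediction] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            gene_id, contig, start, end, strand = parts
            genes.append(
                GenePrediction(gene_id, GenomicInterval(contig, int(start), int(end)), strand)
            )
    return genes


def write_gene_table(genes: Iterable[GenePrediction], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\tcontig\tstart\tend\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.cds.contig}\t{g.cds.start}\t{g.cds.end}\t{g.strand}\n")


def iter_tables(tables: Mapping[str, DepthTable]) -> Iterator[DepthTable]:
    for contig in sorted(tables):
        yield tables[contig]
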