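"""Paralog search, affine-gap global alignment, gap inventory, and ORFs.

The aligner is a Gotoh three-state dynamic program with integer scoring and
deterministic tie-breaking; the paralog locator is a seeded exact-k-mer
anchor chain refined by the global aligner. ORF finding and translation use
the standard genetic code on both strands.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from sexscan.formats_io import GenomicInterval

_NEG = np.int64(-(10**12))

DNA_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class Scoring:
    """Integer alignment scoring. A gap of length L costs
    gap_open + (L - 1) * gap_extend; gap_open must be <= gap_extend."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.gap_open > self.gap_extend:
            raise ValueError("gap_open must be <= gap_extend (opening at least as costly)")

    def score_pair(self, x: str, y: str) -> int:
        return self.match if x == y else self.mismatch

    def gap_cost(self, length: int) -> int:
        return 0 if length == 0 else self.gap_open + (length - 1) * self.gap_extend


@dataclass(frozen=True)
class ParalogAlignment:
    query_id: str
    subject_id: str
    aligned_query: str
    aligned_subject: str
    score: int
    scoring: Scoring

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ValueError("aligned strings must have equal length")

    @property
    def query_seq(self) -> str:
        return self.aligned_query.replace("-", "")

    @property
    def subject_seq(self) -> str:
        return self.aligned_subject.replace("-", "")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_query)

    def identity(self) -> float:
        """Identical residues over columns that are not gap-gap."""
        pairs = [
            (a, b)
            for a, b in zip(self.aligned_query, self.aligned_subject)
            if not (a == "-" and b == "-")
        ]
        if not pairs:
            return 0.0
        return sum(a == b and a != "-" for a, b in pairs) / len(pairs)


@dataclass(frozen=True)
class Gap:
    side: str  # "query" or "subject": the row carrying the gap characters
    start_column: int  # 1-based alignment column
    length: int


@dataclass(frozen=True)
class GapInventory:
    gaps: tuple[Gap, ...]

    @property
    def n_gaps(self) -> int:
        return len(self.gaps)

    def total_gap_length(self, side: str) -> int:
        return sum(g.length for g in self.gaps if g.side == side)

    @property
    def total(self) -> int:
        return sum(g.length for g in self.gaps)


@dataclass(frozen=True)
class OrfAnnotation:
    """An open reading frame; the interval is 1-based inclusive on the
    forward strand and includes the stop codon."""

    interval: GenomicInterval
    strand: str
    protein: str

    @property
    def length_aa(self) -> int:
        return len(self.protein)

    def __post_init__(self) -> None:
        if self.interval.length % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")
        if self.length_aa != self.interval.length // 3 - 1:
            raise ValueError("protein length must equal codons minus stop")


def _validate_seq(seq: str, label: str) -> str:
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in DNA_ALPHABET:
            raise ValueError(f"{label}: invalid residue {ch!r} at position {i + 1}")
    return seq


def global_align(
    a: str,
    b: str,
    scoring: Scoring | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
    validate: bool = True,
) -> ParalogAlignment:
    """Optimal global alignment under affine gap penalties (Gotoh).

    Tie-breaking is deterministic: the traceback prefers a substitution
    column over a gap, and among gaps prefers consuming the longer input.
    """
    scoring = scoring or Scoring()
    if validate:
        a = _validate_seq(a, "query")
        b = _validate_seq(b, "subject")
    else:
        a, b = a.upper(), b.upper()
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    n, m = len(a), len(b)
    open_, ext = np.int64(scoring.gap_open), np.int64(scoring.gap_extend)

    # substitution scores, vectorized over b
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    sub = np.where(av[:, None] == bv[None, :], scoring.match, scoring.mismatch).astype(np.int64)

    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)  # gap in b's row (consumes a)
    Iy = np.full((n + 1, m + 1), _NEG)  # gap in a's row (consumes b)
    M[0, 0] = 0
    Ix[1:, 0] = open_ + ext * np.arange(n, dtype=np.int64)
    Iy[0, 1:] = open_ + ext * np.arange(m, dtype=np.int64)

    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = prev_best[:-1] + sub[i - 1]
        Ix[i, :] = np.maximum(np.maximum(M[i - 1], Iy[i - 1]) + open_, Ix[i - 1] + ext)
        # Iy within-row prefix scan: a horizontal gap starts from M or Ix
        base = np.maximum(M[i], Ix[i])
        shifted = base + open_ - ext * np.arange(1, m + 2, dtype=np.int64)
        running = np.maximum.accumulate(shifted[:-1])
        Iy[i, 1:] = np.maximum(Iy[i, 1:], running + ext * np.arange(2, m + 2, dtype=np.int64) - ext)
        Iy[i, 0] = _NEG

    aligned_a, aligned_b = _traceback(a, b, M, Ix, Iy, scoring)
    score = int(max(M[n, m], Ix[n, m], Iy[n, m]))
    return ParalogAlignment(query_id, subject_id, aligned_a, aligned_b, score, scoring)


def _traceback(
    a: str, b: str, M: np.ndarray, Ix: np.ndarray, Iy: np.ndarray, scoring: Scoring
) -> tuple[str, str]:
    n, m = len(a), len(b)
    open_, ext = scoring.gap_open, scoring.gap_extend
    # state preference: substitution, then the gap consuming the longer input
    gap_pref = ("Ix", "Iy") if n >= m else ("Iy", "Ix")
    states = {"M": M, "Ix": Ix, "Iy": Iy}

    def best_state(i: int, j: int, candidates: Sequence[str]) -> str:
        avail = [s for s in candidates if states[s][i, j] > _NEG]
        top = max(states[s][i, j] for s in avail)
        for s in avail:
            if states[s][i, j] == top:
                return s
        raise AssertionError

    order = ("M",) + gap_pref
    state = best_state(n, m, order)
    i, j = n, m
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - scoring.score_pair(a[i - 1], b[j - 1])
            i, j = i - 1, j - 1
            state = _pick(states, i, j, target, order)
        elif state == "Ix":
            out_a.append(a[i - 1])
            out_b.append("-")
            val = Ix[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] > _NEG and M[i, j] + open_ == val:
                state = "M"
            elif Ix[i, j] > _NEG and Ix[i, j] + ext == val:
                state = "Ix"
            else:
                state = "Iy"
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            val = Iy[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] > _NEG and M[i, j] + open_ == val:
                state = "M"
            elif Iy[i, j] > _NEG and Iy[i, j] + ext == val:
                state = "Iy"
            else:
                state = "Ix"
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def _pick(states: Mapping[str, np.ndarray], i: int, j: int, target: int, order: Sequence[str]) -> str:
    if i == 0 and j == 0:
        return "M"
    for s in order:
        if states[s][i, j] == target:
            return s
    raise AssertionError("traceback lost the optimal path")


def gap_inventory(alignment: ParalogAlignment) -> GapInventory:
    """Maximal gap runs on each alignment row."""
    gaps: list[Gap] = []
    for side, row in (("query", alignment.aligned_query), ("subject", alignment.aligned_subject)):
        start = None
        for col, ch in enumerate(row, 1):
            if ch == "-" and start is None:
                start = col
            elif ch != "-" and start is not None:
                gaps.append(Gap(side, start, col - start))
                start = None
        if start is not None:
            gaps.append(Gap(side, start, len(row) - start + 1))
    gaps.sort(key=lambda g: g.start_column)
    return GapInventory(tuple(gaps))


# ---------------------------------------------------------------------------
# paralog search


@dataclass(frozen=True)
class ParalogHit:
    interval: GenomicInterval
    n_anchors: int


def find_paralog(
    region_seq: str,
    reference: Mapping[str, str],
    exclude: GenomicInterval | None = None,
    k: int = 15,
    min_anchors: int = 3,
    margin: int = 0,
    chain_gap: int = 1000,
) -> ParalogHit | None:
    """Locate the best paralogous interval of ``region_seq`` in the
    reference by exact k-mer anchoring: one anchor per (diagonal, query
    offset), chained per contig into clusters separated by more than
    ``chain_gap`` bp of anchor-free sequence.

    ``exclude`` masks the query's own locus so the self-hit is skipped.
    Returns None when no cluster gathers ``min_anchors`` anchors.
    """
    region_seq = _validate_seq(region_seq, "region_seq")
    if len(region_seq) < k:
        raise ValueError(f"region_seq shorter than k={k}")
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for contig, seq in reference.items():
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            index[seq[i : i + k]].append((contig, i))

    # one anchor per (contig, diagonal, query offset); s is 0-based
    per_contig: dict[str, list[int]] = defaultdict(list)
    for q in range(len(region_seq) - k + 1):
        kmer = region_seq[q : q + k]
        for contig, s in index.get(kmer, ()):
            per_contig[contig].append(s)

    candidates: list[tuple[int, str, int, int]] = []
    for contig, subject_starts in per_contig.items():
        subject_starts.sort()
        cluster: list[int] = []
        for s in subject_starts + [subject_starts[-1] + chain_gap + 1]:
            if cluster and s - cluster[-1] > chain_gap:
                _add_cluster(candidates, contig, cluster, reference, k, margin, min_anchors, exclude)
                cluster = []
            cluster.append(s)
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    n_anchors, contig, start, end = candidates[0]
    return ParalogHit(GenomicInterval(contig, start, end), n_anchors)


def _add_cluster(
    candidates: list[tuple[int, str, int, int]],
    contig: str,
    cluster: list[int],
    reference: Mapping[str, str],
    k: int,
    margin: int,
    min_anchors: int,
    exclude: GenomicInterval | None,
) -> None:
    if len(cluster) < min_anchors:
        return
    start = max(1, cluster[0] + 1 - margin)
    end = min(len(reference[contig]), cluster[-1] + k + margin)
    hit = GenomicInterval(contig, start, end)
    if exclude is not None and hit.overlaps(exclude):
        return
    candidates.append((len(cluster), contig, start, end))


# ---------------------------------------------------------------------------
# ORFs and proteins

_STOPS = {"TAA", "TAG", "TGA"}


def translate(cds: str) -> str:
    """Translate a CDS with the standard code, excluding the stop codon.
    Raises on internal stops or length not divisible by 3."""
    cds = _validate_seq(cds, "cds")
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValueError(f"internal stop codon at aa {protein.index('*') + 1}")
    return protein


def find_orfs(seq: str, min_aa: int = 30, contig: str = "seq") -> list[OrfAnnotation]:
    """ATG-to-stop ORFs of at least ``min_aa`` codons (excluding the stop),
    on both strands; nested starts sharing a stop report the longest only."""
    seq = _validate_seq(seq, "seq")
    orfs: list[OrfAnnotation] = []
    for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        for frame in range(3):
            used_stops: set[int] = set()
            i = frame
            while i + 3 <= len(s):
                if s[i : i + 3] == "ATG":
                    j = i
                    while j + 3 <= len(s):
                        codon = s[j : j + 3]
                        if codon in _STOPS:
                            if j not in used_stops:
                                used_stops.add(j)
                                aa_len = (j - i) // 3
                                if aa_len >= min_aa:
                                    orfs.append(
                                        _make_orf(seq, contig, strand, i, j + 3, s[i : j + 3])
                                    )
                            break
                        j += 3
                i += 3
    orfs.sort(key=lambda o: (o.interval.start, o.interval.end, o.strand))
    return orfs


def _make_orf(seq: str, contig: str, strand: str, start0: int, end0: int, cds: str) -> OrfAnnotation:
    if strand == "+":
        iv = GenomicInterval(contig, start0 + 1, end0)
    else:
        L = len(seq)
        iv = GenomicInterval(contig, L - end0 + 1, L - start0)
    return OrfAnnotation(interval=iv, strand=strand, protein=translate(cds))


def protein_identity(alignment: ParalogAlignment) -> float:
    """Fraction of identical residues over aligned columns, excluding
    columns where both rows are gaps."""
    return alignment.identity()


def align_proteins(p1: str, p2: str, scoring: Scoring | None = None) -> ParalogAlignment:
    """Global protein alignment with the same Gotoh machinery (identity
    scoring by default; pass a Scoring to change weights)."""
    scoring = scoring or Scoring(match=2, mismatch=-1, gap_open=-5, gap_extend=-2)
    return global_align(p1, p2, scoring=scoring, validate=False)


def format_alignment_block(alignment: ParalogAlignment, width: int = 60) -> str:
    """Human-readable block format with a match line."""
    lines = []
    qa, sa = alignment.aligned_query, alignment.aligned_subject
    for i in range(0, len(qa), width):
        q, s = qa[i : i + width], sa[i : i + width]
        match = "".join("|" if x == y and x != "-" else " " for x, y in zip(q, s))
        lines += [f"query   {q}", f"        {match}", f"subject {s}", ""]
    return "\n".join(lines)
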