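"""Primer design in conserved paralog flanks and in-silico PCR.

One primer pair placed in alignment windows identical between the two
paralogs co-amplifies both loci; the deletion-bearing copy yields a shorter
product, so genetic sex reads directly off the gel banding pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Seq import Seq


@dataclass(frozen=True)
class PrimerConstraints:
    min_len: int = 17
    max_len: int = 25
    min_gc: float = 0.4
    max_gc: float = 0.6
    max_tm_diff: float = 5.0
    min_product: int = 50
    max_product: int = 5000


@dataclass(frozen=True)
class FlankWindow:
    """A gap-free alignment window conserved between the two paralogs.

    Coordinates are 0-based offsets into each ungapped sequence; ``side``
    is "left" or "right" of the variable (gapped) core.
    """

    side: str
    column_start: int  # 1-based alignment column
    length: int
    query_offset: int
    subject_offset: int
    sequence: str  # consensus (query) sequence of the window


@dataclass(frozen=True)
class Primer:
    sequence: str  # 5'->3'
    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        return sum(c in "GC" for c in self.sequence) / len(self.sequence)

    @property
    def tm(self) -> float:
        return melting_temperature(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    forward: Primer
    reverse: Primer
    # 0-based binding offsets of the forward primer start on each template
    # (diagnostic metadata; in_silico_pcr re-derives products from sequence)
    products: dict[str, int] = field(default_factory=dict)

    @property
    def tm_difference(self) -> float:
        return abs(self.forward.tm - self.reverse.tm)

    def product_size_spread(self) -> int:
        if len(self.products) < 2:
            return 0
        sizes = sorted(self.products.values())
        return sizes[-1] - sizes[0]


@dataclass(frozen=True)
class Amplicon:
    template: str
    start: int  # 1-based inclusive on the template's forward strand
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AmpliconSet:
    amplicons: tuple[Amplicon, ...]

    def by_template(self) -> dict[str, list[Amplicon]]:
        out: dict[str, list[Amplicon]] = {}
        for amp in self.amplicons:
            out.setdefault(amp.template, []).append(amp)
        return out

    def product_lengths(self) -> dict[str, list[int]]:
        return {t: sorted(a.length for a in amps) for t, amps in self.by_template().items()}


def melting_temperature(primer: str) -> float:
    """Wallace rule for short oligos (<= 14 nt), else the GC-fraction
    formula Tm = 64.9 + 41 * (#GC - 16.4) / N."""
    primer = primer.upper()
    n = len(primer)
    gc = sum(c in "GC" for c in primer)
    at = n - gc
    if n <= 14:
        return 2.0 * at + 4.0 * gc
    return 64.9 + 41.0 * (gc - 16.4) / n


def conserved_flanks(
    aligned_query: str,
    aligned_subject: str,
    window_len: int = 18,
    max_mismatch: int = 0,
) -> list[FlankWindow]:
    """Gap-free alignment windows of ``window_len`` columns with at most
    ``max_mismatch`` mismatches, located left of the first and right of the
    last gapped column. Windows touching a gap column are rejected."""
    if len(aligned_query) != len(aligned_subject):
        raise ValueError("aligned rows must have equal length")
    ncol = len(aligned_query)
    gap_cols = [
        c for c in range(ncol) if aligned_query[c] == "-" or aligned_subject[c] == "-"
    ]
    first_gap = gap_cols[0] if gap_cols else ncol
    last_gap = gap_cols[-1] if gap_cols else -1

    # cumulative residue offsets per column
    q_off, s_off = [], []
    qc = sc = 0
    for c in range(ncol):
        q_off.append(qc)
        s_off.append(sc)
        if aligned_query[c] != "-":
            qc += 1
        if aligned_subject[c] != "-":
            sc += 1

    windows: list[FlankWindow] = []
    for start in range(ncol - window_len + 1):
        cols = range(start, start + window_len)
        if any(aligned_query[c] == "-" or aligned_subject[c] == "-" for c in cols):
            continue
        mismatches = sum(aligned_query[c] != aligned_subject[c] for c in cols)
        if mismatches > max_mismatch:
            continue
        end = start + window_len - 1
        if end < first_gap:
            side = "left"
        elif start > last_gap:
            side = "right"
        else:
            continue  # inside or straddling the variable core
        windows.append(
            FlankWindow(
                side=side,
                column_start=start + 1,
                length=window_len,
                query_offset=q_off[start],
                subject_offset=s_off[start],
                sequence="".join(aligned_query[c] for c in cols),
            )
        )
    return windows


def design_primer_pair(
    flanks: Sequence[FlankWindow],
    templates: Mapping[str, str],
    constraints: PrimerConstraints | None = None,
    max_pairs: int = 20,
) -> list[PrimerPair]:
    """Enumerate primer pairs (forward from left flanks, reverse as the
    reverse complement of right flanks) meeting length/GC constraints, then
    rank by Tm balance and, among ties, the largest product-size spread
    between templates."""
    constraints = constraints or PrimerConstraints()
    lefts = [w for w in flanks if w.side == "left"]
    rights = [w for w in flanks if w.side == "right"]
    if not lefts or not rights:
        return []

    def candidate_primers(windows: Sequence[FlankWindow], reverse: bool) -> list[str]:
        seen: set[str] = set()
        out: list[str] = []
        for w in windows:
            for L in range(constraints.min_len, min(constraints.max_len, w.length) + 1):
                for s in range(w.length - L + 1):
                    sub = w.sequence[s : s + L]
                    primer = str(Seq(sub).reverse_complement()) if reverse else sub
                    gc = sum(c in "GC" for c in primer) / L
                    if not (constraints.min_gc <= gc <= constraints.max_gc):
                        continue
                    if primer not in seen:
                        seen.add(primer)
                        out.append(primer)
        return out

    fwd_cands = candidate_primers(lefts, reverse=False)
    rev_cands = candidate_primers(rights, reverse=True)
    scored: list[tuple[float, int, PrimerPair]] = []
    for f in fwd_cands:
        for r in rev_cands:
            pair = PrimerPair(Primer(f), Primer(r))
            if pair.tm_difference > constraints.max_tm_diff:
                continue
            amps = in_silico_pcr(pair, templates, max_product=constraints.max_product)
            lengths = amps.product_lengths()
            if len(lengths) < len(templates):
                continue  # must amplify every template
            if any(len(v) != 1 for v in lengths.values()):
                continue  # one clean product per template
            if any(v[0] < constraints.min_product for v in lengths.values()):
                continue
            pair = PrimerPair(
                Primer(f), Primer(r), products={t: v[0] for t, v in lengths.items()}
            )
            scored.append((pair.tm_difference, -pair.product_size_spread(), pair))
    scored.sort(key=lambda x: (x[0], x[1], x[2].forward.sequence, x[2].reverse.sequence))
    return [p for _, _, p in scored[:max_pairs]]


def _find_all(haystack: str, needle: str, max_mismatch: int) -> list[int]:
    hits = []
    if max_mismatch == 0:
        start = haystack.find(needle)
        while start != -1:
            hits.append(start)
            start = haystack.find(needle, start + 1)
        return hits
    n = len(needle)
    for i in range(len(haystack) - n + 1):
        mism = 0
        for a, b in zip(haystack[i : i + n], needle):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            hits.append(i)
    return hits


def in_silico_pcr(
    pair: PrimerPair,
    templates: Mapping[str, str],
    max_mismatch: int = 0,
    max_product: int = 5000,
) -> AmpliconSet:
    """Predict PCR products: one primer matching the plus strand and the
    other's reverse complement downstream of it (3' ends facing), in either
    primer ordering; spans longer than ``max_product`` are dropped."""
    amplicons: list[Amplicon] = []
    f = pair.forward.sequence.upper()
    r = pair.reverse.sequence.upper()
    for name, template in templates.items():
        template = template.upper()
        for left, right, strand in (
            (f, str(Seq(r).reverse_complement()), "+"),
            (r, str(Seq(f).reverse_complement()), "-"),
        ):
            for i in _find_all(template, left, max_mismatch):
                for j in _find_all(template, right, max_mismatch):
                    start = i + 1
                    end = j + len(right)
                    if end <= i + len(left) - 1:
                        continue  # right primer not downstream
                    length = end - start + 1
                    if length <= max_product:
                        amplicons.append(Amplicon(name, start, end, strand))
    # deduplicate palindromic double-counts
    unique = sorted(set(amplicons), key=lambda a: (a.template, a.start, a.end, a.strand))
    return AmpliconSet(tuple(unique))


def predict_banding(
    genotype: str,
    locus_products: Mapping[str, int],
    shared_locus: str = "shared",
    w_locus: str = "w",
    min_rel_diff: float = 0.1,
) -> tuple[list[int], bool]:
    """Band sizes (descending) for a genotype, and whether the two bands are
    resolvable on an agarose gel (relative size difference >= min_rel_diff).

    ZZ carries only the shared locus; ZW carries both.
    """
    if genotype not in {"ZZ", "ZW"}:
        raise ValueError(f"unknown genotype {genotype!r}")
    if shared_locus not in locus_products:
        raise ValueError(f"no product for shared locus {shared_locus!r}")
    bands = [locus_products[shared_locus]]
    if genotype == "ZW":
        if w_locus not in locus_products:
            raise ValueError(f"no product for W locus {w_locus!r}")
        bands.append(locus_products[w_locus])
    bands.sort(reverse=True)
    if len(set(bands)) < 2:
        resolvable = genotype == "ZZ"  # a single band needs no resolution
    else:
        big, small = bands[0], bands[-1]
        resolvable = (big - small) / big >= min_rel_diff
    return bands, resolvable
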