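import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from sexscan.marker_design import (
    Primer,
    PrimerConstraints,
    PrimerPair,
    conserved_flanks,
    design_primer_pair,
    in_silico_pcr,
    melting_temperature,
    predict_banding,
)
from sexscan.paralog_alignment import gap_inventory, global_align

ASSAY_FWD = "CGTGTGTTGATTGGCTGA"
ASSAY_REV = "TGGCGATGAGAGCCGAGT"


def _rand_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="module")
def fixture_alignment(default_bundle):
    b = default_bundle
    t = b.truth
    w = b.fasta[t.w_region.contig][t.w_region.start - 1 : t.w_region.end]
    s = b.fasta[t.shared_region.contig][t.shared_region.start - 1 : t.shared_region.end]
    return w, s, global_align(w, s)


class TestConservedFlanks:
    def test_identical_flanks_returned(self, fixture_alignment):
        w, s, aln = fixture_alignment
        flanks = conserved_flanks(aln.aligned_query, aln.aligned_subject, window_len=20)
        sides = {f.side for f in flanks}
        assert sides == {"left", "right"}
        for f in flanks:
            assert "-" not in f.sequence
            # window sequence must occur in both inputs
            assert f.sequence in w and f.sequence in s

    def test_fully_divergent_flanks_empty(self):
        assert conserved_flanks("AAAA--TTTT", "CCCCGGGGGG", window_len=4) == []

    def test_window_spanning_gap_rejected(self):
        aligned_q = "ACGTACGT--GGGGGGGG"
        aligned_s = "ACGTACGTCCGGGGGGGG"
        flanks = conserved_flanks(aligned_q, aligned_s, window_len=6)
        for f in flanks:
            cols = range(f.column_start - 1, f.column_start - 1 + f.length)
            assert all(aligned_q[c] != "-" for c in cols)

    def test_mismatch_budget(self):
        aligned_q = "ACGTACGTAC--TTTTTTTTTT"
        aligned_s = "ACGTACGTAAGGTTTTTTTTTT"
        strict = conserved_flanks(aligned_q, aligned_s, window_len=10, max_mismatch=0)
        loose = conserved_flanks(aligned_q, aligned_s, window_len=10, max_mismatch=1)
        assert {f.side for f in strict} == {"right"}
        assert {f.side for f in loose} == {"left", "right"}


class TestTm:
    def test_wallace_short(self):
        assert melting_temperature("ACGTACGTACGT") == 2 * 6 + 4 * 6

    def test_assay_primers_are_18nt_in_bounds(self):
        constraints = PrimerConstraints()
        for p in (ASSAY_FWD, ASSAY_REV):
            assert len(p) == 18
            assert constraints.min_len <= len(p) <= constraints.max_len
        tm = melting_temperature(ASSAY_FWD)
        assert 40 < tm < 70


class TestDesign:
    def test_fixture_pair_products_differ_by_230(self, fixture_alignment):
        w, s, aln = fixture_alignment
        flanks = conserved_flanks(aln.aligned_query, aln.aligned_subject, window_len=18)
        pairs = design_primer_pair(flanks, {"w": w, "shared": s})
        assert pairs
        best = pairs[0]
        assert best.products["shared"] - best.products["w"] == 230
        assert best.product_size_spread() == 230

    def test_impossible_constraints_empty(self, fixture_alignment):
        w, s, aln = fixture_alignment
        flanks = conserved_flanks(aln.aligned_query, aln.aligned_subject, window_len=18)
        constraints = PrimerConstraints(min_gc=0.99, max_gc=1.0)
        assert design_primer_pair(flanks, {"w": w, "shared": s}, constraints) == []

    def test_no_flanks_empty(self):
        assert design_primer_pair([], {"t": "ACGT"}) == []


class TestInSilicoPcr:
    def test_coordinate_arithmetic_569(self):
        rng = np.random.default_rng(0)
        fwd, rev = ASSAY_FWD, ASSAY_REV
        # forward match starts at position 101; reverse-primer 3' end at 669
        left = _rand_dna(rng, 100)
        insert_len = 569 - len(fwd) - len(rev)
        template = left + fwd + _rand_dna(rng, insert_len) + str(Seq(rev).reverse_complement()) + _rand_dna(rng, 80)
        amps = in_silico_pcr(PrimerPair(Primer(fwd), Primer(rev)), {"t": template})
        assert [a.length for a in amps.amplicons] == [569]
        assert amps.amplicons[0].start == 101
        assert amps.amplicons[0].end == 669

    def test_absent_primers_no_products(self):
        rng = np.random.default_rng(1)
        amps = in_silico_pcr(
            PrimerPair(Primer(ASSAY_FWD), Primer(ASSAY_REV)), {"t": _rand_dna(rng, 400)}
        )
        assert amps.amplicons == ()

    def test_wrong_orientation_no_products(self):
        rng = np.random.default_rng(2)
        fwd, rev = ASSAY_FWD, ASSAY_REV
        # both primers verbatim on the plus strand: 3' ends point the same way
        template = _rand_dna(rng, 50) + fwd + _rand_dna(rng, 100) + rev + _rand_dna(rng, 50)
        amps = in_silico_pcr(PrimerPair(Primer(fwd), Primer(rev)), {"t": template})
        assert amps.amplicons == ()

    def test_max_product_cutoff(self):
        rng = np.random.default_rng(3)
        fwd, rev = ASSAY_FWD, ASSAY_REV
        template = fwd + _rand_dna(rng, 6000) + str(Seq(rev).reverse_complement())
        amps = in_silico_pcr(PrimerPair(Primer(fwd), Primer(rev)), {"t": template}, max_product=5000)
        assert amps.amplicons == ()

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=40, deadline=None)
    def test_strand_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        fwd, rev = ASSAY_FWD, ASSAY_REV
        template = (
            _rand_dna(rng, int(rng.integers(10, 80)))
            + fwd
            + _rand_dna(rng, int(rng.integers(20, 300)))
            + str(Seq(rev).reverse_complement())
            + _rand_dna(rng, int(rng.integers(10, 80)))
        )
        pair = PrimerPair(Primer(fwd), Primer(rev))
        direct = in_silico_pcr(pair, {"t": template})
        flipped = in_silico_pcr(pair, {"t": str(Seq(template).reverse_complement())})
        assert sorted(a.length for a in direct.amplicons) == sorted(
            a.length for a in flipped.amplicons
        )

    @given(seed=st.integers(0, 10**6), d=st.integers(1, 150))
    @settings(max_examples=40, deadline=None)
    def test_internal_deletion_shortens_product_by_d(self, seed, d):
        rng = np.random.default_rng(seed)
        fwd, rev = ASSAY_FWD, ASSAY_REV
        insert = _rand_dna(rng, 200)
        template = _rand_dna(rng, 30) + fwd + insert + str(Seq(rev).reverse_complement()) + _rand_dna(rng, 30)
        cut = int(rng.integers(0, 200 - d + 1))
        deleted = insert[:cut] + insert[cut + d :]
        template2 = _rand_dna(rng, 30) + fwd + deleted + str(Seq(rev).reverse_complement()) + _rand_dna(rng, 30)
        pair = PrimerPair(Primer(fwd), Primer(rev))
        L1 = in_silico_pcr(pair, {"t": template}).amplicons[0].length
        L2 = in_silico_pcr(pair, {"t": template2}).amplicons[0].length
        assert L1 - L2 == d


class TestBanding:
    def test_zw_two_bands_resolvable(self):
        bands, resolvable = predict_banding("ZW", {"shared": 569, "w": 339})
        assert bands == [569, 339]
        assert resolvable  # 230/569 ~ 0.40 >= 0.1

    def test_zz_single_band(self):
        bands, resolvable = predict_banding("ZZ", {"shared": 569, "w": 339})
        assert bands == [569]
        assert resolvable

    def test_equal_products_unresolvable(self):
        bands, resolvable = predict_banding("ZW", {"shared": 500, "w": 500})
        assert bands == [500, 500]
        assert not resolvable

    def test_unknown_genotype(self):
        with pytest.raises(ValueError, match="genotype"):
            predict_banding("XY", {"shared": 569, "w": 339})
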