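import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sexscan.coverage_scan import (
    STATUS_FEMALE,
    STATUS_LOW,
    STATUS_MALE,
    STATUS_SHARED,
    PositionCall,
    ScanConfig,
    SexSpecificRegion,
    WelchResult,
    classify_position,
    merge_calls,
    scan,
    welch_t,
)
from sexscan.formats_io import DepthTable, SampleSheet
from tests.conftest import brute_force_runs, welch_oracle


class TestWelch:
    def test_identical_groups(self):
        r = welch_t([10, 12, 14], [10, 12, 14])
        assert r.t == 0.0
        assert r.p == 1.0

    def test_matches_quadrature_oracle(self):
        a = [10, 11, 12, 13]
        b = [2, 3, 4, 5]
        r = welch_t(a, b)
        t0, df0, p0 = welch_oracle(a, b)
        assert r.t == pytest.approx(t0, abs=1e-12)
        assert r.df == pytest.approx(df0, abs=1e-12)
        assert r.p == pytest.approx(p0, abs=1e-10)

    def test_antisymmetry(self):
        a, b = [1.0, 5.0, 9.0], [2.0, 2.5, 3.0, 8.0]
        r1, r2 = welch_t(a, b), welch_t(b, a)
        assert r1.t == -r2.t
        assert r1.p == r2.p
        assert r1.df == r2.df

    def test_degenerate_zero_variance_distinct_means(self):
        r = welch_t([5, 5, 5], [0, 0, 0])
        assert r.degenerate
        assert math.isnan(r.p)
        assert r.t == math.inf

    def test_group_too_small(self):
        with pytest.raises(ValueError):
            welch_t([1], [2, 3])

    @given(
        a=st.lists(st.integers(0, 40), min_size=2, max_size=10),
        b=st.lists(st.integers(0, 40), min_size=2, max_size=10),
    )
    @settings(max_examples=60, deadline=None)
    def test_p_in_unit_interval(self, a, b):
        r = welch_t(a, b)
        if not r.degenerate:
            assert 0.0 < r.p <= 1.0
            assert r.df > 0


CFG = ScanConfig()


class TestClassify:
    def test_hemizygous_signature_is_female_specific(self):
        # female mean 6.6, males uniformly absent
        depths_f = [7, 6, 7, 6, 7, 7, 6, 7, 6, 7] * 2
        depths_f[0] = 6
        assert np.mean(depths_f) >= 5
        call = classify_position(depths_f, [0] * 20, CFG)
        assert call.status == STATUS_FEMALE

    def test_all_zero_is_low_coverage(self):
        call = classify_position([0, 0, 0], [0, 0, 0], CFG)
        assert call.status == STATUS_LOW

    def test_mean_below_gate_is_low_coverage(self):
        call = classify_position([4.9, 4.9, 4.9, 4.9], [0, 0, 0, 0], CFG)
        assert call.status == STATUS_LOW

    def test_balanced_depth_is_shared(self):
        call = classify_position([12, 13, 14, 12], [13, 12, 14, 13], CFG)
        assert call.status == STATUS_SHARED

    def test_male_specific_symmetric(self):
        call = classify_position([0, 0, 0, 0], [12, 13, 14, 15], CFG)
        assert call.status == STATUS_MALE

    def test_degenerate_presence_absence_counts_as_significant(self):
        # all females exactly 6, all males exactly 0: Welch undefined
        call = classify_position([6] * 5, [0] * 5, CFG)
        assert call.status == STATUS_FEMALE
        assert call.welch is None


def _mk_calls(positions, statuses):
    calls = []
    for p, s in zip(positions, statuses):
        calls.append(
            PositionCall(
                position=p,
                mean_f=6.0 if s == STATUS_FEMALE else 12.0,
                mean_m=0.0 if s == STATUS_FEMALE else 12.0,
                var_f=1.0,
                var_m=1.0,
                max_f=9,
                max_m=0 if s == STATUS_FEMALE else 15,
                welch=WelchResult(t=10.0, df=20.0, p=1e-9),
                status=s,
            )
        )
    return calls


class TestMerge:
    def test_no_target_positions(self):
        calls = _mk_calls(range(1, 100), [STATUS_SHARED] * 99)
        assert merge_calls(calls, CFG) == []

    def test_contiguous_run_of_61(self):
        calls = _mk_calls(range(1, 62), [STATUS_FEMALE] * 61)
        regions = merge_calls(calls, CFG)
        assert len(regions) == 1
        assert regions[0].interval.start == 1
        assert regions[0].interval.end == 61
        assert regions[0].length == 61

    def test_run_of_exactly_50_discarded(self):
        calls = _mk_calls(range(1, 51), [STATUS_FEMALE] * 50)
        assert merge_calls(calls, CFG) == []
        assert len(merge_calls(calls, ScanConfig(min_region_length_bp=50))) == 1

    def test_unsorted_input_rejected(self):
        calls = _mk_calls([5, 3], [STATUS_FEMALE] * 2)
        with pytest.raises(ValueError, match="sorted"):
            merge_calls(calls, CFG)

    def test_gap_bridged_within_merge_gap(self):
        statuses = [STATUS_FEMALE] * 40 + [STATUS_LOW] + [STATUS_FEMALE] * 40
        calls = _mk_calls(range(1, 82), statuses)
        regions = merge_calls(calls, ScanConfig(merge_gap_bp=1))
        assert len(regions) == 1
        assert regions[0].n_positions == 80  # gap position is not a member
        regions0 = merge_calls(calls, ScanConfig(merge_gap_bp=0))
        assert [r.length for r in regions0] == []  # two runs of 40 both < 51

    @given(
        n=st.integers(1, 200),
        seed=st.integers(0, 10**6),
        merge_gap=st.integers(0, 5),
        min_len=st.integers(1, 60),
    )
    @settings(max_examples=80, deadline=None)
    def test_matches_brute_force_enumeration(self, n, seed, merge_gap, min_len):
        rng = np.random.default_rng(seed)
        positions = np.sort(rng.choice(np.arange(1, 400), size=min(n, 399), replace=False))
        statuses = rng.choice(
            [STATUS_FEMALE, STATUS_SHARED, STATUS_LOW, STATUS_MALE], size=len(positions)
        )
        cfg = ScanConfig(merge_gap_bp=merge_gap, min_region_length_bp=min_len)
        got = [
            (r.interval.start, r.interval.end)
            for r in merge_calls(_mk_calls(positions, statuses), cfg)
        ]
        want = brute_force_runs(positions, statuses, STATUS_FEMALE, merge_gap, min_len)
        assert got == want


class TestScan:
    def test_recovers_planted_region(self, default_bundle):
        b = default_bundle
        regions, reports = scan(b.tables, b.sheet)
        assert len(regions) == 1
        assert regions[0].interval.reciprocal_overlap(b.truth.w_region) >= 0.95
        assert regions[0].target_sex == "F"
        total = sum(sum(r.status_counts.values()) for r in reports)
        assert total == sum(t.n_positions for t in b.tables.values())

    def test_short_planted_region_recovered(self, small_params):
        import dataclasses

        from sexscan.synthetic_data import make_fixture

        params = dataclasses.replace(
            small_params, w_region_length=134, n_deletions=3, total_deleted=40, conserved_flank=20
        )
        b = make_fixture(5, params=params)
        regions, _ = scan(b.tables, b.sheet)
        assert len(regions) == 1
        assert regions[0].interval.reciprocal_overlap(b.truth.w_region) >= 0.9

    def test_all_one_sex_rejected(self, default_bundle):
        sheet = SampleSheet({s: "M" for s in default_bundle.sheet.samples})
        with pytest.raises(ValueError, match=">= 2 samples"):
            scan(default_bundle.tables, sheet)

    def test_deterministic(self, default_bundle):
        r1, _ = scan(default_bundle.tables, default_bundle.sheet)
        r2, _ = scan(default_bundle.tables, default_bundle.sheet)
        assert r1 == r2

    def test_sex_swap_symmetry(self, default_bundle):
        b = default_bundle
        female_view, _ = scan(b.tables, b.sheet, ScanConfig(target_sex="F"))
        male_view, _ = scan(b.tables, b.sheet.swapped(), ScanConfig(target_sex="M"))
        assert [r.interval for r in female_view] == [r.interval for r in male_view]
        assert [r.n_positions for r in female_view] == [r.n_positions for r in male_view]

    def test_min_length_monotonicity(self, default_bundle):
        b = default_bundle
        counts = [
            len(scan(b.tables, b.sheet, ScanConfig(min_region_length_bp=L))[0])
            for L in (1, 51, 300, 599)
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 0  # longer than the planted region

    def test_vectorized_matches_scalar_classifier(self, default_bundle):
        b = default_bundle
        table = b.tables[b.truth.w_region.contig]
        rng = np.random.default_rng(0)
        idx = rng.choice(table.n_positions, size=60, replace=False)
        depth_f = table.sample_columns(b.sheet.females)
        depth_m = table.sample_columns(b.sheet.males)
        from sexscan.coverage_scan import _classify_matrix

        codes, _sig = _classify_matrix(depth_f.astype(float), depth_m.astype(float), CFG)
        from sexscan.coverage_scan import _CODE_STATUS

        for i in idx:
            call = classify_position(depth_f[i], depth_m[i], CFG, position=int(table.positions[i]))
            assert call.status == _CODE_STATUS[codes[i]], f"position index {i}"
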