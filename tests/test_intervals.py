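"""Interval algebra against per-base boolean-array oracles and bedtools."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ectopeak as ep
from ectopeak.intervals import (
    CoveragePartition,
    common_new_partition,
    default_min_support,
    ectopic_filter,
    intersect_bases,
    merge_intervals,
    peak_coverage,
    replicated_peaks,
    subtract_bases,
)

from conftest import bool_mask, mask_to_intervals, random_intervals

CHROM_LEN = 50_000


def ps(intervals, label="p"):
    return merge_intervals(intervals, gap=0, label=label)


class TestMerge:
    def test_empty(self):
        assert list(merge_intervals([])) == []

    def test_overlapping_pair_joined(self):
        got = merge_intervals([("c", 0, 100), ("c", 50, 150)], gap=0)
        assert got.intervals() == [ep.GenomicInterval("c", 0, 150)]

    def test_gap_joins_nearby(self):
        got = merge_intervals([("c", 0, 100), ("c", 150, 200)], gap=50)
        assert got.intervals() == [ep.GenomicInterval("c", 0, 200)]
        got = merge_intervals([("c", 0, 100), ("c", 151, 200)], gap=50)
        assert len(got) == 2

    def test_idempotent_and_order_invariant(self, rng):
        ivs = random_intervals(rng, 200, CHROM_LEN)
        merged = merge_intervals(ivs)
        again = merge_intervals(merged.intervals())
        assert merged == again
        shuffled = [ivs[i] for i in rng.permutation(len(ivs))]
        assert merge_intervals(shuffled) == merged

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            merge_intervals([("c", 100, 100)])
        with pytest.raises(ValueError):
            merge_intervals([("c", -1, 50)])

    @given(st.integers(0, 2**32 - 1))
    def test_base_set_matches_boolean_union_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ivs = random_intervals(rng, int(rng.integers(1, 60)), 10_000)
        merged = merge_intervals(ivs)
        oracle = bool_mask(ivs, 10_000)
        assert mask_to_intervals(oracle) == merged.intervals()
        assert merged.coverage == int(oracle.sum())


class TestSetOps:
    def test_intersect_self_and_disjoint(self, rng):
        a = ps(random_intervals(rng, 50, CHROM_LEN))
        _, n = intersect_bases(a, a)
        assert n == a.coverage
        b = ps([("chr2", 0, 10)])
        _, n = intersect_bases(a, b)
        assert n == 0

    def test_subtract_self_and_empty(self, rng):
        a = ps(random_intervals(rng, 50, CHROM_LEN))
        _, n = subtract_bases(a, a)
        assert n == 0
        _, n = subtract_bases(a, ep.PeakSet.empty())
        assert n == a.coverage

    @given(st.integers(0, 2**32 - 1))
    def test_matches_boolean_oracles(self, seed):
        rng = np.random.default_rng(seed)
        a = ps(random_intervals(rng, int(rng.integers(1, 50)), 10_000))
        b = ps(random_intervals(rng, int(rng.integers(1, 50)), 10_000))
        ma, mb = bool_mask(a, 10_000), bool_mask(b, 10_000)
        inter, n_inter = intersect_bases(a, b)
        assert inter.intervals() == mask_to_intervals(ma & mb)
        assert n_inter == int((ma & mb).sum())
        sub, n_sub = subtract_bases(a, b)
        assert sub.intervals() == mask_to_intervals(ma & ~mb)
        assert n_sub == int((ma & ~mb).sum())


class TestPeakCoverage:
    def test_single_interval_kb(self):
        p = ps([("c", 100, 600)])
        assert peak_coverage(p) == 500
        assert p.coverage_kb == 0.5

    def test_empty(self):
        assert peak_coverage(ep.PeakSet.empty()) == 0

    def test_unmerged_input_auto_merged(self):
        assert peak_coverage([("c", 0, 100), ("c", 50, 150)]) == 150

    def test_matches_popcount_oracle(self, rng):
        ivs = random_intervals(rng, 120, 10_000)
        assert peak_coverage(ps(ivs)) == int(bool_mask(ivs, 10_000).sum())


class TestReplicatedPeaks:
    def test_identical_replicates_full_support(self, rng):
        reps = [ps(random_intervals(rng, 30, CHROM_LEN))] * 3
        assert replicated_peaks(reps, 3) == reps[0]

    def test_two_of_three_support_dropped(self):
        reps = [
            ps([("c", 0, 100)]),
            ps([("c", 50, 150)]),
            ps([("c", 5000, 5100)]),
        ]
        # reference interval (c,0,150) touched by 2 replicates only
        assert replicated_peaks(reps, 3).is_empty
        got = replicated_peaks(reps, 2)
        assert got.intervals() == [ep.GenomicInterval("c", 0, 150)]

    def test_min_support_one_is_merged_reference(self, rng):
        reps = [ps(random_intervals(rng, 30, CHROM_LEN)) for _ in range(4)]
        union = merge_intervals([iv for r in reps for iv in r])
        assert replicated_peaks(reps, 1) == union

    def test_coverage_non_increasing_in_support(self, rng):
        reps = [ps(random_intervals(rng, 40, CHROM_LEN)) for _ in range(4)]
        covs = [replicated_peaks(reps, k).coverage for k in range(1, 5)]
        assert covs == sorted(covs, reverse=True)

    def test_out_of_range_support_rejected(self, rng):
        reps = [ps(random_intervals(rng, 5, CHROM_LEN))]
        with pytest.raises(ValueError):
            replicated_peaks(reps, 2)
        with pytest.raises(ValueError):
            replicated_peaks(reps, 0)

    @given(st.integers(0, 2**32 - 1))
    def test_matches_brute_force_support_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        reps = [ps(random_intervals(rng, int(rng.integers(1, 25)), 10_000))
                for _ in range(n)]
        k = int(rng.integers(1, n + 1))
        union = merge_intervals([iv for r in reps for iv in r])
        expected = []
        for iv in union:
            mask_ref = bool_mask([iv], 10_000)
            support = sum(
                1 for r in reps if (mask_ref & bool_mask(r, 10_000)).any()
            )
            if support >= k:
                expected.append(iv)
        assert replicated_peaks(reps, k).intervals() == expected

    def test_default_policy(self):
        assert default_min_support(4) == 3
        assert default_min_support(3) == 3
        assert default_min_support(2) == 2


class TestEctopicFilter:
    MASK = None

    @pytest.fixture(autouse=True)
    def _mask(self):
        self.mask = ps([("c", 1000, 2000)], label="cen")

    def test_peak_inside_centromere_removed(self):
        assert ectopic_filter(ps([("c", 1200, 1300)]), self.mask).is_empty

    def test_single_base_boundary_overlap_removed_whole(self):
        # straddles the left boundary by exactly one base
        assert ectopic_filter(ps([("c", 500, 1001)]), self.mask).is_empty
        # ends exactly at the boundary: zero overlap, retained
        kept = ectopic_filter(ps([("c", 500, 1000)]), self.mask)
        assert kept.intervals() == [ep.GenomicInterval("c", 500, 1000)]
        # starts exactly at the mask end: retained
        kept = ectopic_filter(ps([("c", 2000, 2100)]), self.mask)
        assert len(kept) == 1

    def test_empty_mask_is_identity_and_idempotent(self, rng):
        p = ps(random_intervals(rng, 40, CHROM_LEN))
        empty = ep.PeakSet.empty("cen")
        once = ectopic_filter(p, empty)
        assert once.intervals() == p.intervals()
        twice = ectopic_filter(ectopic_filter(p, self.mask), self.mask)
        assert twice.intervals() == ectopic_filter(p, self.mask).intervals()

    def test_unmasked_chromosome_fully_ectopic(self):
        p = ps([("chr9", 0, 500)])
        assert ectopic_filter(p, self.mask).intervals() == p.intervals()

    @given(st.integers(0, 2**32 - 1))
    def test_result_has_zero_mask_overlap(self, seed):
        rng = np.random.default_rng(seed)
        p = ps(random_intervals(rng, 50, 10_000))
        mask = ps(random_intervals(rng, 5, 10_000, max_len=1500), "cen")
        kept = ectopic_filter(p, mask)
        _, overlap = intersect_bases(kept, mask)
        assert overlap == 0
        # removed-whole semantics: every input peak is either kept intact
        # or absent, never trimmed
        kept_set = set(kept.intervals())
        assert kept_set <= set(p.intervals())


class TestPartition:
    def test_treatment_equals_control(self, rng):
        a = ps(random_intervals(rng, 40, CHROM_LEN))
        part = common_new_partition(a, a)
        assert part.new_bases == 0
        assert part.common_bases == a.coverage

    def test_disjoint(self):
        c = ps([("c", 0, 100)])
        t = ps([("c", 500, 800)])
        part = common_new_partition(c, t)
        assert part.common_bases == 0
        assert part.new_bases == 300
        assert part.control_only_bases == 100

    @given(st.integers(0, 2**32 - 1))
    def test_matches_oracle_and_conserves(self, seed):
        rng = np.random.default_rng(seed)
        c = ps(random_intervals(rng, int(rng.integers(1, 40)), 10_000))
        t = ps(random_intervals(rng, int(rng.integers(1, 40)), 10_000))
        mc, mt = bool_mask(c, 10_000), bool_mask(t, 10_000)
        part = common_new_partition(c, t)
        assert part.common_bases == int((mc & mt).sum())
        assert part.new_bases == int((mt & ~mc).sum())
        assert part.control_only_bases == int((mc & ~mt).sum())
        assert part.common_bases + part.new_bases == part.treatment_total_bases

    def test_invariant_enforced_at_construction(self):
        with pytest.raises(ValueError):
            CoveragePartition(10, 10, 0, 30)
        with pytest.raises(ValueError):
            CoveragePartition(-1, 31, 0, 30)


class TestBedtoolsCrossCheck:
    """Independent oracle: the same operations through bedtools."""

    def test_merge_and_intersect_agree_with_bedtools(self, rng, tmp_path):
        a_ivs = sorted(random_intervals(rng, 80, 20_000))
        b_ivs = sorted(random_intervals(rng, 80, 20_000))
        a_bed, b_bed = tmp_path / "a.bed", tmp_path / "b.bed"
        ep.write_bed(a_ivs, a_bed)
        ep.write_bed(b_ivs, b_bed)

        def run(cmd):
            out = subprocess.run(cmd, capture_output=True, text=True, check=True)
            ivs = []
            for line in out.stdout.splitlines():
                f = line.split("\t")
                ivs.append(ep.GenomicInterval(f[0], int(f[1]), int(f[2])))
            return ivs

        bt_merge = run(["bedtools", "merge", "-i", str(a_bed)])
        assert merge_intervals(a_ivs).intervals() == bt_merge

        am, bm = merge_intervals(a_ivs), merge_intervals(b_ivs)
        am_bed, bm_bed = tmp_path / "am.bed", tmp_path / "bm.bed"
        ep.write_bed(am, am_bed)
        ep.write_bed(bm, bm_bed)
        bt_inter = run(["bedtools", "intersect", "-a", str(am_bed),
                        "-b", str(bm_bed)])
        ours, _ = intersect_bases(am, bm)
        assert ours.intervals() == merge_intervals(bt_inter).intervals()
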