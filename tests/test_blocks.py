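"""Consensus block calling, occupancy metrics, sharing and cohort comparison."""

import numpy as np
import pytest

from conftest import mask_of, random_iset, set_from_mask
from hmcblocks.blocks import (
    PeakSet,
    block_metrics,
    call_blocks,
    classify_peak_sharing,
    cohort_specific_bases,
    cohort_specific_blocks,
    cross_tissue_overlap,
)
from hmcblocks.intervals import GenomicInterval, IntervalSet, normalize


def peaks(sample_id, pairs, cohort="fetal", reads=None):
    return PeakSet.from_raw(
        sample_id, cohort, [GenomicInterval(c, s, e) for c, s, e in pairs], reads
    )


class TestCallBlocks:
    def test_minimal_overlap_defines_block(self):
        s1 = peaks("s1", [("chr1", 100, 200)])
        s2 = peaks("s2", [("chr1", 150, 250)])
        bs = call_blocks([s1, s2], min_support=2)
        assert [(b.interval.start, b.interval.end) for b in bs] == [(150, 200)]

    def test_staggered_three_sample_example(self):
        s1 = peaks("s1", [("chr1", 0, 100), ("chr1", 300, 400)])
        s2 = peaks("s2", [("chr1", 50, 350)])
        s3 = peaks("s3", [("chr1", 80, 120)])
        bs = call_blocks([s1, s2, s3], min_support=2)
        assert [(b.interval.start, b.interval.end) for b in bs] == [
            (50, 120),
            (300, 350),
        ]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="min_support"):
            call_blocks([peaks("s1", [("chr1", 0, 10)])], min_support=2)

    def test_mixed_cohorts_rejected(self):
        s1 = peaks("s1", [("chr1", 0, 100)], cohort="fetal")
        s2 = peaks("s2", [("chr1", 0, 100)], cohort="adult")
        with pytest.raises(ValueError, match="cohort"):
            call_blocks([s1, s2])

    def test_matches_per_base_support_oracle(self, toy_genome):
        rng = np.random.default_rng(17)
        for _ in range(20):
            sets = [
                PeakSet(f"s{i}", "fetal", random_iset(rng, toy_genome, 12))
                for i in range(5)
            ]
            for k in (2, 3, 4):
                bs = call_blocks(sets, min_support=k)
                depth = {c: np.zeros(l, dtype=int) for c, l in toy_genome.chromosomes}
                for ps in sets:
                    for c, m in mask_of(ps.peaks, toy_genome).items():
                        depth[c] += m
                expected = set_from_mask({c: d >= k for c, d in depth.items()})
                assert bs.intervals == expected

    def test_min_support_monotone_shrinkage(self, toy_genome):
        rng = np.random.default_rng(29)
        sets = [
            PeakSet(f"s{i}", "adult", random_iset(rng, toy_genome, 15))
            for i in range(6)
        ]
        prev = call_blocks(sets, min_support=2).intervals
        for k in (3, 4, 5):
            cur = call_blocks(sets, min_support=k).intervals
            assert cur.subtract(prev).total_length == 0  # cur subset of prev
            prev = cur

    def test_blocks_within_peak_union(self, toy_genome):
        rng = np.random.default_rng(31)
        sets = [
            PeakSet(f"s{i}", "fetal", random_iset(rng, toy_genome, 10))
            for i in range(4)
        ]
        bs = call_blocks(sets, min_support=2)
        union = IntervalSet()
        for ps in sets:
            union = union.union(ps.peaks)
        assert bs.intervals.subtract(union).total_length == 0


class TestBlockMetrics:
    def test_full_peak_lengths_and_reads_credited(self):
        s1 = peaks("s1", [("chr1", 100, 200)], reads=[40])
        s2 = peaks("s2", [("chr1", 150, 250)], reads=[60])
        bs = call_blocks([s1, s2])
        b = bs.blocks[0]
        assert (b.n_positive, b.sum_peak_bp, b.sum_reads) == (2, 200, 100)

    def test_clipped_variant_counts_in_block_portion_only(self):
        s1 = peaks("s1", [("chr1", 100, 200)], reads=[40])
        s2 = peaks("s2", [("chr1", 150, 250)], reads=[60])
        bs = block_metrics(call_blocks([s1, s2]), [s1, s2], clip_to_block=True)
        assert bs.blocks[0].sum_peak_bp == 100  # 50 bp in-block from each peak

    def test_two_minimal_500bp_peaks(self):
        s1 = peaks("s1", [("chr1", 0, 500)])
        s2 = peaks("s2", [("chr1", 499, 999)])
        bs = call_blocks([s1, s2])
        assert bs.blocks[0].sum_peak_bp == 1000
        assert bs.blocks[0].sum_reads == 0  # reads absent

    def test_matches_exhaustive_overlap_oracle(self, toy_genome):
        rng = np.random.default_rng(37)
        for _ in range(10):
            isets = [random_iset(rng, toy_genome, 10) for _ in range(4)]
            sets = [
                PeakSet(f"s{i}", "fetal", s, rng.integers(1, 100, size=len(s)))
                for i, s in enumerate(isets)
            ]
            bs = call_blocks(sets, min_support=2)
            for b in bs.blocks:
                n_pos = bp = rd = 0
                for ps in sets:
                    hit = False
                    for p_idx, pk in enumerate(ps.peaks):
                        ov = min(pk.end, b.interval.end) - max(pk.start, b.interval.start)
                        if pk.chrom == b.interval.chrom and ov > 0:
                            hit = True
                            bp += pk.length
                            rd += int(ps.reads[p_idx])
                    n_pos += hit
                assert (b.n_positive, b.sum_peak_bp, b.sum_reads) == (n_pos, bp, rd)
                assert b.n_positive >= bs.min_support


class TestPeakSharing:
    def test_identical_peaks_fully_shared(self):
        s1 = peaks("s1", [("chr1", 0, 100)])
        s2 = peaks("s2", [("chr1", 0, 100)])
        res = classify_peak_sharing([s1, s2])
        assert res["histogram"] == {2: 2}
        assert res["unique_fraction"] == 0.0
        assert res["shared_by_all_fraction"] == 1.0

    def test_disjoint_peaks_all_unique(self):
        s1 = peaks("s1", [("chr1", 0, 100)])
        s2 = peaks("s2", [("chr1", 200, 300)])
        res = classify_peak_sharing([s1, s2])
        assert res["histogram"] == {1: 2}
        assert res["unique_fraction"] == 1.0

    def test_fractions_sum_to_one(self, toy_genome):
        rng = np.random.default_rng(41)
        sets = [
            PeakSet(f"s{i}", "fetal", random_iset(rng, toy_genome, 12))
            for i in range(4)
        ]
        res = classify_peak_sharing(sets)
        assert sum(res["histogram"].values()) == res["n_peaks"]

    def test_matches_quadratic_overlap_oracle(self, toy_genome):
        rng = np.random.default_rng(43)
        sets = [
            PeakSet(f"s{i}", "fetal", random_iset(rng, toy_genome, 10))
            for i in range(3)
        ]
        res = classify_peak_sharing(sets)
        hist: dict[int, int] = {}
        for i, ps in enumerate(sets):
            for pk in ps.peaks:
                deg = 1
                for j, other in enumerate(sets):
                    if j == i:
                        continue
                    if any(
                        o.chrom == pk.chrom and min(o.end, pk.end) > max(o.start, pk.start)
                        for o in other.peaks
                    ):
                        deg += 1
                hist[deg] = hist.get(deg, 0) + 1
        assert res["histogram"] == hist


class TestCohortComparison:
    def make(self, pairs, cohort="fetal"):
        from hmcblocks.blocks import Block, BlockSet

        return BlockSet(
            cohort, 2, [Block(GenomicInterval(c, s, e), 2, 0, 0) for c, s, e in pairs]
        )

    def test_overlapping_block_is_not_exclusive(self):
        a = self.make([("chr1", 100, 200)])
        b = self.make([("chr1", 150, 250)], "adult")
        a_only, b_only, shared = cohort_specific_blocks(a, b)
        assert len(a_only) == 0 and len(b_only) == 0 and len(shared) == 1

    def test_disjoint_blocks_are_exclusive(self):
        a = self.make([("chr1", 100, 200)])
        b = self.make([("chr1", 300, 400)], "adult")
        a_only, b_only, shared = cohort_specific_blocks(a, b)
        assert len(a_only) == 1 and len(b_only) == 1 and shared == []

    def test_partition_verified_by_overlap_oracle(self, toy_genome):
        rng = np.random.default_rng(47)
        for _ in range(10):
            a = self.make(
                [(i.chrom, i.start, i.end) for i in random_iset(rng, toy_genome, 15)]
            )
            b = self.make(
                [(i.chrom, i.start, i.end) for i in random_iset(rng, toy_genome, 15)],
                "adult",
            )
            a_only, _, shared = cohort_specific_blocks(a, b)
            overlapping_a = {id(pair[0]) for pair in shared}
            assert len(a_only) + len(overlapping_a) == len(a)
            for blk in a_only:
                assert b.intervals.overlap_bp(blk.interval) == 0

    def test_base_level_variant_keeps_long_fragments(self):
        a = self.make([("chr1", 100, 300)])
        b = self.make([("chr1", 180, 220)], "adult")
        frags = cohort_specific_bases(a, b, min_fragment=60)
        assert frags.to_list() == [
            GenomicInterval("chr1", 100, 180),
            GenomicInterval("chr1", 220, 300),
        ]
        assert cohort_specific_bases(a, b, min_fragment=100).to_list() == []

    def test_cross_tissue_overlap_arithmetic(self):
        a = self.make([("chr1", 0, 1000)])
        b = self.make([("chr1", 500, 1500)], "adult")
        c = self.make([("chr1", 900, 1100)], "other")
        out = cross_tissue_overlap(a, b, c)
        assert out["bp_ab"] == 500
        assert out["bp_abc"] == 100
        assert out["pct_of_b_in_a"] == 50.0

    def test_cross_tissue_identical_and_disjoint(self):
        a = self.make([("chr1", 0, 1000)])
        assert cross_tissue_overlap(a, a)["pct_of_b_in_a"] == 100.0
        d = self.make([("chr2", 0, 1000)], "adult")
        out = cross_tissue_overlap(a, d)
        assert out["bp_ab"] == 0 and out["pct_of_b_in_a"] == 0.0
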