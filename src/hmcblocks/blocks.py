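"""Consensus 5hmC block construction and cohort comparison.

A *5hmC block* is a maximal genomic run where at least ``min_support``
samples of one cohort show peak occupancy.  Blocks carry the occupancy
metrics used in the study's supplementary block tables: the number of
5hmC-positive samples, the summed length of every contributing peak, and
the summed read counts of those peaks.

Peak lengths and reads are credited in full to every block a peak
overlaps (no splitting); a clipped-length variant is available via
``clip_to_block=True`` in :func:`block_metrics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import Genome, GenomicInterval, IntervalSet, support_profile

COHORTS = ("fetal", "adult", "other")

__all__ = [
    "PeakSet",
    "Block",
    "BlockSet",
    "call_blocks",
    "block_metrics",
    "classify_peak_sharing",
    "cohort_specific_blocks",
    "cohort_specific_bases",
    "cross_tissue_overlap",
    "read_manifest",
]


@dataclass
class PeakSet:
    """One sample's called 5hmC peaks, optionally with per-peak read counts.

    Peaks are normalized on construction; if raw peaks merge, their read
    counts are summed onto the merged peak.
    """

    sample_id: str
    cohort: str
    peaks: IntervalSet
    reads: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}; expected one of {COHORTS}")
        if self.reads is not None:
            self.reads = np.asarray(self.reads, dtype=np.int64)
            if len(self.reads) != len(self.peaks):
                raise ValueError("reads must align 1:1 with normalized peaks")
            if (self.reads < 0).any():
                raise ValueError("read counts must be non-negative")

    @classmethod
    def from_raw(
        cls,
        sample_id: str,
        cohort: str,
        intervals: Sequence[GenomicInterval],
        reads: Sequence[int] | None = None,
        genome: Genome | None = None,
    ) -> "PeakSet":
        iset = IntervalSet.from_intervals(intervals, genome)
        if reads is None:
            return cls(sample_id, cohort, iset)
        if len(reads) != len(intervals):
            raise ValueError("reads must align 1:1 with raw peaks")
        merged_reads = np.zeros(len(iset), dtype=np.int64)
        merged = list(iset)
        # assign each raw peak's reads to the merged peak containing it
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for idx, iv in enumerate(merged):
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, idx))
        for iv, r in zip(intervals, reads):
            for s, e, idx in by_chrom[iv.chrom]:
                if s <= iv.start and iv.end <= e:
                    merged_reads[idx] += int(r)
                    break
        return cls(sample_id, cohort, iset, merged_reads)

    @classmethod
    def from_bed(cls, path, sample_id: str, cohort: str, genome: Genome | None = None):
        from .intervals import read_bed_records

        intervals, scores = read_bed_records(path, genome)
        return cls.from_raw(sample_id, cohort, intervals, scores, genome)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class Block:
    interval: GenomicInterval
    n_positive: int = 0
    sum_peak_bp: int = 0
    sum_reads: int = 0


@dataclass
class BlockSet:
    """Disjoint, sorted consensus blocks of one cohort."""

    cohort: str
    min_support: int
    blocks: list[Block] = field(default_factory=list)

    @property
    def intervals(self) -> IntervalSet:
        return IntervalSet.from_intervals(b.interval for b in self.blocks)

    @property
    def total_bp(self) -> int:
        return sum(b.interval.length for b in self.blocks)

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    b.interval.chrom,
                    b.interval.start,
                    b.interval.end,
                    b.n_positive,
                    b.sum_peak_bp,
                    b.sum_reads,
                )
                for b in self.blocks
            ],
            columns=["chrom", "start", "end", "n_positive", "sum_peak_bp", "sum_reads"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, cohort: str = "other", min_support: int = 2) -> "BlockSet":
        df = pd.read_csv(path, sep="\t")
        blocks = [
            Block(
                GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
                int(r.n_positive),
                int(r.sum_peak_bp),
                int(r.sum_reads),
            )
            for r in df.itertuples()
        ]
        return cls(cohort, min_support, blocks)


def read_manifest(path) -> list[tuple[str, str, str]]:
    """Read a cohort manifest TSV: sample_id<TAB>cohort<TAB>bed_path."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected sample_id, cohort, bed_path")
            rows.append((fields[0], fields[1], fields[2]))
    return rows


def call_blocks(
    peak_sets: Sequence[PeakSet], min_support: int = 2
) -> BlockSet:
    """Call consensus blocks: maximal runs with per-base support >= min_support.

    All peak sets must come from one cohort, and there must be at least
    ``min_support`` samples (otherwise no base could qualify).
    Occupancy metrics are filled in from the same peak sets.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if len(peak_sets) < min_support:
        raise ValueError(
            f"need at least min_support={min_support} samples, got {len(peak_sets)}"
        )
    cohorts = {ps.cohort for ps in peak_sets}
    if len(cohorts) != 1:
        raise ValueError(f"peak sets span multiple cohorts: {sorted(cohorts)}")
    runs = support_profile([ps.peaks for ps in peak_sets])
    qualified = IntervalSet.from_intervals(
        iv for iv, depth in runs if depth >= min_support
    )
    bset = BlockSet(cohorts.pop(), min_support, [Block(iv) for iv in qualified])
    return block_metrics(bset, peak_sets)


def block_metrics(
    block_set: BlockSet,
    peak_sets: Sequence[PeakSet],
    clip_to_block: bool = False,
) -> BlockSet:
    """Fill per-block occupancy metrics from the cohort's peak sets.

    n_positive: samples with >= 1 bp of peak overlapping the block.
    sum_peak_bp: summed length of every overlapping peak across positive
    samples — full peak lengths by default, in-block portions if
    ``clip_to_block`` is set.
    sum_reads: summed read counts of those peaks (0 where reads are absent).
    """
    n_pos = np.zeros(len(block_set.blocks), dtype=np.int64)
    sum_bp = np.zeros(len(block_set.blocks), dtype=np.int64)
    sum_rd = np.zeros(len(block_set.blocks), dtype=np.int64)
    blocks = block_set.blocks
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for idx, b in enumerate(blocks):
        by_chrom.setdefault(b.interval.chrom, []).append(
            (b.interval.start, b.interval.end, idx)
        )
    for ps in peak_sets:
        hit = np.zeros(len(blocks), dtype=bool)
        peak_list = list(ps.peaks)
        reads = ps.reads if ps.reads is not None else np.zeros(len(peak_list), np.int64)
        for p_idx, peak in enumerate(peak_list):
            for s, e, b_idx in by_chrom.get(peak.chrom, ()):
                ov = min(e, peak.end) - max(s, peak.start)
                if ov > 0:
                    hit[b_idx] = True
                    sum_bp[b_idx] += ov if clip_to_block else peak.length
                    sum_rd[b_idx] += int(reads[p_idx])
        n_pos += hit
    new_blocks = [
        Block(b.interval, int(n_pos[i]), int(sum_bp[i]), int(sum_rd[i]))
        for i, b in enumerate(blocks)
    ]
    return BlockSet(block_set.cohort, block_set.min_support, new_blocks)


def classify_peak_sharing(peak_sets: Sequence[PeakSet]) -> dict:
    """Per-peak sharing degrees over the pooled peak list of a cohort.

    Each peak's degree is the number of samples (including its own) with at
    least 1 bp overlapping it.  Fractions are over all peaks of all samples.
    """
    if len(peak_sets) < 2:
        raise ValueError("peak sharing needs at least 2 samples")
    n_samples = len(peak_sets)
    histogram: dict[int, int] = {}
    total = 0
    for i, ps in enumerate(peak_sets):
        for peak in ps.peaks:
            degree = 1
            for j, other in enumerate(peak_sets):
                if j != i and other.peaks.overlap_bp(peak) > 0:
                    degree += 1
            histogram[degree] = histogram.get(degree, 0) + 1
            total += 1
    unique = histogram.get(1, 0) / total if total else 0.0
    shared_by_all = histogram.get(n_samples, 0) / total if total else 0.0
    return {
        "histogram": dict(sorted(histogram.items())),
        "n_peaks": total,
        "unique_fraction": unique,
        "shared_by_all_fraction": shared_by_all,
    }


def cohort_specific_blocks(
    a: BlockSet, b: BlockSet
) -> tuple[BlockSet, BlockSet, list[tuple[Block, Block]]]:
    """Split two cohorts' blocks into exclusive and shared parts.

    A block is cohort-exclusive iff it has zero bp overlap with *every*
    block of the other cohort (block-level exclusivity).  ``shared`` lists
    every overlapping (a_block, b_block) pair.
    """
    b_iset = b.intervals
    a_iset = a.intervals
    a_only = [blk for blk in a.blocks if b_iset.overlap_bp(blk.interval) == 0]
    b_only = [blk for blk in b.blocks if a_iset.overlap_bp(blk.interval) == 0]
    shared: list[tuple[Block, Block]] = []
    b_by_chrom: dict[str, list[Block]] = {}
    for blk in b.blocks:
        b_by_chrom.setdefault(blk.interval.chrom, []).append(blk)
    for blk in a.blocks:
        for other in b_by_chrom.get(blk.interval.chrom, ()):
            ov = min(blk.interval.end, other.interval.end) - max(
                blk.interval.start, other.interval.start
            )
            if ov > 0:
                shared.append((blk, other))
    return (
        BlockSet(a.cohort, a.min_support, a_only),
        BlockSet(b.cohort, b.min_support, b_only),
        shared,
    )


def cohort_specific_bases(
    a: BlockSet, b: BlockSet, min_fragment: int = 1
) -> IntervalSet:
    """Base-level variant: a's block bases not covered by b, as fragments
    of at least ``min_fragment`` bp."""
    frags = a.intervals.subtract(b.intervals)
    return IntervalSet.from_intervals(
        iv for iv in frags if iv.length >= min_fragment
    )


def _iset(x) -> IntervalSet:
    return x.intervals if isinstance(x, BlockSet) else x


def cross_tissue_overlap(a, b, c=None) -> dict:
    """Base-pair overlap bookkeeping between two (optionally three) block sets."""
    ia, ib = _iset(a), _iset(b)
    ab = ia.intersect(ib)
    out = {
        "bp_a": ia.total_length,
        "bp_b": ib.total_length,
        "bp_ab": ab.total_length,
        "pct_of_b_in_a": (100.0 * ab.total_length / ib.total_length)
        if ib.total_length
        else 0.0,
    }
    if c is not None:
        out["bp_abc"] = ab.intersect(_iset(c)).total_length
    return out
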