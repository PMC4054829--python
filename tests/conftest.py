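"""Shared fixtures and brute-force per-base oracles.

The oracles deliberately avoid the package's sweep/merge algorithms:
interval sets are expanded to boolean per-base masks on a toy genome and
all expected values are computed by direct counting.
"""

from __future__ import annotations

import numpy as np
import pytest

from hmcblocks.intervals import Genome, GenomicInterval, IntervalSet


@pytest.fixture
def toy_genome():
    return Genome([("chr1", 10_000), ("chr2", 10_000), ("chr3", 10_000)])


def mask_of(iset: IntervalSet, genome: Genome) -> dict[str, np.ndarray]:
    """Per-base boolean occupancy of an interval set."""
    masks = {c: np.zeros(l, dtype=bool) for c, l in genome.chromosomes}
    for iv in iset:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks


def set_from_mask(masks: dict[str, np.ndarray]) -> IntervalSet:
    """Rebuild an interval set from boolean masks (runs of True)."""
    intervals = []
    for chrom in sorted(masks):
        m = masks[chrom]
        padded = np.concatenate([[False], m, [False]])
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        intervals.extend(GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return IntervalSet.from_intervals(intervals)


def random_iset(rng: np.random.Generator, genome: Genome, n: int,
                max_len: int = 500) -> IntervalSet:
    """n random raw intervals, normalized (may merge)."""
    intervals = []
    for _ in range(n):
        chrom, length = genome.chromosomes[int(rng.integers(len(genome.chromosomes)))]
        w = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, length - w + 1))
        intervals.append(GenomicInterval(chrom, start, start + w))
    return IntervalSet.from_intervals(intervals)
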