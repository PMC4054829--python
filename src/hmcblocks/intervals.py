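"""Interval algebra over a declared genome.

Coordinates are BED-convention 0-based half-open everywhere, in memory and
on disk.  An :class:`IntervalSet` is always *normalized*: per chromosome the
intervals are sorted, pairwise disjoint, and bookended neighbours
(``end == next start``) are merged, so equal-support runs form one
continuous genomic interval.  Strand plays no role in interval arithmetic.

Chromosomes are identified by name against a :class:`Genome` declaration;
an interval on an undeclared chromosome or outside its bounds is an error,
never silently dropped — this surfaces genome/annotation mismatches early.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "BedParseError",
    "GenomeBoundsError",
    "Genome",
    "GenomicInterval",
    "IntervalSet",
    "normalize",
    "support_profile",
    "read_bed",
    "write_bed",
]


class BedParseError(ValueError):
    """A BED line that cannot be interpreted (reported with its line number)."""


class GenomeBoundsError(ValueError):
    """An interval that falls outside the declared genome."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.chrom}:{self.start}-{self.end}"


class Genome:
    """Ordered chromosome declaration: unique names with positive lengths."""

    def __init__(self, chromosomes: Iterable[tuple[str, int]]):
        chroms = [(str(name), int(length)) for name, length in chromosomes]
        names = [c[0] for c in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome declaration")
        for name, length in chroms:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self.chromosomes: list[tuple[str, int]] = chroms
        self.lengths: dict[str, int] = dict(chroms)
        self.names: list[str] = names
        self.size: int = sum(self.lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Genome) and self.chromosomes == other.chromosomes

    def __repr__(self) -> str:  # pragma: no cover
        return f"Genome({self.chromosomes!r})"

    def check_interval(self, iv: GenomicInterval) -> None:
        length = self.lengths.get(iv.chrom)
        if length is None:
            raise GenomeBoundsError(f"chromosome {iv.chrom!r} not declared in genome")
        if iv.end > length:
            raise GenomeBoundsError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                f"chromosome length {length}"
            )

    @classmethod
    def from_tsv(cls, path) -> "Genome":
        chroms: list[tuple[str, int]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
                chroms.append((fields[0], int(fields[1])))
        return cls(chroms)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self.chromosomes:
                fh.write(f"{name}\t{length}\n")


def _as_array(pairs: Sequence[tuple[int, int]]) -> np.ndarray:
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)


def _merge_sorted(arr: np.ndarray) -> np.ndarray:
    """Coalesce a (start-sorted) array; bookended intervals merge too."""
    if len(arr) <= 1:
        return arr
    out: list[list[int]] = [[int(arr[0, 0]), int(arr[0, 1])]]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1][1] = int(e)
        else:
            out.append([int(s), int(e)])
    return np.asarray(out, dtype=np.int64)


class IntervalSet:
    """A normalized set of genomic intervals (sorted, disjoint, merged).

    Internally one ``(n, 2)`` int64 array per chromosome; chromosome keys are
    kept lexicographically sorted so iteration and file output are
    deterministic.
    """

    def __init__(self, data: dict[str, np.ndarray] | None = None):
        data = data or {}
        self._data = {c: data[c] for c in sorted(data) if len(data[c])}

    # -- construction -------------------------------------------------
    @classmethod
    def from_intervals(
        cls, intervals: Iterable[GenomicInterval], genome: Genome | None = None
    ) -> "IntervalSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            if genome is not None:
                genome.check_interval(iv)
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        data = {}
        for chrom, pairs in by_chrom.items():
            arr = _as_array(pairs)
            arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
            data[chrom] = _merge_sorted(arr)
        return cls(data)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, int, int]], genome: Genome | None = None
    ) -> "IntervalSet":
        return cls.from_intervals(
            (GenomicInterval(c, s, e) for c, s, e in pairs), genome
        )

    # -- basic protocol -----------------------------------------------
    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self._data:
            for s, e in self._data[chrom]:
                yield GenomicInterval(chrom, int(s), int(e))

    def __len__(self) -> int:
        return sum(len(a) for a in self._data.values())

    def __bool__(self) -> bool:
        return len(self) > 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if set(self._data) != set(other._data):
            return False
        return all(np.array_equal(self._data[c], other._data[c]) for c in self._data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"IntervalSet({len(self)} intervals, {self.total_length} bp)"

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def array(self, chrom: str) -> np.ndarray:
        return self._data.get(chrom, np.empty((0, 2), dtype=np.int64))

    @property
    def total_length(self) -> int:
        return int(
            sum((a[:, 1] - a[:, 0]).sum() for a in self._data.values())
        )

    def to_list(self) -> list[GenomicInterval]:
        return list(self)

    # -- set algebra ---------------------------------------------------
    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        data = {}
        for chrom in self._data:
            if chrom not in other._data:
                continue
            arr = _intersect_arrays(self._data[chrom], other._data[chrom])
            if len(arr):
                data[chrom] = arr
        return IntervalSet(data)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        data = {}
        for chrom, a in self._data.items():
            b = other._data.get(chrom)
            arr = a if b is None else _subtract_arrays(a, b)
            if len(arr):
                data[chrom] = arr.copy()
        return IntervalSet(data)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        data = {}
        for chrom in set(self._data) | set(other._data):
            stacked = np.vstack([self.array(chrom), other.array(chrom)])
            stacked = stacked[np.lexsort((stacked[:, 1], stacked[:, 0]))]
            data[chrom] = _merge_sorted(stacked)
        return IntervalSet(data)

    def overlaps(self, iv: GenomicInterval) -> bool:
        return self.overlap_bp(iv) > 0

    def overlap_bp(self, iv: GenomicInterval) -> int:
        """Base pairs of ``iv`` covered by this set."""
        arr = self.array(iv.chrom)
        if not len(arr):
            return 0
        cov = self.coverage_between(iv.chrom, np.array([iv.start]), np.array([iv.end]))
        return int(cov[0])

    def coverage_between(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Vectorized covered-bp of half-open query windows on one chromosome."""
        arr = self.array(chrom)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if not len(arr):
            return np.zeros(len(starts), dtype=np.int64)
        iv_s, iv_e = arr[:, 0], arr[:, 1]
        cum = np.concatenate([[0], np.cumsum(iv_e - iv_s)])
        i0 = np.searchsorted(iv_e, starts, side="right")
        i1 = np.searchsorted(iv_s, ends, side="left")
        total = cum[i1] - cum[i0]
        has = i1 > i0
        if np.any(has):
            # clip the first and last partially covered intervals
            first_s = np.where(has, iv_s[np.minimum(i0, len(iv_s) - 1)], 0)
            last_e = np.where(has, iv_e[np.maximum(i1 - 1, 0)], 0)
            total = total - np.where(has, np.maximum(starts - first_s, 0), 0)
            total = total - np.where(has, np.maximum(last_e - ends, 0), 0)
        return np.maximum(total, 0)

    def contains_points(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean membership of single base positions."""
        arr = self.array(chrom)
        positions = np.asarray(positions, dtype=np.int64)
        if not len(arr):
            return np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(arr[:, 0], positions, side="right") - 1
        ok = idx >= 0
        safe = np.maximum(idx, 0)
        return ok & (positions < arr[safe, 1])


def _intersect_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((int(s), int(e)))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return _as_array(out)


def _subtract_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = int(s)
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            if b[k, 0] > cur:
                out.append((cur, int(b[k, 0])))
            cur = max(cur, int(b[k, 1]))
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, int(e)))
    return _as_array(out)


def normalize(
    intervals: Iterable[GenomicInterval], genome: Genome | None = None
) -> IntervalSet:
    """Sort, bounds-check and coalesce raw intervals into an IntervalSet."""
    return IntervalSet.from_intervals(intervals, genome)


def support_profile(
    peak_sets: Sequence[IntervalSet],
) -> list[tuple[GenomicInterval, int]]:
    """Maximal runs of constant per-base sample support across input sets.

    Returns ``(interval, depth)`` runs with depth >= 1; their concatenation
    tiles the union of the inputs, and
    ``sum(run length * depth) == sum of per-sample total lengths``.
    """
    chroms = sorted({c for ps in peak_sets for c in ps.chroms})
    runs: list[tuple[GenomicInterval, int]] = []
    for chrom in chroms:
        pos_list = []
        delta_list = []
        for ps in peak_sets:
            arr = ps.array(chrom)
            if not len(arr):
                continue
            pos_list.append(arr[:, 0])
            delta_list.append(np.ones(len(arr), dtype=np.int64))
            pos_list.append(arr[:, 1])
            delta_list.append(-np.ones(len(arr), dtype=np.int64))
        if not pos_list:
            continue
        pos = np.concatenate(pos_list)
        delta = np.concatenate(delta_list)
        upos, inv = np.unique(pos, return_inverse=True)
        net = np.zeros(len(upos), dtype=np.int64)
        np.add.at(net, inv, delta)
        keep = net != 0  # boundaries where the depth actually changes
        upos, net = upos[keep], net[keep]
        depth = np.cumsum(net)
        for idx in range(len(upos) - 1):
            d = int(depth[idx])
            if d > 0:
                runs.append(
                    (GenomicInterval(chrom, int(upos[idx]), int(upos[idx + 1])), d)
                )
    return runs


# -- BED I/O -----------------------------------------------------------


def read_bed_records(
    path, genome: Genome | None = None
) -> tuple[list[GenomicInterval], list[int] | None]:
    """Read BED3/BED5 records in file order, without normalization.

    Returns the intervals plus the score column (BED5) or None (BED3).
    Malformed lines are rejected with their line number; so is start >= end.
    """
    intervals: list[GenomicInterval] = []
    scores: list[int] = []
    saw_score = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise BedParseError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            iv = GenomicInterval(fields[0], start, end)
            if genome is not None:
                genome.check_interval(iv)
            intervals.append(iv)
            if len(fields) >= 5:
                saw_score = True
                try:
                    scores.append(int(float(fields[4])))
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: bad score field") from exc
            else:
                scores.append(0)
    return intervals, (scores if saw_score else None)


def read_bed(path, genome: Genome | None = None) -> "IntervalSet":
    """Read a BED file as a normalized IntervalSet (scores dropped)."""
    intervals, _ = read_bed_records(path, genome)
    return IntervalSet.from_intervals(intervals)


def write_bed(
    iset_or_records, path, scores: Sequence[int] | None = None, names=None
) -> None:
    """Write intervals (IntervalSet or iterable) as BED3, or BED5 with scores."""
    records = list(iset_or_records)
    if scores is not None and len(scores) != len(records):
        raise ValueError("scores must align 1:1 with intervals")
    with open(path, "w") as fh:
        for i, iv in enumerate(records):
            if scores is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = names[i] if names is not None else f"peak_{i}"
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{scores[i]}\n")
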