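"""Interval data model, BED I/O, and the interval algebra used throughout.

Coordinates are BED-style 0-based half-open everywhere. A :class:`PeakSet`
is a sorted collection of intervals for one assay / cell type / replicate;
"overlap" between peaks defaults to >= 1 bp and is configurable where a
rule demands more (the 100 bp methylation-ensemble rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .genome import GenomeAssembly

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class Interval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PeakSet:
    """Sorted set of intervals with an optional provenance label.

    Intervals are kept sorted by (chrom, start, end); duplicates and
    overlaps are permitted until :func:`merge` is applied.
    """

    intervals: tuple[Interval, ...]
    label: str = ""
    _by_chrom: dict[str, np.ndarray] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        ivs = tuple(sorted(self.intervals))
        object.__setattr__(self, "intervals", ivs)
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in ivs:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        arrays = {c: np.asarray(v, dtype=np.int64).reshape(-1, 2) for c, v in by_chrom.items()}
        object.__setattr__(self, "_by_chrom", arrays)

    @classmethod
    def from_intervals(cls, intervals: Iterable[Interval], label: str = "") -> "PeakSet":
        return cls(tuple(intervals), label)

    @classmethod
    def from_arrays(
        cls,
        chroms: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
        label: str = "",
    ) -> "PeakSet":
        return cls(
            tuple(Interval(c, int(s), int(e)) for c, s, e in zip(chroms, starts, ends)),
            label,
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> Interval:
        return self.intervals[i]

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def arrays(self, chrom: str) -> np.ndarray:
        """(n, 2) array of [start, end) rows for one chromosome."""
        return self._by_chrom.get(chrom, np.empty((0, 2), dtype=np.int64))

    @property
    def total_bases(self) -> int:
        """Covered bases after coalescing overlaps."""
        return sum(int((arr[:, 1] - arr[:, 0]).sum()) for arr in merge(self)._by_chrom.values())

    def validate(self, genome: GenomeAssembly) -> None:
        """Raise if any interval leaves the assembly."""
        for iv in self.intervals:
            if iv.chrom not in genome:
                raise ValueError(f"chromosome {iv.chrom!r} not in assembly ({self.label or 'peak set'})")
            if iv.end > genome.length(iv.chrom):
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome length "
                    f"{genome.length(iv.chrom)}"
                )

    def relabel(self, label: str) -> "PeakSet":
        return PeakSet(self.intervals, label)


def read_bed(path: str | Path, genome: GenomeAssembly | None = None, label: str | None = None) -> PeakSet:
    """Read a BED3+ file into a sorted :class:`PeakSet`.

    Extra columns beyond the first three are ignored. Unsorted input is
    sorted with a logged warning. Malformed coordinates raise a
    ``ValueError`` naming the offending line; when a genome is supplied,
    unknown chromosomes raise as well.
    """
    path = Path(path)
    intervals: list[Interval] = []
    n_extra_cols = 0
    prev: tuple[str, int, int] | None = None
    sorted_input = True
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 fields, got {line!r}")
            n_extra_cols = max(n_extra_cols, len(fields) - 3)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates in {line!r}") from exc
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}")
            key = (chrom, start, end)
            if prev is not None and key < prev:
                sorted_input = False
            prev = key
            intervals.append(Interval(chrom, start, end))
    if not sorted_input:
        logger.warning("%s: input not coordinate-sorted; sorting", path)
    if n_extra_cols:
        logger.info("%s: ignored %d extra BED column(s)", path, n_extra_cols)
    ps = PeakSet(tuple(intervals), label if label is not None else path.stem)
    if genome is not None:
        ps.validate(genome)
    return ps


def write_bed(ps: PeakSet, path: str | Path, names: Sequence[str] | None = None) -> None:
    """Write a PeakSet as BED3 (or BED4 when per-interval names are given)."""
    if names is not None and len(names) != len(ps):
        raise ValueError("names must match the number of intervals")
    with open(path, "w") as fh:
        for i, iv in enumerate(ps):
            if names is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\n")


def merge(a: PeakSet) -> PeakSet:
    """Coalesce overlapping or abutting intervals into their union.

    Covered bases are conserved; abutting intervals ([0,10) and [10,20))
    merge into one region.
    """
    out: list[Interval] = []
    for chrom in a.chroms:
        arr = a.arrays(chrom)
        cur_s, cur_e = arr[0]
        for s, e in arr[1:]:
            if s <= cur_e:  # overlap or abut
                cur_e = max(cur_e, e)
            else:
                out.append(Interval(chrom, int(cur_s), int(cur_e)))
                cur_s, cur_e = s, e
        out.append(Interval(chrom, int(cur_s), int(cur_e)))
    return PeakSet(tuple(out), a.label)


def _overlap_bp_with_merged(query: np.ndarray, merged: np.ndarray) -> np.ndarray:
    """Total overlap (bp) of each query row against disjoint sorted regions."""
    if len(query) == 0:
        return np.zeros(0, dtype=np.int64)
    if len(merged) == 0:
        return np.zeros(len(query), dtype=np.int64)
    m_starts, m_ends = merged[:, 0], merged[:, 1]
    # prefix sums of merged widths give O(log m) per query, fully vectorized
    cum = np.concatenate([[0], np.cumsum(m_ends - m_starts)])
    lo = np.searchsorted(m_ends, query[:, 0], side="right")
    hi = np.searchsorted(m_starts, query[:, 1], side="left")
    out = np.zeros(len(query), dtype=np.int64)
    valid = lo < hi
    l, h = lo[valid], hi[valid]
    qs, qe = query[valid, 0], query[valid, 1]
    total = cum[h] - cum[l]
    total -= np.maximum(0, qs - m_starts[l])
    total -= np.maximum(0, m_ends[h - 1] - qe)
    out[valid] = total
    return out


def overlap_bp(a: PeakSet, b: PeakSet) -> np.ndarray:
    """Per-interval bp of overlap of ``a`` against the merged coverage of ``b``.

    Returned in the sorted order of ``a.intervals``.
    """
    mb = merge(b)
    out = np.zeros(len(a), dtype=np.int64)
    pos = 0
    for chrom in a.chroms:
        q = a.arrays(chrom)
        res = _overlap_bp_with_merged(q, mb.arrays(chrom))
        out[pos : pos + len(q)] = res
        pos += len(q)
    # a.intervals are sorted by (chrom, start, end) and a.chroms is sorted,
    # so the per-chromosome concatenation matches interval order.
    return out


def overlap_flags(a: PeakSet, b: PeakSet, min_bp: int = 1) -> np.ndarray:
    """Boolean flag per interval of ``a``: has >= min_bp overlap with ``b``."""
    if min_bp < 1:
        raise ValueError(f"min_bp must be >= 1, got {min_bp}")
    return overlap_bp(a, b) >= min_bp


def intersect_any(a: PeakSet, b: PeakSet, min_bp: int = 1) -> PeakSet:
    """Subset of ``a``'s intervals with >= min_bp bases overlapping ``b``.

    Coordinates of ``a`` are retained unchanged.
    """
    flags = overlap_flags(a, b, min_bp=min_bp)
    return PeakSet(tuple(iv for iv, f in zip(a.intervals, flags) if f), a.label)


def subtract_any(a: PeakSet, b: PeakSet) -> PeakSet:
    """Subset of ``a``'s intervals with zero overlapping bases against ``b``.

    Together with :func:`intersect_any` this partitions ``a``.
    """
    flags = overlap_flags(a, b, min_bp=1)
    return PeakSet(tuple(iv for iv, f in zip(a.intervals, flags) if not f), a.label)


def nearest_point_distance(a: Interval, p: int) -> int:
    """Distance in bp from point ``p`` to the nearest base of ``a``.

    Zero when ``p`` lies inside the half-open interval; otherwise the
    distance to the nearest covered base (``start`` or ``end - 1``).
    """
    if a.start <= p < a.end:
        return 0
    return min(abs(p - a.start), abs(p - (a.end - 1)))
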