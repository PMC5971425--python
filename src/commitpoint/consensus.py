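"""Consensus peak construction across replicates and across peak-calling tools.

Three rules are implemented:

* accessibility (two biological replicates): peaks present in *both*
  replicates within the same merged region are kept;
* histone-mark ChIP (four replicates): peaks present in *all* replicates
  within the same merged region are kept;
* methylation enrichment (tool ensemble): replicate peaks called by two
  or more peak-calling tools and overlapping each other by at least
  100 bp are kept.

Consensus coordinates are the merged-region footprint: the whole pooled
region is retained once the required support is met.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .intervals import Interval, PeakSet, merge, overlap_flags

Require = Literal["all", "at_least_two"]


@dataclass(frozen=True)
class ReplicateGroup:
    """Peak sets from >= 2 replicates of one assay in one cell type."""

    cell_type: str
    assay: str
    replicates: tuple[PeakSet, ...]

    def __post_init__(self) -> None:
        if len(self.replicates) < 2:
            raise ValueError(
                f"{self.cell_type}/{self.assay}: need >= 2 replicates, got {len(self.replicates)}"
            )


def consensus_in_merged_regions(g: ReplicateGroup, require: Require = "all") -> PeakSet:
    """Merged pooled regions supported by the required number of replicates.

    All replicate peaks are pooled and merged; a merged region is emitted
    iff the required number of distinct replicates each contribute at
    least one peak overlapping it. Output coordinates are the
    merged-region coordinates.
    """
    if require not in ("all", "at_least_two"):
        raise ValueError(f"require must be 'all' or 'at_least_two', got {require!r}")
    pooled = PeakSet(
        tuple(iv for rep in g.replicates for iv in rep),
        f"{g.cell_type}.{g.assay}.pooled",
    )
    regions = merge(pooled)
    need = len(g.replicates) if require == "all" else 2
    support = np.zeros(len(regions), dtype=np.int64)
    for rep in g.replicates:
        support += overlap_flags(regions, rep)
    kept = tuple(iv for iv, n in zip(regions.intervals, support) if n >= need)
    return PeakSet(kept, f"{g.cell_type}.{g.assay}.consensus")


def ensemble_consensus(
    tool_calls: Sequence[PeakSet],
    min_tools: int = 2,
    min_overlap_bp: int = 100,
    label: str = "ensemble.consensus",
) -> PeakSet:
    """Merged regions supported by >= min_tools tools with >= min_overlap_bp pairwise overlap.

    A merged region of the pooled calls is kept iff some pair of peaks
    from two distinct tools inside the region overlaps by at least
    ``min_overlap_bp`` (the best supporting pair decides). With more than
    two tools any qualifying pair suffices.
    """
    if min_overlap_bp < 1:
        raise ValueError(f"min_overlap_bp must be >= 1, got {min_overlap_bp}")
    if len(tool_calls) < min_tools:
        raise ValueError(f"need >= {min_tools} tool call sets, got {len(tool_calls)}")
    pooled = PeakSet(tuple(iv for tool in tool_calls for iv in tool), "pooled")
    regions = merge(pooled)
    kept: list[Interval] = []
    # peaks per tool per region, then best cross-tool pairwise overlap
    per_tool_flags = [overlap_flags(regions, tool) for tool in tool_calls]
    for ridx, region in enumerate(regions.intervals):
        tools_here = [t for t in range(len(tool_calls)) if per_tool_flags[t][ridx]]
        if len(tools_here) < min_tools:
            continue
        peaks_by_tool = [
            [
                iv
                for iv in tool_calls[t]
                if iv.chrom == region.chrom and iv.start < region.end and iv.end > region.start
            ]
            for t in tools_here
        ]
        if _best_cross_tool_overlap(peaks_by_tool) >= min_overlap_bp:
            kept.append(region)
    return PeakSet(tuple(kept), label)


def _best_cross_tool_overlap(peaks_by_tool: list[list[Interval]]) -> int:
    best = 0
    for i in range(len(peaks_by_tool)):
        for j in range(i + 1, len(peaks_by_tool)):
            for p in peaks_by_tool[i]:
                for q in peaks_by_tool[j]:
                    best = max(best, min(p.end, q.end) - max(p.start, q.start))
    return best
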