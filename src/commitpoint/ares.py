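"""Active regulatory elements (AREs): derivation, specificity, establishment,
chromatin state, nearest-TSS assignment, and expression/methylation overlap.

An ARE is an H3K27ac consensus peak that also lies in accessible (ATAC)
chromatin. AREs keep their H3K27ac footprint (they are filtered, not
clipped) so downstream TSS distances stay stable. Cell specificity is a
reciprocal-overlap partition between the ARE sets of two cell types. The
*establishment stage* of an ARE is the most primitive stage whose
accessible-chromatin profile already contains it; an ARE first seen at a
later stage is established *de novo* there.
"""

from __future__ import annotations

import bisect
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import (
    Interval,
    PeakSet,
    intersect_any,
    merge,
    nearest_point_distance,
    overlap_flags,
    subtract_any,
)

CHROMATIN_STATES = ("active", "poised", "open", "acetylated_only")
DE_NOVO = "de novo"


@dataclass(frozen=True)
class TssAnnotation:
    """Transcription start sites: (gene id, chrom, position, strand) records."""

    records: tuple[tuple[str, str, int, str], ...]
    _by_chrom: dict[str, tuple[list[int], list[str]]] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, str]]] = {}
        for gene, chrom, pos, strand in self.records:
            if pos < 0:
                raise ValueError(f"negative TSS position for {gene!r}")
            if strand not in ("+", "-"):
                raise ValueError(f"strand must be '+' or '-' for {gene!r}, got {strand!r}")
            by_chrom.setdefault(chrom, []).append((pos, gene))
        packed = {}
        for chrom, items in by_chrom.items():
            items.sort()
            packed[chrom] = ([p for p, _ in items], [g for _, g in items])
        object.__setattr__(self, "_by_chrom", packed)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TssAnnotation":
        """Read a 4-column TSV: gene, chrom, position, strand (header optional)."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.iloc[0, 0] in ("gene", "gene_id") or not df.iloc[0, 2].lstrip("-").isdigit():
            df = df.iloc[1:]
        recs = tuple(
            (str(r[0]), str(r[1]), int(r[2]), str(r[3])) for r in df.itertuples(index=False)
        )
        return cls(recs)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tchrom\tposition\tstrand\n")
            for gene, chrom, pos, strand in self.records:
                fh.write(f"{gene}\t{chrom}\t{pos}\t{strand}\n")

    def __len__(self) -> int:
        return len(self.records)

    def positions(self, chrom: str) -> tuple[list[int], list[str]]:
        """Sorted positions and parallel gene ids on one chromosome."""
        return self._by_chrom.get(chrom, ([], []))


@dataclass(frozen=True)
class AreRecord:
    """One annotated ARE."""

    interval: Interval
    specificity: str  # "cell_specific" | "shared"
    establishment_stage: str
    de_novo: bool
    chromatin_state: str
    nearest_gene: str | None
    tss_distance: int | None
    proximity_class: str | None  # "cPE" | "cEE" | None when unassigned
    methylated: bool
    target_expressed: bool


@dataclass(frozen=True)
class AreCatalog:
    """All annotated AREs for one cell type."""

    cell_type: str
    records: tuple[AreRecord, ...]
    provenance: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "specificity": r.specificity,
                "establishment_stage": r.establishment_stage,
                "de_novo": r.de_novo,
                "chromatin_state": r.chromatin_state,
                "nearest_gene": r.nearest_gene if r.nearest_gene is not None else "unassigned",
                "tss_distance": r.tss_distance if r.tss_distance is not None else -1,
                "proximity_class": r.proximity_class if r.proximity_class is not None else "unassigned",
                "methylated": r.methylated,
                "target_expressed": r.target_expressed,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def derive_ares(h3k27ac: PeakSet, atac: PeakSet) -> tuple[PeakSet, float]:
    """H3K27ac peaks retained iff they overlap accessible chromatin.

    Returns the retained peaks (with their own H3K27ac coordinates) and
    the fraction of H3K27ac peaks retained. An empty H3K27ac input gives
    an empty output and a NaN fraction with a warning.
    """
    if len(h3k27ac) == 0:
        warnings.warn("empty H3K27ac set: ARE retention fraction undefined", stacklevel=2)
        return PeakSet((), h3k27ac.label), math.nan
    ares = intersect_any(h3k27ac, atac)
    return ares.relabel(f"{h3k27ac.label}.ares"), len(ares) / len(h3k27ac)


def partition_specificity(
    ares_a: PeakSet, ares_b: PeakSet
) -> tuple[PeakSet, PeakSet, PeakSet]:
    """Split two ARE sets into a-specific, b-specific, and shared regions.

    Specific AREs have no overlap in the other set. Shared regions are
    the merged union of reciprocally overlapping AREs, so each overlap
    cluster is counted once.
    """
    a_specific = subtract_any(ares_a, ares_b)
    b_specific = subtract_any(ares_b, ares_a)
    a_in = intersect_any(ares_a, ares_b)
    b_in = intersect_any(ares_b, ares_a)
    shared = merge(PeakSet(tuple(a_in) + tuple(b_in), "shared"))
    return a_specific, b_specific, shared


@dataclass(frozen=True)
class EstablishmentProfile:
    """Per-ARE establishment stages plus per-stage presence fractions."""

    stages: tuple[str, ...]
    presence: pd.DataFrame  # bool, one column per stage, one row per ARE
    establishment_stage: tuple[str | None, ...]  # None: absent from every stage
    de_novo: tuple[bool, ...]

    @property
    def presence_fractions(self) -> dict[str, float]:
        return {s: float(self.presence[s].mean()) for s in self.stages}

    def stage_counts(self) -> dict[str, int]:
        from collections import Counter

        c = Counter(s for s in self.establishment_stage if s is not None)
        return {s: c.get(s, 0) for s in self.stages}


def establishment_profile(
    ares: PeakSet, stage_atac: Sequence[tuple[str, PeakSet]]
) -> EstablishmentProfile:
    """Earliest accessible stage per ARE along an ordered lineage.

    ``stage_atac`` lists (stage name, accessibility peak set) pairs from
    most primitive to the ARE's own cell type. Presence is >= 1 bp
    overlap; the earliest present stage is the establishment stage, and
    any ARE not present at the first stage is flagged de novo.
    """
    if len(stage_atac) == 0:
        raise ValueError("stage_atac must list at least one (stage, PeakSet) pair")
    stages = tuple(s for s, _ in stage_atac)
    if len(set(stages)) != len(stages):
        raise ValueError("duplicate stage names in stage_atac")
    flags = {s: overlap_flags(ares, ps) if len(ares) else np.zeros(0, bool) for s, ps in stage_atac}
    presence = pd.DataFrame(flags, columns=list(stages))
    est: list[str | None] = []
    de_novo: list[bool] = []
    for i in range(len(ares)):
        stage_hit = next((s for s in stages if flags[s][i]), None)
        est.append(stage_hit)
        de_novo.append(stage_hit is not None and stage_hit != stages[0])
    return EstablishmentProfile(stages, presence, tuple(est), tuple(de_novo))


def classify_chromatin_state(
    ares: PeakSet, ref_h3k4me1: PeakSet, ref_h3k27ac: PeakSet
) -> tuple[list[str], dict[str, float]]:
    """Classify AREs against reference progenitor H3K4me1/H3K27ac peaks.

    active = both marks; poised = H3K4me1 only; open = neither;
    acetylated_only = H3K27ac only. Returns per-ARE states (in sorted
    interval order) and the four fractions, which sum to 1 for any
    non-empty input.
    """
    me1 = overlap_flags(ares, ref_h3k4me1) if len(ares) else np.zeros(0, bool)
    k27 = overlap_flags(ares, ref_h3k27ac) if len(ares) else np.zeros(0, bool)
    states = []
    for m, k in zip(me1, k27):
        if m and k:
            states.append("active")
        elif m:
            states.append("poised")
        elif k:
            states.append("acetylated_only")
        else:
            states.append("open")
    n = len(states)
    fractions = {
        s: (states.count(s) / n if n else math.nan) for s in CHROMATIN_STATES
    }
    return states, fractions


def assign_nearest_tss(
    ares: PeakSet, tss: TssAnnotation
) -> list[tuple[str | None, int | None]]:
    """Nearest TSS gene and edge distance for every ARE.

    The distance is minimized over all TSS on the ARE's chromosome
    (0 when a TSS falls inside the ARE); ties are broken by the
    lexicographically smallest gene id. AREs on chromosomes with no TSS
    are reported as ``(None, None)``.
    """
    if len(tss) == 0:
        raise ValueError("TSS annotation is empty")
    out: list[tuple[str | None, int | None]] = []
    for iv in ares:
        positions, genes = tss.positions(iv.chrom)
        if not positions:
            out.append((None, None))
            continue
        # candidate nearest positions around both interval edges
        cand_idx: set[int] = set()
        for point in (iv.start, iv.end - 1):
            j = bisect.bisect_left(positions, point)
            for k in (j - 1, j, j + 1):
                if 0 <= k < len(positions):
                    cand_idx.add(k)
        best = min(nearest_point_distance(iv, positions[k]) for k in cand_idx)
        # collect every TSS achieving the minimum for the lexicographic tie-break
        if best == 0:
            lo = bisect.bisect_left(positions, iv.start)
            hi = bisect.bisect_left(positions, iv.end)
            winners = genes[lo:hi]
        else:
            winners = []
            for p in (iv.start - best, iv.end - 1 + best):
                lo = bisect.bisect_left(positions, p)
                hi = bisect.bisect_right(positions, p)
                winners.extend(genes[lo:hi])
        out.append((min(winners), best))
    return out


def classify_proximity(distance: int, threshold: int = 1000) -> str:
    """Candidate promoter (cPE) vs candidate enhancer (cEE) element.

    cPE iff the TSS edge distance is within the threshold, boundary
    inclusive (exactly 1000 bp is a cPE).
    """
    if distance < 0:
        raise ValueError(f"distance must be non-negative, got {distance}")
    return "cPE" if distance <= threshold else "cEE"


@dataclass(frozen=True)
class TargetExpression:
    n_ares: int
    n_unassigned: int
    n_target_genes: int
    n_expressed: int
    percent: float  # of target genes expressed, integer-rounded


def target_expressed_fraction(
    assignments: Sequence[tuple[str | None, int | None]],
    expressed: set[str],
    decimals: int = 0,
) -> TargetExpression:
    """Unique nearest-TSS target genes and the expressed subset.

    AREs without an assigned gene are excluded from the tally and
    counted separately.
    """
    from .expression import rounded_percent

    assigned = [g for g, _ in assignments if g is not None]
    n_unassigned = len(assignments) - len(assigned)
    targets = set(assigned)
    n_expr = len(targets & expressed)
    pct = rounded_percent(n_expr, len(targets), decimals) if targets else math.nan
    return TargetExpression(len(assignments), n_unassigned, len(targets), n_expr, pct)


def methylation_overlap_fraction(
    ares: PeakSet, methylation: PeakSet, decimals: int = 1
) -> tuple[int, int, float]:
    """(k, n, percent): AREs overlapping >= 1 methylation peak.

    The percentage is rounded half-up to one decimal by default; an
    empty ARE set yields a NaN percentage.
    """
    from .expression import rounded_percent

    n = len(ares)
    if n == 0:
        warnings.warn("empty ARE set: methylation overlap percent undefined", stacklevel=2)
        return 0, 0, math.nan
    k = int(overlap_flags(ares, methylation).sum())
    return k, n, rounded_percent(k, n, decimals)


def build_catalog(
    cell_type: str,
    ares: PeakSet,
    specificity: str,
    profile: EstablishmentProfile,
    states: Sequence[str],
    assignments: Sequence[tuple[str | None, int | None]],
    expressed: set[str],
    methylated_flags: Sequence[bool],
    tss_threshold: int = 1000,
    provenance: str = "",
) -> AreCatalog:
    """Assemble per-ARE annotations into an :class:`AreCatalog`."""
    n = len(ares)
    for name, seq in (
        ("profile", profile.establishment_stage),
        ("states", states),
        ("assignments", assignments),
        ("methylated_flags", methylated_flags),
    ):
        if len(seq) != n:
            raise ValueError(f"{name} length {len(seq)} != number of AREs {n}")
    records = []
    for i, iv in enumerate(ares):
        gene, dist = assignments[i]
        records.append(
            AreRecord(
                interval=iv,
                specificity=specificity,
                establishment_stage=profile.establishment_stage[i] or "absent",
                de_novo=profile.de_novo[i],
                chromatin_state=states[i],
                nearest_gene=gene,
                tss_distance=dist,
                proximity_class=classify_proximity(dist, tss_threshold) if dist is not None else None,
                methylated=bool(methylated_flags[i]),
                target_expressed=gene in expressed if gene is not None else False,
            )
        )
    return AreCatalog(cell_type, tuple(records), provenance)
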