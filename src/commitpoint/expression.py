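"""Expressed-set thresholding, lineage maintenance chains and proportion tests.

A transcript is called *expressed* in a cell type when its abundance is
at least 1 TPM (transcripts per million); the threshold is a parameter
with that default. Maintenance along a lineage is the cumulative
intersection of expressed sets from the most primitive stage onward, so
the per-stage counts are non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest


@dataclass(frozen=True)
class Lineage:
    """Ordered cell-type stages of one differentiation path, most primitive first."""

    name: str
    stages: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.stages) < 2:
            raise ValueError(f"lineage {self.name!r} needs >= 2 stages")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError(f"lineage {self.name!r} has repeated stages")


class ExpressionMatrix:
    """Gene x cell-type TPM table.

    Wraps a pandas DataFrame indexed by gene id with one non-negative
    TPM column per cell type.
    """

    def __init__(self, tpm: pd.DataFrame):
        if tpm.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if (tpm.values < 0).any():
            raise ValueError("TPM values must be non-negative")
        if tpm.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        self.tpm = tpm.astype(float)

    @classmethod
    def from_tsv(cls, path: str | Path, gene_column: str | None = None) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t")
        gene_col = gene_column if gene_column is not None else df.columns[0]
        return cls(df.set_index(gene_col))

    def to_tsv(self, path: str | Path) -> None:
        self.tpm.rename_axis("gene").reset_index().to_csv(path, sep="\t", index=False)

    @property
    def genes(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.tpm.columns)

    def __contains__(self, cell: str) -> bool:
        return cell in self.tpm.columns


def expressed_set(e: ExpressionMatrix, cell: str, threshold: float = 1.0) -> set[str]:
    """Genes with TPM >= threshold in one cell type (boundary inclusive)."""
    if cell not in e:
        raise KeyError(f"cell type {cell!r} not in expression matrix")
    col = e.tpm[cell]
    return set(col.index[col >= threshold])


def maintenance_chain(e: ExpressionMatrix, lin: Lineage, threshold: float = 1.0) -> list[int]:
    """Counts of genes expressed at every stage up to and including stage k.

    The cumulative intersection makes the sequence non-increasing; the
    first element is the expressed count at the root stage.
    """
    maintained: set[str] | None = None
    counts: list[int] = []
    for stage in lin.stages:
        stage_set = expressed_set(e, stage, threshold)
        maintained = stage_set if maintained is None else maintained & stage_set
        counts.append(len(maintained))
    return counts


def maintained_sets(e: ExpressionMatrix, lin: Lineage, threshold: float = 1.0) -> list[set[str]]:
    """The cumulative-intersection gene sets behind :func:`maintenance_chain`."""
    out: list[set[str]] = []
    acc: set[str] | None = None
    for stage in lin.stages:
        stage_set = expressed_set(e, stage, threshold)
        acc = stage_set if acc is None else acc & stage_set
        out.append(set(acc))
    return out


def rounded_percent(numerator: int, denominator: int, decimals: int = 0) -> float:
    """100 * numerator / denominator, rounded half-up to ``decimals`` places.

    Half-up rounding matches how summary tables are conventionally
    printed (62.5 -> 63 at integer precision), unlike banker's rounding.
    """
    if denominator <= 0:
        raise ValueError(f"denominator must be positive, got {denominator}")
    if numerator < 0:
        raise ValueError(f"numerator must be non-negative, got {numerator}")
    quant = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        quant, rounding=ROUND_HALF_UP
    )
    return float(value)


def exclusive_overlap(sets: Mapping[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Counts of the 7 exclusive regions of a three-set Venn partition.

    Keys are sorted tuples of the set names whose members populate the
    region exclusively; values sum to the cardinality of the union.
    """
    if len(sets) != 3:
        raise ValueError(f"exactly three named sets required, got {len(sets)}")
    names = sorted(sets)
    universe = set().union(*sets.values())
    counts: dict[tuple[str, ...], int] = {}
    for mask in range(1, 8):
        members = [names[i] for i in range(3) if mask >> i & 1]
        region = set(universe)
        for name in names:
            if name in members:
                region &= sets[name]
            else:
                region -= sets[name]
        counts[tuple(members)] = len(region)
    return counts


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test, two-sided.

    Returns ``(z, p)`` where z uses the pooled-variance estimate and p
    comes from the standard normal, clipped to [0, 1]. Equal observed
    proportions give z = 0, p = 1 even when the pooled variance is
    degenerate (all successes or all failures).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("sample sizes must be positive")
        if not 0 <= k <= n:
            raise ValueError(f"count {k} outside [0, {n}]")
    if k1 * n2 == k2 * n1:  # identical proportions, incl. degenerate pooled variance
        return 0.0, 1.0
    z, p = proportions_ztest(
        count=np.array([k1, k2]), nobs=np.array([n1, n2]), alternative="two-sided"
    )
    return float(z), float(min(max(p, 0.0), 1.0))
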