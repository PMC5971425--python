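"""Synthetic cohort generator with planted, exactly recoverable ground truth.

The generator emulates the statistical structure of a two-lineage
hematopoietic study — a multipotent root (LSK-like), a shared myeloid
progenitor, then committed and mature stages of an erythroid-like and a
megakaryocyte-like branch — without any sequence content:

* a genome of equal-length chromosomes partitioned into per-gene blocks,
  one TSS per block, so every planted regulatory element has an
  unambiguous nearest gene;
* hierarchically nested accessibility (ATAC) peaks: an element planted
  at stage *s* is accessible at every later stage of its lineage, which
  makes per-stage presence fractions cumulative;
* H3K27ac peaks in the two mature cells defining active regulatory
  elements (AREs), split into cell-specific and shared classes with
  configurable per-stage establishment fractions;
* root-population reference H3K4me1/H3K27ac peaks realizing configured
  poised/active/open/acetylated-only proportions;
* per-stage methylation peaks hitting a configured fraction of the AREs
  established at that stage, emitted as two peak-caller "tool" tracks;
* a TPM table with a configurable on/off structure: root expression,
  per-stage retention and small de novo gain rates.

Class proportions (establishment, chromatin state, methylation) are
realized by largest-remainder quota rather than independent draws, so
aggregate fractions match the configuration exactly and every per-element
label is recoverable by the pipeline. Placement is collision-free by
construction: each gene block holds at most one element per side of its
TSS, with margins larger than the replicate coordinate jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .expression import Lineage
from .genome import GenomeAssembly

CLASSES = ("a_specific", "b_specific", "shared")
STATES = ("active", "poised", "open", "acetylated_only")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Defaults describe a desk-scale cohort with the on/off and
    establishment structure of a two-branch hematopoietic system:
    ~13k of 20k genes expressed at the root, megakaryocyte-like AREs
    mostly established at the root (0.89) and erythroid-like AREs
    established late (0.64 at the root, 0.14 de novo at commitment).
    """

    seed: int = 0
    n_chromosomes: int = 19
    chromosome_length: int = 10_000_000
    n_genes: int = 20_000
    lineages: tuple[Lineage, ...] = (
        Lineage("erythroid", ("LSK", "CMP", "CFU-E", "ERY")),
        Lineage("megakaryocytic", ("LSK", "CMP", "CFU-MK", "iMK")),
    )
    # AREs per specificity class (a = first lineage's mature cell)
    n_ares: Mapping[str, int] = field(
        default_factory=lambda: {"a_specific": 2098, "b_specific": 6386, "shared": 5989}
    )
    # per class: fraction established at each stage index along the lineage
    establishment_fractions: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "a_specific": (0.64, 0.20, 0.14, 0.02),
            "b_specific": (0.89, 0.08, 0.01, 0.02),
            "shared": (0.98, 0.01, 0.005, 0.005),
        }
    )
    # per class: (active, poised, open, acetylated_only) in the root reference
    state_proportions: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "a_specific": (0.20, 0.57, 0.21, 0.02),
            "b_specific": (0.46, 0.41, 0.09, 0.04),
            "shared": (0.79, 0.15, 0.04, 0.02),
        }
    )
    # per class: fraction of stage-s-established AREs overlapped by stage-s methylation
    methylation_overlap_rate: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "a_specific": (0.186, 0.037, 0.115, 0.021),
            "b_specific": (0.078, 0.023, 0.178, 0.124),
            "shared": (0.05, 0.05, 0.05, 0.05),
        }
    )
    # fraction of mature-cell H3K27ac peaks backed by accessible chromatin
    k27ac_atac_retention: float = 0.97
    # per class: fraction of ARE target genes expressed in the mature cell
    target_expressed_rate: Mapping[str, float] = field(
        default_factory=lambda: {"a_specific": 0.82, "b_specific": 0.89, "shared": 0.93}
    )
    peak_width: tuple[float, float] = (500.0, 100.0)  # mean, sd; truncated to bounds
    peak_width_bounds: tuple[int, int] = (200, 800)
    meth_peak_width: int = 300
    # nearest-TSS geometry: promoter band is <= 1 kb, enhancer band beyond it;
    # sampled away from the boundary so replicate jitter cannot flip the class
    cpe_fraction: float = 0.4
    promoter_distance_range: tuple[int, int] = (0, 950)
    enhancer_distance_range: tuple[int, int] = (1051, 3500)
    replicate_jitter_bp: int = 25
    meth_tool_jitter_bp: int = 20
    n_atac_replicates: int = 2
    n_chip_replicates: int = 4
    n_noise_peaks: int = 200  # replicate-specific peaks per ATAC/ChIP replicate
    n_meth_noise_peaks: int = 150  # tool-specific methylation peaks per tool
    n_reference_noise_peaks: int = 200  # extra root-reference peaks off AREs
    tpm_lognormal: tuple[float, float] = (1.0, 1.5)  # (mu, sigma) above the 1-TPM floor
    root_expressed_fraction: float = 0.6533
    expression_retention: Mapping[str, float] = field(
        default_factory=lambda: {
            "CMP": 0.900,
            "CFU-E": 0.745,
            "ERY": 0.940,
            "CFU-MK": 0.949,
            "iMK": 0.943,
        }
    )
    expression_gain: float = 0.06  # de novo activation rate for silent genes per stage
    nested: bool = True  # accessibility persists once established
    maintenance_prob: float = 0.8  # per-stage persistence when nested=False

    def __post_init__(self) -> None:
        if len(self.lineages) != 2:
            raise ValueError("exactly two lineages are required")
        la, lb = self.lineages
        if len(la.stages) != len(lb.stages):
            raise ValueError("lineages must have the same number of stages")
        prefix = _shared_prefix_len(la.stages, lb.stages)
        if prefix < 1 or prefix >= len(la.stages):
            raise ValueError("lineages must share a root prefix and diverge before the end")
        if set(la.stages[prefix:]) & set(lb.stages[prefix:]):
            raise ValueError("post-branch stages must be disjoint between lineages")
        n_stages = len(la.stages)
        for cls in CLASSES:
            fr = self.establishment_fractions[cls]
            if len(fr) != n_stages or abs(sum(fr) - 1.0) > 1e-9:
                raise ValueError(f"establishment_fractions[{cls}] must sum to 1 over {n_stages} stages")
            if abs(sum(self.state_proportions[cls]) - 1.0) > 1e-9:
                raise ValueError(f"state_proportions[{cls}] must sum to 1")
            for r in self.methylation_overlap_rate[cls]:
                if not 0.0 <= r <= 1.0:
                    raise ValueError("methylation rates must lie in [0, 1]")
        if not 0 < self.k27ac_atac_retention <= 1:
            raise ValueError("k27ac_atac_retention must lie in (0, 1]")
        if self.peak_width_bounds[0] < 2 * self.replicate_jitter_bp + 10:
            raise ValueError("minimum peak width too small for the configured jitter")
        # planted methylation peaks sit inside their ARE with 20 bp margins;
        # the two tool tracks must keep >= 100 bp pairwise overlap after jitter
        meth_w = min(self.meth_peak_width, self.peak_width_bounds[0] - 40)
        if meth_w - 2 * self.meth_tool_jitter_bp < 100:
            raise ValueError(
                "methylation peak width / tool jitter violate the 100 bp ensemble rule"
            )

    @property
    def n_stages(self) -> int:
        return len(self.lineages[0].stages)

    @property
    def shared_prefix(self) -> int:
        return _shared_prefix_len(self.lineages[0].stages, self.lineages[1].stages)

    @property
    def cell_types(self) -> list[str]:
        la, lb = self.lineages
        return list(la.stages) + [s for s in lb.stages if s not in la.stages]


def _shared_prefix_len(a: Sequence[str], b: Sequence[str]) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


@dataclass(frozen=True)
class GroundTruth:
    """Planted per-ARE labels and the per-gene per-cell expressed flags."""

    ares: pd.DataFrame
    expression: pd.DataFrame  # bool, genes x cell types

    def write(self, outdir: Path) -> None:
        outdir.mkdir(parents=True, exist_ok=True)
        self.ares.to_csv(outdir / "ares.tsv", sep="\t", index=False)
        self.expression.rename_axis("gene").reset_index().to_csv(
            outdir / "expression.tsv", sep="\t", index=False
        )


@dataclass(frozen=True)
class CohortBundle:
    """Paths of every emitted file, plus the planted ground truth."""

    root: Path
    chrom_sizes: Path
    tss: Path
    tpm: Path
    atac: dict[str, list[Path]]  # cell type -> replicate BEDs
    h3k27ac: dict[str, list[Path]]  # mature cell -> replicate BEDs
    reference: dict[str, Path]  # "h3k4me1" / "h3k27ac" root reference BEDs
    methylation: dict[str, dict[str, Path]]  # cell type -> tool -> BED
    pipeline_config: Path
    ground_truth: GroundTruth


def _quota_counts(proportions: Sequence[float], n: int) -> list[int]:
    """Largest-remainder apportionment of n items to the given proportions."""
    raw = [p * n for p in proportions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _quota_labels(
    labels: Sequence[str], proportions: Sequence[float], n: int, rng: np.random.Generator
) -> np.ndarray:
    counts = _quota_counts(proportions, n)
    out = np.repeat(np.array(labels, dtype=object), counts)
    return rng.permutation(out)


def _write_bed(path: Path, rows: list[tuple[str, int, int]]) -> None:
    rows = sorted(rows)
    with open(path, "w") as fh:
        for chrom, s, e in rows:
            fh.write(f"{chrom}\t{s}\t{e}\n")


def generate_cohort(cfg: SimulationConfig, outdir: str | Path) -> CohortBundle:
    """Generate the full file bundle and its ground truth under ``outdir``.

    The same configuration (including seed) always produces a
    byte-identical bundle.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    lin_a, lin_b = cfg.lineages
    prefix = cfg.shared_prefix
    cells = cfg.cell_types

    # ---- genome and gene blocks ------------------------------------------
    genome = GenomeAssembly.from_items(
        (f"chr{i + 1}", cfg.chromosome_length) for i in range(cfg.n_chromosomes)
    )
    blocks_per_chrom = -(-cfg.n_genes // cfg.n_chromosomes)  # ceil
    block_w = cfg.chromosome_length // blocks_per_chrom
    d_max = cfg.enhancer_distance_range[1]
    w_max = cfg.peak_width_bounds[1]
    needed = 2 * (d_max + w_max + cfg.replicate_jitter_bp + 75)
    if block_w < needed:
        raise ValueError(
            f"gene blocks of {block_w} bp are too narrow for the requested geometry "
            f"(need >= {needed} bp); enlarge the genome or reduce n_genes/distances"
        )
    total_ares = sum(cfg.n_ares[c] for c in CLASSES)
    if total_ares * (w_max + cfg.meth_peak_width) > 0.5 * genome.total_length:
        raise ValueError("requested peak bases exceed ~50% of the genome")
    if total_ares > cfg.n_genes:
        raise ValueError("more AREs requested than gene blocks available")

    gene_ids = [f"gene{i:05d}" for i in range(cfg.n_genes)]
    block_chrom = [f"chr{i // blocks_per_chrom + 1}" for i in range(cfg.n_genes)]
    block_start = [(i % blocks_per_chrom) * block_w for i in range(cfg.n_genes)]
    tss_pos = [s + block_w // 2 for s in block_start]
    strand = rng.choice(np.array(["+", "-"]), size=cfg.n_genes)

    # ---- expression on/off structure and TPM table -----------------------
    expressed: dict[str, np.ndarray] = {}
    root = lin_a.stages[0]
    expressed[root] = rng.random(cfg.n_genes) < cfg.root_expressed_fraction
    parent_of: dict[str, str] = {}
    for lin in cfg.lineages:
        for i in range(1, len(lin.stages)):
            parent_of[lin.stages[i]] = lin.stages[i - 1]
    for cell in cells:
        if cell == root:
            continue
        parent = expressed[parent_of[cell]]
        keep = rng.random(cfg.n_genes) < cfg.expression_retention[cell]
        gain = rng.random(cfg.n_genes) < cfg.expression_gain
        expressed[cell] = np.where(parent, keep, gain)
    tpm = pd.DataFrame(index=pd.Index(gene_ids, name="gene"))
    mu, sigma = cfg.tpm_lognormal
    for cell in cells:
        on = expressed[cell]
        values = np.where(
            on,
            1.0 + rng.lognormal(mu, sigma, cfg.n_genes),
            rng.uniform(0.0, 0.999, cfg.n_genes),
        )
        tpm[cell] = np.round(values, 3)

    # ---- choose host genes per ARE class (planted target-expression rate)
    mature_a, mature_b = lin_a.stages[-1], lin_b.stages[-1]
    class_expr_flag = {
        "a_specific": expressed[mature_a],
        "b_specific": expressed[mature_b],
        "shared": expressed[mature_a] & expressed[mature_b],
    }
    # two ARE slots per gene block (left/right of the TSS)
    slots_used: dict[int, set[str]] = {}
    ares_rows: list[dict] = []

    def pick_hosts(cls: str, n: int) -> list[int]:
        want_expr = int(round(cfg.target_expressed_rate[cls] * n))
        flag = class_expr_flag[cls]
        free = np.array(
            [len(slots_used.get(g, ())) < 2 for g in range(cfg.n_genes)], dtype=bool
        )
        pool_on = np.flatnonzero(flag & free)
        pool_off = np.flatnonzero(~flag & free)
        if len(pool_on) < want_expr or len(pool_off) < n - want_expr:
            raise ValueError(
                f"not enough free gene blocks for class {cls!r}: "
                f"need {want_expr} expressed / {n - want_expr} silent hosts"
            )
        chosen = list(rng.choice(pool_on, size=want_expr, replace=False)) + list(
            rng.choice(pool_off, size=n - want_expr, replace=False)
        )
        return [int(g) for g in chosen]

    for cls in CLASSES:
        n_c = cfg.n_ares[cls]
        hosts = pick_hosts(cls, n_c)
        est_idx = _quota_labels(
            [str(i) for i in range(cfg.n_stages)],
            cfg.establishment_fractions[cls],
            n_c,
            rng,
        ).astype(int)
        states = _quota_labels(STATES, cfg.state_proportions[cls], n_c, rng)
        # methylation quota within each establishment-stage group
        meth = np.zeros(n_c, dtype=bool)
        for s in range(cfg.n_stages):
            members = np.flatnonzero(est_idx == s)
            k = int(round(cfg.methylation_overlap_rate[cls][s] * len(members)))
            if k:
                meth[rng.choice(members, size=k, replace=False)] = True
        is_cpe = _quota_labels(
            ["cPE", "cEE"], (cfg.cpe_fraction, 1 - cfg.cpe_fraction), n_c, rng
        )
        for i in range(n_c):
            g = hosts[i]
            used = slots_used.setdefault(g, set())
            slot = "L" if "L" not in used else "R"
            used.add(slot)
            width = int(
                np.clip(
                    rng.normal(cfg.peak_width[0], cfg.peak_width[1]),
                    *cfg.peak_width_bounds,
                )
            )
            if is_cpe[i] == "cPE":
                lo, hi = cfg.promoter_distance_range
                if slot == "R":
                    lo = max(lo, 601)  # keep clear of a possible TSS-containing left peak
                d = int(rng.integers(lo, hi + 1))
            else:
                lo, hi = cfg.enhancer_distance_range
                d = int(rng.integers(lo, hi + 1))
            t = tss_pos[g]
            if slot == "L":
                if d == 0:
                    start = t - width // 2
                else:
                    start = t - d + 1 - width
            else:
                start = t + d
            ares_rows.append(
                {
                    "are_id": f"{cls}_{i:05d}",
                    "class": cls,
                    "gene": gene_ids[g],
                    "chrom": block_chrom[g],
                    "start": start,
                    "end": start + width,
                    "establishment_index": int(est_idx[i]),
                    "establishment_stage_a": lin_a.stages[est_idx[i]]
                    if cls != "b_specific"
                    else "",
                    "establishment_stage_b": lin_b.stages[est_idx[i]]
                    if cls != "a_specific"
                    else "",
                    "chromatin_state": str(states[i]),
                    "methylated": bool(meth[i]),
                    "tss_distance": d,
                    "proximity_class": str(is_cpe[i]),
                    "target_expressed": bool(class_expr_flag[cls][g]),
                }
            )
    gt_ares = pd.DataFrame(ares_rows).sort_values(["chrom", "start", "end"], kind="mergesort")
    gt_ares = gt_ares.reset_index(drop=True)

    # free blocks host auxiliary (non-ARE) features
    free_blocks = np.array(
        [g for g in range(cfg.n_genes) if g not in slots_used], dtype=np.int64
    )

    def aux_peaks(n: int, width: int, blocks: np.ndarray) -> list[tuple[str, int, int]]:
        chosen = rng.choice(blocks, size=n, replace=False)
        out = []
        for g in chosen:
            g = int(g)
            lo = block_start[g] + 100
            hi = block_start[g] + block_w - 100 - width
            s = int(rng.integers(lo, hi + 1))
            out.append((block_chrom[g], s, s + width))
        return out

    def jitter(rows: list[tuple[str, int, int]], j: int) -> list[tuple[str, int, int]]:
        out = []
        for chrom, s, e in rows:
            ds = int(rng.integers(-j, j + 1))
            de = int(rng.integers(-j, j + 1))
            out.append((chrom, max(0, s + ds), e + de))
        return out

    # ---- presence of each ARE in each cell's accessibility profile -------
    stage_pos: dict[str, dict[str, int]] = {
        lin.name: {s: i for i, s in enumerate(lin.stages)} for lin in cfg.lineages
    }

    def present_in(cell: str, cls: str, est: int, row_idx: int) -> bool:
        positions = []
        for lin in cfg.lineages:
            if cell in stage_pos[lin.name]:
                if cls == "a_specific" and lin is not lin_a:
                    if stage_pos[lin.name][cell] >= prefix:
                        continue
                if cls == "b_specific" and lin is not lin_b:
                    if stage_pos[lin.name][cell] >= prefix:
                        continue
                positions.append(stage_pos[lin.name][cell])
        if not positions:
            return False
        pos = max(positions)
        if pos < est:
            return False
        if cfg.nested or pos == est:
            return True
        # non-nested mode: accessibility persists stage-to-stage in a chain,
        # deterministic per ARE so presence is monotone along the lineage
        persist = np.random.default_rng((cfg.seed, 7919, row_idx)).random(cfg.n_stages)
        return bool((persist[est:pos] < cfg.maintenance_prob).all())

    are_interval = list(
        zip(gt_ares["chrom"], gt_ares["start"].astype(int), gt_ares["end"].astype(int))
    )
    cls_list = list(gt_ares["class"])
    est_list = [int(x) for x in gt_ares["establishment_index"]]
    state_list = list(gt_ares["chromatin_state"])
    meth_list = list(gt_ares["methylated"])

    # ---- write genome, TSS, TPM ------------------------------------------
    chrom_sizes_path = outdir / "genome.chrom.sizes"
    genome.to_chrom_sizes(chrom_sizes_path)
    tss_path = outdir / "tss.tsv"
    with open(tss_path, "w") as fh:
        fh.write("gene\tchrom\tposition\tstrand\n")
        for g in range(cfg.n_genes):
            fh.write(f"{gene_ids[g]}\t{block_chrom[g]}\t{tss_pos[g]}\t{strand[g]}\n")
    tpm_path = outdir / "tpm.tsv"
    tpm.reset_index().to_csv(tpm_path, sep="\t", index=False)

    # ---- ATAC replicates per cell ----------------------------------------
    atac_dir = outdir / "atac"
    atac_dir.mkdir(exist_ok=True)
    atac_paths: dict[str, list[Path]] = {}
    for cell in cells:
        planted = [
            are_interval[i]
            for i in range(len(gt_ares))
            if present_in(cell, cls_list[i], est_list[i], i)
        ]
        reps = []
        # replicate-specific noise lives in distinct free blocks per stage
        noise_blocks = rng.choice(
            free_blocks, size=cfg.n_noise_peaks * cfg.n_atac_replicates, replace=False
        )
        for r in range(cfg.n_atac_replicates):
            rows = jitter(planted, cfg.replicate_jitter_bp)
            blocks_r = noise_blocks[r * cfg.n_noise_peaks : (r + 1) * cfg.n_noise_peaks]
            rows += aux_peaks(cfg.n_noise_peaks, 400, blocks_r)
            path = atac_dir / f"{cell}.rep{r + 1}.bed"
            _write_bed(path, rows)
            reps.append(path)
        atac_paths[cell] = reps

    # ---- H3K27ac ChIP replicates in the mature cells ---------------------
    chip_dir = outdir / "h3k27ac"
    chip_dir.mkdir(exist_ok=True)
    chip_paths: dict[str, list[Path]] = {}
    extra_frac = (1.0 - cfg.k27ac_atac_retention) / cfg.k27ac_atac_retention
    for cell, classes in ((mature_a, ("a_specific", "shared")), (mature_b, ("b_specific", "shared"))):
        members = [
            are_interval[i] for i in range(len(gt_ares)) if cls_list[i] in classes
        ]
        n_extra = int(round(extra_frac * len(members)))
        extras = aux_peaks(n_extra, 500, free_blocks) if n_extra else []
        reps = []
        for r in range(cfg.n_chip_replicates):
            rows = jitter(members + extras, cfg.replicate_jitter_bp)
            rows += aux_peaks(cfg.n_noise_peaks, 400, free_blocks)
            path = chip_dir / f"{cell}.rep{r + 1}.bed"
            _write_bed(path, rows)
            reps.append(path)
        chip_paths[cell] = reps

    # ---- root-reference marks realizing the chromatin states -------------
    ref_dir = outdir / "reference"
    ref_dir.mkdir(exist_ok=True)
    me1_rows = [
        are_interval[i]
        for i in range(len(gt_ares))
        if state_list[i] in ("active", "poised")
    ]
    k27_rows = [
        are_interval[i]
        for i in range(len(gt_ares))
        if state_list[i] in ("active", "acetylated_only")
    ]
    me1_rows += aux_peaks(cfg.n_reference_noise_peaks, 600, free_blocks)
    k27_rows += aux_peaks(cfg.n_reference_noise_peaks, 600, free_blocks)
    ref_paths = {
        "h3k4me1": ref_dir / "root.h3k4me1.bed",
        "h3k27ac": ref_dir / "root.h3k27ac.bed",
    }
    _write_bed(ref_paths["h3k4me1"], me1_rows)
    _write_bed(ref_paths["h3k27ac"], k27_rows)

    # ---- methylation tool tracks per cell --------------------------------
    meth_dir = outdir / "methylation"
    meth_dir.mkdir(exist_ok=True)
    meth_paths: dict[str, dict[str, Path]] = {}
    meth_cell_of_row: list[str | None] = []
    for i in range(len(gt_ares)):
        if not meth_list[i]:
            meth_cell_of_row.append(None)
            continue
        lin = lin_b if cls_list[i] == "b_specific" else lin_a
        meth_cell_of_row.append(lin.stages[est_list[i]])
    for cell in cells:
        planted = []
        for i in range(len(gt_ares)):
            if meth_cell_of_row[i] != cell:
                continue
            chrom, s, e = are_interval[i]
            center = (s + e) // 2
            half = cfg.meth_peak_width // 2
            lo = max(s + 20, center - half)
            planted.append((chrom, lo, min(e - 20, lo + cfg.meth_peak_width)))
        tools = {}
        for tool in ("toolA", "toolB"):
            rows = []
            for chrom, s, e in planted:
                # jitter inward-bounded so the tool pair keeps >= 100 bp overlap
                ds = int(rng.integers(-cfg.meth_tool_jitter_bp, cfg.meth_tool_jitter_bp + 1))
                de = int(rng.integers(-cfg.meth_tool_jitter_bp, cfg.meth_tool_jitter_bp + 1))
                rows.append((chrom, max(0, s + ds), e + de))
            rows += aux_peaks(cfg.n_meth_noise_peaks, 300, free_blocks)
            path = meth_dir / f"{cell}.{tool}.bed"
            _write_bed(path, rows)
            tools[tool] = path
        meth_paths[cell] = tools

    # ---- ground truth and ready-to-run pipeline config -------------------
    gt = GroundTruth(
        ares=gt_ares,
        expression=pd.DataFrame(
            {c: expressed[c] for c in cells}, index=pd.Index(gene_ids, name="gene")
        ),
    )
    gt.write(outdir / "ground_truth")
    # paths are stored relative to the cohort root so the bundle is portable
    # (and byte-identical across output locations for one seed)
    def rel(p: Path) -> str:
        return str(p.relative_to(outdir))

    pipeline_cfg = {
        "genome": rel(chrom_sizes_path),
        "tss": rel(tss_path),
        "expression": rel(tpm_path),
        "lineages": {lin.name: list(lin.stages) for lin in cfg.lineages},
        "atac": {c: [rel(p) for p in atac_paths[c]] for c in cells},
        "h3k27ac": {c: [rel(p) for p in chip_paths[c]] for c in chip_paths},
        "reference": {k: rel(v) for k, v in ref_paths.items()},
        "methylation": {c: {t: rel(p) for t, p in meth_paths[c].items()} for c in cells},
        "thresholds": {
            "tpm": 1.0,
            "tss_proximity_bp": 1000,
            "min_overlap_bp": 1,
            "mbd_min_tools": 2,
            "mbd_min_overlap_bp": 100,
        },
        "permutation": {"n": 500, "seed": cfg.seed},
        "output": "report",
    }
    cfg_path = outdir / "pipeline.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(pipeline_cfg, fh, sort_keys=True)
    return CohortBundle(
        root=outdir,
        chrom_sizes=chrom_sizes_path,
        tss=tss_path,
        tpm=tpm_path,
        atac=atac_paths,
        h3k27ac=chip_paths,
        reference=ref_paths,
        methylation=meth_paths,
        pipeline_config=cfg_path,
        ground_truth=gt,
    )


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A fast, reduced cohort for tests and examples (same structure)."""
    base = dict(
        seed=seed,
        n_chromosomes=4,
        chromosome_length=6_000_000,
        n_genes=2_000,
        n_ares={"a_specific": 220, "b_specific": 420, "shared": 300},
        n_noise_peaks=40,
        n_meth_noise_peaks=30,
        n_reference_noise_peaks=40,
    )
    base.update(overrides)
    return SimulationConfig(**base)
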