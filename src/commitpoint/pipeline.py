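"""End-to-end orchestration: consensus -> AREs -> establishment -> state ->
TSS/proximity -> expression & methylation overlap -> permutation tests.

The pipeline consumes a single YAML configuration naming every input
file and threshold, and writes a bundle of summary tables (TSV) plus a
JSON digest. With a fixed permutation seed the whole report is
reproducible byte for byte, and every number in it can be recomputed by
calling the underlying module functions with the same inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import ares as ares_mod
from .ares import (
    TssAnnotation,
    assign_nearest_tss,
    build_catalog,
    classify_chromatin_state,
    derive_ares,
    establishment_profile,
    partition_specificity,
    target_expressed_fraction,
)
from .consensus import ReplicateGroup, consensus_in_merged_regions, ensemble_consensus
from .expression import (
    ExpressionMatrix,
    Lineage,
    exclusive_overlap,
    expressed_set,
    maintenance_chain,
    rounded_percent,
    two_proportion_test,
)
from .genome import GenomeAssembly
from .intervals import PeakSet, overlap_flags, read_bed
from .permutation import PermutationConfig, permutation_overlap_test

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    tpm: float = 1.0
    tss_proximity_bp: int = 1000
    min_overlap_bp: int = 1
    mbd_min_tools: int = 2
    mbd_min_overlap_bp: int = 100

    def __post_init__(self) -> None:
        for name in ("tss_proximity_bp", "min_overlap_bp", "mbd_min_tools", "mbd_min_overlap_bp"):
            if getattr(self, name) < 1:
                raise ValueError(f"threshold {name} must be positive")


@dataclass(frozen=True)
class PipelineConfig:
    genome: Path
    tss: Path
    expression: Path
    lineages: tuple[Lineage, ...]
    atac: Mapping[str, tuple[Path, ...]]  # cell -> replicate BEDs
    h3k27ac: Mapping[str, tuple[Path, ...]]  # mature cell -> replicate BEDs
    reference: Mapping[str, Path]  # h3k4me1 / h3k27ac root reference
    methylation: Mapping[str, Mapping[str, Path]]  # cell -> tool -> BED
    output: Path
    thresholds: Thresholds = field(default_factory=Thresholds)
    permutation_n: int = 500
    permutation_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a configuration; relative paths resolve against the YAML's directory."""
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def resolve(p: str) -> Path:
            q = Path(p)
            return q if q.is_absolute() else base / q

        lineages = tuple(
            Lineage(name, tuple(stages)) for name, stages in raw["lineages"].items()
        )
        thr = Thresholds(**raw.get("thresholds", {}))
        perm = raw.get("permutation", {})
        return cls(
            genome=resolve(raw["genome"]),
            tss=resolve(raw["tss"]),
            expression=resolve(raw["expression"]),
            lineages=lineages,
            atac={c: tuple(resolve(p) for p in ps) for c, ps in raw["atac"].items()},
            h3k27ac={c: tuple(resolve(p) for p in ps) for c, ps in raw["h3k27ac"].items()},
            reference={k: resolve(v) for k, v in raw["reference"].items()},
            methylation={
                c: {t: resolve(p) for t, p in tools.items()}
                for c, tools in raw.get("methylation", {}).items()
            },
            output=resolve(raw["output"]),
            thresholds=thr,
            permutation_n=int(perm.get("n", 500)),
            permutation_seed=int(perm.get("seed", 0)),
        )

    def validate_files(self) -> None:
        """Fail before any computation if a referenced input is missing."""
        missing: list[str] = []
        paths: list[Path] = [self.genome, self.tss, self.expression]
        for group in (self.atac, self.h3k27ac):
            for ps in group.values():
                paths.extend(ps)
        paths.extend(self.reference.values())
        for tools in self.methylation.values():
            paths.extend(tools.values())
        for p in paths:
            if not Path(p).exists():
                missing.append(str(p))
        if missing:
            raise FileNotFoundError("missing input file(s): " + ", ".join(sorted(missing)))


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle under ``cfg.output``.

    Returns a dictionary of the in-memory results (catalogs, tables,
    permutation outcomes) mirroring what is written to disk.
    """
    cfg.validate_files()
    out = Path(cfg.output)
    out.mkdir(parents=True, exist_ok=True)
    thr = cfg.thresholds
    stage = "load-inputs"
    try:
        genome = GenomeAssembly.from_chrom_sizes(cfg.genome)
        tss = TssAnnotation.from_tsv(cfg.tss)
        expr = ExpressionMatrix.from_tsv(cfg.expression)
        lin_a, lin_b = cfg.lineages
        mature_a, mature_b = lin_a.stages[-1], lin_b.stages[-1]
        cells = list(dict.fromkeys(list(lin_a.stages) + list(lin_b.stages)))

        stage = "atac-consensus"
        atac_consensus: dict[str, PeakSet] = {}
        for cell, reps in cfg.atac.items():
            group = ReplicateGroup(
                cell, "atac", tuple(read_bed(p, genome, f"{cell}.atac.{i}") for i, p in enumerate(reps))
            )
            atac_consensus[cell] = consensus_in_merged_regions(group, require="all")

        stage = "h3k27ac-consensus"
        chip_consensus: dict[str, PeakSet] = {}
        for cell, reps in cfg.h3k27ac.items():
            group = ReplicateGroup(
                cell, "h3k27ac", tuple(read_bed(p, genome, f"{cell}.k27.{i}") for i, p in enumerate(reps))
            )
            chip_consensus[cell] = consensus_in_merged_regions(group, require="all")

        stage = "methylation-consensus"
        meth_consensus: dict[str, PeakSet] = {}
        for cell, tools in cfg.methylation.items():
            calls = [read_bed(p, genome, f"{cell}.mbd.{t}") for t, p in tools.items()]
            meth_consensus[cell] = ensemble_consensus(
                calls,
                min_tools=thr.mbd_min_tools,
                min_overlap_bp=thr.mbd_min_overlap_bp,
                label=f"{cell}.mbd.consensus",
            )

        stage = "derive-ares"
        ares_by_cell: dict[str, PeakSet] = {}
        retention: dict[str, float] = {}
        for cell in (mature_a, mature_b):
            ares_cell, frac = derive_ares(chip_consensus[cell], atac_consensus[cell])
            ares_by_cell[cell] = ares_cell
            retention[cell] = frac

        stage = "specificity-partition"
        a_spec, b_spec, shared = partition_specificity(
            ares_by_cell[mature_a], ares_by_cell[mature_b]
        )
        class_sets = {"a_specific": a_spec, "b_specific": b_spec, "shared": shared}
        class_lineage = {"a_specific": lin_a, "b_specific": lin_b, "shared": lin_a}

        stage = "expression-sets"
        expressed = {c: expressed_set(expr, c, thr.tpm) for c in cells}
        class_expressed = {
            "a_specific": expressed[mature_a],
            "b_specific": expressed[mature_b],
            "shared": expressed[mature_a] & expressed[mature_b],
        }

        stage = "establishment-and-annotation"
        catalogs: dict[str, ares_mod.AreCatalog] = {}
        profiles = {}
        for cls, ps in class_sets.items():
            lin = class_lineage[cls]
            stage_atac = [(s, atac_consensus[s]) for s in lin.stages]
            profile = establishment_profile(ps, stage_atac)
            states, _ = classify_chromatin_state(
                ps, read_bed(cfg.reference["h3k4me1"], genome), read_bed(cfg.reference["h3k27ac"], genome)
            )
            assignments = assign_nearest_tss(ps, tss)
            meth_flags = _methylation_flags(ps, profile, lin, meth_consensus)
            catalogs[cls] = build_catalog(
                cell_type={"a_specific": mature_a, "b_specific": mature_b, "shared": "shared"}[cls],
                ares=ps,
                specificity="shared" if cls == "shared" else "cell_specific",
                profile=profile,
                states=states,
                assignments=assignments,
                expressed=class_expressed[cls],
                methylated_flags=meth_flags,
                tss_threshold=thr.tss_proximity_bp,
            )
            profiles[cls] = profile

        stage = "summary-tables"
        tables = _write_tables(
            out, cfg, genome, expr, expressed, atac_consensus, meth_consensus,
            retention, class_sets, profiles, catalogs, class_expressed,
        )

        stage = "permutation-tests"
        perm_rows = []
        for cls, ps in class_sets.items():
            lin = class_lineage[cls]
            for idx, s in enumerate(lin.stages):
                pcfg = PermutationConfig(
                    n_permutations=cfg.permutation_n,
                    seed=cfg.permutation_seed + 1000 * idx + hash_cls(cls),
                )
                res = permutation_overlap_test(ps, atac_consensus[s], genome, pcfg)
                perm_rows.append(
                    {
                        "class": cls,
                        "stage": s,
                        "observed": res.observed,
                        "null_mean": round(res.null_mean, 3),
                        "null_sd": round(res.null_sd, 3),
                        "z": round(res.z, 3) if res.z_defined else "undefined",
                        "p_empirical": round(res.p_empirical, 6),
                        "n_permutations": res.n_permutations,
                    }
                )
        perm_df = pd.DataFrame(perm_rows)
        perm_df.to_csv(out / "permutation_tests.tsv", sep="\t", index=False)
        tables["permutation_tests"] = perm_df

        stage = "digest"
        digest = {
            "thresholds": {
                "tpm": thr.tpm,
                "tss_proximity_bp": thr.tss_proximity_bp,
                "min_overlap_bp": thr.min_overlap_bp,
                "mbd_min_tools": thr.mbd_min_tools,
                "mbd_min_overlap_bp": thr.mbd_min_overlap_bp,
            },
            "permutation": {"n": cfg.permutation_n, "seed": cfg.permutation_seed},
            "ares": {cls: len(ps) for cls, ps in class_sets.items()},
            "h3k27ac_atac_retention": {c: round(v, 4) for c, v in retention.items()},
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(digest, fh, indent=2, sort_keys=True)
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
    return {
        "catalogs": catalogs,
        "class_sets": class_sets,
        "profiles": profiles,
        "tables": tables,
        "digest": digest,
        "atac_consensus": atac_consensus,
        "meth_consensus": meth_consensus,
    }


def hash_cls(cls: str) -> int:
    """Small stable per-class offset for permutation sub-seeds."""
    return {"a_specific": 1, "b_specific": 2, "shared": 3}.get(cls, 9)


def _methylation_flags(ps, profile, lin: Lineage, meth_consensus) -> list[bool]:
    """Flag each ARE by overlap with the methylation peaks of its establishment stage."""
    flags = [False] * len(ps)
    for s in lin.stages:
        if s not in meth_consensus:
            continue
        hits = overlap_flags(ps, meth_consensus[s]) if len(ps) else []
        for i in range(len(ps)):
            if profile.establishment_stage[i] == s and hits[i]:
                flags[i] = True
    return flags


def _write_tables(
    out, cfg, genome, expr, expressed, atac_consensus, meth_consensus,
    retention, class_sets, profiles, catalogs, class_expressed,
):
    thr = cfg.thresholds
    lin_a, lin_b = cfg.lineages
    tables: dict[str, pd.DataFrame] = {}

    # feature counts per cell population
    rows = []
    cells = list(dict.fromkeys(list(lin_a.stages) + list(lin_b.stages)))
    for c in cells:
        rows.append(
            {
                "cell_type": c,
                "n_expressed": len(expressed[c]),
                "n_atac_consensus": len(atac_consensus[c]) if c in atac_consensus else 0,
                "n_methylation_consensus": len(meth_consensus[c]) if c in meth_consensus else 0,
            }
        )
    tables["feature_counts"] = pd.DataFrame(rows)

    # maintenance chains with percentages
    rows = []
    for lin in (lin_a, lin_b):
        counts = maintenance_chain(expr, lin, thr.tpm)
        for i, s in enumerate(lin.stages):
            rows.append(
                {
                    "lineage": lin.name,
                    "stage": s,
                    "n_maintained": counts[i],
                    "pct_of_root": rounded_percent(counts[i], counts[0]),
                    "pct_of_previous": rounded_percent(counts[i], counts[i - 1]) if i else 100.0,
                }
            )
    tables["maintenance_chains"] = pd.DataFrame(rows)

    # expressed-set Venn across the shared progenitor and the two mature cells
    branch_point = lin_a.stages[1] if len(lin_a.stages) > 2 else lin_a.stages[0]
    venn = exclusive_overlap(
        {
            branch_point: expressed[branch_point],
            lin_a.stages[-1]: expressed[lin_a.stages[-1]],
            lin_b.stages[-1]: expressed[lin_b.stages[-1]],
        }
    )
    tables["expressed_venn"] = pd.DataFrame(
        [{"region": "+".join(k), "count": v} for k, v in sorted(venn.items())]
    )

    # mature-cell maintained fractions compared by a two-proportion test
    chain_a = maintenance_chain(expr, lin_a, thr.tpm)
    chain_b = maintenance_chain(expr, lin_b, thr.tpm)
    z, p = two_proportion_test(chain_a[-1], chain_a[0], chain_b[-1], chain_b[0])
    tables["maintained_proportion_test"] = pd.DataFrame(
        [
            {
                "lineage_a_maintained": chain_a[-1],
                "lineage_a_root": chain_a[0],
                "lineage_b_maintained": chain_b[-1],
                "lineage_b_root": chain_b[0],
                "z": round(z, 4),
                "p_two_sided": p,
            }
        ]
    )

    # per-class establishment presence fractions and stage counts
    rows = []
    for cls, profile in profiles.items():
        fr = profile.presence_fractions
        counts = profile.stage_counts()
        for s in profile.stages:
            rows.append(
                {
                    "class": cls,
                    "stage": s,
                    "n_established": counts[s],
                    "presence_fraction": round(fr[s], 4),
                }
            )
    tables["establishment"] = pd.DataFrame(rows)

    # chromatin states per class
    rows = []
    for cls, cat in catalogs.items():
        df = cat.to_frame()
        n = len(df)
        for state in ares_mod.CHROMATIN_STATES:
            k = int((df["chromatin_state"] == state).sum())
            rows.append(
                {
                    "class": cls,
                    "state": state,
                    "count": k,
                    "fraction": round(k / n, 4) if n else float("nan"),
                }
            )
    tables["chromatin_states"] = pd.DataFrame(rows)

    # target-gene expression per class and establishment stage (cumulative)
    rows = []
    for cls, cat in catalogs.items():
        df = cat.to_frame()
        stages = list(profiles[cls].stages)
        for i, s in enumerate(stages):
            sub = df[df["establishment_stage"].isin(stages[: i + 1])]
            assignments = [
                (g if g != "unassigned" else None, None) for g in sub["nearest_gene"]
            ]
            te = target_expressed_fraction(assignments, class_expressed[cls])
            rows.append(
                {
                    "class": cls,
                    "established_by": s,
                    "n_ares": te.n_ares,
                    "n_unassigned": te.n_unassigned,
                    "n_target_genes": te.n_target_genes,
                    "n_expressed": te.n_expressed,
                    "pct_expressed": te.percent,
                }
            )
    tables["target_expression"] = pd.DataFrame(rows)

    # methylation overlap per class and establishment stage
    rows = []
    for cls, cat in catalogs.items():
        df = cat.to_frame()
        for s in profiles[cls].stages:
            sub = df[df["establishment_stage"] == s]
            n = len(sub)
            k = int(sub["methylated"].sum())
            rows.append(
                {
                    "class": cls,
                    "establishment_stage": s,
                    "n_methylated": k,
                    "n_ares": n,
                    "pct": rounded_percent(k, n, 1) if n else float("nan"),
                }
            )
    tables["methylation_overlap"] = pd.DataFrame(rows)

    # proximity classes
    rows = []
    for cls, cat in catalogs.items():
        df = cat.to_frame()
        for pc in ("cPE", "cEE"):
            rows.append({"class": cls, "proximity_class": pc, "count": int((df["proximity_class"] == pc).sum())})
    tables["proximity_classes"] = pd.DataFrame(rows)

    for name, df in tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    for cls, cat in catalogs.items():
        cat.to_tsv(out / f"are_catalog_{cls}.tsv")
    return tables
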