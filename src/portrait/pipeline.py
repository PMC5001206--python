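"""End-to-end orchestration: subtyping, the four similarity layers, scoring.

Two entry points:

* :func:`score_cohort` runs the whole comparison in memory on a
  :class:`~portrait.simulate.SyntheticCohort` (or any equivalently shaped
  tables) — this is what the tests and the analysis drivers use;
* :func:`run_pipeline` is the file-driven variant behind ``portrait run``:
  it reads the per-layer inputs named in a YAML config, executes whichever
  layers have inputs, writes every intermediate table as TSV plus a run
  manifest, and aborts naming the failing stage on error.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .cnv import (
    DEFAULT_FGA_THRESHOLD_CELL,
    DEFAULT_FGA_THRESHOLD_TUMOR,
    cnv_similarity,
    fga_per_sample,
    map_segments_to_genes,
)
from .correlate import write_correlation_table
from .errors import PortraitError
from .expression import expression_similarity
from .io import (
    LabeledMatrix,
    MutationTable,
    SegmentTable,
    read_annotations,
    read_bed_coverage,
    read_gene_models,
    read_maf,
    read_matrix,
    read_seg,
    write_bed_coverage,
    write_gene_models,
    write_maf,
    write_matrix,
    write_seg,
)
from .mutation import binarize, filter_somatic_functional, mutation_similarity
from .protein import protein_similarity
from .scoring import components_from_means, rank_cell_lines
from .simulate import SyntheticCohort
from .subtyping import SubtypeCall, call_samples


def _split_matrix(matrix: LabeledMatrix, ids: list[str]) -> LabeledMatrix:
    return LabeledMatrix(matrix.data[[s for s in ids if s in matrix.data.columns]])


def score_cohort(
    cohort: SyntheticCohort,
    *,
    policy: str = "require_all",
    top_fraction: float = 0.10,
    subtype_match: bool = False,
) -> dict[str, Any]:
    """Run all four layers and the score on a generated cohort.

    Returns a dict with the per-layer correlation tables, the subtype calls,
    and the final score table.
    """
    cells, tumors = cohort.cell_ids, cohort.tumor_ids
    subtype_map = cohort.subtype_map() if subtype_match else None

    calls: list[SubtypeCall] = call_samples(
        pd.DataFrame(index=pd.Index(cells + tumors, name="sample_id")),
        expression=cohort.expression,
        centroids=cohort.centroids,
    )

    expr = expression_similarity(
        _split_matrix(cohort.expression, cells), _split_matrix(cohort.expression, tumors)
    )

    gene_cnv = map_segments_to_genes(cohort.segments, cohort.gene_models)
    cnv = cnv_similarity(
        _split_matrix(gene_cnv, cells), _split_matrix(gene_cnv, tumors),
        top_fraction=top_fraction,
    )

    muts = filter_somatic_functional(cohort.mutations)
    panel = sorted(set(muts.df["gene_id"]))
    binary = binarize(muts, panel, cells + tumors)
    mut = mutation_similarity(_split_matrix(binary, cells), _split_matrix(binary, tumors))

    prot = protein_similarity(
        _split_matrix(cohort.proteins, cells), _split_matrix(cohort.proteins, tumors),
        subtype_map=subtype_map,
    )

    components = components_from_means(
        cells,
        expression=expr.mean_per_cell(subtype_map),
        cnv=cnv.mean_per_cell(subtype_map),
        mutation=mut.mean_per_cell(subtype_map),
        protein=prot.mean_per_cell(subtype_map),
    )
    scores = rank_cell_lines(components, policy)
    return {
        "expression": expr, "cnv": cnv, "mutation": mut, "protein": prot,
        "subtype_calls": calls, "scores": scores, "gene_cnv": gene_cnv,
    }


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write a cohort as the standard SEG/MAF/BED/TSV files the CLI consumes."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cells, tumors = cohort.cell_ids, cohort.tumor_ids
    write_matrix(_split_matrix(cohort.expression, cells), out / "expr_cells.tsv")
    write_matrix(_split_matrix(cohort.expression, tumors), out / "expr_tumors.tsv")
    write_matrix(_split_matrix(cohort.proteins, cells), out / "rppa_cells.tsv")
    write_matrix(_split_matrix(cohort.proteins, tumors), out / "rppa_tumors.tsv")
    write_matrix(cohort.centroids, out / "centroids.tsv")
    seg = cohort.segments.df
    write_seg(SegmentTable(seg[seg["sample_id"].isin(cells)]), out / "cells.seg")
    write_seg(SegmentTable(seg[seg["sample_id"].isin(tumors)]), out / "tumors.seg")
    mut = cohort.mutations.df
    write_maf(MutationTable(mut[mut["sample_id"].isin(cells)]), out / "cells.maf")
    write_maf(MutationTable(mut[mut["sample_id"].isin(tumors)]), out / "tumors.maf")
    write_bed_coverage(cohort.coverage, out / "coverage.bed")
    write_gene_models(cohort.gene_models, out / "genes.bed")
    truth = cohort.truth.reset_index()
    with open(out / "truth.tsv", "w", encoding="utf-8", newline="\n") as fh:
        truth.to_csv(fh, sep="\t", index=False)


@dataclass
class PipelineConfig:
    """File-driven pipeline configuration (see ``portrait run --help``)."""

    outdir: Path
    expression: dict[str, Any] = field(default_factory=dict)
    cnv: dict[str, Any] = field(default_factory=dict)
    mutation: dict[str, Any] = field(default_factory=dict)
    protein: dict[str, Any] = field(default_factory=dict)
    subtyping: dict[str, Any] = field(default_factory=dict)
    policy: str = "require_all"
    subtype_match: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "outdir" not in raw:
            raise PortraitError("pipeline config must name an outdir")
        return cls(
            outdir=Path(raw["outdir"]),
            expression=raw.get("expression") or {},
            cnv=raw.get("cnv") or {},
            mutation=raw.get("mutation") or {},
            protein=raw.get("protein") or {},
            subtyping=raw.get("subtyping") or {},
            policy=raw.get("policy", "require_all"),
            subtype_match=bool(raw.get("subtype_match", False)),
        )


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Execute the configured layers; returns the score table.

    Per-layer correlation tables, FGA values and the score table are written
    under ``config.outdir``; a ``manifest.json`` records inputs, parameters
    and the package version.  On failure a ``FAILED`` marker naming the stage
    is left in the output directory and the error re-raised.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "policy": config.policy,
        "subtype_match": config.subtype_match,
        "layers": {},
    }
    stage = "setup"
    means: dict[str, pd.Series] = {}
    cell_ids: list[str] = []
    try:
        subtype_map = None
        if config.subtyping:
            stage = "subtyping"
            ann_path = config.subtyping["annotations"]
            ann = read_annotations(ann_path)
            expr_m = centroids = None
            if "expression" in config.subtyping:
                expr_m = read_matrix(config.subtyping["expression"])
            if "centroids" in config.subtyping:
                centroids = read_matrix(config.subtyping["centroids"])
            calls = call_samples(ann, expression=expr_m, centroids=centroids)
            call_df = pd.DataFrame(
                {
                    "sample_id": [c.sample_id for c in calls],
                    "ihc": [c.ihc_label.value for c in calls],
                    "centroid": [c.centroid_label.value for c in calls],
                    "centroid_r": [c.centroid_correlation for c in calls],
                    "final": [c.final_label.value for c in calls],
                }
            )
            with open(out / "subtype_calls.tsv", "w", encoding="utf-8", newline="\n") as fh:
                call_df.to_csv(fh, sep="\t", index=False)
            subtype_map = dict(zip(call_df["sample_id"], call_df["final"]))
            manifest["layers"]["subtyping"] = {"annotations": str(ann_path)}

        if config.expression:
            stage = "expression"
            cells = read_matrix(config.expression["cells"])
            tumors = read_matrix(config.expression["tumors"])
            genes = None
            if config.expression.get("genes"):
                genes = [
                    ln.strip()
                    for ln in open(config.expression["genes"], encoding="utf-8")
                    if ln.strip()
                ]
            table = expression_similarity(cells, tumors, genes)
            write_correlation_table(table, out / "expr_corr.tsv")
            means["expression"] = table.mean_per_cell(
                subtype_map if config.subtype_match else None
            )
            cell_ids = cell_ids or list(table.cell_ids)
            manifest["layers"]["expression"] = {
                k: str(v) for k, v in config.expression.items()
            }

        if config.cnv:
            stage = "cnv"
            seg_cells = read_seg(config.cnv["cells_seg"])
            seg_tumors = read_seg(config.cnv["tumors_seg"])
            models = read_gene_models(config.cnv["gene_models"])
            t_cell = float(config.cnv.get("fga_threshold_cell", DEFAULT_FGA_THRESHOLD_CELL))
            t_tumor = float(config.cnv.get("fga_threshold_tumor", DEFAULT_FGA_THRESHOLD_TUMOR))
            fga = pd.concat(
                [fga_per_sample(seg_cells, t_cell), fga_per_sample(seg_tumors, t_tumor)]
            )
            fga.rename_axis("sample_id").to_frame().to_csv(out / "fga.tsv", sep="\t")
            gc = map_segments_to_genes(seg_cells, models)
            gt = map_segments_to_genes(seg_tumors, models)
            table = cnv_similarity(
                gc, gt, top_fraction=float(config.cnv.get("top_fraction", 0.10))
            )
            write_correlation_table(table, out / "cnv_corr.tsv")
            means["cnv"] = table.mean_per_cell(subtype_map if config.subtype_match else None)
            cell_ids = cell_ids or list(table.cell_ids)
            manifest["layers"]["cnv"] = {
                "fga_threshold_cell": t_cell, "fga_threshold_tumor": t_tumor,
            }

        if config.mutation:
            stage = "mutation"
            maf_cells = filter_somatic_functional(read_maf(config.mutation["cells_maf"]))
            maf_tumors = filter_somatic_functional(read_maf(config.mutation["tumors_maf"]))
            if config.mutation.get("panel"):
                panel = [
                    ln.strip()
                    for ln in open(config.mutation["panel"], encoding="utf-8")
                    if ln.strip()
                ]
            else:
                panel = sorted(
                    set(maf_cells.df["gene_id"]) | set(maf_tumors.df["gene_id"])
                )
            bc = binarize(maf_cells, panel, maf_cells.sample_ids)
            bt = binarize(maf_tumors, panel, maf_tumors.sample_ids)
            table = mutation_similarity(bc, bt)
            write_correlation_table(table, out / "mut_corr.tsv")
            means["mutation"] = table.mean_per_cell(
                subtype_map if config.subtype_match else None
            )
            cell_ids = cell_ids or list(table.cell_ids)
            manifest["layers"]["mutation"] = {"panel_size": len(panel)}

        if config.protein:
            stage = "protein"
            cells = read_matrix(config.protein["cells"])
            tumors = read_matrix(config.protein["tumors"])
            table = protein_similarity(
                cells, tumors,
                subtype_map=subtype_map if config.subtype_match else None,
            )
            write_correlation_table(table, out / "prot_corr.tsv")
            means["protein"] = table.mean_per_cell()
            cell_ids = cell_ids or list(table.cell_ids)
            manifest["layers"]["protein"] = {
                k: str(v) for k, v in config.protein.items()
            }

        stage = "scoring"
        if not means:
            raise PortraitError("no layer inputs configured")
        components = components_from_means(cell_ids, **means)
        scores = rank_cell_lines(components, config.policy)
        with open(out / "scores.tsv", "w", encoding="utf-8", newline="\n") as fh:
            scores.to_csv(fh, sep="\t", index=False)
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return scores
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n", encoding="utf-8")
        print(f"pipeline failed in stage {stage!r}: {exc}", file=sys.stderr)
        raise
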