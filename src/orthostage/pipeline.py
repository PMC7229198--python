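"""End-to-end drivers: QC -> common genes -> harmonize -> joint PCA -> staging.

These functions wire the per-module operations into the cross-species staging
analysis so that scripts, tests and the CLI all execute the same path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .harmonize import HarmonizedMatrix, harmonize, merge_species
from .qc_filter import (
    QCConfig,
    common_genes,
    filter_cells,
    filter_genes_by_phenotype,
    log2_cpm,
)
from .quantify import CountMatrix
from .staging import PCAResult, assign_stage, run_pca


def synthetic_qc_config() -> QCConfig:
    """QC thresholds scaled to the synthetic matrices (~2,000 genes, ~25k
    counts/cell); the class defaults target the deposited human data."""
    return QCConfig(
        min_total_counts=5_000,
        max_total_counts=150_000,
        min_genes_detected=500,
        gene_cutoff_log2cpm=1.0,
    )


@dataclass
class StagingRun:
    common_gene_list: list
    harmonized: HarmonizedMatrix
    pca: PCAResult
    assignments: list
    qc_reports: dict = field(default_factory=dict)


def prepare_dataset(
    matrix: CountMatrix,
    qc_config: QCConfig,
    phenotype_key: str = "phenotype",
):
    """Cell QC, log2(CPM+1), and the phenotype-group gene filter for one
    dataset. Returns (retained matrix, log matrix, retained gene list, report)."""
    retained, report = filter_cells(matrix, qc_config)
    log_matrix = log2_cpm(retained)
    genes = filter_genes_by_phenotype(
        log_matrix,
        retained.feature_ids,
        retained.cell_meta[phenotype_key].to_numpy(),
        cutoff=qc_config.gene_cutoff_log2cpm,
        min_cell_fraction=qc_config.min_cell_fraction,
    )
    return retained, log_matrix, genes, report


def harmonize_and_stage(
    matrix_a: CountMatrix,
    matrix_b: CountMatrix,
    qc_config_a: QCConfig,
    qc_config_b: QCConfig,
    reference_dataset: str = "B",
    stage_key: str = "phenotype",
    pcs=(2, 3),
    n_components: int = 10,
    method: str = "centroid",
    stage_order=None,
    ortholog_map: dict | None = None,
) -> StagingRun:
    """The full cross-species analysis on two count matrices.

    Dataset B (the labeled embryo reference by default) provides stage labels;
    dataset A's cells are the queries whose developmental position is called.
    """
    ret_a, log_a, genes_a, rep_a = prepare_dataset(matrix_a, qc_config_a, stage_key)
    ret_b, log_b, genes_b, rep_b = prepare_dataset(matrix_b, qc_config_b, stage_key)

    shared = common_genes(genes_a, genes_b, ortholog_map)
    if not shared:
        raise ValueError("no genes pass the filters in both datasets")
    idx_a = [ret_a.feature_ids.index(g) for g in shared]
    idx_b = [ret_b.feature_ids.index(g) for g in shared]

    harm_a = harmonize(
        log_a[:, idx_a], ret_a.cell_ids, shared, ret_a.cell_meta, {"dataset": "A"}
    )
    harm_b = harmonize(
        log_b[:, idx_b], ret_b.cell_ids, shared, ret_b.cell_meta, {"dataset": "B"}
    )
    merged = merge_species(harm_a, harm_b, shared)

    k = min(n_components, min(merged.values.shape) - 1)
    pca = run_pca(merged.values, k=k)

    is_query = (merged.cell_meta["dataset"] == ("A" if reference_dataset == "B" else "B")).to_numpy()
    labels = merged.cell_meta[stage_key].to_numpy()
    assignments = assign_stage(
        pca, labels, is_query, pcs=pcs, method=method,
        stage_order=stage_order, cell_ids=merged.cell_ids,
    )
    return StagingRun(
        common_gene_list=shared,
        harmonized=merged,
        pca=pca,
        assignments=assignments,
        qc_reports={"A": rep_a, "B": rep_b},
    )


def staging_accuracy(run: StagingRun, truth_stage_of_cell: dict) -> float:
    """Fraction of query cells assigned their true stage.

    Merged cell ids carry a ``<dataset>:`` prefix; the truth mapping uses the
    original ids.
    """
    correct = total = 0
    for a in run.assignments:
        original = a.cell_id.split(":", 1)[1]
        if original in truth_stage_of_cell:
            total += 1
            correct += a.assigned_stage == truth_stage_of_cell[original]
    if total == 0:
        raise ValueError("no query cell has a truth label")
    return correct / total


def species_separation_on_pc1(run: StagingRun) -> dict:
    """Overlap diagnostics of the two datasets' PC1 score distributions."""
    pc1 = run.pca.scores[:, 0]
    ds = run.harmonized.cell_meta["dataset"].to_numpy()
    a, b = pc1[ds == "A"], pc1[ds == "B"]
    lo, hi = (a, b) if np.median(a) < np.median(b) else (b, a)
    n_overlap = int((lo >= hi.min()).sum() + (hi <= lo.max()).sum())
    return {
        "n_overlapping_cells": n_overlap,
        "separated": bool(lo.max() < hi.min()),
        "gap": float(hi.min() - lo.max()),
    }


def stage_order_correlation(run: StagingRun, stage_order, components=(2, 3)) -> dict:
    """Best Spearman correlation between stage rank and a PC score."""
    from scipy.stats import spearmanr

    order = {s: i for i, s in enumerate(stage_order)}
    labels = run.harmonized.cell_meta["phenotype"].to_numpy()
    stage_rank = np.array([order[s] for s in labels], dtype=float)
    best = {"component": None, "spearman_rho": 0.0}
    for comp in components:
        rho = spearmanr(stage_rank, run.pca.scores[:, comp - 1]).statistic
        if abs(rho) > abs(best["spearman_rho"]):
            best = {"component": comp, "spearman_rho": float(rho)}
    return best
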