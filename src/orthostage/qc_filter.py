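"""Cell- and gene-level quality filters and log2(CPM+1) normalization.

Boundary conventions follow the filters' wording exactly: cells with *fewer
than* ``min_total_counts`` total counts, *more than* ``max_total_counts``
counts, or *fewer than* ``min_genes_detected`` detected genes are removed, so
a cell sitting exactly on any threshold is kept. Gene retention requires
expression *strictly above* the cutoff in *at least* ``min_cell_fraction`` of
one phenotype group's cells (fraction boundary inclusive).

The default thresholds are those used for the deposited human CelSeq2 data
(12,500 / 60,000 / 4,500); they are dataset-scale parameters and should be
rescaled for matrices of different depth or gene-universe size. The two QC
descriptions in the source protocols differ in whether a lower counts bound is
applied; all three thresholds are on by default and ``min_total_counts=None``
reproduces the "<4,500 genes or >60,000 counts" variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantify import CountMatrix


@dataclass
class QCConfig:
    min_total_counts: int | None = 12_500
    max_total_counts: int | None = 60_000
    min_genes_detected: int | None = 4_500
    gene_cutoff_log2cpm: float = 1.0  # 1 for the non-human primate data, 5 for human
    min_cell_fraction: float = 0.10
    min_count_gene_filter: int = 1

    def __post_init__(self):
        if not 0 < self.min_cell_fraction <= 1:
            raise ValueError("min_cell_fraction must be in (0, 1]")
        if (
            self.min_total_counts is not None
            and self.max_total_counts is not None
            and self.min_total_counts >= self.max_total_counts
        ):
            raise ValueError("min_total_counts must be < max_total_counts")


def filter_cells(matrix: CountMatrix, config: QCConfig):
    """Remove low-quality cells; returns (retained matrix, report DataFrame)."""
    if matrix.n_cells == 0:
        warnings.warn("empty matrix passed to filter_cells", stacklevel=2)
        return matrix, pd.DataFrame(columns=["total_counts", "genes_detected", "retained"])

    totals = matrix.counts.sum(axis=1)
    detected = (matrix.counts > 0).sum(axis=1)
    keep = np.ones(matrix.n_cells, dtype=bool)
    if config.min_total_counts is not None:
        keep &= totals >= config.min_total_counts
    if config.max_total_counts is not None:
        keep &= totals <= config.max_total_counts
    if config.min_genes_detected is not None:
        keep &= detected >= config.min_genes_detected
    report = pd.DataFrame(
        {"total_counts": totals, "genes_detected": detected, "retained": keep},
        index=list(matrix.cell_ids),
    )
    return matrix.subset_cells(keep), report


def log2_cpm(matrix: CountMatrix) -> np.ndarray:
    """log2(1 + counts-per-million), computed per cell on the full matrix.

    CPM uses each cell's total over *all* genes, so it must be computed before
    any gene filtering.
    """
    totals = matrix.counts.sum(axis=1).astype(float)
    if (totals == 0).any():
        raise ValueError(
            "cell(s) with zero total counts; remove them with filter_cells first"
        )
    cpm = matrix.counts / totals[:, None] * 1e6
    return np.log2(1.0 + cpm)


def _group_fractions(values: np.ndarray, labels, predicate) -> np.ndarray:
    """Max over groups of the per-gene fraction of cells satisfying predicate."""
    labels = np.asarray(labels)
    best = np.zeros(values.shape[1])
    for group in pd.unique(labels):
        mask = labels == group
        n = int(mask.sum())
        if n == 0:
            continue
        frac = predicate(values[mask]).sum(axis=0) / n
        best = np.maximum(best, frac)
    return best


def filter_genes_by_phenotype(
    log_matrix: np.ndarray,
    gene_ids,
    phenotype_labels,
    cutoff: float,
    min_cell_fraction: float = 0.10,
) -> list:
    """Genes expressed strictly above ``cutoff`` log2(CPM+1) in at least
    ``min_cell_fraction`` of the cells of at least one phenotype group."""
    if len(phenotype_labels) != log_matrix.shape[0]:
        raise ValueError("one phenotype label required per cell")
    best = _group_fractions(log_matrix, phenotype_labels, lambda v: v > cutoff)
    return [g for g, f in zip(gene_ids, best) if f >= min_cell_fraction]


def filter_genes_min_count(
    matrix: CountMatrix,
    group_labels,
    min_count: int = 1,
    min_cell_fraction: float = 0.10,
) -> list:
    """Genes achieving ``min_count`` raw counts in at least
    ``min_cell_fraction`` of the cells of at least one condition group."""
    if len(group_labels) != matrix.n_cells:
        raise ValueError("one group label required per cell")
    best = _group_fractions(matrix.counts, group_labels, lambda v: v >= min_count)
    return [g for g, f in zip(matrix.feature_ids, best) if f >= min_cell_fraction]


def common_genes(set_a, set_b, ortholog_map: dict | None = None) -> list:
    """Deterministic sorted intersection of two gene sets.

    ``ortholog_map`` translates species-B ids into the shared (species-A /
    metaexon-table) namespace before intersecting; identity if omitted.
    """
    a = set(set_a)
    if ortholog_map is not None:
        b = {ortholog_map[g] for g in set_b if g in ortholog_map}
    else:
        b = set(set_b)
    return sorted(a & b)
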