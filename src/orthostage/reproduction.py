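"""Deposited-data reproduction checks.

These functions re-run the exact published filters on locally supplied copies
of the deposited datasets (the human CelSeq2 single-cell counts, the macaque
SC3-seq reference, and the published ortholog table). They take file paths —
downloading is the caller's job — and return the three headline numbers:
cells retained by the human cell QC variant, genes passing the 1-count/10%
filter, and the size of the cross-species common gene set.

Expected directory layout (see analysis/07_reproduce_accessions.py):

    <data_dir>/human_counts/        MTX bundle (matrix.mtx, cells.tsv,
                                    features.tsv, cell_meta.tsv with a
                                    ``phenotype`` column; control wells
                                    already excluded)
    <data_dir>/macaque_counts/      MTX bundle, cell_meta.tsv with the embryo
                                    stage in ``phenotype``
    <data_dir>/ortholog_genes.tsv   columns: gene_id_human, gene_id_macaque
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .matrix_io import read_matrix
from .qc_filter import (
    QCConfig,
    common_genes,
    filter_cells,
    filter_genes_by_phenotype,
    filter_genes_min_count,
    log2_cpm,
)

#: The "<4,500 expressed genes or >60,000 counts" cell-QC variant (no lower
#: counts bound), as applied to the deposited human data.
HUMAN_QC_VARIANT = QCConfig(
    min_total_counts=None,
    max_total_counts=60_000,
    min_genes_detected=4_500,
    gene_cutoff_log2cpm=5.0,
)

MACAQUE_QC = QCConfig(
    min_total_counts=None,
    max_total_counts=None,
    min_genes_detected=None,
    gene_cutoff_log2cpm=1.0,
)


def human_cell_qc(data_dir) -> dict:
    """Cell QC on the deposited human matrix; returns input/retained counts."""
    matrix = read_matrix(Path(data_dir) / "human_counts", fmt="mtx")
    retained, _ = filter_cells(matrix, HUMAN_QC_VARIANT)
    return {"n_input_cells": matrix.n_cells, "n_retained_cells": retained.n_cells,
            "matrix": retained}


def human_gene_detection(data_dir) -> dict:
    """The 1-count-in-10%-of-a-group gene filter on the retained human cells."""
    qc = human_cell_qc(data_dir)
    matrix = qc["matrix"]
    genes = filter_genes_min_count(
        matrix,
        matrix.cell_meta["phenotype"].to_numpy(),
        min_count=1,
        min_cell_fraction=0.10,
    )
    return {"n_retained_cells": matrix.n_cells, "n_genes_detected": len(genes),
            "genes": genes, "matrix": matrix}


def cross_species_common_genes(data_dir) -> dict:
    """Intersect filtered human and macaque gene sets through the ortholog
    table; returns the common-gene count."""
    data_dir = Path(data_dir)
    human = human_gene_detection(data_dir)
    macaque = read_matrix(data_dir / "macaque_counts", fmt="mtx")
    log_mac = log2_cpm(macaque)
    genes_mac = filter_genes_by_phenotype(
        log_mac,
        macaque.feature_ids,
        macaque.cell_meta["phenotype"].to_numpy(),
        cutoff=MACAQUE_QC.gene_cutoff_log2cpm,
        min_cell_fraction=0.10,
    )
    orth = pd.read_csv(data_dir / "ortholog_genes.tsv", sep="\t")
    ortholog_map = dict(zip(orth["gene_id_macaque"], orth["gene_id_human"]))
    human_in_table = set(orth["gene_id_human"])
    shared = common_genes(
        [g for g in human["genes"] if g in human_in_table], genes_mac, ortholog_map
    )
    return {
        "n_human_genes": len(human["genes"]),
        "n_macaque_genes": len(genes_mac),
        "n_common_genes": len(shared),
        "common_genes": shared,
    }
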