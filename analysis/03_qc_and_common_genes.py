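#!/usr/bin/env python
"""Cell QC, log2(CPM+1) normalization, per-phenotype gene filtering, and the
cross-species common gene set on the simulated count matrices.

The QC thresholds here are scaled to the synthetic data (~2,000 genes,
~25k counts/cell); the package defaults carry the deposited-data values.
"""

import argparse
from pathlib import Path

import pandas as pd

from orthostage import filter_cells, filter_genes_by_phenotype, log2_cpm, common_genes
from orthostage.matrix_io import read_matrix, write_matrix
from orthostage.pipeline import synthetic_qc_config


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results/qc"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    config = synthetic_qc_config()
    gene_sets = {}
    for sp in ("A", "B"):
        matrix = read_matrix(args.sim / f"counts_{sp}", fmt="mtx")
        retained, report = filter_cells(matrix, config)
        genes = filter_genes_by_phenotype(
            log2_cpm(retained), retained.feature_ids,
            retained.cell_meta["phenotype"].to_numpy(),
            config.gene_cutoff_log2cpm, config.min_cell_fraction,
        )
        gene_sets[sp] = genes
        report.to_csv(args.out / f"cell_qc_{sp}.tsv", sep="\t")
        write_matrix(retained, args.out / f"filtered_{sp}", fmt="mtx")
        print(
            f"species {sp}: {retained.n_cells}/{matrix.n_cells} cells retained, "
            f"{len(genes)}/{matrix.n_features} genes pass the "
            f"{config.gene_cutoff_log2cpm} log2(CPM+1) / "
            f"{config.min_cell_fraction:.0%}-of-a-phenotype filter"
        )

    shared = common_genes(gene_sets["A"], gene_sets["B"])
    pd.Series(shared).to_csv(args.out / "common_genes.txt", index=False, header=False)
    print(f"common gene set: {len(shared)} genes -> {args.out / 'common_genes.txt'}")


if __name__ == "__main__":
    main()
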