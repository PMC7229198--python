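#!/usr/bin/env python
"""Re-run the deposited-data checks on locally staged copies of the published
datasets (network downloads are the caller's job; nothing here is synthetic).

Expected layout under --data-dir:

    human_counts/       MTX bundle of the human CelSeq2 single-cell counts
                        (matrix.mtx, cells.tsv, features.tsv, cell_meta.tsv
                        with a ``phenotype`` column for the sorted fractions;
                        control wells excluded -> 370 cells)
    macaque_counts/     MTX bundle of the macaque embryo SC3-seq reference,
                        cell_meta.tsv with the embryo stage in ``phenotype``
    ortholog_genes.tsv  two columns: gene_id_human, gene_id_macaque (the
                        published metaexon table's gene pairing)

Reported numbers to compare with the published analysis: 300/370 cells
retained by the "<4,500 genes or >60,000 counts" QC, 8,403 genes passing the
1-count-in-10%-of-a-group filter, and 7,308 cross-species common genes.
"""

import argparse
import json
from pathlib import Path

from orthostage.reproduction import (
    cross_species_common_genes,
    human_cell_qc,
    human_gene_detection,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", type=Path, default=Path("data/accessions"))
    ap.add_argument("--out", type=Path, default=Path("results/accessions.json"))
    args = ap.parse_args()

    if not args.data_dir.exists():
        raise SystemExit(
            f"{args.data_dir} not found — stage the deposited datasets there "
            "first (see this script's docstring for the layout)"
        )

    qc = human_cell_qc(args.data_dir)
    genes = human_gene_detection(args.data_dir)
    shared = cross_species_common_genes(args.data_dir)
    results = {
        "human_cells_input": qc["n_input_cells"],
        "human_cells_retained": qc["n_retained_cells"],
        "human_genes_detected": genes["n_genes_detected"],
        "common_genes": shared["n_common_genes"],
    }
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(results, indent=2))
    for k, v in results.items():
        print(f"{k}: {v}")


if __name__ == "__main__":
    main()
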