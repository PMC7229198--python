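#!/usr/bin/env python
"""Quantitative staging: nearest-centroid assignment of species-A query cells
to the species-B reference stages in the PC2/PC3 subspace, scored against the
generator's stage truth."""

import argparse
from pathlib import Path

import pandas as pd

from orthostage import assign_stage, run_pca
from orthostage.sim_counts import DEFAULT_STAGES


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--pca", type=Path, default=Path("results/pca"))
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results/staging"))
    ap.add_argument("--pcs", default="2,3")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    merged = pd.read_csv(args.pca / "merged_harmonized.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(args.pca / "pca_scores.tsv", sep="\t", index_col=0)
    pca = run_pca(merged.to_numpy(), k=10)
    pcs = [int(p) for p in args.pcs.split(",")]
    is_query = (meta["dataset"] == "A").to_numpy()
    assignments = assign_stage(
        pca, meta["phenotype"].to_numpy(), is_query, pcs=pcs,
        stage_order=list(DEFAULT_STAGES), cell_ids=list(merged.index),
    )

    truth = pd.read_csv(args.sim / "stage_labels.tsv", sep="\t", index_col=0)["stage"]
    rows = []
    for a in assignments:
        original = a.cell_id.split(":", 1)[1]
        rows.append({
            "cell_id": a.cell_id,
            "assigned_stage": a.assigned_stage,
            "true_stage": truth.get(original),
            "tie": a.tie,
        })
    out = pd.DataFrame(rows)
    out.to_csv(args.out / "stage_assignments.tsv", sep="\t", index=False)

    acc = (out.assigned_stage == out.true_stage).mean()
    confusion = pd.crosstab(out.true_stage, out.assigned_stage)
    confusion.to_csv(args.out / "confusion.tsv", sep="\t")
    print(f"{len(out)} query cells staged on PCs {pcs}; accuracy vs truth: {acc:.1%}")
    print(confusion.to_string())


if __name__ == "__main__":
    main()
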