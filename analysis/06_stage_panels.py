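#!/usr/bin/env python
"""Derive stage-specific gene panels from the labeled reference dataset and
summarize per-cell panel scores across the query cell groups — the data
behind a string-section (violin-grid) figure."""

import argparse
from pathlib import Path

import pandas as pd

from orthostage import derive_stage_panels, log2_cpm, panel_distributions
from orthostage.matrix_io import read_matrix
from orthostage.panels import default_stage_sets, write_panels
from orthostage.sim_counts import DEFAULT_STAGES


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--qc", type=Path, default=Path("results/qc"))
    ap.add_argument("--out", type=Path, default=Path("results/panels"))
    ap.add_argument("--min-effect", type=float, default=1.0)
    ap.add_argument("--min-detect-frac", type=float, default=0.5)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    ref = read_matrix(args.qc / "filtered_B", fmt="mtx")      # labeled reference
    query = read_matrix(args.qc / "filtered_A", fmt="mtx")    # cells to profile
    log_ref = log2_cpm(ref)
    labels_ref = ref.cell_meta["phenotype"].to_numpy()

    panels = derive_stage_panels(
        log_ref, ref.feature_ids, labels_ref,
        stage_sets=default_stage_sets(list(DEFAULT_STAGES)),
        min_effect=args.min_effect, min_detect_frac=args.min_detect_frac,
    )
    write_panels(panels, args.out / "panels.tsv")

    shared = [g for g in query.feature_ids if g in set(ref.feature_ids)]
    log_query = log2_cpm(query.subset_features(shared))
    usable = [p for p in panels if set(p.genes) <= set(shared)]
    summary = panel_distributions(
        log_query, shared, usable, query.cell_meta["phenotype"].to_numpy()
    )
    summary.to_csv(args.out / "panel_summaries.tsv", sep="\t", index=False)

    print(f"{len(panels)} panels derived from the reference "
          f"({', '.join(p.panel_id for p in panels)})")
    medians = summary.pivot(index="panel_id", columns="group", values="median")
    print("median panel score per query group:")
    print(medians.round(3).to_string())


if __name__ == "__main__":
    main()
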