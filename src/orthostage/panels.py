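"""Stage-specific gene panels and their per-group expression summaries.

Panels are derived from a labeled reference by a transparent effect-size plus
detection-fraction rule: a gene marks a stage set S when its mean
log-expression in S exceeds the mean in the complement by at least
``min_effect`` log2 units and it is detected (value > 0) in at least
``min_detect_frac`` of S's cells. Panels may also be supplied directly as a
two-column TSV to bypass derivation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GenePanel:
    panel_id: str
    stage_set: list
    genes: list
    derivation_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"panel {self.panel_id} has no genes")


#: Default stage-set structure: single stages plus nested developmental spans,
#: mirroring a string-section figure's row layout.
def default_stage_sets(stage_order):
    sets = [(s, [s]) for s in stage_order]
    if len(stage_order) >= 3:
        sets.append(("+".join(stage_order[:2]), list(stage_order[:2])))
        sets.append(("+".join(stage_order[-2:]), list(stage_order[-2:])))
    return sets


def derive_stage_panels(
    log_expr: np.ndarray,
    gene_ids,
    stage_labels,
    stage_sets=None,
    min_effect: float = 1.0,
    min_detect_frac: float = 0.5,
):
    """Derive one panel per configured stage set from labeled reference cells.

    Stage sets with fewer than 2 member cells are excluded with a warning;
    stage sets yielding no genes are omitted.
    """
    log_expr = np.asarray(log_expr, dtype=float)
    labels = np.asarray(stage_labels, dtype=object)
    if len(labels) != log_expr.shape[0]:
        raise ValueError("one stage label required per cell")
    stages = list(pd.unique(labels))
    if len(stages) < 2:
        raise ValueError("panel derivation requires at least 2 stages")
    if stage_sets is None:
        stage_sets = default_stage_sets(stages)

    gene_ids = list(gene_ids)
    panels = []
    for panel_id, members in stage_sets:
        in_mask = np.isin(labels, list(members))
        n_in = int(in_mask.sum())
        if n_in < 2:
            warnings.warn(f"stage set {panel_id} has {n_in} cell(s); skipped", stacklevel=2)
            continue
        out_mask = ~in_mask
        if not out_mask.any():
            warnings.warn(f"stage set {panel_id} covers every cell; skipped", stacklevel=2)
            continue
        effect = log_expr[in_mask].mean(axis=0) - log_expr[out_mask].mean(axis=0)
        detect = (log_expr[in_mask] > 0).sum(axis=0) / n_in
        chosen = [
            g for g, e, d in zip(gene_ids, effect, detect)
            if e >= min_effect and d >= min_detect_frac
        ]
        if chosen:
            panels.append(
                GenePanel(
                    panel_id=panel_id,
                    stage_set=list(members),
                    genes=chosen,
                    derivation_params={
                        "min_effect": min_effect, "min_detect_frac": min_detect_frac
                    },
                )
            )
    return panels


def panel_scores(log_expr: np.ndarray, gene_ids, panel: GenePanel) -> np.ndarray:
    """Per-cell mean expression over the panel's genes."""
    pos = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in panel.genes if g not in pos]
    if missing:
        raise KeyError(f"panel {panel.panel_id}: genes absent from matrix: {missing[:5]}")
    idx = [pos[g] for g in panel.genes]
    return np.asarray(log_expr, dtype=float)[:, idx].mean(axis=1)


def panel_distributions(
    log_expr: np.ndarray, gene_ids, panels, group_labels
) -> pd.DataFrame:
    """Distribution summaries of per-cell panel scores per cell group.

    Returns a tidy DataFrame (one row per panel x group) with median,
    quartiles, extremes, group size and the underlying values (for violins).
    Empty groups are skipped with a warning.
    """
    labels = np.asarray(group_labels, dtype=object)
    rows = []
    for panel in panels:
        scores = panel_scores(log_expr, gene_ids, panel)
        for group in pd.unique(labels):
            mask = labels == group
            if not mask.any():
                warnings.warn(f"group {group} is empty; skipped", stacklevel=2)
                continue
            v = np.sort(scores[mask])
            rows.append(
                {
                    "panel_id": panel.panel_id,
                    "group": group,
                    "n": len(v),
                    "median": float(np.median(v)),
                    "q1": float(np.percentile(v, 25)),
                    "q3": float(np.percentile(v, 75)),
                    "min": float(v[0]),
                    "max": float(v[-1]),
                    "values": ",".join(f"{x:.6g}" for x in v),
                }
            )
    return pd.DataFrame(rows)


def write_panels(panels, path) -> None:
    """Two-column TSV: panel_id, gene_id."""
    with open(path, "w") as fh:
        fh.write("panel_id\tgene_id\n")
        for p in panels:
            for g in p.genes:
                fh.write(f"{p.panel_id}\t{g}\n")


def read_panels(path):
    frame = pd.read_csv(path, sep="\t")
    panels = []
    for pid, sub in frame.groupby("panel_id", sort=False):
        panels.append(GenePanel(panel_id=pid, stage_set=[], genes=sub["gene_id"].tolist()))
    return panels
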