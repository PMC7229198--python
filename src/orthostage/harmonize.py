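"""Cross-species harmonization: per-cell min-tie ranking and z-scoring.

Within each cell, genes are ranked by abundance (lowest value -> rank 1; ties
share the minimum rank of their tie group), then ranks are z-scored per cell.
Because ranks depend only on the ordering of values within a cell, the result
is bit-identical under any strictly increasing per-cell transform of the
input — this is what removes a species- or platform-specific monotone
distortion before the joint PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class HarmonizedMatrix:
    """Cells x common-genes matrix of z-scored ranks with carried metadata."""

    values: np.ndarray
    cell_ids: list
    gene_ids: list
    cell_meta: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    degenerate_cells: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("values shape does not match ids")


def rank_cells(log_matrix: np.ndarray) -> np.ndarray:
    """Per-cell ascending ranks with minimum-value tie handling.

    Lowest abundance -> rank 1; tied values all receive the smallest rank of
    their tie group (e.g. [0, 3, 3, 7] -> [1, 2, 2, 4]).
    """
    log_matrix = np.asarray(log_matrix)
    return rankdata(log_matrix, method="min", axis=1).astype(float)


def zscore_cells(
    rank_matrix: np.ndarray,
    cell_ids,
    gene_ids,
    cell_meta: pd.DataFrame | None = None,
    provenance: dict | None = None,
) -> HarmonizedMatrix:
    """Z-score each cell's rank vector (sample sd, n-1 denominator).

    Cells with zero rank variance (constant expression) are flagged and
    emitted as all-zero rows with a warning.
    """
    rank_matrix = np.asarray(rank_matrix, dtype=float)
    if rank_matrix.shape[1] < 2:
        raise ValueError("z-scoring requires at least 2 genes")
    means = rank_matrix.mean(axis=1, keepdims=True)
    sds = rank_matrix.std(axis=1, ddof=1, keepdims=True)
    degenerate = np.flatnonzero(sds[:, 0] == 0)
    safe_sds = np.where(sds == 0, 1.0, sds)
    values = (rank_matrix - means) / safe_sds
    if degenerate.size:
        values[degenerate] = 0.0
        warnings.warn(
            f"{degenerate.size} constant cell(s) emitted as zero rows", stacklevel=2
        )
    if cell_meta is None:
        cell_meta = pd.DataFrame(index=list(cell_ids))
    return HarmonizedMatrix(
        values=values,
        cell_ids=list(cell_ids),
        gene_ids=list(gene_ids),
        cell_meta=cell_meta.loc[list(cell_ids)],
        provenance=dict(provenance or {}),
        degenerate_cells=[cell_ids[i] for i in degenerate],
    )


def harmonize(
    log_matrix: np.ndarray,
    cell_ids,
    gene_ids,
    cell_meta: pd.DataFrame | None = None,
    provenance: dict | None = None,
) -> HarmonizedMatrix:
    """rank_cells followed by zscore_cells (the full per-dataset transform)."""
    return zscore_cells(
        rank_cells(log_matrix), cell_ids, gene_ids, cell_meta, provenance
    )


def merge_species(
    harmonized_a: HarmonizedMatrix,
    harmonized_b: HarmonizedMatrix,
    common_gene_list=None,
) -> HarmonizedMatrix:
    """Row-concatenate two harmonized datasets over an identical gene list.

    Cell order is deterministic: dataset A rows first, then B, each in their
    original order; a ``dataset`` column records provenance.
    """
    if list(harmonized_a.gene_ids) != list(harmonized_b.gene_ids):
        raise ValueError("gene lists differ between datasets; harmonize on the same list")
    if common_gene_list is not None and list(common_gene_list) != list(harmonized_a.gene_ids):
        raise ValueError("datasets are not on the requested common gene list")

    values = np.vstack([harmonized_a.values, harmonized_b.values])
    label_a = harmonized_a.provenance.get("dataset", "A")
    label_b = harmonized_b.provenance.get("dataset", "B")
    cell_ids = [f"{label_a}:{c}" for c in harmonized_a.cell_ids] + [
        f"{label_b}:{c}" for c in harmonized_b.cell_ids
    ]
    meta_a = harmonized_a.cell_meta.copy()
    meta_a["dataset"] = label_a
    meta_b = harmonized_b.cell_meta.copy()
    meta_b["dataset"] = label_b
    meta = pd.concat([meta_a, meta_b], axis=0)
    meta.index = cell_ids
    return HarmonizedMatrix(
        values=values,
        cell_ids=cell_ids,
        gene_ids=list(harmonized_a.gene_ids),
        cell_meta=meta,
        provenance={"merged": [label_a, label_b]},
        degenerate_cells=harmonized_a.degenerate_cells + harmonized_b.degenerate_cells,
    )
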