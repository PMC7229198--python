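"""Read-to-feature assignment and the CountMatrix container.

A read is counted once for the unique feature it overlaps by at least
``min_overlap`` bp (1 by default, the featureCounts convention); reads
overlapping features of two or more genes are discarded as ambiguous; reads on
chromosomes absent from the feature set are logged as unassigned. Strand is
ignored by default (the two platforms differ in strandedness), with a
``stranded`` switch.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


@dataclass
class CountMatrix:
    """Cells x features integer counts with per-cell metadata."""

    counts: np.ndarray
    cell_ids: list
    feature_ids: list
    cell_meta: pd.DataFrame = field(default=None)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells x features)")
        if self.counts.shape != (len(self.cell_ids), len(self.feature_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.feature_ids)} features"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=list(self.cell_ids))
        else:
            self.cell_meta = self.cell_meta.loc[list(self.cell_ids)]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask) -> "CountMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return CountMatrix(
            self.counts[idx],
            [self.cell_ids[i] for i in idx],
            list(self.feature_ids),
            self.cell_meta.iloc[idx],
        )

    def subset_features(self, feature_ids) -> "CountMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in feature_ids]
        return CountMatrix(
            self.counts[:, idx], list(self.cell_ids), list(feature_ids), self.cell_meta
        )

    def to_anndata(self):
        import anndata as ad

        return ad.AnnData(
            X=self.counts.copy(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=list(self.feature_ids)),
        )


@dataclass
class AssignmentLog:
    n_assigned: int = 0
    n_ambiguous: int = 0
    n_unassigned: int = 0

    @property
    def total(self) -> int:
        return self.n_assigned + self.n_ambiguous + self.n_unassigned


def assign_reads(
    reads: pd.DataFrame,
    features,
    level: str = "metaexon",
    min_overlap: int = 1,
    stranded: bool = False,
):
    """Count read intervals over metaexon (or gene) features.

    Parameters
    ----------
    reads
        DataFrame with columns chrom, start, end, strand, cell_id.
    features
        List of (feature_id, gene_id, GenomicInterval). Within one gene,
        intervals must be non-overlapping (the post-collapse guarantee).
    level
        "metaexon" counts per feature; "gene" sums each gene's features.

    Returns (CountMatrix, AssignmentLog). A read overlapping two features of
    the same gene is assigned to the larger overlap (ties: leftmost feature).
    """
    if level not in ("metaexon", "gene"):
        raise ValueError(f"bad level {level!r}")

    trees: dict = defaultdict(IntervalTree)
    feat_info = {}
    for fid, gene_id, iv in features:
        trees[iv.chrom].addi(iv.start, iv.end, (fid, gene_id, iv))
        feat_info[fid] = gene_id

    log = AssignmentLog()
    tallies: dict = defaultdict(int)
    cells_seen = list(dict.fromkeys(reads["cell_id"]))
    for row in reads.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            log.n_unassigned += 1
            continue
        overlaps = []
        for node in tree.overlap(row.start, row.end):
            fid, gene_id, iv = node.data
            if stranded and row.strand in ("+", "-") and iv.strand != row.strand:
                continue
            ov = min(row.end, iv.end) - max(row.start, iv.start)
            if ov >= min_overlap:
                overlaps.append((fid, gene_id, ov, iv.start))
        if not overlaps:
            log.n_unassigned += 1
            continue
        genes = {g for _, g, _, _ in overlaps}
        if len(genes) >= 2:
            log.n_ambiguous += 1
            continue
        fid = min(overlaps, key=lambda t: (-t[2], t[3]))[0]
        tallies[(row.cell_id, fid)] += 1
        log.n_assigned += 1

    feature_ids = [fid for fid, _, _ in features]
    counts = np.zeros((len(cells_seen), len(feature_ids)), dtype=np.int64)
    cell_pos = {c: i for i, c in enumerate(cells_seen)}
    feat_pos = {f: i for i, f in enumerate(feature_ids)}
    for (cell, fid), n in tallies.items():
        counts[cell_pos[cell], feat_pos[fid]] = n

    matrix = CountMatrix(counts, cells_seen, feature_ids)
    if level == "gene":
        matrix = sum_to_genes(matrix, feat_info)
    return matrix, log


def sum_to_genes(matrix: CountMatrix, feature_gene: dict) -> CountMatrix:
    """Sum metaexon-level counts to gene level (column aggregation)."""
    genes = sorted({feature_gene[f] for f in matrix.feature_ids})
    gene_pos = {g: i for i, g in enumerate(genes)}
    counts = np.zeros((matrix.n_cells, len(genes)), dtype=matrix.counts.dtype)
    for j, fid in enumerate(matrix.feature_ids):
        counts[:, gene_pos[feature_gene[fid]]] += matrix.counts[:, j]
    return CountMatrix(counts, list(matrix.cell_ids), genes, matrix.cell_meta)


def sum_within_individuals(matrix: CountMatrix, group_key: str) -> CountMatrix:
    """Sum cells' counts within individuals (or any cell_meta grouping).

    Total counts are conserved. Metadata columns constant within a group are
    carried through; varying ones are dropped.
    """
    if group_key not in matrix.cell_meta.columns:
        raise KeyError(f"cell_meta has no column {group_key!r}")
    if matrix.cell_meta[group_key].isna().any():
        raise ValueError(f"missing values in grouping column {group_key!r}")

    groups = list(dict.fromkeys(matrix.cell_meta[group_key]))
    counts = np.zeros((len(groups), matrix.n_features), dtype=matrix.counts.dtype)
    meta_rows = []
    for i, g in enumerate(groups):
        mask = (matrix.cell_meta[group_key] == g).to_numpy()
        counts[i] = matrix.counts[mask].sum(axis=0)
        sub = matrix.cell_meta.loc[mask]
        row = {
            col: sub[col].iloc[0]
            for col in sub.columns
            if sub[col].nunique(dropna=False) == 1
        }
        row[group_key] = g
        meta_rows.append(row)
    meta = pd.DataFrame(meta_rows, index=[str(g) for g in groups])
    return CountMatrix(counts, [str(g) for g in groups], list(matrix.feature_ids), meta)
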