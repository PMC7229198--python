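"""Joint PCA and quantitative developmental-stage assignment.

PCA is a deterministic full SVD of the (column-centered) harmonized matrix;
no per-gene variance scaling is applied since rows are already rank-z-scored.
Component signs are fixed so the gene with the largest absolute loading on
each component loads positively.

Stage assignment quantifies what is otherwise read off a score plot: each
unlabeled query cell is placed at the reference stage minimizing Euclidean
distance in a selected principal-component subspace (components 2 and 3 by
default — the pre/post-implantation axis and the post-implantation stage
axis), either to stage centroids or by k-nearest-neighbor majority vote.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PCAResult:
    scores: np.ndarray        # cells x k
    loadings: np.ndarray      # genes x k
    variance_fraction: np.ndarray
    k: int
    mean_: np.ndarray = None  # per-gene centering vector

    def __post_init__(self):
        vf = np.asarray(self.variance_fraction)
        if np.any(np.diff(vf) > 1e-12) or vf.min() < -1e-12 or vf.sum() > 1 + 1e-9:
            raise ValueError("variance fractions must be nonincreasing, in [0,1], sum <= 1")


@dataclass
class StageAssignment:
    cell_id: str
    assigned_stage: str
    distances: dict
    pcs_used: list
    tie: bool = False


def run_pca(values: np.ndarray, k: int, center: bool = True) -> PCAResult:
    """Deterministic PCA via full SVD with a fixed sign convention."""
    if k <= 0:
        raise ValueError("k must be positive")
    X = np.asarray(values, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in input")
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min(cells, genes)={min(X.shape)}")
    mean = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # Sign convention: the largest-|loading| gene of each component is positive.
    for j in range(len(s)):
        g = np.argmax(np.abs(Vt[j]))
        if Vt[j, g] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    total = (s ** 2).sum()
    var_frac = (s ** 2 / total) if total > 0 else np.zeros_like(s)
    return PCAResult(
        scores=(U * s)[:, :k],
        loadings=Vt[:k].T,
        variance_fraction=var_frac[:k],
        k=k,
        mean_=mean,
    )


def pca_single_dataset(log_matrix: np.ndarray, k: int, center: bool = True) -> PCAResult:
    """PCA of one species' normalized log2(CPM+1) matrix (no ranking) —
    the within-species cell-state continuum view."""
    return run_pca(log_matrix, k=k, center=center)


def _stage_order_index(stage_order):
    return {s: i for i, s in enumerate(stage_order)}


def assign_stage(
    pca: PCAResult,
    reference_labels,
    query_mask,
    pcs=(2, 3),
    method: str = "centroid",
    knn_k: int = 15,
    stage_order=None,
    cell_ids=None,
):
    """Assign each query cell to a reference stage in a PC subspace.

    Parameters
    ----------
    pca
        Joint PCA of reference and query cells together.
    reference_labels
        Per-cell stage label (array-like, aligned with pca.scores rows); the
        entries for query cells are ignored.
    query_mask
        Boolean per-cell mask; True = query, False = reference.
    pcs
        1-based component indices spanning the assignment subspace.
    method
        "centroid": nearest stage centroid. "knn": majority stage among the
        ``knn_k`` nearest reference cells.
    stage_order
        Developmental ordering of stage labels, used to break exact ties in
        favor of the earliest stage (defaults to sorted label order).

    Returns a list of :class:`StageAssignment`, one per query cell, in input
    order. Stages with zero reference cells are excluded with a warning.
    """
    if method not in ("centroid", "knn"):
        raise ValueError(f"bad method {method!r}")
    pcs = list(pcs)
    if max(pcs) > pca.k or min(pcs) < 1:
        raise ValueError(f"requested components {pcs} not in PCA (k={pca.k})")
    labels = np.asarray(reference_labels, dtype=object)
    query_mask = np.asarray(query_mask, dtype=bool)
    sub = pca.scores[:, [p - 1 for p in pcs]]
    ref_idx = np.flatnonzero(~query_mask)
    ref_labels = labels[ref_idx]
    stages = [s for s in pd.unique(ref_labels) if s is not None]
    if stage_order is None:
        stage_order = sorted(stages)
    order = _stage_order_index(stage_order)
    usable = [s for s in stages if (ref_labels == s).sum() > 0]
    dropped = set(stage_order) - set(usable)
    if dropped:
        warnings.warn(f"stage(s) with no reference cells excluded: {sorted(dropped)}", stacklevel=2)
    usable = sorted(usable, key=lambda s: order.get(s, len(order)))

    out = []
    query_idx = np.flatnonzero(query_mask)
    if cell_ids is None:
        cell_ids = [str(i) for i in range(len(query_mask))]
    if method == "centroid":
        centroids = {s: sub[ref_idx[ref_labels == s]].mean(axis=0) for s in usable}
        for qi in query_idx:
            dists = {s: float(np.linalg.norm(sub[qi] - c)) for s, c in centroids.items()}
            dmin = min(dists.values())
            best = [s for s in usable if np.isclose(dists[s], dmin, rtol=0, atol=1e-12)]
            out.append(
                StageAssignment(
                    cell_id=str(cell_ids[qi]), assigned_stage=best[0], distances=dists,
                    pcs_used=pcs, tie=len(best) > 1,
                )
            )
    else:
        ref_points = sub[ref_idx]
        for qi in query_idx:
            d = np.linalg.norm(ref_points - sub[qi], axis=1)
            nn = np.argsort(d, kind="stable")[: min(knn_k, len(d))]
            votes: dict = {}
            for i in nn:
                votes.setdefault(ref_labels[i], []).append(d[i])
            max_votes = max(len(v) for v in votes.values())
            winners = [s for s, v in votes.items() if len(v) == max_votes]
            if len(winners) > 1:
                winners.sort(key=lambda s: (float(np.mean(votes[s])), order.get(s, len(order))))
            mean_d = {s: float(np.mean(v)) for s, v in votes.items()}
            out.append(
                StageAssignment(
                    cell_id=str(cell_ids[qi]), assigned_stage=winners[0], distances=mean_d,
                    pcs_used=pcs, tie=len(winners) > 1,
                )
            )
    return out


def screeplot_table(pca: PCAResult) -> pd.DataFrame:
    """Variance-accounted-for per component, as a tidy table."""
    return pd.DataFrame(
        {
            "component": np.arange(1, pca.k + 1),
            "variance_fraction": pca.variance_fraction,
        }
    )
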