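"""Lossless CountMatrix IO: MTX (with companion id/metadata files) and TSV."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .quantify import CountMatrix


def write_matrix(matrix: CountMatrix, path, fmt: str = "mtx") -> None:
    """Write a CountMatrix.

    ``mtx``: ``path`` is a directory receiving matrix.mtx (cells x features),
    cells.tsv, features.tsv and cell_meta.tsv. ``tsv``: ``path`` is a file;
    cells are rows, features are columns; metadata lands next to it as
    ``<stem>.cell_meta.tsv``.
    """
    path = Path(path)
    if fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(
            str(path / "matrix.mtx"), scipy.sparse.csr_matrix(matrix.counts), field="integer"
        )
        pd.Series(matrix.cell_ids).to_csv(path / "cells.tsv", index=False, header=False)
        pd.Series(matrix.feature_ids).to_csv(path / "features.tsv", index=False, header=False)
        matrix.cell_meta.to_csv(path / "cell_meta.tsv", sep="\t")
    elif fmt == "tsv":
        frame = pd.DataFrame(matrix.counts, index=matrix.cell_ids, columns=matrix.feature_ids)
        frame.to_csv(path, sep="\t")
        matrix.cell_meta.to_csv(path.with_suffix("").parent / (path.stem + ".cell_meta.tsv"), sep="\t")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_matrix(path, fmt: str = "mtx") -> CountMatrix:
    path = Path(path)
    if fmt == "mtx":
        counts = scipy.io.mmread(str(path / "matrix.mtx"))
        counts = np.asarray(counts.todense()).astype(np.int64)
        cells = pd.read_csv(path / "cells.tsv", header=None)[0].astype(str).tolist() if counts.shape[0] else []
        features = pd.read_csv(path / "features.tsv", header=None)[0].astype(str).tolist() if counts.shape[1] else []
        if counts.shape != (len(cells), len(features)):
            raise ValueError(
                f"MTX dimensions {counts.shape} do not match id files "
                f"({len(cells)} cells, {len(features)} features)"
            )
        meta_path = path / "cell_meta.tsv"
        meta = (
            pd.read_csv(meta_path, sep="\t", index_col=0)
            if meta_path.exists()
            else None
        )
        if meta is not None:
            meta.index = meta.index.astype(str)
        return CountMatrix(counts, cells, features, meta)
    if fmt == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        meta_path = path.with_suffix("").parent / (path.stem + ".cell_meta.tsv")
        meta = pd.read_csv(meta_path, sep="\t", index_col=0) if meta_path.exists() else None
        cells = [str(c) for c in frame.index]
        if meta is not None:
            meta.index = meta.index.astype(str)
        return CountMatrix(
            frame.to_numpy().astype(np.int64), cells, [str(c) for c in frame.columns], meta
        )
    raise ValueError(f"unknown format {fmt!r}")
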