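"""Plain-text readers and writers for matrices, QC tables and point patterns.

Count matrices round-trip either as MatrixMarket (``matrix.mtx`` in
genes x cells orientation with ``genes.tsv``/``cells.tsv`` sidecars, the
common exchange layout for scRNA-seq counts) or as a dense CSV pair. All
formats are versioned plain text so outputs diff cleanly.
"""
from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


def write_counts(adata: ad.AnnData, path: str | Path, fmt: str = "mtx") -> None:
    """Write a count matrix with cell metadata to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if sp.issparse(X):
        X = X.toarray()
    X = np.asarray(X)
    if fmt == "mtx":
        scipy.io.mmwrite(path / "matrix.mtx", sp.csr_matrix(X.T.astype(np.int64)), field="integer")
        pd.DataFrame({"gene": adata.var_names}).to_csv(
            path / "genes.tsv", sep="\t", index=False
        )
        cells = adata.obs.reset_index().rename(columns={"index": "cell_id"})
        if "cell_id" not in cells.columns:
            cells.insert(0, "cell_id", adata.obs_names)
        cells.to_csv(path / "cells.tsv", sep="\t", index=False)
    elif fmt == "csv":
        pd.DataFrame(
            X.T.astype(np.int64), index=adata.var_names, columns=adata.obs_names
        ).rename_axis("gene").to_csv(path / "counts.csv")
        adata.obs.rename_axis("cell_id").to_csv(path / "cells.csv")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_counts(path: str | Path, fmt: str = "mtx") -> ad.AnnData:
    """Read a count matrix written by :func:`write_counts`."""
    path = Path(path)
    if fmt == "mtx":
        X = scipy.io.mmread(path / "matrix.mtx")
        X = np.asarray(sp.coo_matrix(X).todense()).T
        genes = pd.read_csv(path / "genes.tsv", sep="\t")["gene"].astype(str)
        cells = pd.read_csv(path / "cells.tsv", sep="\t")
        if "cell_id" not in cells.columns:
            raise ValueError("cells.tsv must have a cell_id column")
        cells = cells.set_index("cell_id")
        cells.index = cells.index.astype(str)
        if X.shape != (len(cells), len(genes)):
            raise ValueError(
                f"matrix shape {X.shape} does not match sidecars "
                f"({len(cells)} cells, {len(genes)} genes)"
            )
    elif fmt == "csv":
        counts = pd.read_csv(path / "counts.csv", index_col=0)
        cells = pd.read_csv(path / "cells.csv", index_col=0)
        cells.index = cells.index.astype(str)
        X = counts.to_numpy().T
        genes = counts.index.astype(str)
        if X.shape[0] != len(cells):
            raise ValueError("cell metadata rows do not match matrix columns")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return ad.AnnData(
        X=np.asarray(X, dtype=np.int64),
        obs=cells,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )


def write_qc_table(table: pd.DataFrame, path: str | Path) -> None:
    table.rename_axis("cell_id").to_csv(path)


def read_qc_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="cell_id")


_PATTERN_COLUMNS = ["cell_id", "x", "y", "category", "dapi", "section_id", "mouse_id"]


def write_point_patterns(patterns: list, path: str | Path) -> None:
    """Write sections as one cells CSV plus a JSON sidecar with windows."""
    from .proximity import PointPattern  # local import avoids cycle

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frames = []
    windows = {}
    for pat in patterns:
        if not isinstance(pat, PointPattern):
            raise TypeError("expected PointPattern instances")
        frames.append(pat.cells)
        windows[pat.section_id] = list(pat.window)
    cols = _PATTERN_COLUMNS + (
        ["region"] if any("region" in f.columns for f in frames) else []
    )
    pd.concat(frames, ignore_index=True)[cols].to_csv(path / "cells.csv", index=False)
    with open(path / "windows.json", "w") as fh:
        json.dump(windows, fh, indent=2, sort_keys=True)


def read_point_patterns(path: str | Path) -> list:
    from .proximity import PointPattern

    path = Path(path)
    cells = pd.read_csv(path / "cells.csv")
    with open(path / "windows.json") as fh:
        windows = json.load(fh)
    patterns = []
    for section_id, sub in cells.groupby("section_id", sort=True):
        if str(section_id) not in windows:
            raise ValueError(f"no window recorded for section {section_id}")
        w, h = windows[str(section_id)]
        patterns.append(PointPattern(cells=sub.reset_index(drop=True), window=(w, h)))
    return patterns
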