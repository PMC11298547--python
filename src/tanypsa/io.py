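"""Reading and writing 10x-style MatrixMarket count directories.

A dataset directory holds ``matrix.mtx`` (genes as rows, cells as columns,
1-based coordinate integer format — CellRanger orientation), single-column
``barcodes.tsv`` and ``features.tsv``, and a tab-separated ``cells.tsv``
metadata table with a header (cell_id, condition, population, ...).
"""

from __future__ import annotations

import os

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._errors import FormatError

MATRIX = "matrix.mtx"
BARCODES = "barcodes.tsv"
FEATURES = "features.tsv"
METADATA = "cells.tsv"


def write_dataset(adata: ad.AnnData, outdir: str | os.PathLike) -> str:
    """Write counts plus cell metadata; round-trips exactly through read_dataset."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    X = sp.coo_matrix(adata.X).T  # genes x cells on disk
    scipy.io.mmwrite(os.path.join(outdir, MATRIX), X, field="integer")
    with open(os.path.join(outdir, BARCODES), "w") as fh:
        fh.write("\n".join(adata.obs_names) + "\n")
    with open(os.path.join(outdir, FEATURES), "w") as fh:
        fh.write("\n".join(adata.var_names) + "\n")
    meta = adata.obs.reset_index(names="cell_id")
    meta.to_csv(os.path.join(outdir, METADATA), sep="\t", index=False)
    return outdir


def read_dataset(indir: str | os.PathLike) -> ad.AnnData:
    """Read a dataset directory back into cells x genes AnnData (CSR counts)."""
    indir = os.fspath(indir)
    path = os.path.join(indir, MATRIX)
    if not os.path.exists(path):
        raise FormatError(f"missing {MATRIX} in {indir}")
    M = scipy.io.mmread(path)  # genes x cells
    barcodes = _read_column(os.path.join(indir, BARCODES))
    features = _read_column(os.path.join(indir, FEATURES))
    if M.shape[0] != len(features):
        raise FormatError(
            f"{MATRIX} declares {M.shape[0]} genes but {FEATURES} has {len(features)} lines")
    if M.shape[1] != len(barcodes):
        raise FormatError(
            f"{MATRIX} declares {M.shape[1]} cells but {BARCODES} has {len(barcodes)} lines")
    obs = pd.DataFrame(index=pd.Index(barcodes, name=None))
    meta_path = os.path.join(indir, METADATA)
    if os.path.exists(meta_path):
        meta = pd.read_csv(meta_path, sep="\t", dtype={"cell_id": str})
        if "cell_id" not in meta.columns:
            raise FormatError(f"{METADATA} lacks a cell_id column")
        meta = meta.set_index("cell_id")
        if not meta.index.equals(obs.index):
            raise FormatError(f"{METADATA} cell_id column does not match {BARCODES}")
        obs = meta
        for col in ("condition", "population"):
            if col in obs.columns:
                obs[col] = obs[col].astype("category")
    X = sp.csr_matrix(M.T.astype(np.int64))
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=features))
    adata.obs_names = [str(b) for b in barcodes]
    return adata


def _read_column(path: str) -> list[str]:
    if not os.path.exists(path):
        raise FormatError(f"missing {os.path.basename(path)}")
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip() != ""]
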