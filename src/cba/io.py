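"""Readers and writers for the standard single-cell exchange formats.

Supported batch inputs: MatrixMarket sparse counts with gene/barcode TSV
sidecars (10x-style triplet), dense CSV (cells x genes with a header row of
gene identifiers), and the HDF5 single-cell container (``.h5ad``).
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .data import ExpressionBatch, FeatureMatrix


def read_batch(path: str, batch_tag: Optional[str] = None) -> ExpressionBatch:
    """Load a batch, dispatching on the file extension.

    ``.mtx`` expects ``genes.tsv`` and ``barcodes.tsv`` sidecars next to the
    matrix (matrix stored genes x cells, as 10x writes it). ``.csv`` expects
    cells x genes with gene ids in the header and cell ids in the first
    column. ``.h5ad`` is read through anndata.
    """
    ext = os.path.splitext(path)[1].lower()
    if ext == ".mtx":
        return _read_mtx(path, batch_tag)
    if ext == ".csv":
        return _read_csv(path, batch_tag)
    if ext == ".h5ad":
        import anndata as ad

        return ExpressionBatch.from_anndata(ad.read_h5ad(path), batch_tag)
    raise ValueError(f"unrecognized batch format: {path!r}")


def _read_mtx(path: str, batch_tag: Optional[str]) -> ExpressionBatch:
    mat = scipy.io.mmread(path)
    base = os.path.dirname(path)
    genes = pd.read_csv(os.path.join(base, "genes.tsv"), sep="\t", header=None)
    barcodes = pd.read_csv(os.path.join(base, "barcodes.tsv"), sep="\t", header=None)
    counts = sp.csr_matrix(mat).T  # genes x cells on disk -> cells x genes
    return ExpressionBatch(
        counts=counts,
        gene_ids=genes.iloc[:, 0].astype(str).tolist(),
        cell_ids=barcodes.iloc[:, 0].astype(str).tolist(),
        batch_tag=batch_tag or os.path.basename(base) or "batch",
    )


def _read_csv(path: str, batch_tag: Optional[str]) -> ExpressionBatch:
    df = pd.read_csv(path, index_col=0)
    return ExpressionBatch(
        counts=df.to_numpy(dtype=float),
        gene_ids=[str(g) for g in df.columns],
        cell_ids=[str(c) for c in df.index],
        batch_tag=batch_tag or os.path.splitext(os.path.basename(path))[0],
    )


def write_batch_mtx(batch: ExpressionBatch, out_dir: str) -> None:
    """Write a batch as matrix.mtx (genes x cells) + genes/barcodes TSVs."""
    os.makedirs(out_dir, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(out_dir, "matrix.mtx"), sp.csr_matrix(batch.counts.T)
    )
    pd.Series(batch.gene_ids).to_csv(
        os.path.join(out_dir, "genes.tsv"), sep="\t", header=False, index=False
    )
    pd.Series(batch.cell_ids).to_csv(
        os.path.join(out_dir, "barcodes.tsv"), sep="\t", header=False, index=False
    )


def write_features_csv(fm: FeatureMatrix, path: str) -> None:
    cols = [f"PC{i + 1}" for i in range(fm.k)]
    idx = fm.cell_ids if fm.cell_ids else list(range(fm.n_cells))
    pd.DataFrame(fm.values, index=idx, columns=cols).to_csv(path)


def write_features_h5ad(
    batch: ExpressionBatch, fm: FeatureMatrix, path: str, key: str = "X_pca"
) -> None:
    """Write the batch with the reduced-dimension slot filled."""
    adata = batch.to_anndata()
    adata.obsm[key] = fm.values
    adata.write_h5ad(path)


def write_labels_csv(cell_ids: list[str], labels: np.ndarray, path: str) -> None:
    pd.DataFrame({"cell_id": cell_ids, "cluster": np.asarray(labels)}).to_csv(
        path, index=False
    )


def read_labels_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path)
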