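"""Preprocessing chain shared by both batches.

The chain is: drop cells from tiny annotated clusters, intersect gene sets
and drop genes expressed in too few cells, total-count normalize and log
transform, select highly variable genes jointly, and embed both batches in
one PCA space fit on their stacked cells.  The number of retained components
is picked at the bending point of the scree curve.
"""

from __future__ import annotations

import warnings
from collections import Counter
from typing import Sequence

import numpy as np

from .data import ExpressionBatch, FeatureMatrix

DEFAULT_SCALE = 1e4
DEFAULT_K_CANDIDATES = (10, 15, 20, 25, 30)


def filter_small_clusters(
    batch: ExpressionBatch, min_cells: int = 10
) -> ExpressionBatch:
    """Remove cells whose annotated cluster has fewer than ``min_cells`` cells.

    Clusters with too few cells destabilize the cluster matching and the
    gated losses, so they are dropped up front using the annotation provided
    with the dataset.  "Fewer than" is strict: a cluster of exactly
    ``min_cells`` cells is kept.
    """
    if batch.provided_labels is None:
        raise ValueError("annotation required: batch has no provided_labels")
    sizes = Counter(batch.provided_labels)
    keep = [i for i, lab in enumerate(batch.provided_labels) if sizes[lab] >= min_cells]
    return batch.subset_cells(keep)


def filter_genes(
    b1: ExpressionBatch,
    b2: ExpressionBatch,
    min_cells_1: int = 50,
    min_cells_2: int = 50,
) -> tuple[ExpressionBatch, ExpressionBatch]:
    """Intersect gene sets and drop genes expressed in too few cells.

    A gene counts as expressed in a cell when its count is > 0.  A retained
    gene must be expressed in at least ``min_cells_1`` cells of batch 1 AND
    ``min_cells_2`` cells of batch 2; both outputs share an identical ordered
    gene list.
    """
    shared = [g for g in b1.gene_ids if g in set(b2.gene_ids)]
    if not shared:
        raise ValueError("no shared genes between the two batches")
    idx1 = {g: i for i, g in enumerate(b1.gene_ids)}
    idx2 = {g: i for i, g in enumerate(b2.gene_ids)}
    b1 = b1.subset_genes([idx1[g] for g in shared])
    b2 = b2.subset_genes([idx2[g] for g in shared])
    expressed1 = (b1.counts > 0).sum(axis=0)
    expressed2 = (b2.counts > 0).sum(axis=0)
    keep = np.flatnonzero((expressed1 >= min_cells_1) & (expressed2 >= min_cells_2))
    if keep.size == 0:
        raise ValueError("no genes pass the expression filter")
    return b1.subset_genes(keep), b2.subset_genes(keep)


def normalize_log(batch: ExpressionBatch, scale: float = DEFAULT_SCALE) -> ExpressionBatch:
    """Total-count normalize each cell to ``scale`` and log transform.

    Each entry becomes ``ln(count / cell_total * scale + 1)``, with cell
    totals computed on the current (post-filtering) gene set.
    """
    totals = batch.counts.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        bad = np.flatnonzero(totals.ravel() <= 0)
        raise ValueError(
            f"empty cell(s) with zero total count at rows {bad[:5].tolist()}"
        )
    return batch.with_counts(np.log1p(batch.counts / totals * scale))


def select_hvg(b1: ExpressionBatch, b2: ExpressionBatch) -> list[str]:
    """Select highly variable genes jointly on the two normalized batches.

    Both batches must be on the same gene set and already log-normalized.
    Uses the mean-binned normalized-dispersion criterion (scanpy's
    ``highly_variable_genes`` with default parameters) on the vertically
    concatenated cells, returning one shared gene subset in input gene order.
    """
    if b1.gene_ids != b2.gene_ids:
        raise ValueError("batches must share an identical ordered gene list")
    if len(b1.gene_ids) < 2:
        raise ValueError("need at least 2 genes for HVG selection")
    import anndata as ad
    import scanpy as sc

    stacked = ad.AnnData(
        X=np.vstack([b1.counts, b2.counts]).astype(np.float32),
        var={"gene_id": b1.gene_ids},
    )
    stacked.var_names = b1.gene_ids
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(stacked)
    mask = stacked.var["highly_variable"].to_numpy()
    return [g for g, m in zip(b1.gene_ids, mask) if m]


def restrict_to_genes(
    batch: ExpressionBatch, genes: Sequence[str]
) -> ExpressionBatch:
    index = {g: i for i, g in enumerate(batch.gene_ids)}
    return batch.subset_genes([index[g] for g in genes])


def pca_embed(
    b1: ExpressionBatch, b2: ExpressionBatch, k: int
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Embed both batches in one PCA space fit on their stacked cells.

    Genes are centered (not scaled) across the union of cells so both
    batches share principal axes.  Per-component explained-variance ratios
    are attached to both outputs.
    """
    if b1.gene_ids != b2.gene_ids:
        raise ValueError("batches must share an identical ordered gene list")
    stacked = np.vstack([b1.counts, b2.counts])
    max_rank = min(stacked.shape)
    if k > max_rank:
        raise ValueError(f"k={k} exceeds min(cells, genes)={max_rank}")
    from sklearn.decomposition import PCA

    pca = PCA(n_components=k, svd_solver="full" if max_rank <= 500 else "randomized",
              random_state=0)
    scores = pca.fit_transform(stacked)
    ratios = pca.explained_variance_ratio_.copy()
    n1 = b1.n_cells
    f1 = FeatureMatrix(scores[:n1], b1.batch_tag, list(b1.cell_ids), ratios)
    f2 = FeatureMatrix(scores[n1:], b2.batch_tag, list(b2.cell_ids), ratios)
    return f1, f2


def choose_k(
    variance_ratios: Sequence[float],
    candidates: Sequence[int] = DEFAULT_K_CANDIDATES,
) -> int:
    """Pick the candidate dimensionality nearest the scree-curve elbow.

    The elbow is the component index maximizing the discrete second
    difference of the per-component explained-variance ratios (the point of
    maximum curvature of the scree plot).  Flat scree curves and nearest-tie
    cases resolve to the smallest candidate.
    """
    candidates = sorted(candidates)
    if not candidates:
        raise ValueError("candidates must be non-empty")
    r = np.asarray(variance_ratios, dtype=float)
    if len(candidates) == 1 or r.size < 3:
        return candidates[0]
    curvature = r[:-2] - 2 * r[1:-1] + r[2:]  # value at interior index i+1
    elbow = int(np.argmax(curvature)) + 1
    dist = np.abs(np.asarray(candidates) - elbow)
    return int(candidates[int(np.argmin(dist))])
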