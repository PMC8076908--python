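"""Core data containers for two-batch single-cell alignment.

An :class:`ExpressionBatch` holds one batch's cells-by-genes count (or
normalized) matrix together with gene/cell identifiers, an optional
author-provided cell-type annotation and an optional unsupervised cluster
labelling.  A :class:`FeatureMatrix` holds the low-dimensional per-cell
feature vectors (principal components) that the alignment network consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp


def _as_dense(x) -> np.ndarray:
    if sp.issparse(x):
        x = x.toarray()
    return np.asarray(x, dtype=np.float64)


@dataclass
class ExpressionBatch:
    """One batch of single-cell expression: cells x genes."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    batch_tag: str
    provided_labels: Optional[list[str]] = None
    cluster_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = _as_dense(self.counts)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D cells x genes matrix")
        n, g = self.counts.shape
        if n != len(self.cell_ids):
            raise ValueError(
                f"{n} rows but {len(self.cell_ids)} cell_ids in batch "
                f"{self.batch_tag!r}"
            )
        if g != len(self.gene_ids):
            raise ValueError(
                f"{g} columns but {len(self.gene_ids)} gene_ids in batch "
                f"{self.batch_tag!r}"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.provided_labels is not None:
            self.provided_labels = list(self.provided_labels)
            if len(self.provided_labels) != n:
                raise ValueError("provided_labels length mismatch")
        if self.cluster_labels is not None:
            self.cluster_labels = np.asarray(self.cluster_labels, dtype=int)
            if self.cluster_labels.shape != (n,):
                raise ValueError("cluster_labels length mismatch")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, index: Sequence[int] | np.ndarray) -> "ExpressionBatch":
        index = np.asarray(index)
        return ExpressionBatch(
            counts=self.counts[index],
            gene_ids=self.gene_ids,
            cell_ids=[self.cell_ids[i] for i in index],
            batch_tag=self.batch_tag,
            provided_labels=(
                [self.provided_labels[i] for i in index]
                if self.provided_labels is not None
                else None
            ),
            cluster_labels=(
                self.cluster_labels[index] if self.cluster_labels is not None else None
            ),
        )

    def subset_genes(self, index: Sequence[int] | np.ndarray) -> "ExpressionBatch":
        index = np.asarray(index)
        return ExpressionBatch(
            counts=self.counts[:, index],
            gene_ids=[self.gene_ids[i] for i in index],
            cell_ids=self.cell_ids,
            batch_tag=self.batch_tag,
            provided_labels=self.provided_labels,
            cluster_labels=self.cluster_labels,
        )

    def with_counts(self, counts: np.ndarray) -> "ExpressionBatch":
        return replace(self, counts=counts)

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (cells x genes)."""
        import anndata as ad
        import pandas as pd

        obs = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        obs["batch"] = self.batch_tag
        if self.provided_labels is not None:
            obs["provided_label"] = self.provided_labels
        if self.cluster_labels is not None:
            obs["cluster"] = self.cluster_labels
        var = pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id"))
        return ad.AnnData(X=self.counts.copy(), obs=obs, var=var)

    @classmethod
    def from_anndata(cls, adata, batch_tag: Optional[str] = None) -> "ExpressionBatch":
        tag = batch_tag
        if tag is None:
            tag = str(adata.obs["batch"].iloc[0]) if "batch" in adata.obs else "batch"
        provided = None
        for key in ("provided_label", "cell_type", "celltype", "cell_ontology_class"):
            if key in adata.obs:
                provided = adata.obs[key].astype(str).tolist()
                break
        return cls(
            counts=_as_dense(adata.X),
            gene_ids=adata.var_names.tolist(),
            cell_ids=adata.obs_names.tolist(),
            batch_tag=tag,
            provided_labels=provided,
        )


@dataclass
class FeatureMatrix:
    """Per-cell feature vectors (top-k principal components) for one batch.

    Rows align 1:1 with the parent :class:`ExpressionBatch`'s cells.
    ``variance_ratios`` carries the explained-variance ratio of each retained
    component (shared between the two batches of a pair, since the PCA is fit
    on their stacked cells).
    """

    values: np.ndarray
    source_batch: str
    cell_ids: list[str] = field(default_factory=list)
    variance_ratios: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.cell_ids and len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("cell_ids length mismatch")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]
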