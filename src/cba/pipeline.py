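"""End-to-end alignment pipeline: preprocessing -> clustering/matching ->
paired-autoencoder training -> per-cell aligned embedding."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import preprocess as pp
from .clustermatch import ClusterMatch, build_cluster_match
from .data import ExpressionBatch, FeatureMatrix
from .network import NetworkConfig, PairedAutoencoder
from .train import AlignmentResult, FitSettings, embed_cells, fit


@dataclass
class PipelineConfig:
    """All knobs of the alignment chain, with the reference defaults."""

    min_cluster_cells: int = 10
    min_cells_per_gene: tuple[int, int] = (50, 50)
    scale: float = 1e4
    n_pcs: Optional[int] = None  # None: scree-elbow choice among k_candidates
    k_candidates: tuple[int, ...] = pp.DEFAULT_K_CANDIDATES
    hvg: bool = True
    min_hvg: int = 50  # fall back to all genes below this
    louvain_resolution: float = 1.0
    louvain_neighbors: int = 15
    hidden_dims: tuple[int, ...] = (512,)
    embed_dim: Optional[int] = None
    embed_repeats: int = 16
    fit: FitSettings = field(default_factory=FitSettings)
    seed: int = 0
    apply_cell_filter: bool = False  # needs provided_labels


@dataclass
class PipelineOutput:
    f1: FeatureMatrix
    f2: FeatureMatrix
    cluster_match: ClusterMatch
    net: PairedAutoencoder
    result: AlignmentResult
    n_pcs: int
    hvg_genes: list[str]

    @property
    def unaligned_embedding(self) -> np.ndarray:
        """Stacked PCA features before alignment (batch 1 rows first)."""
        return np.vstack([self.f1.values, self.f2.values])

    @property
    def batch_tags(self) -> np.ndarray:
        return np.asarray(self.result.batch_of_cell)


def align(
    b1: ExpressionBatch, b2: ExpressionBatch, config: Optional[PipelineConfig] = None
) -> PipelineOutput:
    """Run the full alignment chain on two raw count batches."""
    cfg = config or PipelineConfig()
    if cfg.apply_cell_filter:
        b1 = pp.filter_small_clusters(b1, cfg.min_cluster_cells)
        b2 = pp.filter_small_clusters(b2, cfg.min_cluster_cells)
    b1, b2 = pp.filter_genes(b1, b2, *cfg.min_cells_per_gene)
    b1 = pp.normalize_log(b1, cfg.scale)
    b2 = pp.normalize_log(b2, cfg.scale)
    hvg_genes = list(b1.gene_ids)
    if cfg.hvg:
        selected = pp.select_hvg(b1, b2)
        if len(selected) >= cfg.min_hvg:
            hvg_genes = selected
            b1 = pp.restrict_to_genes(b1, hvg_genes)
            b2 = pp.restrict_to_genes(b2, hvg_genes)
        else:
            warnings.warn(
                f"only {len(selected)} highly variable genes; keeping all genes"
            )

    k_max = min(max(cfg.k_candidates), b1.n_genes, b1.n_cells + b2.n_cells)
    f1, f2 = pp.pca_embed(b1, b2, k=max(cfg.n_pcs or 0, k_max))
    if cfg.n_pcs is not None:
        k = cfg.n_pcs
    else:
        k = pp.choose_k(f1.variance_ratios, [c for c in cfg.k_candidates
                                             if c <= k_max] or [k_max])
    f1 = FeatureMatrix(f1.values[:, :k], f1.source_batch, f1.cell_ids,
                       f1.variance_ratios[:k])
    f2 = FeatureMatrix(f2.values[:, :k], f2.source_batch, f2.cell_ids,
                       f2.variance_ratios[:k])

    cm = build_cluster_match(
        f1, f2, resolution=cfg.louvain_resolution, seed=cfg.seed,
        n_neighbors=cfg.louvain_neighbors,
    )
    net = PairedAutoencoder(NetworkConfig(
        input_dim=k, n_classes_b1=cm.K1, n_classes_b2=cm.K2,
        hidden_dims=cfg.hidden_dims, embed_dim=cfg.embed_dim, seed=cfg.seed,
    ))
    fit_settings = cfg.fit
    if fit_settings.seed != cfg.seed:
        fit_settings = FitSettings(**{**fit_settings.__dict__, "seed": cfg.seed})
    state = fit(net, f1, f2, cm, fit_settings)
    result = embed_cells(net, f1, f2, cm, R=cfg.embed_repeats,
                         seed=cfg.seed, train_state=state)
    return PipelineOutput(f1=f1, f2=f2, cluster_match=cm, net=net,
                          result=result, n_pcs=k, hvg_genes=hvg_genes)
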