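"""Synthetic two-batch scRNA-seq generator.

Emulates the statistical structure the alignment method assumes: K shared
cell populations drawn as a Gaussian mixture in a low-dimensional latent
expression space, a linear map from latent space to per-gene log-intensity,
an additive per-batch technical shift in gene space, and negative-binomial
count noise with cell-specific library sizes.  Two optional perturbations
probe the method's failure modes: a batch-exclusive subpopulation inside one
shared cluster, and a cluster deleted from one batch (so the other batch
carries a cell type with no counterpart).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .data import ExpressionBatch


@dataclass
class SubclusterSpec:
    """A batch-exclusive subgroup inside one shared cluster."""

    host_cluster: int
    batch: int  # 1 or 2
    offset_magnitude: float
    fraction: float = 0.4


@dataclass
class DroppedClusterSpec:
    """A cluster removed from one batch (the other batch keeps it)."""

    cluster: int
    batch: int  # 1 or 2: the batch the cluster is removed FROM


@dataclass
class SimConfig:
    n_clusters: int = 4
    cells_per_cluster: tuple[int, int] = (75, 75)  # per batch
    n_genes: int = 500
    latent_dim: int = 10
    cluster_separation: float = 6.0
    batch_shift_magnitude: float = 3.0
    subcluster: Optional[SubclusterSpec] = None
    dropped_cluster: Optional[DroppedClusterSpec] = None
    library_size: float = 2000.0
    library_sigma: float = 0.3
    noise_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or min(self.cells_per_cluster) < 1:
            raise ValueError("need at least one cluster and one cell per cluster")
        if self.cluster_separation < 0 or self.batch_shift_magnitude < 0:
            raise ValueError("magnitudes must be non-negative")
        for spec, attr in ((self.subcluster, "host_cluster"),
                           (self.dropped_cluster, "cluster")):
            if spec is not None:
                cid = getattr(spec, attr)
                if not 0 <= cid < self.n_clusters:
                    raise ValueError(f"{attr}={cid} outside [0, {self.n_clusters})")
                if spec.batch not in (1, 2):
                    raise ValueError("batch must be 1 or 2")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cells_per_cluster"] = list(self.cells_per_cluster)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if d.get("subcluster") is not None:
            d["subcluster"] = SubclusterSpec(**d["subcluster"])
        if d.get("dropped_cluster") is not None:
            d["dropped_cluster"] = DroppedClusterSpec(**d["dropped_cluster"])
        d["cells_per_cluster"] = tuple(d["cells_per_cluster"])
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth aligned 1:1 with the generated cells."""

    clusters1: np.ndarray
    clusters2: np.ndarray
    subcluster_flag1: np.ndarray
    subcluster_flag2: np.ndarray
    shift1: np.ndarray
    shift2: np.ndarray


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = mean + dispersion * mean^2."""
    if dispersion <= 0:
        return rng.poisson(mean).astype(np.float64)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(np.float64)


def generate(config: SimConfig) -> tuple[ExpressionBatch, ExpressionBatch, SimTruth]:
    """Generate the two batches and their ground truth.

    Cluster means sit on a sphere of radius ``cluster_separation`` in latent
    space; cells add unit isotropic latent noise.  Gene-space log-intensity
    is ``z @ W + baseline + batch_shift``; per-cell gene proportions are its
    softmax, scaled by a log-normal library size whose expectation equals
    ``library_size``, then observed through negative-binomial noise.
    """
    rng = np.random.default_rng(config.seed)
    K, G, L = config.n_clusters, config.n_genes, config.latent_dim

    means = rng.normal(size=(K, L))
    means *= config.cluster_separation / np.linalg.norm(means, axis=1, keepdims=True)
    loadings = rng.normal(size=(L, G)) / np.sqrt(L)
    baseline = rng.normal(0.0, 0.5, size=G)

    # The shift magnitude is expressed on the latent scale (commensurate with
    # cluster_separation): a latent displacement of norm m maps through the
    # loadings to a gene-space vector of norm ~ m * sqrt(G/L).
    shift_dir = rng.normal(size=G)
    shift_dir /= np.linalg.norm(shift_dir)
    shift_norm = config.batch_shift_magnitude * np.sqrt(G / L)
    shifts = {1: np.zeros(G), 2: shift_norm * shift_dir}

    sub = config.subcluster
    sub_dir = None
    if sub is not None:
        sub_dir = rng.normal(size=L)
        sub_dir *= sub.offset_magnitude / np.linalg.norm(sub_dir)

    batches: dict[int, ExpressionBatch] = {}
    truths: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for b in (1, 2):
        n_per = config.cells_per_cluster[b - 1]
        cluster_ids = []
        z_rows = []
        sub_flags = []
        for k in range(K):
            if (config.dropped_cluster is not None
                    and config.dropped_cluster.cluster == k
                    and config.dropped_cluster.batch == b):
                continue
            z = means[k] + rng.normal(size=(n_per, L))
            flags = np.zeros(n_per, dtype=bool)
            if sub is not None and sub.host_cluster == k and sub.batch == b:
                n_sub = int(round(sub.fraction * n_per))
                flags[:n_sub] = True
                z[:n_sub] += sub_dir
            z_rows.append(z)
            cluster_ids.extend([k] * n_per)
            sub_flags.append(flags)
        if not z_rows:
            raise ValueError(f"batch {b} has zero cells under this config")
        z_all = np.vstack(z_rows)
        n = z_all.shape[0]
        x = z_all @ loadings + baseline + shifts[b]
        x = x - x.max(axis=1, keepdims=True)
        props = np.exp(x)
        props /= props.sum(axis=1, keepdims=True)
        lib = rng.lognormal(
            np.log(config.library_size) - config.library_sigma ** 2 / 2,
            config.library_sigma, size=n,
        )
        counts = _nb_counts(rng, props * lib[:, None], config.noise_dispersion)
        clusters = np.asarray(cluster_ids, dtype=int)
        batches[b] = ExpressionBatch(
            counts=counts,
            gene_ids=[f"gene{g}" for g in range(G)],
            cell_ids=[f"b{b}_cell{i}" for i in range(n)],
            batch_tag=f"batch{b}",
            provided_labels=[f"type{c}" for c in clusters],
        )
        truths[b] = (clusters, np.concatenate(sub_flags))

    truth = SimTruth(
        clusters1=truths[1][0], clusters2=truths[2][0],
        subcluster_flag1=truths[1][1], subcluster_flag2=truths[2][1],
        shift1=shifts[1], shift2=shifts[2],
    )
    return batches[1], batches[2], truth


def scenario_presets() -> dict[str, SimConfig]:
    """Three deterministic study scenarios.

    ``pancreas-like``: four shared populations, moderate technical shift —
    the plain integration setting.  ``subcluster``: one batch carries an
    exclusive subgroup inside a shared cluster, which a good alignment must
    not erase.  ``missing-type``: one cluster is deleted from batch 1, so
    the matching step must leave the orphan batch-2 cluster unmatched.
    """
    return {
        "pancreas-like": SimConfig(),
        "subcluster": SimConfig(
            subcluster=SubclusterSpec(host_cluster=0, batch=1,
                                      offset_magnitude=4.0, fraction=0.4),
        ),
        "missing-type": SimConfig(
            dropped_cluster=DroppedClusterSpec(cluster=0, batch=1),
        ),
    }
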