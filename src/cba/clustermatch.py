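"""Per-batch Louvain clustering and cross-batch cluster matching.

Each batch is clustered independently on its PCA features.  A batch-1
cluster ``i`` is matched to the batch-2 cluster ``j*`` minimizing

    U[i, j] = log10( mean over all cross-pairs (p in i, q in j) of
                     cosine distance d_cos(p, q) )

The log10 emphasizes small distances.  From the matching we build the gate
matrices consumed by the losses: within-batch same-cluster indicators C1 and
C2, and the inter-batch weight matrix M = M1 * M2, where M1 broadcasts the
(0-1 normalized) closeness of the matched cluster pair and M2 converts
per-cell-pair Euclidean distance into a similarity so that more similar
matched cells are pulled together harder.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass

import numpy as np
from sklearn.metrics.pairwise import cosine_distances, euclidean_distances
from sklearn.neighbors import NearestNeighbors

from .data import FeatureMatrix

LOG_FLOOR = 1e-12  # floor on mean distances before log10, avoids -inf


@dataclass
class ClusterMatch:
    """Cross-batch cluster matching and the loss gate matrices.

    ``match[i]`` is the batch-2 cluster matched to batch-1 cluster ``i``
    (matching is directional; batch-2 clusters hit by no ``i`` stay
    unmatched).  ``M`` is zero exactly on cell pairs from non-matched
    clusters.
    """

    U: np.ndarray
    match: np.ndarray
    C1: np.ndarray
    C2: np.ndarray
    M1: np.ndarray
    M2: np.ndarray
    M: np.ndarray
    labels1: np.ndarray
    labels2: np.ndarray

    @property
    def K1(self) -> int:
        return self.U.shape[0]

    @property
    def K2(self) -> int:
        return self.U.shape[1]

    @property
    def cluster_sizes(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.bincount(self.labels1, minlength=self.K1),
                np.bincount(self.labels2, minlength=self.K2))

    def unmatched_batch2_clusters(self) -> list[int]:
        return sorted(set(range(self.K2)) - set(self.match.tolist()))


def louvain_cluster(
    features: FeatureMatrix | np.ndarray,
    resolution: float = 1.0,
    seed: int = 0,
    n_neighbors: int = 15,
) -> np.ndarray:
    """Louvain community detection on a kNN graph of the feature space.

    Returns contiguous integer labels starting at 0, deterministic for a
    given seed (igraph's modularity optimization is randomized).
    """
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells to cluster")
    if n_neighbors >= n:
        raise ValueError(f"n_neighbors={n_neighbors} must be < n_cells={n}")
    import igraph as ig

    nn = NearestNeighbors(n_neighbors=n_neighbors).fit(x)
    _, idx = nn.kneighbors(x)
    edges = set()
    for p in range(n):
        for q in idx[p, 1:]:  # skip self
            edges.add((min(p, int(q)), max(p, int(q))))
    graph = ig.Graph(n=n, edges=sorted(edges))
    state = _pyrandom.getstate()
    try:
        _pyrandom.seed(seed)
        part = graph.community_multilevel(resolution=resolution)
    finally:
        _pyrandom.setstate(state)
    labels = np.asarray(part.membership, dtype=int)
    # relabel to contiguous ids ordered by first occurrence
    _, first = np.unique(labels, return_index=True)
    order = labels[np.sort(first)]
    remap = {int(old): new for new, old in enumerate(order)}
    return np.array([remap[int(l)] for l in labels], dtype=int)


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - cos(angle between u and v); in [0, 2]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("undefined angle: zero-norm vector")
    return float(1.0 - u @ v / (nu * nv))


def cluster_distance_matrix(
    f1: FeatureMatrix | np.ndarray,
    labels1: np.ndarray,
    f2: FeatureMatrix | np.ndarray,
    labels2: np.ndarray,
) -> np.ndarray:
    """U[i, j] = log10(mean cross-pair cosine distance), shape K1 x K2."""
    x1 = f1.values if isinstance(f1, FeatureMatrix) else np.asarray(f1)
    x2 = f2.values if isinstance(f2, FeatureMatrix) else np.asarray(f2)
    labels1 = np.asarray(labels1)
    labels2 = np.asarray(labels2)
    if labels1.shape[0] != x1.shape[0] or labels2.shape[0] != x2.shape[0]:
        raise ValueError("labels must cover all cells of their batch")
    k1 = int(labels1.max()) + 1
    k2 = int(labels2.max()) + 1
    d = cosine_distances(x1, x2)
    U = np.empty((k1, k2))
    for i in range(k1):
        rows = labels1 == i
        for j in range(k2):
            U[i, j] = np.log10(max(d[np.ix_(rows, labels2 == j)].mean(), LOG_FLOOR))
    return U


def match_clusters(U: np.ndarray) -> np.ndarray:
    """match[i] = argmin_j U[i, j]; ties resolve to the lowest column index."""
    U = np.asarray(U)
    if U.size == 0:
        raise ValueError("empty cluster distance matrix")
    if not np.all(np.isfinite(U)):
        raise ValueError("cluster distance matrix must be finite")
    return np.argmin(U, axis=1)


def intra_batch_matrix(labels: np.ndarray) -> np.ndarray:
    """C[p, q] = 1 iff cells p and q share a cluster; symmetric, unit diagonal."""
    labels = np.asarray(labels)
    return (labels[:, None] == labels[None, :]).astype(np.float64)


def inter_batch_weight_matrix(
    f1: FeatureMatrix | np.ndarray,
    labels1: np.ndarray,
    f2: FeatureMatrix | np.ndarray,
    labels2: np.ndarray,
    U: np.ndarray,
    match: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build (M1, M2, M) for all cross-batch cell pairs.

    M1 broadcasts min-max normalized -U[i, match(i)] (cluster-level matched
    closeness) to cell pairs of matched clusters; if all matched clusters are
    equally close the normalization degenerates and matched entries get 1.
    M2 = 1 - minmax(Euclidean distance) over matched pairs, a per-pair
    similarity in [0, 1].  Non-matched pairs are 0 in all three.
    """
    x1 = f1.values if isinstance(f1, FeatureMatrix) else np.asarray(f1)
    x2 = f2.values if isinstance(f2, FeatureMatrix) else np.asarray(f2)
    labels1 = np.asarray(labels1)
    labels2 = np.asarray(labels2)
    match = np.asarray(match)
    n1, n2 = x1.shape[0], x2.shape[0]
    matched_mask = match[labels1][:, None] == labels2[None, :]
    M1 = np.zeros((n1, n2))
    M2 = np.zeros((n1, n2))
    if matched_mask.any():
        neg_u = -U[np.arange(len(match)), match]
        lo, hi = neg_u.min(), neg_u.max()
        if hi > lo:
            m1_cluster = (neg_u - lo) / (hi - lo)
        else:
            m1_cluster = np.ones_like(neg_u)
        M1[matched_mask] = m1_cluster[labels1][:, None].repeat(n2, 1)[matched_mask]
        dist = euclidean_distances(x1, x2)
        dm = dist[matched_mask]
        lo_d, hi_d = dm.min(), dm.max()
        if hi_d > lo_d:
            M2[matched_mask] = 1.0 - (dm - lo_d) / (hi_d - lo_d)
        else:
            M2[matched_mask] = 1.0
    return M1, M2, M1 * M2


def build_cluster_match(
    f1: FeatureMatrix | np.ndarray,
    f2: FeatureMatrix | np.ndarray,
    resolution: float = 1.0,
    seed: int = 0,
    n_neighbors: int = 15,
    labels1: np.ndarray | None = None,
    labels2: np.ndarray | None = None,
) -> ClusterMatch:
    """Cluster both batches, match clusters, and assemble all gate matrices."""
    if labels1 is None:
        labels1 = louvain_cluster(f1, resolution=resolution, seed=seed,
                                  n_neighbors=n_neighbors)
    if labels2 is None:
        labels2 = louvain_cluster(f2, resolution=resolution, seed=seed + 1,
                                  n_neighbors=n_neighbors)
    U = cluster_distance_matrix(f1, labels1, f2, labels2)
    match = match_clusters(U)
    C1 = intra_batch_matrix(labels1)
    C2 = intra_batch_matrix(labels2)
    M1, M2, M = inter_batch_weight_matrix(f1, labels1, f2, labels2, U, match)
    return ClusterMatch(U=U, match=match, C1=C1, C2=C2, M1=M1, M2=M2, M=M,
                        labels1=np.asarray(labels1), labels2=np.asarray(labels2))
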