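"""Integration quality metrics: kBET rejection rate, silhouette, NMI, ARI, FMI.

kBET asks, for each cell, whether the batch composition of its k nearest
neighbors is consistent with the global batch proportions (chi-square
goodness of fit); the reported number is the fraction of cells whose test
rejects at level alpha.  Low rejection means well-mixed batches.  The
clustering indices compare an unsupervised clustering of the aligned
embedding against reference labels.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.metrics import (
    adjusted_rand_score,
    fowlkes_mallows_score,
    normalized_mutual_info_score,
    silhouette_score,
)
from sklearn.neighbors import NearestNeighbors


@dataclass
class EvaluationReport:
    """The five integration metrics for one embedding."""

    kbet_rejection: Optional[float]
    silhouette: Optional[float]
    nmi: Optional[float]
    ari: Optional[float]
    fmi: Optional[float]
    params: dict

    def as_dict(self) -> dict:
        return asdict(self)


def kbet_rejection(
    embedding: np.ndarray,
    batch_tags: np.ndarray,
    k: Optional[int] = None,
    alpha: float = 0.05,
) -> float:
    """Fraction of cells whose kNN batch composition rejects the global mix.

    For each cell the batch counts among its k nearest neighbors (excluding
    the cell itself) are compared to ``k *`` global proportions with a
    chi-square goodness-of-fit test at level ``alpha``.  ``k`` defaults to
    min(25, 10% of cells).
    """
    embedding = np.asarray(embedding)
    tags = np.asarray(batch_tags)
    n = embedding.shape[0]
    uniq, tag_idx = np.unique(tags, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("metric undefined for a single batch")
    if k is None:
        k = min(25, max(2, n // 10))
    if k >= n:
        raise ValueError(f"k={k} must be < number of cells {n}")
    props = np.bincount(tag_idx) / n
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    neigh = tag_idx[idx[:, 1:]]  # drop self
    expected = k * props
    rejected = 0
    for row in neigh:
        observed = np.bincount(row, minlength=len(uniq))
        stat = ((observed - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(stat, df=len(uniq) - 1)
        rejected += p < alpha
    return rejected / n


def silhouette(embedding: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient with Euclidean distance."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette undefined for a single label")
    return float(silhouette_score(np.asarray(embedding), labels, metric="euclidean"))


def _check_lengths(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape[0] != b.shape[0]:
        raise ValueError("labelings must have equal length")
    return a, b


def ari(labels_a, labels_b) -> float:
    """Rand index adjusted for chance (hypergeometric expectation)."""
    a, b = _check_lengths(labels_a, labels_b)
    return float(adjusted_rand_score(a, b))


def nmi(labels_a, labels_b) -> float:
    """Mutual information normalized by the arithmetic mean of entropies.

    Two constant labelings agree perfectly (1); a constant against a
    non-constant carries no information (0).
    """
    a, b = _check_lengths(labels_a, labels_b)
    const_a = len(np.unique(a)) == 1
    const_b = len(np.unique(b)) == 1
    if const_a and const_b:
        return 1.0
    if const_a or const_b:
        return 0.0
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def fmi(labels_a, labels_b) -> float:
    """Geometric mean of pairwise precision and recall over same-cluster pairs."""
    a, b = _check_lengths(labels_a, labels_b)
    return float(fowlkes_mallows_score(a, b))


def evaluate_embedding(
    embedding: np.ndarray,
    batch_tags: np.ndarray,
    reference_labels1: np.ndarray,
    reference_labels2: np.ndarray,
    k: Optional[int] = None,
    alpha: float = 0.05,
    louvain_resolution: float = 1.0,
    louvain_neighbors: int = 15,
    seed: int = 0,
) -> EvaluationReport:
    """Full metric suite for one aligned embedding.

    The embedding is re-clustered (Louvain); silhouette scores that joint
    clustering, and NMI/ARI/FMI compare it with each batch's original
    cluster labels restricted to that batch's cells, averaged over the two
    batches.
    """
    from .clustermatch import louvain_cluster

    embedding = np.asarray(embedding)
    tags = np.asarray(batch_tags)
    joint = louvain_cluster(embedding, resolution=louvain_resolution,
                            seed=seed, n_neighbors=louvain_neighbors)
    uniq = np.unique(tags)
    n1 = int((tags == uniq[0]).sum())
    ref = {uniq[0]: np.asarray(reference_labels1),
           uniq[1]: np.asarray(reference_labels2)}
    scores = {"nmi": [], "ari": [], "fmi": []}
    for tag in uniq[:2]:
        mask = tags == tag
        scores["nmi"].append(nmi(joint[mask], ref[tag]))
        scores["ari"].append(ari(joint[mask], ref[tag]))
        scores["fmi"].append(fmi(joint[mask], ref[tag]))
    try:
        sil = silhouette(embedding, joint)
    except ValueError:
        sil = None
    return EvaluationReport(
        kbet_rejection=kbet_rejection(embedding, tags, k=k, alpha=alpha),
        silhouette=sil,
        nmi=float(np.mean(scores["nmi"])),
        ari=float(np.mean(scores["ari"])),
        fmi=float(np.mean(scores["fmi"])),
        params=dict(k=k, alpha=alpha, louvain_resolution=louvain_resolution,
                    seed=seed, n_batch1=n1, label_sources="per-batch clusters"),
    )
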