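"""Pair sampling, Adam training loop, early stopping, and cell embedding.

The network consumes two cross-batch cell pairs at a time, so training
reduces to sampling minibatches of (A, B, C, D) index quadruples with their
loss gates attached.  Sampling is stratified: a configurable fraction of
quadruples is drawn so that (A, B) and (C, D) fall in matched clusters and
(A, C) share a batch-1 cluster — unstratified sampling would rarely hit a
nonzero gate and starve the structure/cluster losses.

After training, each cell is embedded by pairing it with random partners
from its matched cluster in the other batch and averaging the pair
bottleneck vector over ``R`` partners, which removes partner-choice noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .clustermatch import ClusterMatch
from .data import FeatureMatrix
from .network import PairedAutoencoder, loss_and_grads


@dataclass
class TrainState:
    epoch: int = 0
    history: dict[str, list[float]] = field(default_factory=lambda: {
        "reconstruction": [], "structure": [], "cluster": [],
        "prediction": [], "total": [],
    })
    rng_seed: int = 0
    stopped_early: bool = False


@dataclass
class AlignmentResult:
    """Aligned per-cell embedding for all cells of both batches.

    Rows of ``embedding`` are batch-1 cells followed by batch-2 cells;
    ``batch_of_cell`` carries the originating batch tag per row.
    """

    embedding: np.ndarray
    reconstructions: np.ndarray
    batch_of_cell: list[str]
    train_state: TrainState


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: list[np.ndarray], lr: float = 5e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * math.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def sample_pairs(
    f1: FeatureMatrix,
    f2: FeatureMatrix,
    cm: ClusterMatch,
    batch_size: int,
    rng: np.random.Generator,
    matched_fraction: float = 0.75,
) -> dict:
    """Draw a minibatch of (A, B, C, D) quadruples with loss gates.

    A and C index batch-1 cells, B and D batch-2 cells.  With probability
    ``matched_fraction`` per quadruple, B (resp. D) is drawn from the batch-2
    cluster matched to A's (resp. C's) cluster, and C from A's own cluster;
    otherwise all four are uniform.  If a batch-1 cluster has no matched
    cells the draw falls back to uniform with a warning.
    """
    n1, n2 = f1.n_cells, f2.n_cells
    if n1 == 0 or n2 == 0:
        raise ValueError("both batches must be non-empty")
    labels1, labels2 = cm.labels1, cm.labels2
    cells_by_cluster2 = {j: np.flatnonzero(labels2 == j) for j in range(cm.K2)}
    cells_by_cluster1 = {i: np.flatnonzero(labels1 == i) for i in range(cm.K1)}

    idx_a = rng.integers(0, n1, size=batch_size)
    idx_c = rng.integers(0, n1, size=batch_size)
    idx_b = rng.integers(0, n2, size=batch_size)
    idx_d = rng.integers(0, n2, size=batch_size)
    stratified = rng.random(batch_size) < matched_fraction

    warned = False
    for s in np.flatnonzero(stratified):
        ca = labels1[idx_a[s]]
        pool_c = cells_by_cluster1[int(ca)]
        idx_c[s] = pool_c[rng.integers(0, len(pool_c))]
        for which, cell in (("b", idx_a[s]), ("d", idx_c[s])):
            target = int(cm.match[labels1[cell]])
            pool = cells_by_cluster2.get(target, np.array([], dtype=int))
            if len(pool) == 0:
                if not warned:
                    warnings.warn("matched cluster has no cells; "
                                  "falling back to uniform sampling")
                    warned = True
                continue
            if which == "b":
                idx_b[s] = pool[rng.integers(0, len(pool))]
            else:
                idx_d[s] = pool[rng.integers(0, len(pool))]

    return dict(
        a=f1.values[idx_a], b=f2.values[idx_b],
        c=f1.values[idx_c], d=f2.values[idx_d],
        c1_gate=cm.C1[idx_a, idx_c], c2_gate=cm.C2[idx_b, idx_d],
        m_ab=cm.M[idx_a, idx_b], m_cd=cm.M[idx_c, idx_d],
        labels_a=labels1[idx_a], labels_b=labels2[idx_b],
        labels_c=labels1[idx_c], labels_d=labels2[idx_d],
        idx=(idx_a, idx_b, idx_c, idx_d),
    )


@dataclass
class FitSettings:
    lr: float = 5e-4
    max_epochs: int = 10_000
    batch_size: int = 256
    matched_fraction: float = 0.75
    patience_window: int = 100
    tol: float = 1e-4
    seed: int = 0
    log_every: int = 0  # 0 = silent


def fit(
    net: PairedAutoencoder,
    f1: FeatureMatrix,
    f2: FeatureMatrix,
    cm: ClusterMatch,
    settings: Optional[FitSettings] = None,
) -> TrainState:
    """Train with Adam until the smoothed total loss stops decreasing.

    One epoch is ``ceil((n1 + n2) / batch_size)`` minibatches.  Training
    stops when the mean total loss over the last patience window improves on
    the previous window by less than ``tol`` (relative), or at
    ``max_epochs``.
    """
    s = settings or FitSettings()
    rng = np.random.default_rng(s.seed)
    opt = Adam(net.params, lr=s.lr)
    state = TrainState(rng_seed=s.seed)
    steps = max(1, math.ceil((f1.n_cells + f2.n_cells) / s.batch_size))
    w = s.patience_window
    for epoch in range(1, s.max_epochs + 1):
        sums = dict.fromkeys(state.history, 0.0)
        for _ in range(steps):
            mb = sample_pairs(f1, f2, cm, s.batch_size, rng, s.matched_fraction)
            losses, grads = loss_and_grads(
                net, mb["a"], mb["b"], mb["c"], mb["d"],
                mb["c1_gate"], mb["c2_gate"], mb["m_ab"], mb["m_cd"],
                mb["labels_a"], mb["labels_b"], mb["labels_c"], mb["labels_d"],
            )
            if not np.isfinite(losses["total"]):
                bad = [k for k, v in losses.items() if not np.isfinite(v)]
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {', '.join(bad)}"
                )
            opt.step(grads)
            for k in sums:
                sums[k] += losses[k]
        for k in sums:
            state.history[k].append(sums[k] / steps)
        state.epoch = epoch
        if s.log_every and epoch % s.log_every == 0:
            h = state.history
            print(f"epoch {epoch}: total={h['total'][-1]:.5f} "
                  f"Lr={h['reconstruction'][-1]:.5f} Ls={h['structure'][-1]:.5f} "
                  f"Lc={h['cluster'][-1]:.5f} Lp={h['prediction'][-1]:.5f}")
        if epoch >= 2 * w:
            recent = float(np.mean(state.history["total"][-w:]))
            previous = float(np.mean(state.history["total"][-2 * w:-w]))
            denom = max(abs(previous), 1e-12)
            if (previous - recent) / denom < s.tol:
                state.stopped_early = True
                break
    return state


def embed_cells(
    net: PairedAutoencoder,
    f1: FeatureMatrix,
    f2: FeatureMatrix,
    cm: ClusterMatch,
    R: int = 16,
    seed: int = 0,
    train_state: Optional[TrainState] = None,
) -> AlignmentResult:
    """Per-cell aligned embedding, averaged over R random matched partners.

    A batch-1 cell is paired with cells of its matched batch-2 cluster; a
    batch-2 cell with cells of the batch-1 clusters that match onto its
    cluster.  Cells of an unmatched batch-2 cluster draw partners uniformly
    from batch 1 (the embedding stays defined; the cell simply gets no
    cluster-specific pull).
    """
    rng = np.random.default_rng(seed)
    n1, n2 = f1.n_cells, f2.n_cells
    labels1, labels2 = cm.labels1, cm.labels2
    cells2_by_cluster = {j: np.flatnonzero(labels2 == j) for j in range(cm.K2)}
    partners_for_cluster2 = {
        j: np.flatnonzero(np.isin(labels1, np.flatnonzero(cm.match == j)))
        for j in range(cm.K2)
    }

    emb = np.zeros((n1 + n2, net.config.embed_dim))
    rec = np.zeros((n1 + n2, net.config.input_dim))
    d = net.config.input_dim

    def _accumulate(rows, left, right, own_is_left):
        out = net.embed(left, right)
        r, _ = net.decoder.forward(out)
        own = r[:, :d] if own_is_left else r[:, d:]
        emb[rows] += out / R
        rec[rows] += own / R

    for _ in range(R):
        partner_of_1 = np.empty(n1, dtype=int)
        for i in range(cm.K1):
            rows = np.flatnonzero(labels1 == i)
            pool = cells2_by_cluster.get(int(cm.match[i]), np.array([], dtype=int))
            if len(pool) == 0:
                pool = np.arange(n2)
            partner_of_1[rows] = pool[rng.integers(0, len(pool), size=len(rows))]
        _accumulate(np.arange(n1), f1.values, f2.values[partner_of_1], True)

        partner_of_2 = np.empty(n2, dtype=int)
        for j in range(cm.K2):
            rows = np.flatnonzero(labels2 == j)
            pool = partners_for_cluster2[j]
            if len(pool) == 0:
                pool = np.arange(n1)
            partner_of_2[rows] = pool[rng.integers(0, len(pool), size=len(rows))]
        _accumulate(n1 + np.arange(n2), f1.values[partner_of_2], f2.values, False)

    tags = [f1.source_batch] * n1 + [f2.source_batch] * n2
    return AlignmentResult(
        embedding=emb, reconstructions=rec, batch_of_cell=tags,
        train_state=train_state or TrainState(),
    )
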