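"""Two-stream paired autoencoder with a per-batch softmax classifier head.

One shared autoencoder processes two cross-batch cell pairs at a time:
stream 1 encodes the concatenation of cell A (batch 1) and cell B (batch 2)
into the bottleneck vector M and decodes it to reconstructions (A4, B4);
stream 2 does the same for the pair (C, D) giving N and (C4, D4).  Four loss
terms shape the embedding:

* reconstruction ``L_r``      — reconstructions match the inputs,
* structure-preserving ``L_s`` — same-batch, same-cluster reconstructions
  (A4 vs C4, B4 vs D4) stay close, gated by the C matrices,
* cluster-preserving ``L_c``  — cross-batch reconstructions of matched
  clusters (A4 vs B4, C4 vs D4) stay close, weighted by M,
* cluster-prediction ``L_p``  — a softmax classifier on each reconstruction
  must recover the cell's own within-batch cluster label.

The total loss is the unweighted sum.  All computation is dense NumPy;
gradients are hand-derived and checked against finite differences in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

LEAKY_SLOPE = 0.01


@dataclass
class NetworkConfig:
    """Architecture and loss configuration for the paired autoencoder.

    ``input_dim`` is the number of per-cell features (retained PCs); the
    encoder consumes concatenated pairs, so its input width is
    ``2 * input_dim``.  ``embed_dim`` defaults to ``min(128, input_dim)`` so
    the bottleneck always compresses the pair.
    """

    input_dim: int
    n_classes_b1: int
    n_classes_b2: int
    hidden_dims: tuple[int, ...] = (512,)
    embed_dim: Optional[int] = None
    seed: int = 0
    loss_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.embed_dim is None:
            self.embed_dim = min(128, max(2, self.input_dim))
        if not self.hidden_dims:
            raise ValueError("hidden_dims must be non-empty")
        if self.embed_dim >= 2 * self.input_dim:
            raise ValueError("embed_dim must be < 2 * input_dim")
        if self.n_classes_b1 < 1 or self.n_classes_b2 < 1:
            raise ValueError("need at least one class per batch")


@dataclass
class PairForward:
    """Outputs of one forward pass through both streams (batched rows)."""

    a1: np.ndarray
    b1: np.ndarray
    c1: np.ndarray
    d1: np.ndarray
    Mvec: np.ndarray
    Nvec: np.ndarray
    A4: np.ndarray
    B4: np.ndarray
    C4: np.ndarray
    D4: np.ndarray
    probs_A: np.ndarray
    probs_B: np.ndarray
    probs_C: np.ndarray
    probs_D: np.ndarray
    caches: dict = field(default_factory=dict, repr=False)

    @property
    def E2(self) -> np.ndarray:
        """Concatenated reconstruction of stream inputs from batch 1: A4 || C4."""
        return np.concatenate([self.A4, self.C4], axis=1)

    @property
    def F2(self) -> np.ndarray:
        """Concatenated reconstruction of stream inputs from batch 2: B4 || D4."""
        return np.concatenate([self.B4, self.D4], axis=1)


def leaky_relu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, LEAKY_SLOPE * x)


def leaky_relu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, LEAKY_SLOPE)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class _MLP:
    """Dense stack with leaky-ReLU hidden activations and a linear output."""

    def __init__(self, dims: Sequence[int], rng: np.random.Generator):
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for din, dout in zip(dims[:-1], dims[1:]):
            # He-style init, suitable for leaky-ReLU stacks
            self.W.append(rng.normal(0.0, np.sqrt(2.0 / din), size=(din, dout)))
            self.b.append(np.zeros(dout))

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list]:
        cache = []
        h = x
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            cache.append((h, z))
            h = z if i == last else leaky_relu(z)
        return h, cache

    def backward(self, dout: np.ndarray, cache: list) -> tuple[np.ndarray, list, list]:
        dW = [np.zeros_like(W) for W in self.W]
        db = [np.zeros_like(b) for b in self.b]
        last = len(self.W) - 1
        dh = dout
        for i in range(last, -1, -1):
            h_in, z = cache[i]
            dz = dh if i == last else dh * leaky_relu_grad(z)
            dW[i] = h_in.T @ dz
            db[i] = dz.sum(axis=0)
            dh = dz @ self.W[i].T
        return dh, dW, db

    @property
    def params(self) -> list[np.ndarray]:
        return self.W + self.b


class PairedAutoencoder:
    """The shared encoder/decoder applied to both streams, plus classifiers.

    Weights are shared between streams: a single alignment function serves
    every cell pair.  The classifier heads act on reconstructions, one head
    per batch (batch-1 head scores A4 and C4, batch-2 head scores B4 and D4).
    """

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d2 = 2 * config.input_dim
        enc_dims = [d2, *config.hidden_dims, config.embed_dim]
        dec_dims = [config.embed_dim, *reversed(config.hidden_dims), d2]
        self.encoder = _MLP(enc_dims, rng)
        self.decoder = _MLP(dec_dims, rng)
        d = config.input_dim
        self.Wc1 = rng.normal(0.0, np.sqrt(1.0 / d), size=(d, config.n_classes_b1))
        self.bc1 = np.zeros(config.n_classes_b1)
        self.Wc2 = rng.normal(0.0, np.sqrt(1.0 / d), size=(d, config.n_classes_b2))
        self.bc2 = np.zeros(config.n_classes_b2)

    # ---- parameter plumbing ------------------------------------------------

    @property
    def params(self) -> list[np.ndarray]:
        return [*self.encoder.params, *self.decoder.params,
                self.Wc1, self.bc1, self.Wc2, self.bc2]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w

    # ---- forward -----------------------------------------------------------

    def forward_pair(self, a1, b1, c1, d1) -> PairForward:
        a1, b1, c1, d1 = (np.atleast_2d(np.asarray(x, dtype=float))
                          for x in (a1, b1, c1, d1))
        d = self.config.input_dim
        for name, x in zip("abcd", (a1, b1, c1, d1)):
            if x.shape[1] != d:
                raise ValueError(f"input {name}1 has {x.shape[1]} features, "
                                 f"expected {d}")
        x1 = np.concatenate([a1, b1], axis=1)
        x2 = np.concatenate([c1, d1], axis=1)
        Mvec, enc_cache1 = self.encoder.forward(x1)
        Nvec, enc_cache2 = self.encoder.forward(x2)
        r1, dec_cache1 = self.decoder.forward(Mvec)
        r2, dec_cache2 = self.decoder.forward(Nvec)
        A4, B4 = r1[:, :d], r1[:, d:]
        C4, D4 = r2[:, :d], r2[:, d:]
        return PairForward(
            a1=a1, b1=b1, c1=c1, d1=d1, Mvec=Mvec, Nvec=Nvec,
            A4=A4, B4=B4, C4=C4, D4=D4,
            probs_A=softmax(A4 @ self.Wc1 + self.bc1),
            probs_B=softmax(B4 @ self.Wc2 + self.bc2),
            probs_C=softmax(C4 @ self.Wc1 + self.bc1),
            probs_D=softmax(D4 @ self.Wc2 + self.bc2),
            caches=dict(enc1=enc_cache1, enc2=enc_cache2,
                        dec1=dec_cache1, dec2=dec_cache2),
        )

    def embed(self, left: np.ndarray, right: np.ndarray) -> np.ndarray:
        """Bottleneck vector for the cross-batch pair (left, right)."""
        x = np.concatenate([np.atleast_2d(left), np.atleast_2d(right)], axis=1)
        out, _ = self.encoder.forward(x)
        return out


# ---- losses (batched; mean over minibatch rows) ----------------------------


def loss_reconstruction(a1, c1, b1, d1, E2, F2, eps_r: int) -> float:
    """Mean of (1/2eps_r)*||a||c - E2||^2 + (1/2eps_r)*||b||d - F2||^2."""
    ac = np.concatenate([np.atleast_2d(a1), np.atleast_2d(c1)], axis=1)
    bd = np.concatenate([np.atleast_2d(b1), np.atleast_2d(d1)], axis=1)
    t1 = ((ac - np.atleast_2d(E2)) ** 2).sum(axis=1) / (2 * eps_r)
    t2 = ((bd - np.atleast_2d(F2)) ** 2).sum(axis=1) / (2 * eps_r)
    return float(np.mean(t1 + t2))


def loss_structure(A4, C4, B4, D4, c1_gate, c2_gate, eps_s: int) -> float:
    """Same-batch pull, gated by the binary same-cluster indicators."""
    A4, C4, B4, D4 = map(np.atleast_2d, (A4, C4, B4, D4))
    g1 = np.atleast_1d(np.asarray(c1_gate, dtype=float))
    g2 = np.atleast_1d(np.asarray(c2_gate, dtype=float))
    t1 = ((A4 - C4) ** 2).sum(axis=1) * g1 / eps_s
    t2 = ((B4 - D4) ** 2).sum(axis=1) * g2 / eps_s
    return float(np.mean(t1 + t2))


def loss_cluster(A4, B4, C4, D4, m_ab, m_cd, eps_c: int) -> float:
    """Cross-batch pull, weighted by the matched-cluster weights M."""
    A4, B4, C4, D4 = map(np.atleast_2d, (A4, B4, C4, D4))
    w1 = np.atleast_1d(np.asarray(m_ab, dtype=float))
    w2 = np.atleast_1d(np.asarray(m_cd, dtype=float))
    t1 = ((A4 - B4) ** 2).sum(axis=1) * w1 / eps_c
    t2 = ((C4 - D4) ** 2).sum(axis=1) * w2 / eps_c
    return float(np.mean(t1 + t2))


def loss_prediction(
    probs: Sequence[np.ndarray], onehots: Sequence[np.ndarray]
) -> float:
    """Sum over the four cells of mean (1/eps_p)*||softmax - onehot||^2.

    ``eps_p`` is the class count of the relevant head (the softmax output
    length), taken from each probability matrix.
    """
    total = 0.0
    for p, o in zip(probs, onehots):
        p = np.atleast_2d(p)
        o = np.atleast_2d(o)
        if p.shape != o.shape:
            raise ValueError("one-hot target shape does not match class count")
        total += float(np.mean(((p - o) ** 2).sum(axis=1) / p.shape[1]))
    return total


def total_loss(lr: float, ls: float, lc: float, lp: float,
               weights: tuple[float, float, float, float] = (1, 1, 1, 1)) -> float:
    return weights[0] * lr + weights[1] * ls + weights[2] * lc + weights[3] * lp


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.atleast_1d(np.asarray(labels, dtype=int))
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("label index outside class count")
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


# ---- fused loss + gradients ------------------------------------------------


def loss_and_grads(
    net: PairedAutoencoder,
    a1, b1, c1, d1,
    c1_gate, c2_gate, m_ab, m_cd,
    labels_a, labels_b, labels_c, labels_d,
) -> tuple[dict, list[np.ndarray]]:
    """Compute all four losses and gradients w.r.t. every network parameter.

    Gates and labels are per-minibatch-row vectors.  Returns
    ``(losses, grads)`` with ``grads`` ordered like ``net.params``.
    """
    cfg = net.config
    d = cfg.input_dim
    fwd = net.forward_pair(a1, b1, c1, d1)
    n = fwd.a1.shape[0]
    w_r, w_s, w_c, w_p = cfg.loss_weights

    oh_a = one_hot(labels_a, cfg.n_classes_b1)
    oh_b = one_hot(labels_b, cfg.n_classes_b2)
    oh_c = one_hot(labels_c, cfg.n_classes_b1)
    oh_d = one_hot(labels_d, cfg.n_classes_b2)

    lr_val = loss_reconstruction(fwd.a1, fwd.c1, fwd.b1, fwd.d1, fwd.E2, fwd.F2, d)
    ls_val = loss_structure(fwd.A4, fwd.C4, fwd.B4, fwd.D4, c1_gate, c2_gate, d)
    lc_val = loss_cluster(fwd.A4, fwd.B4, fwd.C4, fwd.D4, m_ab, m_cd, d)
    lp_val = loss_prediction(
        (fwd.probs_A, fwd.probs_B, fwd.probs_C, fwd.probs_D),
        (oh_a, oh_b, oh_c, oh_d),
    )
    losses = dict(
        reconstruction=lr_val, structure=ls_val, cluster=lc_val,
        prediction=lp_val,
        total=total_loss(lr_val, ls_val, lc_val, lp_val, cfg.loss_weights),
    )

    g1 = np.atleast_1d(np.asarray(c1_gate, dtype=float))[:, None]
    g2 = np.atleast_1d(np.asarray(c2_gate, dtype=float))[:, None]
    w1 = np.atleast_1d(np.asarray(m_ab, dtype=float))[:, None]
    w2 = np.atleast_1d(np.asarray(m_cd, dtype=float))[:, None]

    # d(loss)/d(reconstruction), all terms mean-reduced over the minibatch
    dA4 = w_r * (fwd.A4 - fwd.a1) / (d * n)
    dB4 = w_r * (fwd.B4 - fwd.b1) / (d * n)
    dC4 = w_r * (fwd.C4 - fwd.c1) / (d * n)
    dD4 = w_r * (fwd.D4 - fwd.d1) / (d * n)

    diff_ac = fwd.A4 - fwd.C4
    diff_bd = fwd.B4 - fwd.D4
    dA4 += w_s * 2.0 * diff_ac * g1 / (d * n)
    dC4 -= w_s * 2.0 * diff_ac * g1 / (d * n)
    dB4 += w_s * 2.0 * diff_bd * g2 / (d * n)
    dD4 -= w_s * 2.0 * diff_bd * g2 / (d * n)

    diff_ab = fwd.A4 - fwd.B4
    diff_cd = fwd.C4 - fwd.D4
    dA4 += w_c * 2.0 * diff_ab * w1 / (d * n)
    dB4 -= w_c * 2.0 * diff_ab * w1 / (d * n)
    dC4 += w_c * 2.0 * diff_cd * w2 / (d * n)
    dD4 -= w_c * 2.0 * diff_cd * w2 / (d * n)

    dWc1 = np.zeros_like(net.Wc1)
    dbc1 = np.zeros_like(net.bc1)
    dWc2 = np.zeros_like(net.Wc2)
    dbc2 = np.zeros_like(net.bc2)

    def _classifier_back(r4, probs, onehot, Wc):
        # L = mean_rows (1/eps_p) * ||s - onehot||^2, s = softmax(r4 Wc + bc)
        eps_p = probs.shape[1]
        g = w_p * 2.0 * (probs - onehot) / (eps_p * n)
        dz = probs * (g - (g * probs).sum(axis=1, keepdims=True))
        return r4.T @ dz, dz.sum(axis=0), dz @ Wc.T

    gW, gb, dr = _classifier_back(fwd.A4, fwd.probs_A, oh_a, net.Wc1)
    dWc1 += gW; dbc1 += gb; dA4 += dr
    gW, gb, dr = _classifier_back(fwd.C4, fwd.probs_C, oh_c, net.Wc1)
    dWc1 += gW; dbc1 += gb; dC4 += dr
    gW, gb, dr = _classifier_back(fwd.B4, fwd.probs_B, oh_b, net.Wc2)
    dWc2 += gW; dbc2 += gb; dB4 += dr
    gW, gb, dr = _classifier_back(fwd.D4, fwd.probs_D, oh_d, net.Wc2)
    dWc2 += gW; dbc2 += gb; dD4 += dr

    dr1 = np.concatenate([dA4, dB4], axis=1)
    dr2 = np.concatenate([dC4, dD4], axis=1)

    dM, decW1, decb1 = net.decoder.backward(dr1, fwd.caches["dec1"])
    dN, decW2, decb2 = net.decoder.backward(dr2, fwd.caches["dec2"])
    _, encW1, encb1 = net.encoder.backward(dM, fwd.caches["enc1"])
    _, encW2, encb2 = net.encoder.backward(dN, fwd.caches["enc2"])

    enc_grads = [a + b for a, b in zip(encW1 + encb1, encW2 + encb2)]
    dec_grads = [a + b for a, b in zip(decW1 + decb1, decW2 + decb2)]
    grads = [*enc_grads, *dec_grads, dWc1, dbc1, dWc2, dbc2]
    return losses, grads
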