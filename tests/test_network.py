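import numpy as np
import pytest

import cba
from cba.network import (
    NetworkConfig,
    PairedAutoencoder,
    loss_and_grads,
    loss_cluster,
    loss_prediction,
    loss_reconstruction,
    loss_structure,
    one_hot,
    softmax,
    total_loss,
)


# ---- independent naive loss implementations (scalar loops, no shared code) --

def naive_lr(a, c, b, d, E2, F2, eps_r):
    s1 = sum((x - y) ** 2 for x, y in zip(list(a) + list(c), E2))
    s2 = sum((x - y) ** 2 for x, y in zip(list(b) + list(d), F2))
    return s1 / (2 * eps_r) + s2 / (2 * eps_r)


def naive_ls(A4, C4, B4, D4, c1, c2, eps_s):
    t1 = sum((x - y) ** 2 for x, y in zip(A4, C4)) * c1
    t2 = sum((x - y) ** 2 for x, y in zip(B4, D4)) * c2
    return (t1 + t2) / eps_s


def naive_lc(A4, B4, C4, D4, m_ab, m_cd, eps_c):
    t1 = sum((x - y) ** 2 for x, y in zip(A4, B4)) * m_ab
    t2 = sum((x - y) ** 2 for x, y in zip(C4, D4)) * m_cd
    return (t1 + t2) / eps_c


def naive_lp(probs, onehots):
    total = 0.0
    for p, o in zip(probs, onehots):
        total += sum((pi - oi) ** 2 for pi, oi in zip(p, o)) / len(p)
    return total


def tiny_net(input_dim=3, k1=2, k2=3, seed=0):
    return PairedAutoencoder(NetworkConfig(
        input_dim=input_dim, n_classes_b1=k1, n_classes_b2=k2,
        hidden_dims=(5,), embed_dim=2, seed=seed))


class TestForwardPair:
    def test_output_shapes(self, rng):
        net = tiny_net()
        fwd = net.forward_pair(*(rng.normal(size=(4, 3)) for _ in range(4)))
        assert fwd.A4.shape == fwd.B4.shape == fwd.C4.shape == fwd.D4.shape == (4, 3)
        assert fwd.Mvec.shape == fwd.Nvec.shape == (4, 2)
        assert fwd.probs_A.shape == (4, 2) and fwd.probs_B.shape == (4, 3)
        assert fwd.E2.shape == (4, 6)

    def test_class_probs_on_simplex(self, rng):
        net = tiny_net()
        fwd = net.forward_pair(*(rng.normal(size=(6, 3)) for _ in range(4)))
        for p in (fwd.probs_A, fwd.probs_B, fwd.probs_C, fwd.probs_D):
            np.testing.assert_allclose(p.sum(axis=1), 1.0, rtol=1e-12)
            assert np.all(p >= 0)

    def test_identical_streams_identical_outputs(self, rng):
        net = tiny_net()
        a, b = rng.normal(size=(2, 3)), rng.normal(size=(2, 3))
        fwd = net.forward_pair(a, b, a, b)
        np.testing.assert_array_equal(fwd.Mvec, fwd.Nvec)
        np.testing.assert_array_equal(fwd.A4, fwd.C4)
        np.testing.assert_array_equal(fwd.B4, fwd.D4)

    def test_deterministic_given_weights(self, rng):
        net = tiny_net(seed=3)
        inputs = [rng.normal(size=(2, 3)) for _ in range(4)]
        f1 = net.forward_pair(*inputs)
        f2 = net.forward_pair(*inputs)
        np.testing.assert_array_equal(f1.A4, f2.A4)

    def test_dimension_mismatch_rejected(self, rng):
        net = tiny_net()
        with pytest.raises(ValueError, match="features"):
            net.forward_pair(np.zeros((1, 4)), np.zeros((1, 3)),
                             np.zeros((1, 3)), np.zeros((1, 3)))

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            NetworkConfig(input_dim=3, n_classes_b1=2, n_classes_b2=2,
                          embed_dim=6)
        with pytest.raises(ValueError):
            NetworkConfig(input_dim=3, n_classes_b1=2, n_classes_b2=2,
                          hidden_dims=())


class TestLossHandValues:
    def test_reconstruction_perfect_zero(self):
        a = np.array([1.0, 2.0])
        val = loss_reconstruction(a, a, a, a, np.concatenate([a, a]),
                                  np.concatenate([a, a]), 2)
        assert val == 0.0

    def test_reconstruction_hand_case(self):
        a1, c1 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        b1 = d1 = np.zeros(2)
        E2 = np.zeros(4)
        F2 = np.zeros(4)  # stream 2 perfect (b,d zero)
        assert loss_reconstruction(a1, c1, b1, d1, E2, F2, 2) == pytest.approx(0.5)

    def test_reconstruction_stream_symmetry(self, rng):
        a, b, c, d = (rng.normal(size=2) for _ in range(4))
        E2, F2 = rng.normal(size=4), rng.normal(size=4)
        # swapping the roles of the two batches swaps the two terms
        assert loss_reconstruction(a, c, b, d, E2, F2, 2) == pytest.approx(
            loss_reconstruction(b, d, a, c, F2, E2, 2))

    def test_structure_gated_off(self, rng):
        vals = [rng.normal(size=3) for _ in range(4)]
        assert loss_structure(*vals, 0.0, 0.0, 3) == 0.0

    def test_structure_hand_case(self):
        A4, C4 = np.zeros(2), np.ones(2)
        B4 = D4 = np.zeros(2)
        assert loss_structure(A4, C4, B4, D4, 1.0, 0.0, 2) == pytest.approx(1.0)

    def test_cluster_hand_case(self):
        A4, B4 = np.array([1.0, 0.0]), np.zeros(2)
        C4 = D4 = np.zeros(2)
        assert loss_cluster(A4, B4, C4, D4, 1.0, 0.0, 2) == pytest.approx(0.5)

    def test_cluster_linear_in_weight(self, rng):
        A4, B4, C4, D4 = (rng.normal(size=3) for _ in range(4))
        one = loss_cluster(A4, B4, C4, D4, 1.0, 0.0, 3)
        two = loss_cluster(A4, B4, C4, D4, 2.0, 0.0, 3)
        assert two == pytest.approx(2 * one)

    def test_prediction_exact_zero(self):
        oh = one_hot(np.array([1]), 3)
        assert loss_prediction([oh] * 4, [oh] * 4) == 0.0

    def test_prediction_uniform_vs_onehot(self):
        p = np.array([[0.5, 0.5]])
        oh = np.array([[1.0, 0.0]])
        zero = np.array([[1.0, 0.0]])
        val = loss_prediction([p, zero, zero, zero], [oh, zero, zero, zero])
        assert val == pytest.approx(0.25)

    def test_prediction_upper_bound_on_simplex(self, rng):
        # ||p - onehot||^2 <= 2 for p on the simplex
        for _ in range(20):
            logits = rng.normal(scale=5, size=(1, 4))
            p = softmax(logits)
            oh = one_hot(rng.integers(0, 4, 1), 4)
            assert loss_prediction([p], [oh]) <= 2 / 4 + 1e-12

    def test_prediction_label_out_of_range(self):
        with pytest.raises(ValueError):
            one_hot(np.array([3]), 3)

    def test_total_is_sum(self):
        assert total_loss(0.5, 1.0, 0.5, 0.25) == pytest.approx(2.25)
        assert total_loss(0, 0, 0, 0) == 0.0


class TestLossOracleEquivalence:
    """Implementation losses match naive scalar-loop formulas, tol 1e-8."""

    def test_random_instances(self, rng):
        for _ in range(20):
            eps = int(rng.integers(2, 9))
            a, b, c, d, A4, B4, C4, D4 = (rng.normal(size=eps)
                                          for _ in range(8))
            E2 = np.concatenate([A4, C4])
            F2 = np.concatenate([B4, D4])
            g1, g2 = rng.integers(0, 2, 2).astype(float)
            m1, m2 = rng.random(2)
            assert loss_reconstruction(a, c, b, d, E2, F2, eps) == pytest.approx(
                naive_lr(a, c, b, d, E2, F2, eps), abs=1e-8)
            assert loss_structure(A4, C4, B4, D4, g1, g2, eps) == pytest.approx(
                naive_ls(A4, C4, B4, D4, g1, g2, eps), abs=1e-8)
            assert loss_cluster(A4, B4, C4, D4, m1, m2, eps) == pytest.approx(
                naive_lc(A4, B4, C4, D4, m1, m2, eps), abs=1e-8)
            k = int(rng.integers(2, 5))
            probs = [softmax(rng.normal(size=(1, k)))[0] for _ in range(4)]
            ohs = [one_hot(rng.integers(0, k, 1), k)[0] for _ in range(4)]
            assert loss_prediction(
                [p[None] for p in probs], [o[None] for o in ohs]
            ) == pytest.approx(naive_lp(probs, ohs), abs=1e-8)

    def test_all_losses_zero_at_perfect_fit(self, rng):
        """Perfect reconstruction + consistent one-hot prediction zero every
        loss for arbitrary gate matrices when the compared cells coincide."""
        x = rng.normal(size=4)
        E2 = np.concatenate([x, x])
        assert loss_reconstruction(x, x, x, x, E2, E2, 4) == 0.0
        assert loss_structure(x, x, x, x, 1.0, 1.0, 4) == 0.0
        assert loss_cluster(x, x, x, x, 1.0, 1.0, 4) == 0.0


class TestGradients:
    def test_matches_finite_differences(self, rng):
        net = tiny_net(seed=1)
        n = 3
        args = dict(
            a1=rng.normal(size=(n, 3)), b1=rng.normal(size=(n, 3)),
            c1=rng.normal(size=(n, 3)), d1=rng.normal(size=(n, 3)),
            c1_gate=rng.integers(0, 2, n).astype(float),
            c2_gate=rng.integers(0, 2, n).astype(float),
            m_ab=rng.random(n), m_cd=rng.random(n),
            labels_a=rng.integers(0, 2, n), labels_b=rng.integers(0, 3, n),
            labels_c=rng.integers(0, 2, n), labels_d=rng.integers(0, 3, n),
        )

        def total():
            losses, _ = loss_and_grads(net, **args)
            return losses["total"]

        _, grads = loss_and_grads(net, **args)
        h = 1e-6
        for p, g in zip(net.params, grads):
            take = min(12, p.size)
            flat = np.unravel_index(
                rng.choice(p.size, size=take, replace=False), p.shape)
            for j in range(take):
                ix = tuple(int(f[j]) for f in flat)
                orig = p[ix]
                p[ix] = orig + h
                lp = total()
                p[ix] = orig - h
                lm = total()
                p[ix] = orig
                fd = (lp - lm) / (2 * h)
                if abs(fd) + abs(g[ix]) < 1e-10:
                    continue
                assert abs(fd - g[ix]) / max(abs(fd), abs(g[ix])) < 1e-4
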