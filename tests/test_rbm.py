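"""Sparse-RBM building block: energy, conditionals, contrastive divergence.

The exact-inference oracle enumerates all visible/hidden configurations of
a small binary RBM (<= 6 visible, <= 4 hidden units) to get the partition
function, the exact log-likelihood and its analytic gradient, which are
then checked against finite differences and against the statistics the CD
code computes.
"""

import itertools

import numpy as np
import pytest

from eegfatigue import (
    RBMParams,
    TrainConfig,
    cd_step,
    energy,
    hidden_conditional,
    train_sparse_rbm,
    visible_conditional,
)
from eegfatigue.rbm import reconstruction_mse, sigmoid


# ---------------------------------------------------------------------------
# brute-force oracle (independent of the training code)

def all_states(n):
    return np.array(list(itertools.product([0.0, 1.0], repeat=n)))


def partition_function(params):
    vs, hs = all_states(params.n_visible), all_states(params.n_hidden)
    return sum(np.exp(-energy(v, h, params)) for v in vs for h in hs)


def exact_log_likelihood(data, params):
    """Mean log p(v) over rows of data, by full enumeration."""
    hs = all_states(params.n_hidden)
    logZ = np.log(partition_function(params))
    ll = 0.0
    for v in data:
        ll += np.log(sum(np.exp(-energy(v, h, params)) for h in hs)) - logZ
    return ll / len(data)


def exact_gradient_W(data, params):
    """d mean-log-likelihood / dW via exact expectations."""
    vs, hs = all_states(params.n_visible), all_states(params.n_hidden)
    # data term: <v_i p(h_j|v)>
    pos = np.zeros_like(params.W)
    for v in data:
        pos += np.outer(hidden_conditional(v, params), v)
    pos /= len(data)
    # model term: exact <v_i h_j>
    Z = partition_function(params)
    neg = np.zeros_like(params.W)
    for v in vs:
        for h in hs:
            neg += np.exp(-energy(v, h, params)) / Z * np.outer(h, v)
    return pos - neg


def tiny_params(n_vis=3, n_hid=2, seed=0, scale=0.5):
    rng = np.random.default_rng(seed)
    return RBMParams(
        W=scale * rng.standard_normal((n_hid, n_vis)),
        a=scale * rng.standard_normal(n_vis),
        b=scale * rng.standard_normal(n_hid),
    )


# ---------------------------------------------------------------------------
# energy and conditionals

class TestEnergy:
    def test_zero_configuration_zero_energy(self):
        assert energy(np.zeros(3), np.zeros(2), tiny_params()) == 0.0

    def test_hand_evaluated_case(self):
        # E = -(w11*v1*h1) - a1*v1 = -(0.5*1*1) - 0.1 = -0.6; with h=1, b=-0.3: +0.3
        p = RBMParams(W=np.array([[0.5, -0.2]]), a=np.array([0.1, 0.0]), b=np.array([-0.3]))
        val = energy(np.array([1.0, 0.0]), np.array([1.0]), p)
        assert val == pytest.approx(-(0.5) - 0.1 - (-0.3))
        assert val == pytest.approx(-0.3)

    def test_linear_in_parameters(self):
        p = tiny_params(seed=2)
        v = np.array([1.0, 0.0, 1.0])
        h = np.array([0.0, 1.0])
        doubled = RBMParams(2 * p.W, 2 * p.a, 2 * p.b)
        assert energy(v, h, doubled) == pytest.approx(2 * energy(v, h, p))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            energy(np.zeros(4), np.zeros(2), tiny_params())


class TestConditionals:
    def test_zero_params_give_half(self):
        p = RBMParams(np.zeros((2, 3)), np.zeros(3), np.zeros(2))
        np.testing.assert_array_equal(hidden_conditional(np.ones(3), p), [0.5, 0.5])
        np.testing.assert_array_equal(visible_conditional(np.ones(2), p), [0.5, 0.5, 0.5])

    def test_sigmoid_saturation(self):
        p = RBMParams(np.zeros((1, 1)), np.zeros(1), np.array([50.0]))
        assert hidden_conditional(np.zeros(1), p)[0] == pytest.approx(1.0)

    def test_hand_case_sigma_of_two(self):
        p = RBMParams(W=np.array([[1.0, 1.0]]), a=np.zeros(2), b=np.zeros(1))
        assert hidden_conditional(np.ones(2), p)[0] == pytest.approx(0.8808, abs=1e-4)

    def test_probabilities_strictly_inside_unit_interval(self):
        p = tiny_params(seed=5, scale=2.0)
        hv = hidden_conditional(np.array([1.0, 0.0, 1.0]), p)
        vv = visible_conditional(np.array([1.0, 0.0]), p)
        assert np.all((hv > 0) & (hv < 1)) and np.all((vv > 0) & (vv < 1))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            hidden_conditional(np.zeros(5), tiny_params())
        with pytest.raises(ValueError):
            visible_conditional(np.zeros(5), tiny_params())


# ---------------------------------------------------------------------------
# exact-inference invariants

def test_boltzmann_distribution_normalizes():
    """Sum over all (v, h) of exp(-E)/Z equals 1 for an enumerable RBM."""
    p = tiny_params(n_vis=4, n_hid=3, seed=7)
    Z = partition_function(p)
    total = sum(
        np.exp(-energy(v, h, p)) / Z
        for v in all_states(4) for h in all_states(3)
    )
    assert total == pytest.approx(1.0, abs=1e-9)


def test_analytic_gradient_matches_finite_difference():
    """Exact log-likelihood gradient vs central finite differences, 1e-5."""
    rng = np.random.default_rng(11)
    p = tiny_params(n_vis=5, n_hid=3, seed=11)
    data = (rng.random((6, 5)) < 0.5).astype(float)
    grad = exact_gradient_W(data, p)
    eps = 1e-5
    for j, i in [(0, 0), (1, 2), (2, 4)]:
        pp, pm = tiny_params(5, 3, 11), tiny_params(5, 3, 11)
        pp.W[j, i] += eps
        pm.W[j, i] -= eps
        fd = (exact_log_likelihood(data, pp) - exact_log_likelihood(data, pm)) / (2 * eps)
        assert grad[j, i] == pytest.approx(fd, abs=1e-5)


def test_positive_phase_matches_hidden_enumeration():
    """<v_i h_j>_data equals enumeration over all hidden configurations."""
    p = tiny_params(n_vis=3, n_hid=2, seed=3)
    v = np.array([1.0, 0.0, 1.0])
    hp = hidden_conditional(v, p)
    expected = np.zeros((2, 3))
    for h in all_states(2):
        w = np.prod(hp**h * (1 - hp) ** (1 - h))  # p(h | v)
        expected += w * np.outer(h, v)
    np.testing.assert_allclose(expected, np.outer(hp, v), atol=1e-12)


# ---------------------------------------------------------------------------
# contrastive divergence updates

class TestCDStep:
    def test_zero_learning_rate_leaves_params(self, toy_binary_data):
        p = tiny_params(n_vis=12, n_hid=4, seed=1)
        cfg = TrainConfig(eta=1e-300, seed=1)  # eta must be > 0; effectively zero
        new, _, _ = cd_step(toy_binary_data[:10], p, cfg, np.random.default_rng(0))
        np.testing.assert_allclose(new.W, p.W, atol=1e-290)

    def test_lambda_zero_equals_plain_cd(self, toy_binary_data):
        p = tiny_params(n_vis=12, n_hid=4, seed=1)
        out = []
        for lam in (0.0, 0.0):
            cfg = TrainConfig(lambda_=lam, seed=3)
            new, _, _ = cd_step(toy_binary_data[:20], p.copy(), cfg,
                                np.random.default_rng(3))
            out.append(new)
        np.testing.assert_array_equal(out[0].W, out[1].W)
        # and a sparse step differs
        cfg = TrainConfig(lambda_=5.0, seed=3)
        sparse, _, _ = cd_step(toy_binary_data[:20], p.copy(), cfg,
                               np.random.default_rng(3))
        assert not np.allclose(sparse.b, out[0].b)

    def test_rejects_unscaled_batch(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            cd_step(np.array([[2.0, -1.0]]), tiny_params(2, 2),
                    TrainConfig(), np.random.default_rng(0))


class TestTrainSparseRBM:
    def test_deterministic_under_seed(self, toy_binary_data):
        runs = [train_sparse_rbm(toy_binary_data, 4, TrainConfig(seed=5, max_epoch=5))
                for _ in range(2)]
        np.testing.assert_array_equal(runs[0][0].W, runs[1][0].W)

    def test_reconstruction_mse_improves(self, toy_binary_data):
        cfg = TrainConfig(seed=2, max_epoch=30, eta=0.05, lambda_=0.0)
        params, trace = train_sparse_rbm(toy_binary_data, 6, cfg)
        assert trace.epoch_mse_train[-1] < trace.epoch_mse_train[0]

    def test_sparsity_monotone_in_lambda(self, toy_binary_data):
        """|mean hidden activation - p| non-increasing over lambda {0, 1, 5}."""
        p_target = 0.02
        gaps = []
        for lam in (0.0, 1.0, 5.0):
            cfg = TrainConfig(seed=4, max_epoch=40, lambda_=lam, p_target=p_target)
            params, _ = train_sparse_rbm(toy_binary_data, 6, cfg)
            q = hidden_conditional(toy_binary_data, params).mean()
            gaps.append(abs(q - p_target))
        assert gaps[0] >= gaps[1] >= gaps[2]

    def test_rejects_empty_or_unscaled(self):
        with pytest.raises(ValueError, match="empty"):
            train_sparse_rbm(np.empty((0, 3)), 2, TrainConfig())
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            train_sparse_rbm(np.array([[1.5, 0.2]]), 2, TrainConfig())


def test_sigmoid_matches_closed_form():
    z = np.linspace(-20, 20, 41)
    np.testing.assert_allclose(sigmoid(z), 1 / (1 + np.exp(-z)), atol=1e-12)


def test_reconstruction_mse_zero_for_perfect_autoencoder():
    # strongly saturated single-unit RBM copies a constant-1 visible
    p = RBMParams(W=np.array([[100.0]]), a=np.array([-50.0]), b=np.array([-50.0]))
    assert reconstruction_mse(np.ones((3, 1)), p) < 1e-8
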