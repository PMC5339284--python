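"""Shared feed-forward network machinery: sigmoid layers, MSE backprop,
validation-based early stopping.  Used by both the DBN fine-tuning stage
and the plain ANN baseline."""

from __future__ import annotations

import copy
from typing import Optional

import numpy as np

from .containers import TrainTrace
from .rbm import sigmoid

# a network is a list of (W, b) with W shaped (n_out, n_in)
Net = list[tuple[np.ndarray, np.ndarray]]


def forward(X: np.ndarray, net: Net) -> list[np.ndarray]:
    """Activations per layer (input first, output last); sigmoid throughout."""
    acts = [np.atleast_2d(np.asarray(X, dtype=float))]
    for W, b in net:
        acts.append(sigmoid(acts[-1] @ W.T + b))
    return acts


def predict_proba(X: np.ndarray, net: Net) -> np.ndarray:
    return forward(X, net)[-1]


def mse(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean over samples and output units of squared error."""
    return float(((pred - target) ** 2).mean())


def backprop_gradients(X: np.ndarray, T: np.ndarray, net: Net) -> list[tuple[np.ndarray, np.ndarray]]:
    """Gradients of the squared-error loss w.r.t. every (W, b)."""
    acts = forward(X, net)
    m = T.shape[0]
    out = acts[-1]
    # classic SE backprop: loss 0.5 * sum over units, mean over samples
    # (reported MSE stays mean-over-elements; scaling differs by a constant)
    delta = (out - T) * out * (1.0 - out) / m
    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(net)  # type: ignore
    for layer in range(len(net) - 1, -1, -1):
        a_prev = acts[layer]
        grads[layer] = (delta.T @ a_prev, delta.sum(axis=0))
        if layer > 0:
            W, _ = net[layer]
            delta = (delta @ W) * a_prev * (1.0 - a_prev)
    return grads


def init_net(sizes: list[int], rng: np.random.Generator, init_sd: float = 0.01) -> Net:
    """Zero biases, small Gaussian weights, layer sizes input->output."""
    return [
        (init_sd * rng.standard_normal((sizes[i + 1], sizes[i])), np.zeros(sizes[i + 1]))
        for i in range(len(sizes) - 1)
    ]


def train_early_stopping(
    net: Net,
    X_train: np.ndarray,
    T_train: np.ndarray,
    X_valid: np.ndarray,
    T_valid: np.ndarray,
    eta: float,
    max_epoch: int,
    max_fail: int,
    batch_size: int,
    rng: np.random.Generator,
    momentum: float = 0.0,
) -> tuple[Net, TrainTrace]:
    """Mini-batch gradient descent with validation-MSE early stopping.

    Stops when validation MSE fails to improve for ``max_fail`` consecutive
    epochs and restores the parameters of the best epoch.  The trace
    records full-set train/validation MSE per epoch; ``best_epoch`` indexes
    the minimum of the validation curve.
    """
    n = X_train.shape[0]
    trace = TrainTrace()
    best_net = copy.deepcopy(net)
    best_mse = np.inf
    fails = 0
    velocity = [(np.zeros_like(W), np.zeros_like(b)) for W, b in net]
    for epoch in range(max_epoch):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            grads = backprop_gradients(X_train[idx], T_train[idx], net)
            new_net: Net = []
            new_vel = []
            for (W, b), (gW, gb), (vW, vb) in zip(net, grads, velocity):
                vW = momentum * vW - eta * gW
                vb = momentum * vb - eta * gb
                new_net.append((W + vW, b + vb))
                new_vel.append((vW, vb))
            net, velocity = new_net, new_vel
        trace.epoch_mse_train.append(mse(predict_proba(X_train, net), T_train))
        vm = mse(predict_proba(X_valid, net), T_valid)
        trace.epoch_mse_valid.append(vm)
        if vm < best_mse:
            best_mse = vm
            best_net = copy.deepcopy(net)
            trace.best_epoch = epoch
            fails = 0
        else:
            fails += 1
            if fails >= max_fail:
                trace.stop_reason = "early_stop"
                return best_net, trace
    trace.stop_reason = "max_epoch"
    return best_net, trace


def one_hot(y: np.ndarray, n_classes: int = 2) -> np.ndarray:
    T = np.zeros((len(y), n_classes))
    T[np.arange(len(y)), np.asarray(y, dtype=int)] = 1.0
    return T
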