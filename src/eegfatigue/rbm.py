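"""Sparse restricted Boltzmann machine: energy model, conditionals, CD-k.

The RBM is a bipartite energy-based model over binary visible units v and
hidden units h,

    E(v, h) = - sum_ij w_ij v_i h_j - sum_i a_i v_i - sum_j b_j h_j,

trained by contrastive divergence,

    dw_ij = eta * (<v_i h_j>_data - <v_i h_j>_recon),

with a sparsity penalty lambda * sum_j (p - q_j)^2 pulling the mean hidden
activation q_j = mean_l E[h_j | v^(l)] toward a small target p.  Visible
units are treated as Bernoulli with features min-max scaled to [0, 1] used
as activation probabilities (mean-field); hidden states are sampled only on
the positive-to-negative transition of the CD chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .containers import TrainTrace


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically safe logistic function."""
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(z, dtype=float)))


@dataclass
class RBMParams:
    """Weights and biases of one RBM.

    ``W`` is n_hidden x n_visible (``W[j, i]`` couples hidden j with
    visible i); ``a`` are visible biases, ``b`` hidden biases.
    """

    W: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.W.ndim != 2:
            raise ValueError("W must be 2-D (n_hidden x n_visible)")
        if self.a.shape != (self.W.shape[1],):
            raise ValueError(
                f"visible bias length {self.a.shape} inconsistent with W {self.W.shape}"
            )
        if self.b.shape != (self.W.shape[0],):
            raise ValueError(
                f"hidden bias length {self.b.shape} inconsistent with W {self.W.shape}"
            )
        if not (
            np.all(np.isfinite(self.W))
            and np.all(np.isfinite(self.a))
            and np.all(np.isfinite(self.b))
        ):
            raise ValueError("RBM parameters must be finite")

    @property
    def n_visible(self) -> int:
        return self.W.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[0]

    def copy(self) -> "RBMParams":
        return RBMParams(self.W.copy(), self.a.copy(), self.b.copy())


@dataclass
class TrainConfig:
    """Training hyperparameters shared by RBM pre-training and fine-tuning.

    Defaults follow the fatigue-classification protocol: CD learning rate
    eta = 0.01, sparsity regularization lambda_ = 1, sparseness target
    p_target = 0.02, at most 200 epochs, early-stopping patience
    (max_fail) of 10 validation epochs without improvement.

    ``finetune_eta`` is the step size of the backprop fine-tuning stage.
    It is deliberately separate from ``eta``: the protocol prints 0.01 for
    the RBM training, while its fine-tuning traces converge far too fast
    for a step that small under plain gradient descent (an adaptive
    optimizer was evidently used); the default matches the ANN baseline,
    which runs the identical backprop stage.  ``finetune_momentum`` (0.9,
    the classic choice for backprop over pre-trained stacks) applies only
    to that stage; ``momentum`` governs the CD updates and stays 0.
    """

    eta: float = 0.01
    finetune_eta: float = 1.0
    finetune_momentum: float = 0.9
    lambda_: float = 1.0
    p_target: float = 0.02
    max_epoch: int = 200
    max_fail: int = 10
    batch_size: int = 100
    cd_k: int = 1
    seed: int = 0
    momentum: float = 0.0
    weight_decay: float = 0.0
    init_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError(f"eta must be positive, got {self.eta}")
        if not 0 < self.p_target < 1:
            raise ValueError(f"p_target must be in (0, 1), got {self.p_target}")
        if self.lambda_ < 0:
            raise ValueError(f"lambda_ must be >= 0, got {self.lambda_}")
        if self.max_epoch < 1 or self.max_fail < 1:
            raise ValueError("max_epoch and max_fail must be >= 1")
        if self.batch_size < 1 or self.cd_k < 1:
            raise ValueError("batch_size and cd_k must be >= 1")


def energy(v: np.ndarray, h: np.ndarray, params: RBMParams) -> float:
    """Joint energy E(v, h) of one visible/hidden configuration."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if v.shape != (params.n_visible,) or h.shape != (params.n_hidden,):
        raise ValueError(
            f"dimension mismatch: v{v.shape}, h{h.shape} vs W {params.W.shape}"
        )
    return float(-(h @ params.W @ v) - params.a @ v - params.b @ h)


def hidden_conditional(v: np.ndarray, params: RBMParams) -> np.ndarray:
    """p(h_j = 1 | v) = sigma(b_j + sum_i v_i w_ij); accepts a batch."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != params.n_visible:
        raise ValueError(f"visible size {v.shape[-1]} != {params.n_visible}")
    return sigmoid(v @ params.W.T + params.b)


def visible_conditional(h: np.ndarray, params: RBMParams) -> np.ndarray:
    """p(v_i = 1 | h) = sigma(a_i + sum_j h_j w_ij); accepts a batch."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != params.n_hidden:
        raise ValueError(f"hidden size {h.shape[-1]} != {params.n_hidden}")
    return sigmoid(h @ params.W + params.a)


def cd_step(
    batch: np.ndarray,
    params: RBMParams,
    cfg: TrainConfig,
    rng: np.random.Generator,
    velocity: Optional[dict[str, np.ndarray]] = None,
) -> tuple[RBMParams, dict[str, float], dict[str, np.ndarray]]:
    """One CD-k parameter update on a mini-batch.

    Positive phase uses hidden probabilities given the data; the hidden
    *states* are sampled once, then the negative phase reconstructs the
    visibles mean-field and recomputes hidden probabilities (k times for
    CD-k).  The sparsity penalty lambda * sum_j (p - q_j)^2 contributes its
    exact gradient to the hidden biases and weights.

    Returns updated parameters, batch statistics (mean hidden activation
    and reconstruction MSE), and the updated momentum velocity.
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.min() < 0 or batch.max() > 1:
        raise ValueError("visible batch must be scaled to [0, 1]")
    m = batch.shape[0]

    h_prob = hidden_conditional(batch, params)  # (m, H)
    h_state = (rng.random(h_prob.shape) < h_prob).astype(float)
    v_neg = batch
    h_neg = h_state
    for k in range(cfg.cd_k):
        v_neg = visible_conditional(h_neg, params)  # mean-field visibles
        h_neg_prob = hidden_conditional(v_neg, params)
        if k < cfg.cd_k - 1:
            h_neg = (rng.random(h_neg_prob.shape) < h_neg_prob).astype(float)
    # CD gradient, averaged over the batch
    dW = (h_prob.T @ batch - h_neg_prob.T @ v_neg) / m
    da = (batch - v_neg).mean(axis=0)
    db = (h_prob - h_neg_prob).mean(axis=0)

    # sparsity penalty L = lambda * sum_j (p - q_j)^2, q_j = mean_l h_prob[l, j]
    if cfg.lambda_ > 0:
        q = h_prob.mean(axis=0)
        dsig = h_prob * (1.0 - h_prob)  # sigma'(z) at the data
        coef = 2.0 * cfg.lambda_ * (cfg.p_target - q)  # -dL/dq_j
        db += coef * dsig.mean(axis=0)
        dW += (coef[:, None] * (dsig.T @ batch)) / m
    if cfg.weight_decay > 0:
        dW -= cfg.weight_decay * params.W

    if velocity is None:
        velocity = {"W": np.zeros_like(params.W), "a": np.zeros_like(params.a),
                    "b": np.zeros_like(params.b)}
    velocity["W"] = cfg.momentum * velocity["W"] + cfg.eta * dW
    velocity["a"] = cfg.momentum * velocity["a"] + cfg.eta * da
    velocity["b"] = cfg.momentum * velocity["b"] + cfg.eta * db

    new = RBMParams(params.W + velocity["W"], params.a + velocity["a"],
                    params.b + velocity["b"])
    if not (np.all(np.isfinite(new.W)) and np.all(np.isfinite(new.a))
            and np.all(np.isfinite(new.b))):
        raise FloatingPointError("non-finite RBM update (diverging learning rate?)")
    stats = {
        "mean_hidden_activation": float(h_prob.mean()),
        "recon_mse": float(((batch - v_neg) ** 2).mean()),
    }
    return new, stats, velocity


def reconstruction_mse(data: np.ndarray, params: RBMParams) -> float:
    """Mean squared one-step mean-field reconstruction error."""
    h = hidden_conditional(data, params)
    v = visible_conditional(h, params)
    return float(((np.atleast_2d(data) - v) ** 2).mean())


def init_rbm(n_visible: int, n_hidden: int, cfg: TrainConfig,
             rng: np.random.Generator) -> RBMParams:
    """Zero biases, small Gaussian weights."""
    return RBMParams(
        W=cfg.init_sd * rng.standard_normal((n_hidden, n_visible)),
        a=np.zeros(n_visible),
        b=np.zeros(n_hidden),
    )


def train_sparse_rbm(
    data: np.ndarray,
    n_hidden: int,
    cfg: TrainConfig,
    rng: Optional[np.random.Generator] = None,
    params: Optional[RBMParams] = None,
) -> tuple[RBMParams, TrainTrace]:
    """Mini-batch CD training of one sparse RBM for ``cfg.max_epoch`` epochs.

    Generative pre-training runs for the full epoch budget (no early
    stopping); the per-epoch mean-field reconstruction MSE on the training
    data is recorded in the trace.  Deterministic under ``cfg.seed``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.size == 0:
        raise ValueError("empty training data")
    if data.min() < 0 or data.max() > 1:
        raise ValueError("training data must be scaled to [0, 1]")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if params is None:
        params = init_rbm(data.shape[1], n_hidden, cfg, rng)
    velocity = None
    trace = TrainTrace()
    n = data.shape[0]
    for epoch in range(cfg.max_epoch):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = data[order[start : start + cfg.batch_size]]
            try:
                params, _, velocity = cd_step(batch, params, cfg, rng, velocity)
            except FloatingPointError as exc:
                raise FloatingPointError(
                    f"epoch {epoch}, batch at row {start}: {exc}"
                ) from exc
        trace.epoch_mse_train.append(reconstruction_mse(data, params))
    trace.best_epoch = int(np.argmin(trace.epoch_mse_train))
    trace.stop_reason = "max_epoch"
    return params, trace
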