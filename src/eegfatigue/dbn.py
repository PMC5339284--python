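"""Two-layer sparse deep belief network for binary EEG-state classification.

Training proceeds in three stages:

1. **Generative layer** — a sparse RBM is trained unsupervised on the
   (min-max scaled) training features for the full epoch budget.
2. **Discriminative layer** — a second sparse RBM whose visible layer is
   the first layer's hidden activations concatenated with the one-hot
   class labels (a classification RBM).
3. **Fine-tuning** — the stack is unrolled into a feed-forward sigmoid
   network ``[n_in -> h1 -> h2 -> 2]`` initialized from the RBM weights
   (the label block of the discriminative RBM initializes the output
   head), then trained by backpropagation on one-hot targets with MSE loss
   and validation-based early stopping (patience ``max_fail``, best epoch
   restored).

Setting ``lambda_ = 0`` in the training config recovers a plain
(non-sparse) DBN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _mlp
from .containers import CLASSES, FeatureMatrix, MinMaxScaling, TrainTrace
from .rbm import (
    RBMParams,
    TrainConfig,
    hidden_conditional,
    train_sparse_rbm,
)

N_CLASSES = 2


@dataclass
class DBNModel:
    """A trained (sparse-)DBN: pre-trained RBM stack + fine-tuned network."""

    layers: list[RBMParams]
    net: _mlp.Net  # feed-forward weights incl. 2-unit output head
    architecture: list[int]
    train_trace: TrainTrace
    pretrain_traces: list[TrainTrace] = field(default_factory=list)
    scaling: Optional[MinMaxScaling] = None
    config: Optional[TrainConfig] = None
    classes: tuple[str, str] = CLASSES

    @property
    def n_features(self) -> int:
        return self.architecture[0]


def _check_arch(arch: Sequence[int], n_features: int) -> list[int]:
    arch = [int(a) for a in arch]
    if len(arch) < 3:
        raise ValueError(f"architecture needs at least [n_in, hidden, 2], got {arch}")
    if arch[0] != n_features:
        raise ValueError(f"architecture input size {arch[0]} != n_features {n_features}")
    if arch[-1] != N_CLASSES:
        raise ValueError(f"architecture must end with {N_CLASSES} output units, got {arch[-1]}")
    if any(a < 1 for a in arch):
        raise ValueError(f"layer sizes must be positive, got {arch}")
    return arch


def train_dbn(
    train: FeatureMatrix,
    valid: FeatureMatrix,
    arch: Sequence[int],
    cfg: TrainConfig = TrainConfig(),
) -> DBNModel:
    """Pre-train and fine-tune a sparse-DBN; see module docstring.

    ``train`` and ``valid`` must be min-max scaled to [0, 1] (e.g. via
    :func:`eegfatigue.features.scale_minmax01`).  Deterministic under
    ``cfg.seed``.
    """
    arch = _check_arch(arch, train.n_features)
    for name, fm in (("train", train), ("valid", valid)):
        if fm.X.size and (fm.X.min() < 0 or fm.X.max() > 1):
            raise ValueError(f"{name} features must be scaled to [0, 1]")
    rng = np.random.default_rng(cfg.seed)

    layers: list[RBMParams] = []
    traces: list[TrainTrace] = []
    rep = train.X
    # generative hidden layers (all but the last hidden layer)
    for size in arch[1:-2]:
        params, tr = train_sparse_rbm(rep, size, cfg, rng=rng)
        layers.append(params)
        traces.append(tr)
        rep = hidden_conditional(rep, params)

    # discriminative top layer: visibles = representation (+) one-hot labels
    T = _mlp.one_hot(train.y, N_CLASSES)
    vis2 = np.hstack([rep, T])
    top, tr2 = train_sparse_rbm(vis2, arch[-2], cfg, rng=rng)
    layers.append(top)
    traces.append(tr2)

    # unroll: hidden path keeps the feature block; the label block becomes
    # the output head (transposed), label visible biases become its bias
    n_rep = rep.shape[1]
    net: _mlp.Net = [(p.W.copy(), p.b.copy()) for p in layers[:-1]]
    net.append((top.W[:, :n_rep].copy(), top.b.copy()))
    net.append((top.W[:, n_rep:].T.copy(), top.a[n_rep:].copy()))

    net, trace = _mlp.train_early_stopping(
        net,
        train.X,
        T,
        valid.X,
        _mlp.one_hot(valid.y, N_CLASSES),
        eta=cfg.finetune_eta,
        max_epoch=cfg.max_epoch,
        max_fail=cfg.max_fail,
        batch_size=cfg.batch_size,
        rng=rng,
        momentum=cfg.finetune_momentum,
    )
    return DBNModel(
        layers=layers,
        net=net,
        architecture=list(arch),
        train_trace=trace,
        pretrain_traces=traces,
        scaling=train.scaling,
        config=cfg,
    )


def predict(model: DBNModel, X: np.ndarray | FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Feed-forward class scores and hard labels.

    Returns ``(scores, labels)`` where ``scores`` is the fatigue-class
    activation normalized over the two output units (in [0, 1]; thresholding
    at 0.5 is exactly the argmax rule) and ``labels`` the argmax class
    code; an exact tie breaks toward alert (code 0), so a degenerate model
    never raises a fatigue alarm.
    """
    Xa = X.X if isinstance(X, FeatureMatrix) else np.atleast_2d(np.asarray(X, dtype=float))
    if Xa.shape[1] != model.n_features:
        raise ValueError(f"input has {Xa.shape[1]} features, model expects {model.n_features}")
    out = _mlp.predict_proba(Xa, model.net)  # (n, 2): columns [alert, fatigue]
    return _normalized_scores(out)


def _normalized_scores(out: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    total = out.sum(axis=1)
    scores = np.where(total > 0, out[:, 1] / np.where(total > 0, total, 1.0), 0.5)
    labels = (out[:, 1] > out[:, 0]).astype(int)
    return scores, labels


def grid_search_sparsity(
    train: FeatureMatrix,
    valid: FeatureMatrix,
    arch: Sequence[int],
    lambdas: Sequence[float],
    ps: Sequence[float],
    cfg: TrainConfig = TrainConfig(),
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Train one DBN per (lambda, p) pair at a fixed seed.

    Returns a table with columns (lambda, p, best train MSE, best valid
    MSE, best iteration) and the (lambda, p) pair minimizing validation
    MSE.  A failing cell is recorded with NaN errors and the run continues.
    """
    if not len(lambdas) or not len(ps):
        raise ValueError("lambda and p grids must be non-empty")
    rows = []
    for lam in lambdas:
        for p in ps:
            cell = TrainConfig(**{**cfg.__dict__, "lambda_": float(lam), "p_target": float(p)})
            try:
                model = train_dbn(train, valid, arch, cell)
                tr = model.train_trace
                rows.append(
                    {
                        "lambda": lam,
                        "p": p,
                        "mse_train": tr.best_train_mse,
                        "mse_valid": tr.best_valid_mse,
                        "best_iteration": tr.best_epoch + 1,
                        "error": "",
                    }
                )
            except Exception as exc:  # noqa: BLE001 — record and continue
                rows.append(
                    {
                        "lambda": lam,
                        "p": p,
                        "mse_train": np.nan,
                        "mse_valid": np.nan,
                        "best_iteration": -1,
                        "error": str(exc),
                    }
                )
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["mse_valid"])
    if ok.empty:
        raise RuntimeError("every grid cell failed")
    winner = ok.loc[ok["mse_valid"].idxmin()]
    return table, (float(winner["lambda"]), float(winner["p"]))
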