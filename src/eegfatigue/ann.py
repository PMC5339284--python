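"""Plain feed-forward ANN baseline (single sigmoid hidden layer, MSE loss,
backprop with the same validation-based early stopping as the DBN
fine-tuning stage)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _mlp
from .containers import CLASSES, FeatureMatrix, MinMaxScaling, TrainTrace
from .dbn import _normalized_scores

N_CLASSES = 2


@dataclass
class ANNConfig:
    """Baseline network hyperparameters.

    Hidden size defaults to 15 to mirror the DBN's discriminative path on
    AR features; the reference protocol never prints an ANN layer size or
    learning rate.  The MSE loss is averaged over samples and output
    units, so its raw gradients are small; a unit learning rate with a
    moderately wide weight init is the practical default for a network
    trained from scratch (the DBN fine-tuning stage starts from
    pre-trained weights and can afford a much smaller step).
    """

    n_hidden: int = 15
    eta: float = 1.0
    max_epoch: int = 200
    max_fail: int = 10
    batch_size: int = 100
    seed: int = 0
    momentum: float = 0.9
    init_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError(f"n_hidden must be >= 1, got {self.n_hidden}")
        if self.eta <= 0:
            raise ValueError(f"eta must be positive, got {self.eta}")
        if self.max_epoch < 1 or self.max_fail < 1:
            raise ValueError("max_epoch and max_fail must be >= 1")


@dataclass
class ANNModel:
    net: _mlp.Net
    architecture: list[int]
    train_trace: TrainTrace
    scaling: Optional[MinMaxScaling] = None
    config: Optional[ANNConfig] = None
    classes: tuple[str, str] = CLASSES

    @property
    def n_features(self) -> int:
        return self.architecture[0]


def train_ann(
    train: FeatureMatrix, valid: FeatureMatrix, cfg: ANNConfig = ANNConfig()
) -> ANNModel:
    """Train the baseline network; deterministic under ``cfg.seed``."""
    if train.n_samples == 0:
        raise ValueError("empty training data")
    rng = np.random.default_rng(cfg.seed)
    sizes = [train.n_features, cfg.n_hidden, N_CLASSES]
    net = _mlp.init_net(sizes, rng, cfg.init_sd)
    net, trace = _mlp.train_early_stopping(
        net,
        train.X,
        _mlp.one_hot(train.y, N_CLASSES),
        valid.X,
        _mlp.one_hot(valid.y, N_CLASSES),
        eta=cfg.eta,
        max_epoch=cfg.max_epoch,
        max_fail=cfg.max_fail,
        batch_size=cfg.batch_size,
        rng=rng,
        momentum=cfg.momentum,
    )
    return ANNModel(net=net, architecture=sizes, train_trace=trace,
                    scaling=train.scaling, config=cfg)


def predict_ann(model: ANNModel, X: np.ndarray | FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Fatigue-class scores and hard labels; exact ties break toward alert.

    Scores share the sparse-DBN contract: fatigue activation normalized
    over the two output units, so 0.5 is the decision threshold.
    """
    Xa = X.X if isinstance(X, FeatureMatrix) else np.atleast_2d(np.asarray(X, dtype=float))
    if Xa.shape[1] != model.n_features:
        raise ValueError(f"input has {Xa.shape[1]} features, model expects {model.n_features}")
    out = _mlp.predict_proba(Xa, model.net)
    return _normalized_scores(out)
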