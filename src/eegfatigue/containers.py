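"""Core data containers shared across the pipeline.

Class labels are encoded as small integers throughout: 0 = alert
(negative class), 1 = fatigue (positive class).  ``CLASSES`` fixes the
string names; ``label_code`` / ``label_name`` convert between the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: class names in label-code order (index == integer code)
CLASSES: tuple[str, str] = ("alert", "fatigue")

ALERT, FATIGUE = 0, 1

#: code used for recordings whose state is not known
UNKNOWN = -1


def label_code(name: str) -> int:
    """Map a class name ('alert'/'fatigue'/'unknown') to its integer code."""
    if name == "unknown":
        return UNKNOWN
    try:
        return CLASSES.index(name)
    except ValueError:
        raise ValueError(
            f"invalid class label {name!r}; expected one of {CLASSES + ('unknown',)}"
        ) from None


def label_name(code: int) -> str:
    if code == UNKNOWN:
        return "unknown"
    return CLASSES[code]


@dataclass
class EEGRecording:
    """A multichannel EEG recording: channels x samples, plus metadata.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal amplitudes (microvolt-like units, arbitrary scale).
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        One name per row of ``data``.
    subject_id : int or str
        Identifier of the participant the recording belongs to.
    state : str
        'alert', 'fatigue' or 'unknown'.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    subject_id: object = 0
    state: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got ndim={self.data.ndim}")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got fs={self.fs}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )
        label_code(self.state)  # validates

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        """Record length in seconds."""
        return self.data.shape[1] / self.fs


@dataclass
class SegmentSet:
    """Windows cut from one or more recordings, all of identical shape.

    Attributes
    ----------
    data : ndarray, shape (n_segments, n_channels, window_samples)
    labels : ndarray of int, shape (n_segments,)
        Class code per segment (0 alert, 1 fatigue, -1 unknown).
    provenance : list of (subject_id, state, window_index)
    fs : float
    channel_names : list of str
    """

    data: np.ndarray
    labels: np.ndarray
    provenance: list[tuple]
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("segment data must be 3-D (segments x channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal number of segments")
        if len(self.provenance) != self.data.shape[0]:
            raise ValueError("provenance length must equal number of segments")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def window_samples(self) -> int:
        return self.data.shape[2]


def concat_segment_sets(sets: Sequence[SegmentSet]) -> SegmentSet:
    """Stack several segment sets (same fs/shape) into one."""
    if not sets:
        raise ValueError("no segment sets to concatenate")
    fs = sets[0].fs
    names = sets[0].channel_names
    for s in sets[1:]:
        if s.fs != fs:
            raise ValueError("segment sets have differing sampling rates")
        if s.data.shape[1:] != sets[0].data.shape[1:]:
            raise ValueError("segment sets have differing window shapes")
    return SegmentSet(
        data=np.concatenate([s.data for s in sets], axis=0),
        labels=np.concatenate([s.labels for s in sets]),
        provenance=[p for s in sets for p in s.provenance],
        fs=fs,
        channel_names=names,
    )


@dataclass
class MinMaxScaling:
    """Per-feature min/max learned on a training set, mapping to [0, 1]."""

    mins: np.ndarray
    maxs: np.ndarray


@dataclass
class FeatureMatrix:
    """n_samples x n_features matrix with labels and feature names."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    scaling: Optional[MinMaxScaling] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != len(self.y):
            raise ValueError(f"{self.X.shape[0]} rows but {len(self.y)} labels")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {self.X.shape[1]} columns"
            )

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        """Row subset sharing feature names and scaling metadata."""
        return FeatureMatrix(self.X[idx], self.y[idx], list(self.feature_names), self.scaling)


@dataclass
class TrainTrace:
    """Per-epoch error trace of an iterative training run."""

    epoch_mse_train: list[float] = field(default_factory=list)
    epoch_mse_valid: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stop_reason: str = "max_epoch"  # or "early_stop"

    @property
    def best_valid_mse(self) -> float:
        return self.epoch_mse_valid[self.best_epoch]

    @property
    def best_train_mse(self) -> float:
        return self.epoch_mse_train[self.best_epoch]
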