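"""Feature extraction: autoregressive coefficients and PSD band powers.

Two extractors are provided, mirroring the two compared in the underlying
fatigue-classification method:

* **AR features** — per channel, the coefficients ``a(1..P)`` of an
  autoregressive model ``x(t) = sum_k a(k) x(t-k) + e(t)`` fitted to each
  2 s segment (Burg by default, Yule-Walker optional).  With order P and C
  channels this yields ``P * C`` features per segment (160 for P=5, C=32).

* **PSD band powers** — per channel, the periodogram of the demeaned,
  Hamming-windowed segment integrated with the trapezoidal rule over the
  four classical bands delta (0.5-3 Hz), theta (3.5-7.5 Hz), alpha
  (8-13 Hz) and beta (13.5-30 Hz): ``4 * C`` features (128 for C=32).

Coefficient sign convention: positive ``a(k)`` predict from past samples
(an AR(1) with a(1)=0.5 has positive lag-1 autocorrelation).  Both
statsmodels estimators already follow this convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import periodogram
from statsmodels.regression.linear_model import burg, yule_walker

from .containers import FeatureMatrix, MinMaxScaling, SegmentSet


@dataclass
class ARSpec:
    """Autoregressive model specification (order and estimator)."""

    order: int = 5
    estimator: str = "burg"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"AR order must be >= 1, got {self.order}")
        if self.estimator not in ("burg", "yule_walker"):
            raise ValueError(f"estimator must be 'burg' or 'yule_walker', got {self.estimator!r}")


@dataclass
class BandSpec:
    """Ordered, non-overlapping frequency bands in Hz."""

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "delta": (0.5, 3.0),
            "theta": (3.5, 7.5),
            "alpha": (8.0, 13.0),
            "beta": (13.5, 30.0),
        }
    )

    def __post_init__(self) -> None:
        prev_hi = -np.inf
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name!r} has lower {lo} >= upper {hi}")
            if lo < prev_hi:
                raise ValueError(f"band {name!r} overlaps or is out of order")
            prev_hi = hi

    @property
    def names(self) -> list[str]:
        return list(self.bands)


def fit_ar(x: np.ndarray, spec: ARSpec = ARSpec()) -> np.ndarray:
    """Fit an AR(P) model to a single-channel series; returns a(1..P).

    Raises ``ValueError`` for series that are too short or have zero
    variance (no autocorrelation structure to estimate).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("fit_ar expects a 1-D series")
    if len(x) <= spec.order:
        raise ValueError(f"series of length {len(x)} too short for AR order {spec.order}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance series: AR coefficients undefined")
    if spec.estimator == "burg":
        coeffs, _ = burg(x, order=spec.order, demean=True)
    else:
        coeffs, _ = yule_walker(x, order=spec.order, method="mle")
    return np.asarray(coeffs, dtype=float)


def extract_ar_features(segs: SegmentSet, spec: ARSpec = ARSpec()) -> FeatureMatrix:
    """AR coefficients per channel, concatenated channel-major.

    Output shape: ``n_segments x (order * n_channels)``.  A zero-variance
    channel within a segment contributes a zero block (with a warning)
    rather than failing the whole run.
    """
    if len(segs) == 0:
        raise ValueError("empty segment set")
    n, C, _ = segs.data.shape
    X = np.zeros((n, spec.order * C))
    for i in range(n):
        for c in range(C):
            series = segs.data[i, c]
            try:
                X[i, c * spec.order : (c + 1) * spec.order] = fit_ar(series, spec)
            except ValueError as exc:
                if "zero-variance" in str(exc):
                    warnings.warn(
                        f"segment {i} channel {c}: zero-variance signal, AR block set to 0",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                else:
                    raise ValueError(f"segment {i}, channel {c}: {exc}") from exc
    ch = segs.channel_names or [f"ch{c}" for c in range(C)]
    names = [f"{ch[c]}:ar{k}" for c in range(C) for k in range(1, spec.order + 1)]
    return FeatureMatrix(X, segs.labels.copy(), names)


def band_power_psd(
    x: np.ndarray, fs: float, bands: BandSpec = BandSpec()
) -> np.ndarray:
    """Total spectral power per band for one channel segment.

    The PSD is the periodogram of the demeaned, Hamming-windowed segment;
    band totals integrate the PSD over the frequency bins falling inside
    ``[lower, upper]`` with the trapezoidal rule.  Units: signal-units^2.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("band_power_psd expects a 1-D series of length >= 2")
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    f, p = periodogram(x, fs=fs, window="hamming", detrend="constant")
    out = np.empty(len(bands.bands))
    for k, (name, (lo, hi)) in enumerate(bands.bands.items()):
        mask = (f >= lo) & (f <= hi)
        if mask.sum() < 2:
            raise ValueError(
                f"band {name!r} ({lo}-{hi} Hz) contains fewer than two frequency bins "
                f"at resolution {f[1] - f[0]:g} Hz"
            )
        out[k] = np.trapezoid(p[mask], f[mask])
    return out


def extract_psd_features(segs: SegmentSet, bands: BandSpec = BandSpec()) -> FeatureMatrix:
    """Band powers per channel: ``n_segments x (n_bands * n_channels)``."""
    if len(segs) == 0:
        raise ValueError("empty segment set")
    n, C, _ = segs.data.shape
    nb = len(bands.bands)
    X = np.zeros((n, nb * C))
    for i in range(n):
        for c in range(C):
            X[i, c * nb : (c + 1) * nb] = band_power_psd(segs.data[i, c], segs.fs, bands)
    ch = segs.channel_names or [f"ch{c}" for c in range(C)]
    names = [f"{ch[c]}:{b}" for c in range(C) for b in bands.names]
    return FeatureMatrix(X, segs.labels.copy(), names)


def scale_minmax01(
    train: FeatureMatrix, others: list[FeatureMatrix] | None = None
) -> tuple[FeatureMatrix, list[FeatureMatrix]]:
    """Min-max scale to [0, 1] using the training set's per-feature range.

    Other matrices (validation, test) are mapped with the *training*
    min/max and clipped to [0, 1].  Constant training features map to 0.5
    everywhere.  Returns new matrices; inputs are not modified.
    """
    if train.n_samples == 0:
        raise ValueError("empty training feature matrix")
    mins = train.X.min(axis=0)
    maxs = train.X.max(axis=0)
    span = maxs - mins
    const = span == 0
    safe_span = np.where(const, 1.0, span)
    scaling = MinMaxScaling(mins=mins, maxs=maxs)

    def apply(fm: FeatureMatrix) -> FeatureMatrix:
        Z = (fm.X - mins) / safe_span
        Z = np.clip(Z, 0.0, 1.0)
        Z[:, const] = 0.5
        return FeatureMatrix(Z, fm.y.copy(), list(fm.feature_names), scaling)

    return apply(train), [apply(fm) for fm in (others or [])]


def apply_minmax01(fm: FeatureMatrix, scaling: MinMaxScaling) -> FeatureMatrix:
    """Apply a stored training scaling to a new feature matrix."""
    span = scaling.maxs - scaling.mins
    const = span == 0
    safe_span = np.where(const, 1.0, span)
    Z = np.clip((fm.X - scaling.mins) / safe_span, 0.0, 1.0)
    Z[:, const] = 0.5
    return FeatureMatrix(Z, fm.y.copy(), list(fm.feature_names), scaling)
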