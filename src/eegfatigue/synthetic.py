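"""Synthetic two-class (alert vs fatigue) multichannel EEG generator.

The study data this package targets — monotonous-driving EEG from healthy
adults — is not publicly available, so a generative stand-in is provided.
Each channel is a sum of band-limited oscillators (sinusoids with random
phase and small frequency jitter inside each classical EEG band) whose
relative amplitudes differ by class, plus class-specific AR(2)-coloured
noise, plus white measurement noise.  Fatigue-state channels carry elevated
theta/alpha power and suppressed beta, the direction reported throughout
the driver-fatigue EEG literature; alert channels the reverse.  The class
difference therefore shows up both in band-power spectra and in fitted
autoregressive coefficients, which is exactly what the downstream feature
extractors measure.

Determinism: one RNG stream per dataset, with subject-and-state substreams
derived from ``(seed, subject_id, state)``, so any single recording can be
regenerated without generating the rest of the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .containers import CLASSES, EEGRecording, label_code

#: classical EEG band edges in Hz (lower, upper)
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 3.0),
    "theta": (3.5, 7.5),
    "alpha": (8.0, 13.0),
    "beta": (13.5, 30.0),
}

#: BioSemi 32-channel montage used for default channel names
MONTAGE_32 = [
    "FP1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3",
    "CP1", "CP5", "P7", "P3", "PZ", "PO3", "O1", "OZ",
    "O2", "PO4", "P4", "P8", "CP6", "CP2", "C4", "T8",
    "FC6", "FC2", "F4", "F8", "AF4", "FP2", "FZ", "CZ",
]

#: oscillators summed per band per channel
_N_OSC = 3


def _default_alert_weights() -> dict[str, float]:
    return {"delta": 1.0, "theta": 0.7, "alpha": 0.8, "beta": 1.5}


def _default_fatigue_weights() -> dict[str, float]:
    return {"delta": 1.0, "theta": 1.5, "alpha": 1.5, "beta": 0.5}


def _default_ar_coeffs() -> dict[str, list[float]]:
    # stable AR(2) sets with visibly different spectra per class
    return {"alert": [0.3, -0.2], "fatigue": [0.9, -0.45]}


@dataclass
class SynthConfig:
    """Parameters of the synthetic EEG generator.

    ``band_weights_*`` give the relative oscillation amplitude per band
    (arbitrary units); ``ar_noise_coeffs`` maps each class to a stable AR
    coefficient vector for the coloured-noise component; ``noise_sd`` is
    the white-noise standard deviation added on top.
    """

    n_subjects: int = 43
    fs: float = 256.0
    n_channels: int = 32
    duration_s: float = 20.0
    band_weights_alert: dict[str, float] = field(default_factory=_default_alert_weights)
    band_weights_fatigue: dict[str, float] = field(default_factory=_default_fatigue_weights)
    ar_noise_coeffs: dict[str, list[float]] = field(default_factory=_default_ar_coeffs)
    noise_sd: float = 0.5
    ar_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if self.n_channels < 1:
            raise ValueError(f"n_channels must be >= 1, got {self.n_channels}")
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be >= 1, got {self.n_subjects}")
        for which in (self.band_weights_alert, self.band_weights_fatigue):
            if set(which) != set(BANDS):
                raise ValueError(
                    f"band weights must map exactly {sorted(BANDS)}, got {sorted(which)}"
                )
            if any(w < 0 for w in which.values()):
                raise ValueError("band weights must be non-negative")

    def band_weights(self, cls: str) -> dict[str, float]:
        if cls == "alert":
            return self.band_weights_alert
        if cls == "fatigue":
            return self.band_weights_fatigue
        raise ValueError(f"invalid class label {cls!r}; expected one of {CLASSES}")


def _channel_names(n: int) -> list[str]:
    if n <= len(MONTAGE_32):
        return MONTAGE_32[:n]
    return MONTAGE_32 + [f"CH{i}" for i in range(len(MONTAGE_32), n)]


def _recording_rng(config: SynthConfig, subject_id: int, cls: str) -> np.random.Generator:
    # deterministic substream per (dataset seed, subject, state)
    return np.random.default_rng([int(config.seed), int(subject_id), label_code(cls)])


def generate_recording(cls: str, config: SynthConfig, subject_id: int = 0) -> EEGRecording:
    """Generate one synthetic recording of class ``cls`` for ``subject_id``.

    Each channel is built independently: for every band, ``_N_OSC``
    sinusoids at frequencies drawn uniformly inside the band, with random
    phases, scaled by the class band weight; plus AR(2)-filtered Gaussian
    noise with class-specific coefficients; plus white Gaussian noise.
    """
    weights = config.band_weights(cls)  # validates cls
    rng = _recording_rng(config, subject_id, cls)
    n_samp = int(round(config.fs * config.duration_s))
    t = np.arange(n_samp) / config.fs
    data = np.zeros((config.n_channels, n_samp))

    ar = np.asarray(config.ar_noise_coeffs.get(cls, []), dtype=float)
    # lfilter denominator for x_t = sum a_k x_{t-k} + e_t
    denom = np.concatenate([[1.0], -ar]) if ar.size else np.array([1.0])

    for ch in range(config.n_channels):
        x = np.zeros(n_samp)
        for band, (lo, hi) in BANDS.items():
            w = weights[band]
            if w == 0:
                # burn the same number of draws so other bands are unaffected
                rng.uniform(lo, hi, _N_OSC)
                rng.uniform(0, 2 * np.pi, _N_OSC)
                continue
            freqs = rng.uniform(lo, hi, _N_OSC)
            phases = rng.uniform(0, 2 * np.pi, _N_OSC)
            amp = w / np.sqrt(_N_OSC)
            x += amp * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]).sum(0)
        if config.noise_sd > 0 or config.ar_noise_sd > 0:
            e = rng.standard_normal(n_samp)
            if config.ar_noise_sd > 0 and ar.size:
                x += config.ar_noise_sd * lfilter([1.0], denom, e)
            elif config.ar_noise_sd > 0:
                x += config.ar_noise_sd * e
            if config.noise_sd > 0:
                x += config.noise_sd * rng.standard_normal(n_samp)
        data[ch] = x

    return EEGRecording(
        data=data,
        fs=config.fs,
        channel_names=_channel_names(config.n_channels),
        subject_id=subject_id,
        state=cls,
    )


def generate_dataset(config: SynthConfig) -> tuple[list[EEGRecording], list[str]]:
    """One alert and one fatigue recording per subject.

    Returns the recordings and an aligned list of class-name labels.
    Deterministic under ``config.seed``.
    """
    recordings: list[EEGRecording] = []
    labels: list[str] = []
    for subject in range(1, config.n_subjects + 1):
        for cls in CLASSES:
            recordings.append(generate_recording(cls, config, subject))
            labels.append(cls)
    return recordings, labels
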