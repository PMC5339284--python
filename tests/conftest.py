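import numpy as np
import pytest

from eegfatigue import (
    EEGRecording,
    SegmentSet,
    SynthConfig,
    generate_recording,
    segment_moving_window,
)


@pytest.fixture(scope="session")
def small_config():
    """4-channel, 20 s synthetic config — fast but structurally faithful."""
    return SynthConfig(n_subjects=2, n_channels=4, seed=7)


@pytest.fixture(scope="session")
def alert_recording(small_config):
    return generate_recording("alert", small_config, subject_id=1)


@pytest.fixture(scope="session")
def fatigue_recording(small_config):
    return generate_recording("fatigue", small_config, subject_id=1)


@pytest.fixture(scope="session")
def alert_segments(alert_recording):
    return segment_moving_window(alert_recording, 2.0, 1.75)


@pytest.fixture
def toy_recording():
    """Deterministic 2-channel ramp recording for bookkeeping tests."""
    fs = 8.0
    n = 32  # 4 s
    data = np.vstack([np.arange(n, dtype=float), -np.arange(n, dtype=float)])
    return EEGRecording(data=data, fs=fs, channel_names=["A", "B"], subject_id=9,
                        state="alert")


@pytest.fixture(scope="session")
def toy_binary_data():
    """Two-mode binary-ish dataset in [0,1] for RBM training tests."""
    rng = np.random.default_rng(42)
    a = (rng.random((100, 12)) < 0.9).astype(float)
    a[:, 6:] = (rng.random((100, 6)) < 0.1).astype(float)
    b = 1.0 - a
    return np.vstack([a, b])


def make_segments(n_seg=3, n_ch=2, n_samp=64, fs=32.0, seed=0, label=0):
    rng = np.random.default_rng(seed)
    return SegmentSet(
        data=rng.standard_normal((n_seg, n_ch, n_samp)),
        labels=np.full(n_seg, label),
        provenance=[(1, "alert" if label == 0 else "fatigue", i) for i in range(n_seg)],
        fs=fs,
        channel_names=[f"ch{c}" for c in range(n_ch)],
    )
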