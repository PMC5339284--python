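"""Epoch selection and moving-window segmentation.

Window boundaries are computed in integer samples (half-open
``[start, start + window_samples)``) with ``step = round((window_s -
overlap_s) * fs)``; trailing partial windows are dropped.  With a 20 s
record at 256 Hz, a 2 s window and 1.75 s overlap this yields 73 segments
of 512 samples per state.

Artifact removal (SOBI/CCA/ICA) is deliberately not implemented; a
cleaning callable can be injected via the ``clean`` hook where desired.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

from .containers import EEGRecording, SegmentSet, label_code


def select_state_epoch(rec: EEGRecording, start_s: float, length_s: float) -> EEGRecording:
    """Contiguous slice of a recording, metadata preserved.

    Raises ``ValueError`` when the requested slice extends past the end of
    the record, reporting requested vs available duration.
    """
    if start_s < 0:
        raise ValueError(f"start_s must be >= 0, got {start_s}")
    if length_s <= 0:
        raise ValueError(f"length_s must be positive, got {length_s}")
    start = int(round(start_s * rec.fs))
    n = int(round(length_s * rec.fs))
    if start + n > rec.n_samples:
        raise ValueError(
            f"requested epoch [{start_s}, {start_s + length_s}) s exceeds record "
            f"duration {rec.duration_s} s"
        )
    return EEGRecording(
        data=rec.data[:, start : start + n],
        fs=rec.fs,
        channel_names=list(rec.channel_names),
        subject_id=rec.subject_id,
        state=rec.state,
    )


def segment_moving_window(
    rec: EEGRecording,
    window_s: float = 2.0,
    overlap_s: float = 1.75,
    clean: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> SegmentSet:
    """Cut a recording into overlapping windows.

    The number of segments is ``floor((T - window) / step) + 1`` with
    ``step = window_s - overlap_s`` (all converted to samples).  Labels and
    provenance are copied from the recording.

    Parameters
    ----------
    clean : callable, optional
        Hook applied to the full channels-x-samples array before
        segmentation (e.g. an artifact-removal routine).  Identity when
        omitted.
    """
    if overlap_s < 0 or overlap_s >= window_s:
        raise ValueError(f"need 0 <= overlap_s < window_s, got overlap={overlap_s}, window={window_s}")
    win = int(round(window_s * rec.fs))
    step = int(round((window_s - overlap_s) * rec.fs))
    if step <= 0:
        raise ValueError(f"window step rounds to {step} samples; increase window - overlap")
    if win > rec.n_samples:
        raise ValueError(
            f"window of {window_s} s ({win} samples) longer than record "
            f"({rec.duration_s} s, {rec.n_samples} samples)"
        )
    data = rec.data if clean is None else np.asarray(clean(rec.data), dtype=float)

    n_seg = (rec.n_samples - win) // step + 1
    starts = np.arange(n_seg) * step
    segments = np.stack([data[:, s : s + win] for s in starts])
    code = label_code(rec.state)
    return SegmentSet(
        data=segments,
        labels=np.full(n_seg, code, dtype=int),
        provenance=[(rec.subject_id, rec.state, int(i)) for i in range(n_seg)],
        fs=rec.fs,
        channel_names=list(rec.channel_names),
    )
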