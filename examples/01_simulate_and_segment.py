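"""Generate synthetic two-class EEG and cut it into overlapping windows.

Builds one alert and one fatigue recording for a single subject (32
channels, 20 s at 256 Hz), then applies the 2 s / 1.75 s-overlap moving
window.  The printed segment count (73 per state) is the number of feature
samples each recording contributes downstream.
"""

from eegfatigue import SynthConfig, generate_dataset, segment_moving_window

config = SynthConfig(n_subjects=1, seed=42)
recordings, labels = generate_dataset(config)

for rec in recordings:
    segs = segment_moving_window(rec, window_s=2.0, overlap_s=1.75)
    print(
        f"subject {rec.subject_id} ({rec.state}): "
        f"{rec.n_channels} channels x {rec.n_samples} samples "
        f"-> {len(segs)} segments of {segs.window_samples} samples"
    )
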