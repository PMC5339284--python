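"""Train the two-layer sparse-DBN on a small synthetic cohort.

Runs the full recipe — generative sparse-RBM pre-training, a
discriminative second layer over [hidden activations + one-hot labels],
and backprop fine-tuning with validation-based early stopping — then
scores the held-out test split.  Printed: the best validation MSE and the
iteration it occurred at, plus test sensitivity/specificity/accuracy and
AUROC (fatigue = positive class).
"""

from eegfatigue import (
    ARSpec,
    SynthConfig,
    TrainConfig,
    concat_segment_sets,
    confusion_metrics,
    extract_ar_features,
    generate_dataset,
    holdout_split,
    predict,
    roc_curve,
    scale_minmax01,
    segment_moving_window,
    train_dbn,
)

config = SynthConfig(n_subjects=8, n_channels=8, seed=7)
recordings, _ = generate_dataset(config)
segs = concat_segment_sets([segment_moving_window(r) for r in recordings])
features = extract_ar_features(segs, ARSpec(order=5))
print(f"dataset: {features.n_samples} segments x {features.n_features} AR features")

tr, va, te = holdout_split(features.n_samples, seed=7)
train, (valid, test) = scale_minmax01(features.subset(tr),
                                      [features.subset(va), features.subset(te)])

arch = [features.n_features, 15, 15, 2]
model = train_dbn(train, valid, arch, TrainConfig(seed=7))
trace = model.train_trace
print(f"architecture {arch}; fine-tuning stopped by {trace.stop_reason} "
      f"with best validation MSE {trace.best_valid_mse:.5f} "
      f"at iteration {trace.best_epoch + 1}")

scores, labels = predict(model, test)
rep = confusion_metrics(test.y, labels)
_, auroc = roc_curve(scores, test.y)
print(f"test: sensitivity {rep.sensitivity:.1f}%, specificity {rep.specificity:.1f}%, "
      f"accuracy {rep.accuracy:.1f}%, AUROC {auroc:.4f}")
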