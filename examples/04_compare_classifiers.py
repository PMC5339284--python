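"""Compare ANN, plain DBN and sparse-DBN under 3-fold cross-validation.

Each fold serves once as the test set; fold accuracies feed a one-way
ANOVA and Tukey-Kramer HSD pairwise comparison.  Printed: the per-
classifier mean +/- SD table, the ANOVA F statistic, and each pairwise Q
statistic with its significance tier (critical values at 0.05/0.01 come
from the studentized-range table).
"""

from eegfatigue import (
    ARSpec,
    SynthConfig,
    compare_classifiers,
    concat_segment_sets,
    extract_ar_features,
    generate_dataset,
    make_classifier,
    segment_moving_window,
)

# elevated white noise makes the task non-trivial so the classifiers spread
config = SynthConfig(n_subjects=6, noise_sd=10.0, seed=11)
recordings, _ = generate_dataset(config)
segs = concat_segment_sets([segment_moving_window(r) for r in recordings])
features = extract_ar_features(segs, ARSpec(order=5))

# CD momentum accelerates the RBM pre-training, which would otherwise leave
# the unsupervised layers close to their initialization on this noisy set
classifiers = {
    "ann": make_classifier("ann", seed=11, hidden=[15]),
    "dbn": make_classifier("dbn", seed=11, hidden=[15, 15], momentum=0.9),
    "sparse-dbn": make_classifier("sparse-dbn", seed=11, hidden=[15, 15], momentum=0.9),
}
report = compare_classifiers(features, classifiers, protocol="kfold", seed=11, k=3)

cols = ["classifier", "accuracy_pct_mean", "accuracy_pct_sd", "auroc_mean"]
print(report.table[cols].to_string(index=False))
if report.tukey is not None:
    t = report.tukey
    print(f"\nANOVA: F = {t.F:.3f}, p = {t.p_anova:.4g} "
          f"(q crit: {t.q_crit_05} at 0.05, {t.q_crit_01} at 0.01)")
    for (a, b), q, tier in t.pairwise:
        print(f"  {a} vs {b}: Q = {q:.3f} ({tier})")
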