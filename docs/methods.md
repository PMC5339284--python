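# Methods

This note records the modeling choices behind `eegfatigue`: what each stage
computes, the defaults and why, where the design was genuinely open, and
what the synthetic data does and does not establish.

## Synthetic EEG generator

Each channel of a synthetic recording is the sum of three components:

1. **Band-limited oscillators** — for each of delta (0.5–3 Hz), theta
   (3.5–7.5 Hz), alpha (8–13 Hz) and beta (13.5–30 Hz), three sinusoids at
   frequencies drawn uniformly inside the band, with independent random
   phases, scaled by a class-specific band weight. Defaults: fatigue
   {delta 1.0, theta 1.5, alpha 1.5, beta 0.5}, alert {delta 1.0,
   theta 0.7, alpha 0.8, beta 1.5} — the direction (slow-wave elevation and
   beta suppression under fatigue) follows the fatigue-EEG literature; the
   magnitudes are free parameters of the generator, not a claim about any
   particular dataset.
2. **AR(2)-coloured noise** with class-specific coefficients (alert
   [0.3, −0.2], fatigue [0.9, −0.45]; both stable), so the classes differ
   in autoregressive structure as well as band power.
3. **White Gaussian noise**, standard deviation `noise_sd` (default 0.5).

Defaults otherwise mirror the reference recording setup: 32 channels
(BioSemi montage names), 256 Hz, 20 s per state, one alert and one fatigue
recording per subject, 43 subjects. Randomness uses one `SeedSequence`
stream per dataset with `(seed, subject, state)` substreams, so a single
recording regenerates identically without generating the whole dataset.

Not emulated: eye-blink/EMG/ECG artifacts, volume conduction and
inter-channel correlation, non-stationarity within a recording, and
inter-subject variability beyond phase/frequency resampling. Consequently
the default synthetic classes are far more separable than real driving EEG
— all three classifiers reach 100% test accuracy at default noise — and
passing the end-to-end tests demonstrates that the pipeline machinery is
correct, not that these accuracy levels transfer to real recordings.

## Preprocessing

Windows are computed in integer samples, half-open
`[start, start + window)`, with `step = round((window_s − overlap_s)·fs)`;
trailing partial windows are dropped. A 20 s record at 256 Hz with a 2 s
window and 1.75 s overlap yields floor((5120−512)/64)+1 = 73 segments.
Artifact removal is intentionally out of scope; `segment_moving_window`
accepts an injectable `clean` hook where a SOBI/CCA/ICA routine could be
applied. Epoch choice within a longer recording (`select_state_epoch`) is
left to the caller.

## Features

* **AR coefficients** — Burg estimation by default (stable and accurate on
  512-sample segments), Yule–Walker (MLE) as an option, both via
  statsmodels. The sign convention is `x(t) = Σ a(k) x(t−k) + e(t)`: an
  AR(1) with a(1) = 0.5 has positive lag-1 autocorrelation. Default order
  5, giving order × channels features per segment. A zero-variance channel
  inside a segment yields a zero block plus a warning rather than a hard
  failure.
* **PSD band powers** — periodogram of the demeaned, Hamming-windowed
  segment (one 2 s window is too short for Welch averaging at useful
  resolution), integrated over each band with the trapezoidal rule
  restricted to frequency bins inside the band edges. Units:
  signal-units².
* **Scaling** — per-feature min-max to [0, 1] learned on the training
  split only; validation/test values are clipped into [0, 1]; constant
  training features map to 0.5. Scaling to [0, 1] is required because the
  classifier treats features as Bernoulli visible-unit probabilities.

## Sparse RBM and DBN

Visible units are Bernoulli with the scaled features used as activation
probabilities (mean-field); hidden *states* are sampled only on the
positive-to-negative transition of the CD chain, and reconstructions are
mean-field. CD-1 is the default. The sparsity penalty
`λ Σⱼ (p − q̄ⱼ)²`, with `q̄ⱼ` the batch-mean hidden probability,
contributes its exact gradient to the hidden biases and weights. Weight
init: zero biases, N(0, 0.01²) weights; batch size 100; CD momentum and
weight decay default to 0.

Training protocol (defaults): CD learning rate η = 0.01, λ = 1, p = 0.02,
200 epochs. The generative first layer trains for the full epoch budget
(no early stopping); the discriminative second layer is a classification
RBM whose visible layer is the first layer's hidden activations
concatenated with the one-hot label; at unrolling, its label-block weights
(transposed) and label visible biases initialize the 2-unit output head.
Setting λ = 0 recovers the plain-DBN baseline.

**Fine-tuning** minimizes MSE on one-hot targets (MSE = mean over samples
and output units) by mini-batch gradient descent with validation-based
early stopping: stop after `max_fail = 10` consecutive epochs without a new
validation minimum and restore the best epoch. Two parameters are
deliberately decoupled from the CD stage:

* `finetune_eta = 1.0` — with the gradient normalized per sample, a 0.01
  step leaves backprop effectively inert (validation MSE pinned at the
  ~0.25 all-outputs-0.5 plateau), which contradicts the converged
  fine-tuning traces the protocol itself reports; the reference
  implementation evidently used an adaptive optimizer. The default matches
  the ANN baseline, which runs the identical backprop stage.
* `finetune_momentum = 0.9` — the classic momentum for backprop over
  pre-trained stacks; it carries the optimizer through the early sigmoid
  plateau that would otherwise exhaust the early-stopping patience.

**Prediction** reports, per sample, the fatigue output activation
normalized over the two output units. This is monotone-equivalent to the
argmax decision (score > 0.5 ⇔ fatigue wins), and it makes ROC curves rank
by the decision margin; the raw single-unit activation can rank inversely
on an undertrained head even when the hard labels are correct. An exact
tie breaks toward alert, so a degenerate model never raises a fatigue
alarm.

## ANN baseline

A single-hidden-layer sigmoid network (default 15 hidden units, mirroring
the DBN's discriminative path on AR features) trained from scratch with
the same backprop/early-stopping machinery: eta = 1.0, momentum = 0.9,
init N(0, 0.5²). The reference protocol prints none of these values; they
are documented here as this package's choices. The Bayesian-regularized
network variant is not implemented; the comparison harness accepts any
object with the `train`/`predict` contract, so one can be plugged in.

## Evaluation protocol

* **Hold-out**: shuffled partition into training/validation/test of sizes
  ⌈n/3⌉, ⌈(n−train)/2⌉, remainder — (2,093, 2,093, 2,092) for n = 6,278.
  The default split is segment-wise, which matches the reference counts
  but leaks subjects across subsets (windows from one subject's recording
  can land in both training and test); a subject-wise mode (`groups=` /
  `--split-by subject`) is provided as the methodologically safer option.
* **3-fold cross-validation**: near-equal folds; each fold serves once as
  test while the remaining folds are split 2:1 into train/validation,
  because the early-stopping contract requires a validation set. A
  `repeats` knob reruns each fold with derived seeds (default 1).
* **Metrics**: exact count arithmetic internally; rates displayed at one
  decimal. ROC thresholds sweep the distinct score values with ties
  grouped; AUROC is the trapezoidal area and equals the Mann–Whitney
  pairwise statistic (property-tested).
* **ANOVA + Tukey–Kramer**: one-way ANOVA over per-fold accuracies, then
  `Q = |mean_i − mean_j| / sqrt(MSW/n)` against studentized-range critical
  values from an embedded table (groups 2–10, df 2–30, α ∈ {0.05, 0.01};
  four-decimal precision, following the widely used HSD reference tables —
  e.g. q(0.05; 4, 8) = 4.5293, q(0.01; 4, 8) = 6.2044). df above 30 clamps
  to 30, which is conservative for significance claims.

## Numerical and interface choices

* Sigmoid computed via tanh for numerical stability; all training is
  bit-for-bit reproducible under a fixed seed (NumPy `default_rng`).
* Deterministic per-stage seed substreams derive from one global pipeline
  seed, so stages can be rerun independently.
* File formats are versioned delimited text (+ JSON sidecars/containers);
  readers reject unknown versions. EDF I/O is not implemented; recordings
  are exchanged as TSV + metadata JSON.
* Problem sizes in the shipped tests and acceptance script: the full
  43-subject synthetic cohort (6,278 segments × 160 AR features) for the
  end-to-end run; smaller cohorts (2–8 subjects, 4–32 channels) for unit
  and example runs.

## Known limitations

* The synthetic generator's class separation is construction-deep; results
  on it bound nothing about real EEG beyond pipeline correctness.
* Gaussian-visible RBMs are not provided; continuous features are handled
  only via min-max scaling onto Bernoulli probabilities.
* Plain (non-sparse) DBN pre-training at η = 0.01 for 200 epochs moves the
  first-layer weights very little; on hard inputs its accuracy then
  depends on fine-tuning alone, and adding CD momentum (exposed as a
  config field) is advisable.
* The Tukey table covers balanced groups only, as required by the
  equal-size Q statistic used here.
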