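# Methods

This note documents the models, the synthetic data, the numerical
choices and the known limitations of `ecgfusion`. Nothing here states a
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Problem setting

Single-lead ECG beats, annotated at their R sample, are classified into
three classes: normal sinus beats, premature ventricular contractions
(PVC) and a catch-all "other" class (bundle-branch-block-like and other
abnormal beats). The classifier is an ensemble: several deliberately
diverse multilayer perceptrons are trained on the same 11-feature beat
description, and their outputs are combined. The package's centrepiece
is the comparison of ten combination strategies, in particular *modified
stacked generalization* (MSG), where the trainable level-1 combiner
receives the input feature vector concatenated with the base
classifiers' outputs and can therefore learn per-region expertise — a
blend of classifier fusion and classifier selection.

## Synthetic data generator

Real annotated arrhythmia databases cannot be redistributed with a
package, so all tests and experiments run on a seeded generator.

* **Beat model** — a beat is a sum of five Gaussian bumps (P, Q, R, S,
  T). Defaults (81-sample window at 360 Hz, centre = R): centres
  (−28, −7, 0, +7, +30) samples, amplitudes (0.15, −0.12, 1.20, −0.18,
  0.35) mV, widths (3.5, 1.5, 2.2, 1.8, 6.0) samples. Wave timing is
  deliberately compressed so P and T fit inside the window; see
  *Limitations*.
* **PVC** — P amplitude 0; Q/R widths ×2.5 (a wide complex); S deepened
  ×2.5 and shifted right by 5 samples so the wide complex keeps a
  detectable notch; T inverted (discordant). The RR interval *preceding*
  a PVC is shortened by the factor 0.70.
* **Other** — non-conducted P (amplitude 0) and a notched QRS: a second
  R bump (0.85× amplitude) 3.5 samples right of the first. At these
  widths the two bumps merge into a right-heavy shoulder rather than two
  separate maxima; this is intentional — the class should be hard to
  separate from normal beats on amplitude alone.
* **Rhythm** — RR intervals are 300 ± 25 samples (72 bpm at 360 Hz);
  additive white Gaussian noise, default σ = 0.10 mV.
* **Per-beat variability** — multiplicative amplitude jitter (30%),
  width jitter (18%) and P/T centre jitter (3.5 samples).

The variability/noise defaults were calibrated once so that a single
default MLP reaches roughly 92–94% test accuracy on the three-class
task — the regime reported for individual base classifiers on real
data, and comfortably above the 90% separability floor the ensemble
experiments require. Easier settings make every combiner saturate near
100% and the comparison meaningless; the calibration was frozen before
any ensemble comparison was run.

What the generator does **not** emulate: baseline wander, powerline
interference, electrode artefacts, multi-lead morphology, beat-to-beat
waveform correlation, and realistic PR/QT timing (see *Limitations*).
Passing tests therefore demonstrate correctness of the algorithms and
the claimed qualitative orderings on data with this structure, not
clinical performance.

## Preprocessing

* **Denoising** — stationary (undecimated) wavelet transform, db1,
  depth 5 by default; soft thresholding `sign(x)·max(|x|−t, 0)` of all
  detail levels with the universal threshold t = σ̂·√(2 ln N). σ̂ is the
  MAD/0.6745 estimate from the *finest* detail level: for the
  undecimated transform the white-noise variance is identical at every
  level, while coarse-level MAD estimates would be inflated by signal
  energy and over-shrink. Signals are symmetrically right-padded to a
  multiple of 2^levels and cropped after reconstruction. A zero-variance
  input is returned unchanged with threshold 0.
* **Smoothing** — Savitzky–Golay, window 15 samples, cubic, applied
  after denoising (the order is configurable). Window 15 ≈ 42 ms at
  360 Hz preserves QRS peaks while flattening residual noise.
* **Depth selection** — `denoise_level_sweep` scores depths 2–7 by
  correlation with a clean reference. On the synthetic benchmark (a
  trace with *physiologic* wave durations, since depth selection
  reflects spectral content) the optimum is an interior depth — depth 3
  or 4 depending on noise level — not the shallowest or deepest choice.
  A depth-5 optimum did not reproduce under white Gaussian noise at any
  noise level we scanned (σ 0.05–0.5 mV); depth 5 still yields a clear
  correlation gain over the noisy input and is kept as the operating
  default for comparability.

## Features

Eleven features per beat: amplitudes and positions (0-based window
indices) of P, Q, R, S, T, plus `ratRR = prev_RR / next_RR`
(dimensionless, so sample counts vs seconds is immaterial). R is
anchored at the annotation; Q and S are the valleys nearest the centre
on each side; P is the first peak before Q and T the last peak after S —
any additional extremum candidates are rejected. Extrema are strict
local extrema of the smoothed window with prominence ≥ 5% of the
window's peak-to-peak range. Absent waves are imputed with amplitude 0
and position at the window boundary on their expected side; presence
flags are kept internally but are not features, so the vector stays at
11 elements. Features are z-scored with training-set statistics before
entering any network; the statistics are stored inside the model files.

The first and last annotated beats of a record have no RR context and
are dropped; beats whose window would cross a record edge are skipped
and logged.

## Base classifiers

Single-hidden-layer, fully connected MLPs, logistic sigmoid everywhere,
one-hot targets, squared-error loss E = ½Σ(t−o)², online (per-sample)
gradient descent with a fixed learning rate of 0.1 and uniform
initial weights on a symmetric interval. Diversity comes from the three
configurations (17 hidden / 1700 epochs / ±2), (22 / 2700 / ±3),
(25 / 2000 / ±4); pools of 4–5 experts add (12 / 1500 / ±2) and
(30 / 2200 / ±5). Sample order is a fresh seeded permutation each
epoch, making training bit-reproducible. Epoch counts are honoured
exactly; an optional early-stopping utility selects epochs on a
validation split but is off by default.

Large initial-weight ranges (±4) occasionally saturate the sigmoids and
leave a run stuck near majority-class accuracy. This is realistic
backprop behaviour under these settings and is left in place: the
ensemble layer is what absorbs it.

The hot loop is compiled with numba; `gradients` is a pure-numpy mirror
of the same arithmetic, and the tests verify (a) kernel single steps
equal the numpy gradients exactly and (b) the gradients match central
finite differences to <1e−6 on 2-3-2 and 11-17-3 networks.

## Fusion methods

For a decision profile DP ∈ [0,1]^{L×C}: column-wise mean (≡ sum), min,
max, median, product; majority voting on per-classifier argmaxes; Borda
count with C−1 … 0 points per row and tied supports sharing averaged
points; decision templates DT_j = mean profile of class j, applied via
the bounded similarity 1 − (1/LC)·‖DT_j − DP‖²_F (argmax over this
similarity equals argmin over distance); and weighted averaging with
weights fitted by gbest PSO. Every decision uses one shared tie rule:
lowest class index.

PSO: swarm 30, 100 iterations, inertia 0.72, c1 = c2 = 1.49, per-
dimension velocity clamp 1.0; fitness is the validation error of the
weighted-average ensemble, with candidate weights mapped to the simplex
(clip at 0, renormalize; all-zero clips fall back to uniform) both
inside the fitness and on the returned optimum. Non-finite fitness
values skip the particle's update for that iteration with a warning and
reset it to its personal best.

Decision templates and PSO weights are fitted on the validation set —
the split otherwise reserved for topology selection — so the training
set never leaks into combiner fitting for these two methods.

## Stacking

SG flattens DP row-major (L·C inputs); MSG appends the z-scored input
features (L·C + 11). Both combiners are the same MLP implementation
(defaults for 3 experts: 30 hidden neurons for SG, 45 for MSG, 2000
epochs, init ±2). The combiner trains on the meta inputs of the
training set with *in-sample* base outputs. Two alternatives are
implemented and measured: k-fold out-of-fold stacking (`oof_folds=k`)
and a held-out stacking set (`stack_X/stack_y`). At the package's
training scale (600 beats) out-of-fold stacking *hurt* both SG and MSG
— profiles from fold-trained bases are distribution-shifted relative to
the final full-data bases — so in-sample stacking is the default.
Retraining a combiner never mutates base weights, and `base_subsets`
can bias each base toward a region of the input space (used by the
expertise-segregation experiment, where MSG's advantage over SG is
largest).

`search_combiner_width` sweeps the combiner hidden width over a list
(e.g. 5…80) against validation accuracy, returning the smallest width
on ties.

## Evaluation protocol

Confusion matrices use rows = output (predicted) class and columns =
desired (true) class. "Specificity" is the *normal-class recall* —
the screening convention for this task — not 1 − FPR; the two
sensitivities are the PVC and other-class recalls, and overall accuracy
is trace/total. Percentages are kept at full precision internally and
rendered at 2 decimals.

The multi-seed comparison (`headline_comparison`) repeats the whole
experiment — fresh dataset, fresh initializations — on n independent
seeds and compares *method-level means*: mean accuracy of MSG, of SG,
and of the best individual base classifier, where "best" is chosen by
that same mean (choosing the per-seed maximum on the test set would be
an optimistic selection no protocol uses). Ten seeds at 600/150/3000
(train/validation/test, training and validation class-balanced, test at
a realistic 55/3/42 class mix) run in a couple of minutes; these sizes
are the package's standard experiment scale.

## Limitations

* The 81-sample beat window cannot contain physiologic PR (~160 ms) and
  RT (~250 ms) intervals at 360 Hz, so the beat generator compresses
  wave timing; the denoising benchmark uses a separate
  physiologic-duration trace for exactly this reason.
* The depth-5 denoising optimum did not reproduce (see *Preprocessing*);
  the package treats depth as a configuration key with the documented
  default.
* The Borda tie convention (averaged points) and the PSO
  hyperparameters are standard choices; neither is uniquely implied by
  the method descriptions.
* `ratRR` of a PVC that directly follows another PVC is near 1, so
  rhythm information fades in long PVC runs; morphology carries those
  cases.
* WFDB support covers format 212 and standard binary beat annotations,
  reading only; other signal formats are rejected explicitly.
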