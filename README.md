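# ecgfusion

Three-class ECG arrhythmia beat classification — **normal**, **premature
ventricular contraction (PVC)** and **other** — with an ensemble of
multilayer perceptrons and a full toolbox of classifier-fusion methods,
including **modified stacked generalization (MSG)**: a level-1 neural
combiner that receives the original input features *alongside* the base
classifiers' outputs, so it can learn where in the input space each base
classifier is reliable and fuse or select their votes accordingly.

The package is aimed at biomedical-signal and machine-learning
practitioners who want a self-contained, reproducible implementation of
the classic beat-classification pipeline: wavelet denoising, morphological
feature extraction, diverse backprop MLPs, and ten combination strategies
evaluated side by side.

## The pipeline

1. **Preprocessing** (`ecgfusion.preprocessing`) — stationary (undecimated)
   wavelet denoising: soft thresholding of the detail coefficients with the
   universal threshold *t* = σ̂·√(2 ln N), σ̂ the MAD/0.6745 estimate from
   the finest detail level; then Savitzky–Golay smoothing (window 15,
   cubic). Defaults: db1 wavelet, depth 5.
2. **Features** (`ecgfusion.features`) — beats are cut into 81-sample
   windows (40 samples each side of the annotated R sample at 360 Hz);
   local extrema of the smoothed window are assigned to the five waves
   (R = centre; Q/S = nearest valley left/right of centre; P = first peak,
   T = last peak; extra candidates rejected). Each beat yields 11
   features: amplitudes and positions of P, Q, R, S, T plus
   `ratRR = prev_RR / next_RR` (below 1 for PVC beats).
3. **Base classifiers** (`ecgfusion.mlp`) — from-scratch single-hidden-layer
   sigmoid MLPs trained by online backpropagation on the squared error.
   The three diverse default configurations are (hidden/epochs/init-range)
   17/1700/±2, 22/2700/±3 and 25/2000/±4.
4. **Fusion** (`ecgfusion.fusion`) — for a decision profile *DP(x)* (the
   L×C matrix of per-classifier class supports): mean/sum, min, max,
   median, product, majority voting, Borda count, decision templates
   (class-mean profiles compared by normalized squared Euclidean distance)
   and weighted averaging with weights optimized by gbest particle-swarm
   optimization against validation error.
5. **Stacking** (`ecgfusion.stacking`) — stacked generalization (SG:
   level-1 MLP on the flattened L·C profile) and MSG (profile ⧺ features;
   with 3 experts, 3 classes and 11 features the meta input is 9 vs 20
   elements).
6. **Evaluation** (`ecgfusion.evaluation`) — confusion matrices
   (rows = output class, columns = desired class) and the four summary
   statistics: specificity (normal-class recall), sensitivity (PVC),
   sensitivity (other) and overall accuracy.

A seeded synthetic generator (`ecgfusion.synthetic`) provides labelled
records with class-dependent P/QRS/T morphology (sum-of-Gaussians beats,
PVC with absent P, widened QRS and shortened preceding RR; "other" with
notched QRS and non-conducted P) so the whole pipeline runs without any
database download. A WFDB adapter (`ecgfusion.io`) reads MIT-BIH-style
format-212 records and binary annotation files directly if you have them.

## Worked example

`python examples/train_msg_ensemble.py` trains the three base MLPs and an
MSG combiner on a synthetic split and prints:

```
Confusion matrix (rows = output class, columns = desired class)
            normal       pvc     other
normal         479         0        31
pvc              6        27        17
other           62         2       376

Specificity                  87.57%
Sensitivity (PVC)            93.10%
Sensitivity (other)          88.68%
Overall accuracy             88.20%
```

Column sums are the per-class beat counts; specificity is the fraction of
true normal beats labelled normal (479 of 547 here), the sensitivities are
the same recall for the PVC and other classes, and overall accuracy is the
diagonal total over all 1000 test beats. (This example is deliberately
small; the full-scale comparison below reaches the mid-90s.)

The other examples cover record simulation and feature extraction
(`simulate_and_extract.py`), wavelet-depth selection
(`wavelet_denoising.py`) and the ten-method comparison grid
(`compare_fusion_methods.py`). The same functionality is exposed on the
command line:

```
ecgfusion simulate --beats 600 --seed 1 out/
ecgfusion extract-features out/record.csv out/annotations.csv features.csv
ecgfusion train --mode msg --experts 3 features.csv model.json
ecgfusion evaluate model.json features.csv report.txt
ecgfusion compare-combiners --experts 2,3,4,5 grid.csv
```

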