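"""Confusion matrices and the four summary statistics.

The confusion matrix is oriented with *rows = output (predicted) class*
and *columns = desired (true) class*.  The four statistics follow the
arrhythmia-screening convention for a {normal, PVC, other} problem:

* **specificity** — correctly classified normal beats over all normal
  beats (i.e. the normal class's recall, *not* 1 - FPR);
* **sensitivity (PVC)** and **sensitivity (other)** — per-class recall
  of the two abnormal classes;
* **overall accuracy** — trace over total.

All four are reported as percentages at full floating precision;
rendered reports round to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_CLASS_NAMES = ("normal", "pvc", "other")


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (C, C) ints; rows = predicted, cols = true
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        c = self.counts.shape
        if len(c) != 2 or c[0] != c[1] or c[0] != len(self.class_names):
            raise ValueError("counts must be square and match class_names")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    specificity: float  # %
    sensitivity_pvc: float  # %
    sensitivity_other: float  # %
    overall_accuracy: float  # %


def confusion_matrix(predictions, truths, n_classes: int,
                     class_names: tuple[str, ...] | None = None
                     ) -> ConfusionMatrix:
    """Tally (predicted, true) pairs into a C x C matrix."""
    predictions = np.asarray(predictions, dtype=int)
    truths = np.asarray(truths, dtype=int)
    if predictions.shape != truths.shape:
        raise ValueError("predictions and truths must have equal length")
    for name, arr in (("prediction", predictions), ("truth", truths)):
        bad = np.flatnonzero((arr < 0) | (arr >= n_classes))
        if bad.size:
            raise ValueError(
                f"{name} label {arr[bad[0]]} at index {bad[0]} is outside "
                f"[0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (predictions, truths), 1)
    names = class_names or DEFAULT_CLASS_NAMES[:n_classes]
    if len(names) != n_classes:
        names = tuple(f"class{i}" for i in range(n_classes))
    return ConfusionMatrix(counts=counts, class_names=tuple(names))


def compute_metrics(cm: ConfusionMatrix, normal: int = 0, pvc: int = 1,
                    other: int = 2) -> MetricsReport:
    """Per-class recalls and overall accuracy, as percentages."""
    counts = cm.counts
    col_totals = counts.sum(axis=0)
    for idx in (normal, pvc, other):
        if col_totals[idx] == 0:
            raise ValueError(
                f"no beats of class {cm.class_names[idx]!r}; metric undefined")

    def recall(idx: int) -> float:
        return 100.0 * counts[idx, idx] / col_totals[idx]

    overall = 100.0 * np.trace(counts) / counts.sum()
    return MetricsReport(
        specificity=recall(normal),
        sensitivity_pvc=recall(pvc),
        sensitivity_other=recall(other),
        overall_accuracy=float(overall),
    )


def format_report(cm: ConfusionMatrix, metrics: MetricsReport | None = None
                  ) -> str:
    """Plain-text report: matrix (rows = output class) plus statistics."""
    if metrics is None:
        metrics = compute_metrics(cm)
    names = cm.class_names
    width = max(len(n) for n in names) + 2
    lines = ["Confusion matrix (rows = output class, columns = desired class)"]
    header = " " * width + "".join(f"{n:>10}" for n in names)
    lines.append(header)
    for i, n in enumerate(names):
        lines.append(f"{n:<{width}}" +
                     "".join(f"{cm.counts[i, j]:>10d}" for j in range(len(names))))
    lines.append("")
    lines.append(f"Specificity                  {metrics.specificity:.2f}%")
    lines.append(f"Sensitivity (PVC)            {metrics.sensitivity_pvc:.2f}%")
    lines.append(f"Sensitivity (other)          {metrics.sensitivity_other:.2f}%")
    lines.append(f"Overall accuracy             {metrics.overall_accuracy:.2f}%")
    return "\n".join(lines)


def write_report(path, cm: ConfusionMatrix,
                 metrics: MetricsReport | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(format_report(cm, metrics) + "\n")
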