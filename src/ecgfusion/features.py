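"""Beat segmentation, P/QRS/T landmark assignment and the 11-feature vector.

Each annotated beat is cut into a fixed window of ``half_width`` samples
on each side of the R annotation plus the annotated sample itself
(81 samples by default at 360 Hz).  Local extrema of the smoothed window
are detected and assigned to the five waves with the classic rules:

* R is the annotated centre sample;
* Q is the nearest valley left of centre, S the nearest valley right of
  centre;
* P is the first (earliest) peak before Q, T the last peak after S;
  any further peaks are rejected.

The feature vector holds the five wave amplitudes (mV), the five wave
positions (0-based sample index inside the window) and ``rat_rr``, the
ratio of the RR interval preceding the beat to the one following it.
A shortened preceding interval — the signature of a premature
ventricular beat — pushes ``rat_rr`` below 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .preprocessing import savgol_smooth

log = logging.getLogger(__name__)

FEATURE_NAMES = ("ampP", "ampQ", "ampR", "ampS", "ampT",
                 "posP", "posQ", "posR", "posS", "posT", "ratRR")

#: prominence threshold for extremum detection, as a fraction of the
#: window's peak-to-peak range
PROMINENCE_FRAC = 0.05
#: Savitzky–Golay smoothing applied to the window before extremum search
DETECT_SMOOTH_WINDOW = 7
DETECT_SMOOTH_ORDER = 3


@dataclass
class BeatWindow:
    samples: np.ndarray  # mV, length 2*half_width + 1
    fs: int
    r_index: int  # position of the annotated sample inside the window
    prev_rr: float  # samples
    next_rr: float  # samples
    label: int | None = None  # class code, or None when unknown


@dataclass
class WaveLandmarks:
    """Positions/amplitudes of P,Q,R,S,T inside one window.

    Absent waves carry imputed values (amplitude 0, position at the
    window boundary on their expected side) and ``present=False``.
    """

    positions: np.ndarray  # (5,) float sample indices
    amplitudes: np.ndarray  # (5,) mV
    present: np.ndarray  # (5,) bool


@dataclass
class FeatureVector:
    ampP: float
    ampQ: float
    ampR: float
    ampS: float
    ampT: float
    posP: float
    posQ: float
    posR: float
    posS: float
    posT: float
    rat_rr: float

    def to_array(self) -> np.ndarray:
        return np.array([self.ampP, self.ampQ, self.ampR, self.ampS, self.ampT,
                         self.posP, self.posQ, self.posR, self.posS, self.posT,
                         self.rat_rr])


def segment_beats(samples, annotations, half_width: int = 40,
                  fs: int = 360, labels=None) -> list[BeatWindow]:
    """Cut one window per annotation with defined RR context.

    ``annotations`` are sorted sample indices of R locations.  The first
    and last annotated beats lack a preceding/following RR interval and
    are dropped; beats whose window would cross a record edge are skipped
    with a log message.
    """
    samples = np.asarray(samples, dtype=float)
    annotations = np.asarray(annotations, dtype=int)
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    if len(annotations) == 0:
        return []
    if np.any(np.diff(annotations) < 0):
        raise ValueError("annotations must be sorted")
    windows: list[BeatWindow] = []
    for i in range(1, len(annotations) - 1):
        loc = annotations[i]
        lo, hi = loc - half_width, loc + half_width + 1
        if lo < 0 or hi > len(samples):
            log.warning("beat at sample %d too close to record edge; skipped", loc)
            continue
        windows.append(BeatWindow(
            samples=samples[lo:hi].copy(),
            fs=fs,
            r_index=half_width,
            prev_rr=float(loc - annotations[i - 1]),
            next_rr=float(annotations[i + 1] - loc),
            label=None if labels is None else int(labels[i]),
        ))
    return windows


def detect_peaks_valleys(beat: BeatWindow | np.ndarray,
                         smooth: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Strict local maxima/minima of the (smoothed) window.

    Candidates must exceed a prominence of ``PROMINENCE_FRAC`` times the
    window's peak-to-peak range.  Smoothing is skipped when the window is
    shorter than the smoothing kernel.  Flat windows yield no candidates.
    """
    x = beat.samples if isinstance(beat, BeatWindow) else np.asarray(beat, float)
    if x.size == 0:
        raise ValueError("window must be non-empty")
    ptp = np.ptp(x)
    if ptp == 0.0:
        return np.array([], dtype=int), np.array([], dtype=int)
    if smooth and len(x) >= DETECT_SMOOTH_WINDOW:
        x = savgol_smooth(x, DETECT_SMOOTH_WINDOW, DETECT_SMOOTH_ORDER)
        ptp = np.ptp(x)
    prom = PROMINENCE_FRAC * ptp
    peaks, _ = find_peaks(x, prominence=prom)
    valleys, _ = find_peaks(-x, prominence=prom)
    return peaks, valleys


def assign_waves(peaks, valleys, beat: BeatWindow) -> WaveLandmarks:
    """Map extremum candidates to the five waves.

    R is the annotated centre sample.  Q/S are the valleys nearest the
    centre on the left/right; P is the first peak before Q and T the last
    peak after S ("other peaks are hence rejected").  Missing waves are
    flagged absent and imputed: amplitude 0, position at the window
    boundary on the wave's expected side.
    """
    x = beat.samples
    n = len(x)
    c = beat.r_index
    peaks = np.asarray(peaks, dtype=int)
    valleys = np.asarray(valleys, dtype=int)

    positions = np.zeros(5)
    amplitudes = np.zeros(5)
    present = np.zeros(5, dtype=bool)

    # R: anchored at the annotation
    positions[2], amplitudes[2], present[2] = c, x[c], True

    left_valleys = valleys[valleys < c]
    right_valleys = valleys[valleys > c]
    if left_valleys.size:
        q = int(left_valleys[-1])  # nearest to centre from the left
        positions[1], amplitudes[1], present[1] = q, x[q], True
    else:
        q = None
        positions[1] = 0.0
    if right_valleys.size:
        s = int(right_valleys[0])  # nearest to centre from the right
        positions[3], amplitudes[3], present[3] = s, x[s], True
    else:
        s = None
        positions[3] = n - 1

    p_bound = q if q is not None else c
    p_cands = peaks[peaks < p_bound]
    if p_cands.size:
        p = int(p_cands[0])  # first peak in the window
        positions[0], amplitudes[0], present[0] = p, x[p], True
    else:
        positions[0] = 0.0
    t_bound = s if s is not None else c
    t_cands = peaks[peaks > t_bound]
    if t_cands.size:
        t = int(t_cands[-1])  # last peak in the window
        positions[4], amplitudes[4], present[4] = t, x[t], True
    else:
        positions[4] = n - 1

    return WaveLandmarks(positions=positions, amplitudes=amplitudes,
                         present=present)


def extract_features(beat: BeatWindow) -> FeatureVector:
    """The 11-element morphological + timing feature vector of one beat."""
    if beat.next_rr == 0:
        raise ValueError("next_rr must be nonzero to form the RR ratio")
    peaks, valleys = detect_peaks_valleys(beat)
    lm = assign_waves(peaks, valleys, beat)
    a, p = lm.amplitudes, lm.positions
    return FeatureVector(
        ampP=float(a[0]), ampQ=float(a[1]), ampR=float(a[2]),
        ampS=float(a[3]), ampT=float(a[4]),
        posP=float(p[0]), posQ=float(p[1]), posR=float(p[2]),
        posS=float(p[3]), posT=float(p[4]),
        rat_rr=float(beat.prev_rr / beat.next_rr),
    )


def features_matrix(windows: list[BeatWindow]) -> tuple[np.ndarray, np.ndarray]:
    """Stack feature vectors of many windows; returns (X, labels).

    Labels are -1 where a window has none.
    """
    X = np.array([extract_features(w).to_array() for w in windows])
    y = np.array([-1 if w.label is None else w.label for w in windows])
    return X, y


def features_to_frame(X: np.ndarray, labels=None) -> pd.DataFrame:
    df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    if labels is not None:
        df["label"] = labels
    return df


def write_feature_table(path, X: np.ndarray, labels=None) -> None:
    features_to_frame(X, labels).to_csv(path, index=False)


def read_feature_table(path) -> tuple[np.ndarray, np.ndarray | None]:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns {missing}")
    X = df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = df["label"].to_numpy() if "label" in df.columns else None
    return X, y
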