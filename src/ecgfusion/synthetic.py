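"""Synthetic single-lead ECG generator.

Produces labelled records containing three beat classes — normal sinus
beats, premature ventricular contractions (PVC) and a catch-all "other"
class — with class-dependent P/QRS/T morphology and rhythm structure:

* a beat is modelled as a sum of five Gaussian bumps (P, Q, R, S, T),
  the classic phenomenological morphology model;
* PVC beats have no P wave, a widened QRS, a discordant (inverted) T
  wave, and a shortened RR interval *preceding* the beat;
* "other" beats have a notched QRS (two R bumps) and no conducted P
  wave, mimicking bundle-branch-block morphology.

The default geometry matches the MIT-BIH arrhythmia database setting
(360 Hz sampling, beat windows of 40 samples on each side of the R
annotation) so feature positions downstream live on the same scale as
real records.  All randomness flows through explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

CLASS_NAMES = ("normal", "pvc", "other")
NORMAL, PVC, OTHER = 0, 1, 2

#: default sampling rate (Hz), the MIT-BIH arrhythmia database rate
DEFAULT_FS = 360
#: default beat half-window (samples); windows are 2*40 + 1 = 81 samples
DEFAULT_HALF_WIDTH = 40

WAVE_NAMES = ("P", "Q", "R", "S", "T")


@dataclass(frozen=True)
class BeatMorphology:
    """Gaussian-bump description of one beat.

    ``wave_centers`` are sample offsets of P, Q, R, S, T relative to the
    window centre (the R annotation); ``wave_amplitudes`` are signed peak
    amplitudes in mV; ``wave_widths`` are Gaussian standard deviations in
    samples.
    """

    wave_centers: tuple[float, ...] = (-28.0, -7.0, 0.0, 7.0, 30.0)
    wave_amplitudes: tuple[float, ...] = (0.15, -0.12, 1.20, -0.18, 0.35)
    wave_widths: tuple[float, ...] = (3.5, 1.5, 2.2, 1.8, 6.0)

    def __post_init__(self) -> None:
        c = self.wave_centers
        if not (len(c) == len(self.wave_amplitudes) == len(self.wave_widths) == 5):
            raise ValueError("morphology needs exactly 5 waves (P,Q,R,S,T)")
        if not all(c[i] < c[i + 1] for i in range(4)):
            raise ValueError("wave centers must be ordered P < Q < R < S < T")
        if self.wave_amplitudes[2] <= 0:
            raise ValueError("R amplitude must be positive")
        if self.wave_amplitudes[1] > 0 or self.wave_amplitudes[3] > 0:
            raise ValueError("Q and S amplitudes must be non-positive")


@dataclass(frozen=True)
class RhythmSpec:
    """Beat-to-beat interval model.

    ``base_rr`` is the mean RR interval in samples (300 samples at 360 Hz
    is 72 bpm); ``rr_jitter`` its standard deviation; ``pvc_rr_factor``
    multiplicatively shortens the RR interval that *precedes* a PVC.
    """

    base_rr: float = 300.0
    rr_jitter: float = 25.0
    pvc_rr_factor: float = 0.70

    def __post_init__(self) -> None:
        if not 0.0 < self.pvc_rr_factor < 1.0:
            raise ValueError("pvc_rr_factor must lie in (0, 1)")
        if self.base_rr <= 2 * DEFAULT_HALF_WIDTH + 1:
            raise ValueError("base_rr must exceed the beat window length")


@dataclass
class SyntheticRecord:
    """A generated ECG trace with per-beat ground truth."""

    samples: np.ndarray  # mV
    fs: int
    r_locations: np.ndarray  # sample indices of R annotations
    labels: np.ndarray  # int class codes per beat
    #: absolute sample positions of P,Q,R,S,T for each beat (n_beats, 5);
    #: NaN where the wave is absent for that class
    wave_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.r_locations):
            raise ValueError("labels and r_locations must align")
        if np.any(np.diff(self.r_locations) <= 0):
            raise ValueError("r_locations must be strictly increasing")


# class-dependent morphology adjustments -----------------------------------

#: PVC: no P wave, QRS widened >=2x, deep distinct S notch, discordant T
def pvc_morphology(base: BeatMorphology) -> BeatMorphology:
    c = list(base.wave_centers)
    a = list(base.wave_amplitudes)
    w = list(base.wave_widths)
    a[0] = 0.0  # non-existent P
    a[2] = 0.9 * a[2]
    a[3] = 2.5 * a[3]  # deep S so the wide complex keeps a real notch
    a[4] = -abs(a[4])  # discordant T
    c[3] = c[3] + 5.0  # S pushed right by the broadened R
    w[1] = 2.5 * w[1]
    w[2] = 2.5 * w[2]
    return replace(base, wave_centers=tuple(c), wave_amplitudes=tuple(a),
                   wave_widths=tuple(w))


#: "other": non-conducted P (absent) + notched QRS (second R bump)
def other_morphology(base: BeatMorphology) -> BeatMorphology:
    a = list(base.wave_amplitudes)
    a[0] = 0.0
    a[2] = 0.75 * a[2]
    return replace(base, wave_amplitudes=tuple(a))


#: offset (samples) and relative amplitude of the second R bump of the
#: notched QRS used for the "other" class
NOTCH_OFFSET = 3.5
NOTCH_REL_AMP = 0.85


def class_morphology(cls: int | str, base: BeatMorphology | None = None) -> BeatMorphology:
    """Morphology template for a class code or name."""
    base = base if base is not None else BeatMorphology()
    cls = class_code(cls)
    if cls == NORMAL:
        return base
    if cls == PVC:
        return pvc_morphology(base)
    return other_morphology(base)


def class_code(cls: int | str) -> int:
    if isinstance(cls, str):
        if cls not in CLASS_NAMES:
            raise ValueError(
                f"unknown beat class {cls!r}; expected one of {CLASS_NAMES}"
            )
        return CLASS_NAMES.index(cls)
    if cls not in (NORMAL, PVC, OTHER):
        raise ValueError(f"unknown beat class code {cls!r}; expected 0, 1 or 2")
    return int(cls)


@dataclass(frozen=True)
class MorphJitter:
    """Per-beat morphological variability (fractions / samples)."""

    amp_frac: float = 0.30  # multiplicative amplitude std
    center_sd: float = 3.5  # additive centre std, samples (P and T only)
    width_frac: float = 0.18  # multiplicative width std


def _jittered(morph: BeatMorphology, rng: np.random.Generator,
              jitter: MorphJitter) -> BeatMorphology:
    amps = np.asarray(morph.wave_amplitudes) * (
        1.0 + jitter.amp_frac * rng.standard_normal(5))
    # keep signs/invariants of the template
    signs = np.sign(morph.wave_amplitudes)
    amps = np.where(signs != 0, signs * np.abs(amps), 0.0)
    centers = np.asarray(morph.wave_centers, dtype=float).copy()
    # jitter only P and T centres; QRS stays anchored at the annotation
    centers[0] += jitter.center_sd * rng.standard_normal()
    centers[4] += jitter.center_sd * rng.standard_normal()
    widths = np.asarray(morph.wave_widths) * (
        1.0 + jitter.width_frac * rng.standard_normal(5))
    widths = np.maximum(widths, 0.5)
    return BeatMorphology(tuple(centers), tuple(amps), tuple(widths))


def _render(morph: BeatMorphology, cls: int, half_width: int) -> np.ndarray:
    t = np.arange(-half_width, half_width + 1, dtype=float)
    y = np.zeros_like(t)
    for c, a, w in zip(morph.wave_centers, morph.wave_amplitudes,
                       morph.wave_widths):
        if a != 0.0:
            y += a * np.exp(-0.5 * ((t - c) / w) ** 2)
    if cls == OTHER:
        # notched QRS: second R bump to the right of the main one
        a = morph.wave_amplitudes[2] * NOTCH_REL_AMP
        w = morph.wave_widths[2]
        y += a * np.exp(-0.5 * ((t - (morph.wave_centers[2] + NOTCH_OFFSET)) / w) ** 2)
    return y


def generate_beat(cls: int | str,
                  morph_defaults: BeatMorphology | None = None,
                  seed: int = 0,
                  *,
                  half_width: int = DEFAULT_HALF_WIDTH,
                  jitter: MorphJitter | None = None) -> np.ndarray:
    """One noiseless beat waveform of ``2*half_width + 1`` samples.

    ``jitter=None`` renders the exact class template; passing a
    :class:`MorphJitter` draws one morphological variation from ``seed``.
    Deterministic for fixed arguments.
    """
    code = class_code(cls)
    morph = class_morphology(code, morph_defaults)
    if jitter is not None:
        morph = _jittered(morph, np.random.default_rng(seed), jitter)
    return _render(morph, code, half_width)


def generate_record(n_beats: int,
                    class_mix: tuple[float, float, float] = (0.6, 0.1, 0.3),
                    rhythm: RhythmSpec | None = None,
                    noise_sigma: float = 0.10,
                    seed: int = 0,
                    *,
                    morph: BeatMorphology | None = None,
                    jitter: MorphJitter | None = MorphJitter(),
                    half_width: int = DEFAULT_HALF_WIDTH,
                    fs: int = DEFAULT_FS) -> SyntheticRecord:
    """Generate a labelled multi-beat record.

    Beats are placed at RR-spaced R locations; the RR interval preceding
    each PVC is ``base_rr * pvc_rr_factor`` (plus jitter).  Additive white
    Gaussian noise with standard deviation ``noise_sigma`` (mV) is applied
    to the whole trace.  Deterministic per seed.
    """
    if n_beats < 2:
        raise ValueError("n_beats must be >= 2 (RR ratios undefined otherwise)")
    mix = np.asarray(class_mix, dtype=float)
    if mix.shape != (3,) or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-8:
        raise ValueError("class_mix must be 3 non-negative probabilities summing to 1")
    rhythm = rhythm if rhythm is not None else RhythmSpec()
    rng = np.random.default_rng(seed)

    labels = rng.choice(3, size=n_beats, p=mix)
    # RR interval preceding beat i (i >= 1)
    rr = np.full(n_beats, rhythm.base_rr)
    rr[labels == PVC] *= rhythm.pvc_rr_factor
    rr = rr + rhythm.rr_jitter * rng.standard_normal(n_beats)
    rr = np.maximum(rr, 2 * half_width + 2)  # beats never overlap annotations
    margin = half_width + 1
    r_locations = margin + np.cumsum(np.round(rr)).astype(int)
    n_samples = int(r_locations[-1] + rhythm.base_rr)

    samples = np.zeros(n_samples)
    wave_positions = np.full((n_beats, 5), np.nan)
    for i, (loc, lab) in enumerate(zip(r_locations, labels)):
        m = class_morphology(int(lab), morph)
        if jitter is not None:
            m = _jittered(m, rng, jitter)
        samples[loc - half_width: loc + half_width + 1] += _render(
            m, int(lab), half_width)
        pos = loc + np.asarray(m.wave_centers)
        absent = np.asarray(m.wave_amplitudes) == 0.0
        pos[absent] = np.nan
        wave_positions[i] = pos
    if noise_sigma > 0:
        samples = samples + noise_sigma * rng.standard_normal(n_samples)
    return SyntheticRecord(samples=samples, fs=fs, r_locations=r_locations,
                           labels=labels, wave_positions=wave_positions)


#: physiologic-duration morphology for record-level denoising benchmarks.
#: Beat-window features use compressed wave timing so P and T fit the
#: 81-sample window; wavelet-depth selection, however, depends on the true
#: spectral content of ECG, so denoising experiments use realistic wave
#: durations and placements (P ~100 ms before R, T ~250 ms after, QRS ~30 ms).
DENOISE_TRACE_MORPH = BeatMorphology(
    wave_centers=(-58.0, -12.0, 0.0, 12.0, 90.0),
    wave_amplitudes=(0.15, -0.10, 1.20, -0.20, 0.35),
    wave_widths=(12.0, 3.0, 5.0, 4.0, 22.0),
)


def generate_denoise_trace(n_beats: int = 20, seed: int = 0,
                           rhythm: RhythmSpec | None = None) -> np.ndarray:
    """Clean ECG-like trace with physiologic wave durations.

    Used as the reference signal of denoising experiments (noise is added
    by the caller).  Beats span more than the feature window, which is
    irrelevant here since no segmentation is involved.
    """
    rhythm = rhythm if rhythm is not None else RhythmSpec()
    rng = np.random.default_rng(seed)
    half = 140  # samples rendered on each side of R
    rr = rhythm.base_rr + rhythm.rr_jitter * rng.standard_normal(n_beats)
    locs = half + 1 + np.cumsum(np.round(np.maximum(rr, 2 * half + 2))).astype(int)
    out = np.zeros(int(locs[-1] + rhythm.base_rr))
    wave = _render(DENOISE_TRACE_MORPH, NORMAL, half)
    for loc in locs:
        out[loc - half: loc + half + 1] += wave
    return out


def write_record(record: SyntheticRecord, samples_path, annotations_path) -> None:
    """Write a record as two delimited text files.

    The samples file has one mV value per line; the annotations file has
    ``sample_index,label`` rows — the same minimal schema the WFDB adapter
    emits, so every downstream reader accepts either source.
    """
    np.savetxt(samples_path, record.samples, fmt="%.6f")
    with open(annotations_path, "w") as fh:
        fh.write("sample_index,label\n")
        for loc, lab in zip(record.r_locations, record.labels):
            fh.write(f"{int(loc)},{CLASS_NAMES[int(lab)]}\n")
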