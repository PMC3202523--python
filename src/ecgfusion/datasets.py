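"""End-to-end synthetic dataset construction.

Bundles the full pipeline — record simulation, wavelet denoising,
Savitzky–Golay smoothing, beat segmentation and feature extraction —
into labelled train/validation/test splits.  Training and validation
sets are class-balanced (the study design assigns each class equal
training representation); the test set follows a realistic class mix
dominated by normal beats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import features as _feat
from . import preprocessing as _pre
from . import synthetic as _syn

#: test-set class proportions (normal, pvc, other) echoing the skew of
#: real ambulatory recordings
DEFAULT_TEST_MIX = (0.547, 0.029, 0.424)


@dataclass
class SplitDataset:
    train_X: np.ndarray
    train_y: np.ndarray
    val_X: np.ndarray
    val_y: np.ndarray
    test_X: np.ndarray
    test_y: np.ndarray


def record_to_features(record: _syn.SyntheticRecord,
                       half_width: int = 40,
                       preprocess: bool = True,
                       wavelet_spec: _pre.WaveletSpec | None = None,
                       sg_window: int = 15, sg_order: int = 3
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Denoise, smooth, segment and extract the 11 features per beat."""
    samples = record.samples
    if preprocess:
        spec = wavelet_spec or _pre.WaveletSpec()
        samples = _pre.uwt_denoise(samples, spec).denoised
        samples = _pre.savgol_smooth(samples, sg_window, sg_order)
    windows = _feat.segment_beats(samples, record.r_locations,
                                  half_width=half_width, fs=record.fs,
                                  labels=record.labels)
    return _feat.features_matrix(windows)


def make_split_dataset(n_train_per_class: int = 200,
                       n_val_per_class: int = 50,
                       n_test: int = 3000,
                       test_mix: tuple[float, float, float] = DEFAULT_TEST_MIX,
                       seed: int = 0,
                       noise_sigma: float = 0.10,
                       preprocess: bool = True,
                       half_width: int = 40) -> SplitDataset:
    """Simulate one long record and carve balanced train/val + mixed test.

    The record's generation mix is sized so every class yields enough
    beats; splits are disjoint random subsets drawn from the seeded RNG.
    """
    rng = np.random.default_rng(seed)
    mix = np.asarray(test_mix, dtype=float)
    mix = mix / mix.sum()
    test_counts = np.round(mix * n_test).astype(int)
    test_counts[0] += n_test - test_counts.sum()
    need = test_counts + n_train_per_class + n_val_per_class
    gen_mix = need / need.sum()
    n_beats = int(1.25 * need.sum()) + 4

    for attempt in range(4):
        record = _syn.generate_record(
            n_beats, tuple(gen_mix), noise_sigma=noise_sigma,
            seed=int(rng.integers(2 ** 31)), half_width=half_width)
        X, y = record_to_features(record, half_width=half_width,
                                  preprocess=preprocess)
        counts = np.bincount(y, minlength=3)
        if np.all(counts >= need):
            break
        n_beats = int(1.4 * n_beats)
    else:
        raise RuntimeError("could not generate enough beats per class")

    idx_tr, idx_va, idx_te = [], [], []
    for c in range(3):
        pool = rng.permutation(np.flatnonzero(y == c))
        a = n_train_per_class
        b = a + n_val_per_class
        idx_tr.append(pool[:a])
        idx_va.append(pool[a:b])
        idx_te.append(pool[b:b + test_counts[c]])
    tr = rng.permutation(np.concatenate(idx_tr))
    va = rng.permutation(np.concatenate(idx_va))
    te = rng.permutation(np.concatenate(idx_te))
    return SplitDataset(train_X=X[tr], train_y=y[tr],
                        val_X=X[va], val_y=y[va],
                        test_X=X[te], test_y=y[te])
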