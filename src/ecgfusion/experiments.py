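"""Ensemble comparison experiments.

Drives the full study design: train a pool of diverse base MLPs on a
balanced training set, fit every trainable combiner (decision templates
and PSO weights on the validation set, SG/MSG level-1 networks on the
training set), and score all ten combination methods on a held-out test
set.  Also provides the multi-seed headline comparison of MSG vs SG vs
the best single base classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import fusion as _fusion
from . import stacking as _stack
from .datasets import SplitDataset, make_split_dataset
from .mlp import (BASE_CLASSIFIER_CONFIGS, EXTRA_BASE_CONFIGS, MLPModel,
                  TrainConfig, fit_normalization, train_classifier)
from .stacking import (DEFAULT_COMBINER_EPOCHS, DEFAULT_COMBINER_HIDDEN,
                       DEFAULT_COMBINER_INIT_RANGE, decision_profiles)

METHOD_ORDER = ("max", "min", "mean", "product", "vote", "borda",
                "dt", "pso", "sg", "msg")


def base_configs(n_experts: int, seed: int = 0) -> list[TrainConfig]:
    """The diverse base-classifier pool for 2..5 experts.

    The canonical trio is (17 hidden / 1700 epochs / init range 2),
    (22 / 2700 / 3) and (25 / 2000 / 4); pools of 4-5 add further
    diverse topologies.  Seeds are derived from ``seed`` so each expert
    initializes and visits samples differently.
    """
    pool = list(BASE_CLASSIFIER_CONFIGS) + list(EXTRA_BASE_CONFIGS)
    if not 2 <= n_experts <= len(pool):
        raise ValueError(f"n_experts must be in [2, {len(pool)}]")
    return [replace(cfg, seed=(seed * 101 + i) % (2 ** 31))
            for i, cfg in enumerate(pool[:n_experts])]


def train_bases(data: SplitDataset, cfgs: list[TrainConfig],
                n_classes: int = 3) -> list[MLPModel]:
    norm = fit_normalization(data.train_X)
    return [train_classifier(data.train_X, data.train_y, n_classes, cfg,
                             norm=norm)[0]
            for cfg in cfgs]


def _apply_rowwise(profiles: np.ndarray, fn) -> np.ndarray:
    return np.array([fn(dp) for dp in profiles], dtype=int)


def evaluate_all_methods(data: SplitDataset,
                         cfgs: list[TrainConfig] | None = None,
                         seed: int = 0,
                         combiner_epochs: int = DEFAULT_COMBINER_EPOCHS,
                         pso_cfg: _fusion.PSOConfig | None = None,
                         n_classes: int = 3) -> dict[str, float]:
    """Test accuracy of the ten combination methods plus each base.

    Returns a dict with one entry per method name and ``base_i`` entries
    for the individual classifiers.
    """
    cfgs = cfgs if cfgs is not None else base_configs(3, seed)
    bases = train_bases(data, cfgs, n_classes)
    prof_te = decision_profiles(bases, data.test_X)
    prof_va = decision_profiles(bases, data.val_X)
    y_te = data.test_y

    acc: dict[str, float] = {}
    for i, m in enumerate(bases):
        preds = np.argmax(prof_te[:, i, :], axis=1)
        acc[f"base_{i}"] = float(np.mean(preds == y_te))

    for name in ("max", "min", "mean", "product", "vote", "borda"):
        preds = _apply_rowwise(prof_te, _fusion.SIMPLE_METHODS[name])
        acc[name] = float(np.mean(preds == y_te))

    dts = _fusion.fit_decision_templates(prof_va, data.val_y, n_classes)
    preds = _apply_rowwise(
        prof_te, lambda dp: _fusion.apply_decision_templates(dts, dp)[1])
    acc["dt"] = float(np.mean(preds == y_te))

    pso_cfg = pso_cfg or _fusion.PSOConfig(seed=(seed * 131 + 7) % (2 ** 31))
    w = _fusion.fit_pso_weights(prof_va, data.val_y, pso_cfg)
    supports = np.einsum("l,nlc->nc", w.weights, prof_te)
    acc["pso"] = float(np.mean(np.argmax(supports, axis=1) == y_te))

    L = len(bases)
    for mode in ("sg", "msg"):
        width = DEFAULT_COMBINER_HIDDEN[mode]
        ccfg = TrainConfig(width, combiner_epochs,
                           DEFAULT_COMBINER_INIT_RANGE,
                           seed=(seed * 151 + (13 if mode == "msg" else 11))
                           % (2 ** 31))
        ens = _stack.fit_stacked(data.train_X, data.train_y, cfgs, ccfg,
                                 mode=mode, n_classes=n_classes)
        preds = _stack.predict_ensemble_batch(ens, data.test_X)
        acc[mode] = float(np.mean(preds == y_te))
    return acc


@dataclass
class HeadlineResult:
    """Multi-seed MSG vs SG vs base-classifier comparison.

    Methods are compared at the protocol level: each method's accuracy
    is its mean over seeds, and the single-classifier reference is the
    best *individual classifier* by that same mean — the way published
    per-classifier rates are compared against per-method rates.
    """

    msg: np.ndarray  # per-seed test accuracy
    sg: np.ndarray
    base: np.ndarray  # (n_seeds, L) per-seed, per-classifier accuracy

    @property
    def best_base(self) -> np.ndarray:
        """Per-seed accuracy of the best classifier (by mean accuracy)."""
        return self.base[:, int(np.argmax(self.base.mean(axis=0)))]

    @property
    def best_base_mean(self) -> float:
        return float(self.base.mean(axis=0).max())

    @property
    def msg_wins(self) -> int:
        return int(np.sum(self.msg > self.sg))


def headline_comparison(n_seeds: int = 10,
                        n_train_per_class: int = 200,
                        n_val_per_class: int = 50,
                        n_test: int = 3000,
                        seed: int = 0,
                        combiner_epochs: int = DEFAULT_COMBINER_EPOCHS,
                        n_experts: int = 3) -> HeadlineResult:
    """Repeat the MSG/SG/base comparison over independent seeded runs.

    Each run draws a fresh synthetic dataset and fresh base/combiner
    initializations.
    """
    msg, sg, base = [], [], []
    for k in range(n_seeds):
        run_seed = (seed * 1009 + k) % (2 ** 31)
        data = make_split_dataset(n_train_per_class, n_val_per_class,
                                  n_test, seed=run_seed)
        cfgs = base_configs(n_experts, run_seed)
        bases = train_bases(data, cfgs)
        prof_te = decision_profiles(bases, data.test_X)
        base.append([float(np.mean(np.argmax(prof_te[:, i, :], axis=1)
                                   == data.test_y))
                     for i in range(len(bases))])
        run = {}
        for mode in ("sg", "msg"):
            width = DEFAULT_COMBINER_HIDDEN[mode]
            ccfg = TrainConfig(width, combiner_epochs,
                               DEFAULT_COMBINER_INIT_RANGE,
                               seed=(run_seed + (13 if mode == "msg" else 11))
                               % (2 ** 31))
            ens = _stack.fit_stacked(data.train_X, data.train_y, cfgs, ccfg,
                                     mode=mode, base_models=bases)
            preds = _stack.predict_ensemble_batch(ens, data.test_X)
            run[mode] = float(np.mean(preds == data.test_y))
        msg.append(run["msg"])
        sg.append(run["sg"])
    return HeadlineResult(msg=np.array(msg), sg=np.array(sg),
                          base=np.array(base))


def comparison_grid(expert_counts=(2, 3, 4, 5), seed: int = 0,
                    n_train_per_class: int = 200, n_val_per_class: int = 50,
                    n_test: int = 3000,
                    combiner_epochs: int = DEFAULT_COMBINER_EPOCHS
                    ) -> dict[str, dict[int, float]]:
    """Recognition-rate grid: ten methods x expert counts (percent)."""
    data = make_split_dataset(n_train_per_class, n_val_per_class, n_test,
                              seed=seed)
    grid: dict[str, dict[int, float]] = {m: {} for m in METHOD_ORDER}
    for n_exp in expert_counts:
        acc = evaluate_all_methods(data, base_configs(n_exp, seed), seed=seed,
                                   combiner_epochs=combiner_epochs)
        for m in METHOD_ORDER:
            grid[m][n_exp] = 100.0 * acc[m]
    return grid


def grid_to_text(grid: dict[str, dict[int, float]]) -> str:
    """Delimited methods x expert-counts table."""
    counts = sorted(next(iter(grid.values())).keys())
    lines = ["method," + ",".join(str(c) for c in counts)]
    for m in METHOD_ORDER:
        lines.append(m + "," + ",".join(f"{grid[m][c]:.2f}" for c in counts))
    return "\n".join(lines)
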