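"""Stacked and modified stacked generalization.

Two trainable meta-combiners over a pool of L base MLP classifiers:

* **SG** (stacked generalization): a level-1 MLP maps the flattened
  L x C decision profile (length ``L*C``) to the target class.
* **MSG** (modified stacked generalization): the level-1 MLP receives
  the decision profile *concatenated with the input feature vector*
  (length ``L*C + feature_dim``), so it can learn where in the input
  space each base classifier is reliable and weight their votes
  accordingly — the combiner performs fusion and selection at once.

With 3 base classifiers, 3 classes and 11 beat features the combiner
input is 9 elements for SG and 20 for MSG.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import mlp as _mlp
from .mlp import (MLPModel, TrainConfig, fit_normalization, forward_batch,
                  init_mlp, one_hot, train_backprop)

MODES = ("sg", "msg")

#: default combiner widths found by validation sweeps (3 experts)
DEFAULT_COMBINER_HIDDEN = {"sg": 30, "msg": 45}
DEFAULT_COMBINER_EPOCHS = 2000
DEFAULT_COMBINER_INIT_RANGE = 2.0


@dataclass
class EnsembleModel:
    base_models: list[MLPModel]
    combiner: MLPModel
    mode: str  # "sg" or "msg"
    feature_dim: int
    class_count: int

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        L, C = len(self.base_models), self.class_count
        expect = L * C + (self.feature_dim if self.mode == "msg" else 0)
        if self.combiner.layer_sizes[0] != expect:
            raise ValueError("combiner input width does not match mode")


def build_meta_input(dp: np.ndarray, x: np.ndarray | None, mode: str
                     ) -> np.ndarray:
    """Level-1 input: row-major flattened profile, plus ``x`` for msg."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    dp = np.asarray(dp, dtype=float)
    flat = dp.reshape(-1)
    if mode == "sg":
        return flat
    if x is None:
        raise ValueError("msg mode needs the input feature vector")
    return np.concatenate([flat, np.asarray(x, dtype=float)])


def decision_profiles(base_models: list[MLPModel], X: np.ndarray) -> np.ndarray:
    """Stack of L x C profiles for each row of X; shape (n, L, C)."""
    return np.stack([forward_batch(m, X) for m in base_models], axis=1)


def _meta_matrix(profiles: np.ndarray, Xn: np.ndarray, mode: str) -> np.ndarray:
    flat = profiles.reshape(len(profiles), -1)
    if mode == "sg":
        return flat
    return np.concatenate([flat, Xn], axis=1)


def _oof_profiles(train_X: np.ndarray, train_y: np.ndarray,
                  base_cfgs: list[TrainConfig], n_classes: int,
                  norm: tuple[np.ndarray, np.ndarray], folds: int,
                  seed: int) -> np.ndarray:
    """Out-of-fold decision profiles of the base pool over the training set.

    For each fold, bases are retrained (same configs/seeds) on the fold
    complement and score the fold's samples, so every training sample
    gets base outputs from models that never saw it.
    """
    n = len(train_X)
    if folds < 2 or folds > n:
        raise ValueError("oof_folds must be in [2, n_train]")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    profiles = np.empty((n, len(base_cfgs), n_classes))
    for f in range(folds):
        hold = perm[f::folds]
        fit = np.setdiff1d(perm, hold)
        if len(np.unique(train_y[fit])) < n_classes:
            raise ValueError("a class is absent from a stacking fold")
        for i, cfg in enumerate(base_cfgs):
            m, _ = _mlp.train_classifier(train_X[fit], train_y[fit],
                                         n_classes, cfg, norm=norm)
            profiles[hold, i, :] = forward_batch(m, train_X[hold])
    return profiles


def fit_stacked(train_X: np.ndarray, train_y: np.ndarray,
                base_cfgs: list[TrainConfig],
                combiner_cfg: TrainConfig,
                mode: str = "msg",
                n_classes: int = 3,
                *,
                base_subsets: list[np.ndarray] | None = None,
                stack_X: np.ndarray | None = None,
                stack_y: np.ndarray | None = None,
                oof_folds: int | None = None,
                base_models: list[MLPModel] | None = None) -> EnsembleModel:
    """Train the two-level ensemble.

    Base models train independently on the full training set (or on the
    per-model index subsets in ``base_subsets``, which deliberately
    biases their areas of expertise).  The combiner then trains on the
    meta inputs of the training data — by default in-sample base
    outputs, which at this training scale generalize better than the
    alternatives; ``oof_folds=k`` switches to k-fold out-of-fold base
    outputs (Wolpert's cross-validation recipe) and ``(stack_X,
    stack_y)`` supplies a held-out stacking set.  All randomness is
    carried by the per-config seeds.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if len(base_cfgs) < 2:
        raise ValueError("need at least 2 base classifiers")
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y, dtype=int)
    counts = np.bincount(train_y, minlength=n_classes)
    missing = np.flatnonzero(counts == 0)
    if missing.size:
        raise ValueError(f"classes {missing.tolist()} absent from training data")

    norm = fit_normalization(train_X)
    if base_models is None:
        base_models = []
        for i, cfg in enumerate(base_cfgs):
            if base_subsets is not None:
                idx = np.asarray(base_subsets[i], dtype=int)
                Xi, yi = train_X[idx], train_y[idx]
            else:
                Xi, yi = train_X, train_y
            model, _ = _mlp.train_classifier(Xi, yi, n_classes, cfg, norm=norm)
            base_models.append(model)
    else:
        base_models = list(base_models)

    if stack_X is not None:
        stack_X = np.asarray(stack_X, dtype=float)
        stack_y = np.asarray(stack_y, dtype=int)
        profiles = decision_profiles(base_models, stack_X)
    elif oof_folds is not None and base_subsets is None:
        stack_X, stack_y = train_X, train_y
        profiles = _oof_profiles(train_X, train_y, base_cfgs, n_classes,
                                 norm, oof_folds, combiner_cfg.seed)
    else:
        stack_X, stack_y = train_X, train_y
        profiles = decision_profiles(base_models, stack_X)
    Xn = (stack_X - norm[0]) / norm[1]
    meta_X = _meta_matrix(profiles, Xn, mode)
    meta_T = one_hot(stack_y, n_classes)
    combiner = init_mlp((meta_X.shape[1], combiner_cfg.hidden_neurons,
                         n_classes), combiner_cfg.init_weight_range,
                        combiner_cfg.seed)
    combiner, _ = train_backprop(combiner, meta_X, meta_T, combiner_cfg)
    return EnsembleModel(base_models=base_models, combiner=combiner,
                         mode=mode, feature_dim=train_X.shape[1],
                         class_count=n_classes)


def ensemble_supports(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Combiner class supports for each row of X; shape (n, C)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.feature_dim:
        raise ValueError("input matrix does not match ensemble feature_dim")
    profiles = decision_profiles(model.base_models, X)
    norm_model = model.base_models[0]
    Xn = norm_model.normalize(X)
    meta_X = _meta_matrix(profiles, Xn, model.mode)
    return forward_batch(model.combiner, meta_X)


def predict_ensemble(model: EnsembleModel, x: np.ndarray
                     ) -> tuple[np.ndarray, int]:
    """Class supports and decision for one input (ties: lowest index)."""
    supports = ensemble_supports(model, np.atleast_2d(x))[0]
    return supports, int(np.argmax(supports))


def predict_ensemble_batch(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    return np.argmax(ensemble_supports(model, X), axis=1)


def search_combiner_width(model_or_parts, train_X, train_y, val_X, val_y,
                          widths, mode: str = "msg", n_classes: int = 3,
                          combiner_epochs: int = DEFAULT_COMBINER_EPOCHS,
                          init_weight_range: float = DEFAULT_COMBINER_INIT_RANGE,
                          seed: int = 0) -> tuple[int, dict[int, float]]:
    """Validation sweep over combiner hidden-layer widths.

    ``model_or_parts`` is a list of trained base models (kept fixed).
    One combiner is trained per width; returns the width with the best
    validation accuracy (smaller width on ties) plus the full table.
    """
    widths = list(widths)
    if not widths:
        raise ValueError("widths must be non-empty")
    val_X = np.asarray(val_X, dtype=float)
    val_y = np.asarray(val_y, dtype=int)
    if len(val_X) == 0:
        raise ValueError("validation set must be non-empty")
    base_models = list(model_or_parts)
    train_X = np.asarray(train_X, dtype=float)
    norm_model = base_models[0]
    Xn = norm_model.normalize(train_X)
    meta_X = _meta_matrix(decision_profiles(base_models, train_X), Xn, mode)
    meta_T = one_hot(np.asarray(train_y, int), n_classes)
    meta_val = _meta_matrix(decision_profiles(base_models, val_X),
                            norm_model.normalize(val_X), mode)
    table: dict[int, float] = {}
    for w in widths:
        cfg = TrainConfig(w, combiner_epochs, init_weight_range, seed)
        comb = init_mlp((meta_X.shape[1], w, n_classes),
                        init_weight_range, seed)
        comb, _ = train_backprop(comb, meta_X, meta_T, cfg)
        preds = np.argmax(forward_batch(comb, meta_val), axis=1)
        table[w] = float(np.mean(preds == val_y))
    best = max(sorted(table), key=lambda w: table[w])
    # sorted + max keeps the smallest width on exact ties
    return best, table


# serialization -------------------------------------------------------------

def save_ensemble(model: EnsembleModel, path, run_config: dict | None = None
                  ) -> None:
    """JSON serialization; ``run_config`` is echoed in for provenance."""
    def _m(m: MLPModel) -> dict:
        return {
            "w_hidden": m.w_hidden.tolist(), "w_out": m.w_out.tolist(),
            "activation": m.activation,
            "norm_mean": None if m.norm_mean is None else m.norm_mean.tolist(),
            "norm_std": None if m.norm_std is None else m.norm_std.tolist(),
        }

    doc = {
        "format": "ecgfusion-ensemble-v1",
        "mode": model.mode,
        "feature_dim": model.feature_dim,
        "class_count": model.class_count,
        "base_models": [_m(m) for m in model.base_models],
        "combiner": _m(model.combiner),
        "run_config": run_config,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_ensemble(path) -> EnsembleModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "ecgfusion-ensemble-v1":
        raise ValueError("not an ecgfusion ensemble file")

    def _m(d: dict) -> MLPModel:
        return MLPModel(
            w_hidden=np.array(d["w_hidden"]), w_out=np.array(d["w_out"]),
            activation=d["activation"],
            norm_mean=None if d["norm_mean"] is None else np.array(d["norm_mean"]),
            norm_std=None if d["norm_std"] is None else np.array(d["norm_std"]),
        )

    return EnsembleModel(
        base_models=[_m(d) for d in doc["base_models"]],
        combiner=_m(doc["combiner"]), mode=doc["mode"],
        feature_dim=doc["feature_dim"], class_count=doc["class_count"],
    )
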