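"""Classifier-fusion rules over decision profiles.

A *decision profile* for one input is the L x C matrix ``dp[i, j]`` of
the support classifier ``i`` gives class ``j`` (values in [0, 1]).  This
module implements the non-trainable combiners — mean/sum, minimum,
maximum, median, product, majority voting and Borda count — plus two
trainable ones: decision templates (class-wise mean profiles compared by
normalized squared Euclidean distance) and weighted averaging with the
weight vector optimized by gbest particle swarm optimization against
validation error.

Every combiner resolves ties the same way: the lowest class index wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


def _check_profile(dp) -> np.ndarray:
    dp = np.asarray(dp, dtype=float)
    if dp.ndim != 2 or dp.size == 0:
        raise ValueError("decision profile must be a non-empty L x C matrix")
    return dp


def _decide(supports: np.ndarray) -> int:
    # ties resolve to the lowest class index (np.argmax convention)
    return int(np.argmax(supports))


def combine_mean(dp) -> tuple[np.ndarray, int]:
    dp = _check_profile(dp)
    s = dp.mean(axis=0)
    return s, _decide(s)


def combine_min(dp) -> tuple[np.ndarray, int]:
    dp = _check_profile(dp)
    s = dp.min(axis=0)
    return s, _decide(s)


def combine_max(dp) -> tuple[np.ndarray, int]:
    dp = _check_profile(dp)
    s = dp.max(axis=0)
    return s, _decide(s)


def combine_median(dp) -> tuple[np.ndarray, int]:
    dp = _check_profile(dp)
    s = np.median(dp, axis=0)
    return s, _decide(s)


def combine_product(dp) -> tuple[np.ndarray, int]:
    dp = _check_profile(dp)
    s = dp.prod(axis=0)
    return s, _decide(s)


def majority_vote(dp) -> int:
    """Each classifier votes its argmax; most votes wins (ties: lowest)."""
    dp = _check_profile(dp)
    votes = np.argmax(dp, axis=1)
    counts = np.bincount(votes, minlength=dp.shape[1])
    return _decide(counts)


def borda_count(dp) -> tuple[np.ndarray, int]:
    """Rank-based fusion: within each row the best class earns C-1
    points down to 0 for the last place; within-row support ties share
    the average of the contested point values.  Points are summed over
    classifiers and the class with the most points wins."""
    dp = _check_profile(dp)
    # rankdata is ascending and averages ties: rank 1 = worst -> 0 points
    points = rankdata(dp, axis=1, method="average") - 1.0
    votes = points.sum(axis=0)
    return votes, _decide(votes)


# decision templates --------------------------------------------------------

@dataclass
class DecisionTemplateSet:
    """Per-class mean decision profiles from labelled training data."""

    templates: np.ndarray  # (C, L, C)
    class_counts: np.ndarray  # (C,)


def fit_decision_templates(profiles, labels, n_classes: int
                           ) -> DecisionTemplateSet:
    """Element-wise mean profile of each true class."""
    profiles = np.asarray(profiles, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if profiles.ndim != 3:
        raise ValueError("profiles must have shape (n, L, C)")
    counts = np.bincount(labels, minlength=n_classes)
    for j in range(n_classes):
        if counts[j] == 0:
            raise ValueError(f"class {j} has no training instances")
    templates = np.stack([profiles[labels == j].mean(axis=0)
                          for j in range(n_classes)])
    return DecisionTemplateSet(templates=templates, class_counts=counts[:n_classes])


def apply_decision_templates(dts: DecisionTemplateSet, dp
                             ) -> tuple[np.ndarray, int]:
    """Similarity 1 - mean squared difference to each template; argmax wins.

    The normalized squared Euclidean distance over the L*C cells is
    subtracted from 1 so the score is a bounded similarity; the argmax
    over similarity equals the argmin over distance.
    """
    dp = _check_profile(dp)
    if dts.templates.shape[1:] != dp.shape:
        raise ValueError("profile shape does not match the fitted templates")
    sims = 1.0 - np.mean((dts.templates - dp[None]) ** 2, axis=(1, 2))
    return sims, _decide(sims)


# PSO-weighted averaging ----------------------------------------------------

@dataclass(frozen=True)
class PSOConfig:
    swarm_size: int = 30
    iterations: int = 100
    inertia: float = 0.72
    c1: float = 1.49
    c2: float = 1.49
    v_max: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.swarm_size, self.iterations) < 1:
            raise ValueError("swarm_size and iterations must be >= 1")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("acceleration constants must be positive")
        if self.inertia <= 0 or self.v_max <= 0:
            raise ValueError("inertia and v_max must be positive")


def pso_minimize(objective, dim: int, cfg: PSOConfig = PSOConfig(),
                 init_range: tuple[float, float] = (-1.0, 1.0)
                 ) -> tuple[np.ndarray, float, np.ndarray]:
    """gbest particle swarm minimization.

    Velocity update ``v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x)``
    with per-dimension clamping to ``+-v_max``; positions move by the
    velocity.  A particle whose objective is non-finite is skipped for
    that iteration (with a warning) and reset to its personal best.
    Returns (best position, best value, per-iteration best-value trace).
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    lo, hi = init_range
    x = rng.uniform(lo, hi, size=(cfg.swarm_size, dim))
    v = np.zeros_like(x)
    pbest = x.copy()
    pbest_val = np.empty(cfg.swarm_size)
    for i in range(cfg.swarm_size):
        val = float(objective(x[i]))
        pbest_val[i] = val if np.isfinite(val) else np.inf
    g = int(np.argmin(pbest_val))
    gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])
    trace = np.empty(cfg.iterations)
    for it in range(cfg.iterations):
        r1 = rng.random((cfg.swarm_size, dim))
        r2 = rng.random((cfg.swarm_size, dim))
        v = (cfg.inertia * v + cfg.c1 * r1 * (pbest - x)
             + cfg.c2 * r2 * (gbest - x))
        np.clip(v, -cfg.v_max, cfg.v_max, out=v)
        x = x + v
        for i in range(cfg.swarm_size):
            val = float(objective(x[i]))
            if not np.isfinite(val):
                warnings.warn("non-finite objective value; particle reset "
                              "to its personal best")
                x[i] = pbest[i]
                continue
            if val < pbest_val[i]:
                pbest_val[i] = val
                pbest[i] = x[i].copy()
                if val < gbest_val:
                    gbest_val = val
                    gbest = x[i].copy()
        trace[it] = gbest_val
    return gbest, gbest_val, trace


@dataclass
class WeightVector:
    """Non-negative classifier weights summing to one."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must be non-negative and sum to 1")
        self.weights = w


def _simplex(raw: np.ndarray) -> np.ndarray:
    w = np.clip(raw, 0.0, None)
    s = w.sum()
    if s == 0:
        return np.full_like(w, 1.0 / len(w))
    return w / s


def fit_pso_weights(base_outputs_val: np.ndarray, labels_val,
                    cfg: PSOConfig = PSOConfig()) -> WeightVector:
    """Weights minimizing validation error of the weighted-average rule.

    ``base_outputs_val`` has shape (n, L, C).  Candidate positions are
    mapped onto the simplex (clip to >= 0, renormalize) before scoring,
    and the returned optimum is mapped the same way.
    """
    P = np.asarray(base_outputs_val, dtype=float)
    y = np.asarray(labels_val, dtype=int)
    if P.ndim != 3 or len(P) == 0:
        raise ValueError("need a non-empty (n, L, C) validation profile stack")
    L = P.shape[1]

    def err(raw):
        w = _simplex(np.asarray(raw, dtype=float))
        supports = np.einsum("l,nlc->nc", w, P)
        return float(np.mean(np.argmax(supports, axis=1) != y))

    best, _, _ = pso_minimize(err, dim=L, cfg=cfg, init_range=(0.0, 1.0))
    return WeightVector(_simplex(best))


def combine_weighted(dp, w: WeightVector) -> tuple[np.ndarray, int]:
    dp = _check_profile(dp)
    weights = w.weights if isinstance(w, WeightVector) else np.asarray(w, float)
    if len(weights) != dp.shape[0]:
        raise ValueError("weight vector length must equal the classifier count")
    s = weights @ dp
    return s, _decide(s)


# dispatch ------------------------------------------------------------------

#: methods applicable to a bare decision profile (no training state)
SIMPLE_METHODS = {
    "mean": lambda dp: combine_mean(dp)[1],
    "min": lambda dp: combine_min(dp)[1],
    "max": lambda dp: combine_max(dp)[1],
    "median": lambda dp: combine_median(dp)[1],
    "product": lambda dp: combine_product(dp)[1],
    "median": lambda dp: combine_median(dp)[1],
    "vote": majority_vote,
    "borda": lambda dp: borda_count(dp)[1],
}

ALL_METHODS = ("max", "min", "mean", "product", "vote", "borda",
               "dt", "pso", "sg", "msg")


def combine(method: str, dp, *, dts: DecisionTemplateSet | None = None,
            weights: WeightVector | None = None) -> int:
    """Single-profile dispatch for the stateless and fitted combiners.

    ``dt`` requires a fitted :class:`DecisionTemplateSet`; ``pso``
    requires a fitted :class:`WeightVector`.  The trainable ``sg``/``msg``
    combiners live in :mod:`ecgfusion.stacking` since they also consume
    the input features.
    """
    if method in SIMPLE_METHODS:
        return SIMPLE_METHODS[method](dp)
    if method == "dt":
        if dts is None:
            raise ValueError("method 'dt' needs a fitted DecisionTemplateSet")
        return apply_decision_templates(dts, dp)[1]
    if method == "pso":
        if weights is None:
            raise ValueError("method 'pso' needs a fitted WeightVector")
        return combine_weighted(dp, weights)[1]
    raise ValueError(f"unknown combination method {method!r}")
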