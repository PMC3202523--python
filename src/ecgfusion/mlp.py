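"""From-scratch multilayer perceptron with online backpropagation.

A single-hidden-layer, fully connected network with logistic-sigmoid
units throughout, trained by plain per-sample gradient descent on the
squared error ``E = 1/2 * sum_k (t_k - o_k)^2`` — no momentum, no
adaptive optimizers.  The same implementation serves as a base
classifier and as the level-1 combiner of the stacked ensembles.

The hot training loop is compiled with numba; the backprop arithmetic is
mirrored in :func:`gradients` (pure numpy), which the test suite checks
against central finite differences and against single kernel steps.

Input normalization (per-feature z-scoring fitted on the training set)
is stored inside the model so that serialized models are self-contained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one backprop run."""

    hidden_neurons: int
    epochs: int
    init_weight_range: float  # weights drawn uniformly from [-r, r]
    seed: int = 0
    learning_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.hidden_neurons < 1 or self.epochs < 1:
            raise ValueError("hidden_neurons and epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.init_weight_range <= 0:
            raise ValueError("init_weight_range must be positive")


#: the three diverse base-classifier configurations used throughout:
#: (hidden neurons, epochs, initial-weight range)
BASE_CLASSIFIER_CONFIGS = (
    TrainConfig(hidden_neurons=17, epochs=1700, init_weight_range=2.0),
    TrainConfig(hidden_neurons=22, epochs=2700, init_weight_range=3.0),
    TrainConfig(hidden_neurons=25, epochs=2000, init_weight_range=4.0),
)
#: additional diverse configurations for ensembles of 4 or 5 experts
EXTRA_BASE_CONFIGS = (
    TrainConfig(hidden_neurons=12, epochs=1500, init_weight_range=2.0),
    TrainConfig(hidden_neurons=30, epochs=2200, init_weight_range=3.0),
)


@dataclass
class MLPModel:
    """Weights of an input–hidden–output sigmoid network.

    ``w_hidden`` has shape (hidden, n_in + 1) and ``w_out`` shape
    (n_out, hidden + 1); the last column of each is the bias.
    """

    w_hidden: np.ndarray
    w_out: np.ndarray
    activation: str = "sigmoid"
    norm_mean: np.ndarray | None = None
    norm_std: np.ndarray | None = None

    @property
    def layer_sizes(self) -> tuple[int, int, int]:
        return (self.w_hidden.shape[1] - 1, self.w_hidden.shape[0],
                self.w_out.shape[0])

    def normalize(self, X: np.ndarray) -> np.ndarray:
        if self.norm_mean is None:
            return X
        return (X - self.norm_mean) / self.norm_std


def fit_normalization(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean/std for z-scoring; zero stds are clamped to 1."""
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    return mean, std


def init_mlp(layer_sizes: tuple[int, int, int], init_weight_range: float,
             seed: int, norm: tuple[np.ndarray, np.ndarray] | None = None
             ) -> MLPModel:
    """Fresh model with i.i.d. uniform weights on [-r, r]."""
    if init_weight_range <= 0:
        raise ValueError("init_weight_range must be positive")
    d, h, c = layer_sizes
    rng = np.random.default_rng(seed)
    w1 = rng.uniform(-init_weight_range, init_weight_range, size=(h, d + 1))
    w2 = rng.uniform(-init_weight_range, init_weight_range, size=(c, h + 1))
    mean, std = (None, None) if norm is None else norm
    return MLPModel(w_hidden=w1, w_out=w2, norm_mean=mean, norm_std=std)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def forward(model: MLPModel, x: np.ndarray) -> np.ndarray:
    """Class-support vector for one input (sigmoid outputs in (0,1))."""
    x = np.asarray(x, dtype=float)
    d = model.layer_sizes[0]
    if x.shape != (d,):
        raise ValueError(f"input has shape {x.shape}, model expects ({d},)")
    x = model.normalize(x)
    a1 = _sigmoid(model.w_hidden[:, :-1] @ x + model.w_hidden[:, -1])
    return _sigmoid(model.w_out[:, :-1] @ a1 + model.w_out[:, -1])


def forward_batch(model: MLPModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.layer_sizes[0]:
        raise ValueError("input matrix does not match model input size")
    Xn = model.normalize(X)
    A1 = _sigmoid(Xn @ model.w_hidden[:, :-1].T + model.w_hidden[:, -1])
    return _sigmoid(A1 @ model.w_out[:, :-1].T + model.w_out[:, -1])


def predict_class(model: MLPModel, x: np.ndarray) -> int:
    """Argmax of the supports; ties resolve to the lowest class index."""
    return int(np.argmax(forward(model, x)))


def predict_batch(model: MLPModel, X: np.ndarray) -> np.ndarray:
    return np.argmax(forward_batch(model, X), axis=1)


def gradients(model: MLPModel, x: np.ndarray, t: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    """Backprop gradients of E = 1/2 ||o - t||^2 for one (x, t) pair.

    Pure-numpy mirror of the training kernel; used for gradient checks.
    ``x`` is taken as already normalized.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    z1 = model.w_hidden[:, :-1] @ x + model.w_hidden[:, -1]
    a1 = _sigmoid(z1)
    z2 = model.w_out[:, :-1] @ a1 + model.w_out[:, -1]
    o = _sigmoid(z2)
    delta2 = (o - t) * o * (1.0 - o)
    delta1 = (model.w_out[:, :-1].T @ delta2) * a1 * (1.0 - a1)
    g2 = np.concatenate([np.outer(delta2, a1), delta2[:, None]], axis=1)
    g1 = np.concatenate([np.outer(delta1, x), delta1[:, None]], axis=1)
    return g1, g2


@njit(cache=False)
def _train_kernel(W1, W2, X, T, order, lr):  # pragma: no cover - compiled
    n, d = X.shape
    h = W1.shape[0]
    c = W2.shape[0]
    epochs = order.shape[0]
    errors = np.zeros(epochs)
    a1 = np.zeros(h)
    o = np.zeros(c)
    d2 = np.zeros(c)
    d1 = np.zeros(h)
    for e in range(epochs):
        err = 0.0
        for s in range(n):
            i = order[e, s]
            # forward
            for j in range(h):
                z = W1[j, d]
                for k in range(d):
                    z += W1[j, k] * X[i, k]
                a1[j] = 1.0 / (1.0 + np.exp(-z))
            for j in range(c):
                z = W2[j, h]
                for k in range(h):
                    z += W2[j, k] * a1[k]
                o[j] = 1.0 / (1.0 + np.exp(-z))
            # backward
            for j in range(c):
                diff = o[j] - T[i, j]
                err += 0.5 * diff * diff
                d2[j] = diff * o[j] * (1.0 - o[j])
            for k in range(h):
                acc = 0.0
                for j in range(c):
                    acc += W2[j, k] * d2[j]
                d1[k] = acc * a1[k] * (1.0 - a1[k])
            for j in range(c):
                for k in range(h):
                    W2[j, k] -= lr * d2[j] * a1[k]
                W2[j, h] -= lr * d2[j]
            for j in range(h):
                for k in range(d):
                    W1[j, k] -= lr * d1[j] * X[i, k]
                W1[j, d] -= lr * d1[j]
        errors[e] = err
    return errors


def train_backprop(model: MLPModel, X: np.ndarray, T: np.ndarray,
                   cfg: TrainConfig) -> tuple[MLPModel, np.ndarray]:
    """Online gradient descent for exactly ``cfg.epochs`` epochs.

    The per-epoch visiting order is a seeded permutation, so training is
    bit-reproducible for a fixed config.  Returns the trained model and
    the per-epoch squared-error trace (summed over samples as visited).
    """
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    if len(X) == 0:
        raise ValueError("training set must be non-empty")
    if len(X) != len(T):
        raise ValueError("X and T must have equal length")
    Xn = model.normalize(X)
    rng = np.random.default_rng(cfg.seed)
    order = np.stack([rng.permutation(len(X)) for _ in range(cfg.epochs)])
    W1 = model.w_hidden.copy()
    W2 = model.w_out.copy()
    errors = _train_kernel(W1, W2, np.ascontiguousarray(Xn),
                           np.ascontiguousarray(T),
                           order.astype(np.int64), cfg.learning_rate)
    trained = MLPModel(w_hidden=W1, w_out=W2, activation=model.activation,
                       norm_mean=model.norm_mean, norm_std=model.norm_std)
    return trained, errors


def train_classifier(X: np.ndarray, y: np.ndarray, n_classes: int,
                     cfg: TrainConfig,
                     norm: tuple[np.ndarray, np.ndarray] | None = None
                     ) -> tuple[MLPModel, np.ndarray]:
    """Convenience wrapper: one-hot encode, init from cfg, train."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    T = one_hot(y, n_classes)
    if norm is None:
        norm = fit_normalization(X)
    model = init_mlp((X.shape[1], cfg.hidden_neurons, n_classes),
                     cfg.init_weight_range, cfg.seed, norm=norm)
    return train_backprop(model, X, T, cfg)


def one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if np.any((y < 0) | (y >= n_classes)):
        raise ValueError("labels out of range for one-hot encoding")
    T = np.zeros((len(y), n_classes))
    T[np.arange(len(y)), y] = 1.0
    return T


def early_stopping_epochs(X, y, Xval, yval, n_classes: int, cfg: TrainConfig,
                          eval_every: int = 100) -> tuple[int, np.ndarray]:
    """Cross-validation style epoch selection (optional utility).

    Trains in chunks of ``eval_every`` epochs up to ``cfg.epochs``,
    scoring validation accuracy after each chunk; returns the epoch count
    with the best validation accuracy (earliest on ties) and the
    accuracy curve.
    """
    T = one_hot(np.asarray(y, int), n_classes)
    norm = fit_normalization(np.asarray(X, float))
    model = init_mlp((X.shape[1], cfg.hidden_neurons, n_classes),
                     cfg.init_weight_range, cfg.seed, norm=norm)
    accs = []
    checkpoints = list(range(eval_every, cfg.epochs + 1, eval_every))
    for _ in checkpoints:
        chunk = TrainConfig(cfg.hidden_neurons, eval_every,
                            cfg.init_weight_range, cfg.seed,
                            cfg.learning_rate)
        model, _ = train_backprop(model, X, T, chunk)
        accs.append(float(np.mean(predict_batch(model, Xval) == yval)))
    accs = np.asarray(accs)
    best = int(np.argmax(accs))
    return checkpoints[best], accs


# serialization -------------------------------------------------------------

def save_model(model: MLPModel, path) -> None:
    """Loss-free structured-text (JSON) serialization."""
    doc = {
        "format": "ecgfusion-mlp-v1",
        "activation": model.activation,
        "w_hidden": model.w_hidden.tolist(),
        "w_out": model.w_out.tolist(),
        "norm_mean": None if model.norm_mean is None else model.norm_mean.tolist(),
        "norm_std": None if model.norm_std is None else model.norm_std.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> MLPModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "ecgfusion-mlp-v1":
        raise ValueError("not an ecgfusion MLP model file")
    return MLPModel(
        w_hidden=np.array(doc["w_hidden"]),
        w_out=np.array(doc["w_out"]),
        activation=doc["activation"],
        norm_mean=None if doc["norm_mean"] is None else np.array(doc["norm_mean"]),
        norm_std=None if doc["norm_std"] is None else np.array(doc["norm_std"]),
    )
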