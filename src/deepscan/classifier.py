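"""Feed-forward vessel/non-vessel classifier.

A small dense network — by default input -> 10 -> 8 -> 6 -> 1 with tanh
hidden units and a sigmoid output — trained with full-batch Adam on binary
cross-entropy, with early stopping on a seeded validation split. The network
is deliberately tiny: its input is a standardized 32x32 spectrogram patch
whose classes are nearly linearly separable, and a shallow net keeps scans
cheap and training reproducible. All arithmetic is plain NumPy, so identical
seeds give bit-identical weights.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import FeatureWindow, TrainingSet

logger = logging.getLogger(__name__)

__all__ = ["ClassifierModel", "init_network", "train", "predict"]

DEFAULT_HIDDEN = (10, 8, 6)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class ClassifierModel:
    """Weights, biases and training provenance of the dense network."""

    layer_sizes: list[int]
    input_dim: int
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    activation: str = "tanh"
    threshold: float = 0.5
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        dims = [self.input_dim, *self.layer_sizes, 1]
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (dims[i + 1], dims[i]) or b.shape != (dims[i + 1],):
                raise ValueError(
                    f"layer {i}: weight shape {w.shape} / bias shape {b.shape} "
                    f"inconsistent with architecture {dims}"
                )

    @property
    def n_parameters(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Scores in [0, 1] for a (n, input_dim) batch."""
        a = X
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.tanh(a @ w.T + b)
        z = a @ self.weights[-1].T + self.biases[-1]
        return _sigmoid(z)[:, 0]

    def save(self, path: str | Path) -> None:
        """Serialize to JSON (weights stored as nested lists)."""
        payload = {
            "layer_sizes": self.layer_sizes,
            "input_dim": self.input_dim,
            "activation": self.activation,
            "threshold": self.threshold,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "training_meta": self.training_meta,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        d = json.loads(Path(path).read_text())
        return cls(
            layer_sizes=list(d["layer_sizes"]),
            input_dim=int(d["input_dim"]),
            weights=[np.asarray(w, dtype=np.float64) for w in d["weights"]],
            biases=[np.asarray(b, dtype=np.float64) for b in d["biases"]],
            activation=d.get("activation", "tanh"),
            threshold=float(d.get("threshold", 0.5)),
            training_meta=d.get("training_meta", {}),
        )


def init_network(
    layer_sizes: list[int] | tuple[int, ...] = DEFAULT_HIDDEN,
    input_dim: int = 1024,
    seed: int = 0,
) -> ClassifierModel:
    """Seeded Glorot-uniform initialization of the dense network."""
    layer_sizes = list(layer_sizes)
    if not layer_sizes:
        raise ValueError("at least one hidden layer is required")
    if any(s < 1 for s in layer_sizes):
        raise ValueError("hidden layer widths must be >= 1")
    rng = np.random.default_rng(seed)
    dims = [input_dim, *layer_sizes, 1]
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_out, fan_in)))
        biases.append(np.zeros(fan_out))
    return ClassifierModel(layer_sizes, input_dim, weights, biases,
                           training_meta={"init_seed": seed})


def _forward_cached(model: ClassifierModel, X: np.ndarray):
    acts = [X]
    a = X
    for w, b in zip(model.weights[:-1], model.biases[:-1]):
        a = np.tanh(a @ w.T + b)
        acts.append(a)
    z = a @ model.weights[-1].T + model.biases[-1]
    p = _sigmoid(z)[:, 0]
    return acts, p


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


def train(
    model: ClassifierModel,
    data: TrainingSet,
    epochs: int = 3000,
    learning_rate: float = 0.01,
    validation_fraction: float = 0.2,
    seed: int = 0,
    patience: int = 300,
) -> ClassifierModel:
    """Train with full-batch Adam and early stopping; returns a new model.

    The validation split is seeded; the best-validation-loss weights are
    restored at the end. Training metadata (seed, epochs run, loss history,
    split sizes) is recorded on the returned model.
    """
    X, y = data.X, data.y
    if not np.all(np.isfinite(X)):
        raise ValueError("training features contain non-finite values")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present in the training set")

    rng = np.random.default_rng(seed)
    n = len(y)
    order = rng.permutation(n)
    n_val = int(round(validation_fraction * n))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    weights = [w.copy() for w in model.weights]
    biases = [b.copy() for b in model.biases]
    m_w = [np.zeros_like(w) for w in weights]
    v_w = [np.zeros_like(w) for w in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    work = ClassifierModel(model.layer_sizes, model.input_dim, weights, biases,
                           threshold=model.threshold)
    loss_history: list[float] = []
    best_val = np.inf
    best = ([w.copy() for w in weights], [b.copy() for b in biases])
    best_epoch = 0
    since_best = 0

    for epoch in range(1, epochs + 1):
        acts, p = _forward_cached(work, Xtr)
        loss_history.append(_bce(p, ytr))
        delta = (p - ytr)[:, np.newaxis] / len(ytr)  # sigmoid+BCE gradient
        for li in range(len(weights) - 1, -1, -1):
            gw = delta.T @ acts[li]
            gb = delta.sum(axis=0)
            if li > 0:
                delta = (delta @ weights[li]) * (1.0 - acts[li] ** 2)
            t = epoch
            for g, theta, m, v in ((gw, weights[li], m_w[li], v_w[li]),
                                   (gb, biases[li], m_b[li], v_b[li])):
                m[...] = beta1 * m + (1 - beta1) * g
                v[...] = beta2 * v + (1 - beta2) * g * g
                mhat = m / (1 - beta1**t)
                vhat = v / (1 - beta2**t)
                theta -= learning_rate * mhat / (np.sqrt(vhat) + eps)

        if len(yval):
            val_loss = _bce(work.forward(Xval), yval)
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best = ([w.copy() for w in weights], [b.copy() for b in biases])
                best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= patience:
                    break

    if len(yval):
        weights, biases = best
    trained = ClassifierModel(
        model.layer_sizes,
        model.input_dim,
        weights,
        biases,
        activation=model.activation,
        threshold=model.threshold,
        training_meta={
            **model.training_meta,
            "train_seed": seed,
            "epochs_run": len(loss_history),
            "best_epoch": best_epoch,
            "learning_rate": learning_rate,
            "n_train": int(len(ytr)),
            "n_val": int(len(yval)),
            "loss_history": loss_history,
            "best_val_loss": None if not len(yval) else best_val,
        },
    )
    return trained


def predict(model: ClassifierModel, feature: FeatureWindow | np.ndarray) -> float:
    """Vessel score in [0, 1] for one feature window."""
    x = feature.flat() if isinstance(feature, FeatureWindow) else np.ravel(feature)
    if x.size != model.input_dim:
        raise ValueError(
            f"feature has {x.size} values; model expects {model.input_dim}"
        )
    return float(model.forward(x[np.newaxis, :])[0])
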