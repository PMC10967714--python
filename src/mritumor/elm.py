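"""Extreme learning machine: a single-hidden-layer network whose input
weights and biases are drawn once at random and frozen, and whose output
weights are solved in closed form.

Given n training samples with d features, the hidden representation is
H[l, k] = t(w_k . x_l + b_k) with activation t and H hidden nodes; the
output weights alpha solve min ||H alpha - O|| for one-hot targets O via
the Moore-Penrose pseudoinverse (or a ridge-regularized normal-equation
solve). When H equals the number of distinct samples and ridge is 0 the
system is generically square and full-rank, so the network interpolates
the targets exactly ("zero errors"). Prediction is the argmax of the
decision scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ELMModel",
    "TrainConfig",
    "hidden_matrix",
    "train",
    "decision_scores",
    "predict",
]

_ACTIVATIONS = {
    "sigmoid": lambda u: 1.0 / (1.0 + np.exp(-u)),
    "tanh": np.tanh,
    "relu": lambda u: np.maximum(u, 0.0),
}


@dataclass
class TrainConfig:
    """Hidden-layer size and training options.

    The hidden node count should stay below the sample count (set
    ``allow_H_ge_n`` to lift the check, e.g. for exact interpolation
    with H = n).
    """

    H: int | None = None  # default min(100, n - 1) at train time
    activation: str = "sigmoid"
    seed: int = 0
    ridge: float = 0.0
    allow_H_ge_n: bool = False

    def validate(self) -> None:
        if self.H is not None and self.H < 1:
            raise ValueError("H must be >= 1")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation: {self.activation!r}")
        if self.ridge < 0:
            raise ValueError("ridge must be non-negative")


@dataclass
class ELMModel:
    """Frozen random hidden layer plus solved output weights."""

    W_in: np.ndarray  # H x d
    b: np.ndarray  # length H
    alpha: np.ndarray  # H x C
    activation: str
    classes: np.ndarray  # ordered labels (sorted unique training labels)
    seed: int
    ridge: float
    scaler_lo: np.ndarray  # per-feature training min
    scaler_hi: np.ndarray  # per-feature training max

    def scale(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = self.scaler_hi - self.scaler_lo
        span = np.where(span > 0, span, 1.0)
        return (X - self.scaler_lo) / span

    def to_json(self, path: str | Path) -> None:
        blob = {
            "W_in": self.W_in.tolist(),
            "b": self.b.tolist(),
            "alpha": self.alpha.tolist(),
            "activation": self.activation,
            "classes": [str(c) for c in self.classes],
            "seed": int(self.seed),
            "ridge": float(self.ridge),
            "scaler_lo": self.scaler_lo.tolist(),
            "scaler_hi": self.scaler_hi.tolist(),
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def from_json(cls, path: str | Path) -> "ELMModel":
        blob = json.loads(Path(path).read_text())
        return cls(
            W_in=np.asarray(blob["W_in"], float),
            b=np.asarray(blob["b"], float),
            alpha=np.asarray(blob["alpha"], float),
            activation=blob["activation"],
            classes=np.asarray(blob["classes"]),
            seed=blob["seed"],
            ridge=blob["ridge"],
            scaler_lo=np.asarray(blob["scaler_lo"], float),
            scaler_hi=np.asarray(blob["scaler_hi"], float),
        )


def hidden_matrix(
    X: np.ndarray, W_in: np.ndarray, b: np.ndarray, activation: str = "sigmoid"
) -> np.ndarray:
    """Hidden representation H[l, k] = t(w_k . x_l + b_k)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != W_in.shape[1]:
        raise ValueError(
            f"feature count {X.shape[1]} != model dimension {W_in.shape[1]}"
        )
    return _ACTIVATIONS[activation](X @ W_in.T + b)


def train(X: np.ndarray, y, cfg: TrainConfig | None = None) -> ELMModel:
    """Fit the ELM: min-max scale, random [-1, 1] layer, least-squares alpha.

    Deterministic for a fixed (X, y, cfg, seed).
    """
    cfg = cfg or TrainConfig()
    cfg.validate()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    n, d = X.shape
    classes = np.unique(y)
    C = classes.size
    if C < 2:
        raise ValueError("need at least 2 classes")
    if n < C:
        raise ValueError("need at least one sample per class")

    H = cfg.H if cfg.H is not None else min(100, n - 1)
    if H >= n and not cfg.allow_H_ge_n:
        raise ValueError(
            "hidden node count must be less than the sample count "
            "(set allow_H_ge_n to override)"
        )

    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Xs = (X - lo) / span

    rng = np.random.default_rng(cfg.seed)
    W_in = rng.uniform(-1.0, 1.0, size=(H, d))
    b = rng.uniform(-1.0, 1.0, size=H)
    Hmat = _ACTIVATIONS[cfg.activation](Xs @ W_in.T + b)

    O = (y[:, None] == classes[None, :]).astype(float)  # one-hot targets
    if cfg.ridge > 0:
        A = Hmat.T @ Hmat + cfg.ridge * np.eye(H)
        try:
            alpha = np.linalg.solve(A, Hmat.T @ O)
        except np.linalg.LinAlgError:
            warnings.warn("singular ridge system; falling back to pseudoinverse")
            alpha = np.linalg.pinv(Hmat) @ O
    else:
        alpha = np.linalg.lstsq(Hmat, O, rcond=None)[0]

    return ELMModel(
        W_in=W_in,
        b=b,
        alpha=alpha,
        activation=cfg.activation,
        classes=classes,
        seed=cfg.seed,
        ridge=cfg.ridge,
        scaler_lo=lo.astype(float),
        scaler_hi=hi.astype(float),
    )


def decision_scores(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Per-class scores O = H alpha (rows = samples)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[0] == 0:
        return np.empty((0, model.classes.size))
    Hmat = hidden_matrix(model.scale(X), model.W_in, model.b, model.activation)
    return Hmat @ model.alpha


def predict(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Argmax-decoded class labels; ties break to the first class."""
    scores = decision_scores(model, X)
    return model.classes[np.argmax(scores, axis=1)]
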