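"""Minimal fully-connected networks in NumPy with seeded Adam training.

Two heads are supported: a 2-way softmax (instance classifier) and a single
logistic output (patient-level aggregator). Dropout is applied after the
hidden layer during training only. Everything is float64 and seeded, so a
fixed seed reproduces weights bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigurationError


@dataclass
class TrainConfig:
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0


def _relu(x):
    return np.maximum(x, 0.0)


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class DenseNet:
    """input -> dense(hidden, relu) [-> dropout] -> dense(out, softmax|sigmoid)."""

    def __init__(
        self,
        n_in: int,
        n_hidden: int,
        n_out: int,
        output: str = "softmax",
        dropout_rate: float = 0.0,
        seed: int = 0,
    ):
        if not 0.0 <= dropout_rate < 1.0:
            raise ConfigurationError(f"dropout_rate: must be in [0, 1), got {dropout_rate}")
        if n_hidden < 1:
            raise ConfigurationError(f"hidden units: must be >= 1, got {n_hidden}")
        if output not in ("softmax", "sigmoid"):
            raise ConfigurationError(f"output: unknown head {output!r}")
        self.output = output
        self.dropout_rate = float(dropout_rate)
        rng = np.random.default_rng(seed)
        # He initialization for the ReLU layer, Glorot for the head
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_hidden))
        self.b1 = np.zeros(n_hidden)
        self.W2 = rng.normal(0.0, np.sqrt(1.0 / n_hidden), size=(n_hidden, n_out))
        self.b2 = np.zeros(n_out)

    # -- forward -----------------------------------------------------------
    def _forward(self, X, drop_mask=None):
        h = _relu(X @ self.W1 + self.b1)
        if drop_mask is not None:
            h = h * drop_mask
        z = h @ self.W2 + self.b2
        out = _softmax(z) if self.output == "softmax" else _sigmoid(z)
        return h, out

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        _, out = self._forward(X)
        return out

    # -- training ----------------------------------------------------------
    def _loss(self, X, Y) -> float:
        _, p = self._forward(X)
        eps = 1e-12
        if self.output == "softmax":
            return float(-np.mean(np.log(p[np.arange(len(Y)), Y] + eps)))
        p = p.ravel()
        return float(-np.mean(Y * np.log(p + eps) + (1 - Y) * np.log(1 - p + eps)))

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        config: TrainConfig,
        X_val: Optional[np.ndarray] = None,
        y_val: Optional[np.ndarray] = None,
    ) -> "DenseNet":
        """Minibatch Adam on cross-entropy. If a validation set is given, the
        weights from the best-validation-loss epoch are restored at the end."""
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        rng = np.random.default_rng(config.seed)
        n = X.shape[0]
        params = [self.W1, self.b1, self.W2, self.b2]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        best_val = np.inf
        best_params = None

        for _ in range(config.epochs):
            order = rng.permutation(n)
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                Xb, yb = X[idx], y[idx]
                drop_mask = None
                if self.dropout_rate > 0:
                    keep = 1.0 - self.dropout_rate
                    drop_mask = (rng.random((len(idx), self.W1.shape[1])) < keep) / keep
                h, p = self._forward(Xb, drop_mask)
                nb = len(idx)
                if self.output == "softmax":
                    delta = p.copy()
                    delta[np.arange(nb), yb] -= 1.0
                    delta /= nb
                else:
                    delta = (p.ravel() - yb).reshape(-1, 1) / nb
                gW2 = h.T @ delta
                gb2 = delta.sum(axis=0)
                dh = delta @ self.W2.T
                if drop_mask is not None:
                    dh = dh * drop_mask
                dh = dh * (h > 0)
                gW1 = Xb.T @ dh
                gb1 = dh.sum(axis=0)
                t += 1
                for p_, g, m_, v_ in zip(params, [gW1, gb1, gW2, gb2], m, v):
                    m_ *= beta1
                    m_ += (1 - beta1) * g
                    v_ *= beta2
                    v_ += (1 - beta2) * g * g
                    mhat = m_ / (1 - beta1**t)
                    vhat = v_ / (1 - beta2**t)
                    p_ -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
            if X_val is not None and len(X_val):
                val = self._loss(np.asarray(X_val, dtype=np.float64), np.asarray(y_val))
                if val < best_val:
                    best_val = val
                    best_params = [p_.copy() for p_ in params]

        if best_params is not None:
            self.W1, self.b1, self.W2, self.b2 = best_params
        return self
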