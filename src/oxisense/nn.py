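"""Minimal dense neural networks trained with momentum SGD.

Both networks in this package are shallow fully-connected models: a
regression surrogate (leaky-ReLU hidden layers, mean-squared loss) and a
two-class softmax classifier (ReLU hidden layers, cross-entropy loss).
The implementation is deliberately small and deterministic: He-initialised
weights from a seeded generator, plain momentum SGD with a stepwise
learning-rate decay, and L2 weight regularization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during training."""


def _relu(x: np.ndarray, leak: float) -> np.ndarray:
    return np.where(x > 0, x, leak * x)


def _relu_grad(x: np.ndarray, leak: float) -> np.ndarray:
    return np.where(x > 0, 1.0, leak)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


class MLP:
    """Fully-connected network: ``sizes = (in, hidden..., out)``.

    ``task`` selects the head: ``"regression"`` (identity output + MSE) or
    ``"classification"`` (softmax + cross-entropy, integer labels).
    """

    def __init__(
        self,
        sizes: tuple[int, ...],
        task: str = "regression",
        leak: float = 0.0,
        seed: int = 0,
    ) -> None:
        if task not in ("regression", "classification"):
            raise ValueError(f"unknown task {task!r}")
        self.sizes = tuple(int(s) for s in sizes)
        self.task = task
        self.leak = float(leak)
        rng = np.random.default_rng(seed)
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            for fan_in, fan_out in zip(self.sizes[:-1], self.sizes[1:])
        ]
        self.b = [np.zeros(fan_out) for fan_out in self.sizes[1:]]

    # -- forward ------------------------------------------------------------

    def _forward(self, X: np.ndarray):
        pre, post = [], [X]
        a = X
        for layer, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            pre.append(z)
            if layer < len(self.W) - 1:
                a = _relu(z, self.leak)
            else:
                a = _softmax(z) if self.task == "classification" else z
            post.append(a)
        return pre, post

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Regression outputs, or class labels for classification."""
        out = self._forward(np.atleast_2d(X))[1][-1]
        if self.task == "classification":
            return out.argmax(axis=1)
        return out

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.task != "classification":
            raise ValueError("probabilities only defined for classifiers")
        return self._forward(np.atleast_2d(X))[1][-1]

    # -- loss ---------------------------------------------------------------

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        out = self._forward(np.atleast_2d(X))[1][-1]
        if self.task == "classification":
            p = out[np.arange(len(out)), np.asarray(y, dtype=int)]
            return float(-np.log(np.clip(p, 1e-300, None)).mean())
        return float(0.5 * ((out - y) ** 2).sum(axis=1).mean())

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float((self.predict(X) == np.asarray(y)).mean())

    # -- training -----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        epochs: int = 200,
        lr0: float = 1e-3,
        momentum: float = 0.9,
        l2: float = 1e-6,
        batch_size: int = 32,
        lr_decay: float = 0.95,
        decay_every: int = 10,
        seed: int = 0,
        patience: int | None = None,
    ) -> TrainingHistory:
        """Momentum SGD with stepwise learning-rate decay.

        Validation loss (and accuracy, for classifiers) is recorded every
        epoch when a validation split is supplied; with ``patience`` set,
        training stops early after that many epochs without a new best
        validation loss.  Raises :class:`TrainingDivergedError` on NaN/inf.
        """
        X = np.asarray(X, dtype=float)
        rng = np.random.default_rng(seed)
        vW = [np.zeros_like(W) for W in self.W]
        vb = [np.zeros_like(b) for b in self.b]
        history = TrainingHistory()
        n = len(X)
        best_val, since_best = np.inf, 0
        for epoch in range(epochs):
            lr = lr0 * lr_decay ** (epoch // decay_every)
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                batch = order[start:start + batch_size]
                self._step(X[batch], y[batch], lr, momentum, l2, vW, vb)
            tl = self.loss(X, y)
            if not np.isfinite(tl):
                raise TrainingDivergedError(
                    f"training loss non-finite at epoch {epoch}: "
                    f"lr0={lr0}, momentum={momentum}, l2={l2}, "
                    f"batch_size={batch_size}, sizes={self.sizes}"
                )
            history.train_loss.append(tl)
            if self.task == "classification":
                history.train_accuracy.append(self.accuracy(X, y))
            if X_val is not None and len(X_val):
                vl = self.loss(X_val, y_val)
                history.val_loss.append(vl)
                if self.task == "classification":
                    history.val_accuracy.append(self.accuracy(X_val, y_val))
                if vl < best_val - 1e-15:
                    best_val, since_best = vl, 0
                else:
                    since_best += 1
                    if patience is not None and since_best >= patience:
                        break
        return history

    def _step(self, Xb, yb, lr, momentum, l2, vW, vb) -> None:
        pre, post = self._forward(Xb)
        m = len(Xb)
        if self.task == "classification":
            delta = post[-1].copy()
            delta[np.arange(m), np.asarray(yb, dtype=int)] -= 1.0
            delta /= m
        else:
            delta = (post[-1] - yb) / m
        for layer in reversed(range(len(self.W))):
            gW = post[layer].T @ delta + l2 * self.W[layer]
            gb = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ self.W[layer].T) * _relu_grad(
                    pre[layer - 1], self.leak
                )
            vW[layer] = momentum * vW[layer] - lr * gW
            vb[layer] = momentum * vb[layer] - lr * gb
            self.W[layer] = self.W[layer] + vW[layer]
            self.b[layer] = self.b[layer] + vb[layer]
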