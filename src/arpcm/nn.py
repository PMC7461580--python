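"""Minimal feed-forward neural network (numpy backend).

A small multilayer perceptron for multi-class classification: fully connected
hidden layers with ReLU activations and inverted dropout, a softmax output,
categorical cross-entropy loss, mini-batch ADAM optimisation, and early
stopping on an inner validation split with best-weight restoration.  Sized
for the few-thousand-parameter regime this package trains in; everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .exceptions import DimensionError, DivergenceError


@dataclass
class TrainingHistory:
    """Per-epoch losses and where early stopping triggered."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(y), n_classes))
    out[np.arange(len(y)), y] = 1.0
    return out


class MLPNet:
    """ReLU MLP with softmax head trained by mini-batch ADAM.

    Parameters mirror the usual small-network defaults: ``hidden_sizes`` of
    (128, 32), dropout applied after each hidden activation at train time
    only, batch size 16, ADAM step size 1e-3, early stopping when the inner
    validation loss has not improved for ``patience`` epochs.
    """

    def __init__(
        self,
        n_classes: int,
        hidden_sizes: tuple[int, ...] = (128, 32),
        dropout: float = 0.01,
        batch_size: int = 16,
        learning_rate: float = 1e-3,
        max_epochs: int = 500,
        patience: int = 20,
        validation_fraction: float = 0.1,
        seed: int = 0,
    ):
        if not all(h > 0 for h in hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if not 0 <= dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.n_classes = n_classes
        self.hidden_sizes = tuple(hidden_sizes)
        self.dropout = dropout
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.seed = seed
        self.weights_: list[np.ndarray] | None = None
        self.biases_: list[np.ndarray] | None = None
        self.n_features_: int | None = None
        self.history_: TrainingHistory | None = None

    # -- forward / backward -------------------------------------------------

    def _init_params(self, n_features: int, rng: np.random.Generator) -> None:
        sizes = (n_features, *self.hidden_sizes, self.n_classes)
        self.weights_ = [
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            for fan_in, fan_out in zip(sizes, sizes[1:])
        ]
        self.biases_ = [np.zeros(fan_out) for fan_out in sizes[1:]]
        self.n_features_ = n_features

    def _forward(
        self, X: np.ndarray, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, list]:
        """Return class probabilities and the cache needed for backprop.

        Dropout (inverted scaling) is active only when an rng is supplied.
        """
        cache = []
        a = X
        n_hidden = len(self.weights_) - 1
        for layer in range(n_hidden):
            z = a @ self.weights_[layer] + self.biases_[layer]
            h = np.maximum(z, 0.0)
            if rng is not None and self.dropout > 0:
                mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                h = h * mask
            else:
                mask = None
            cache.append((a, z, mask))
            a = h
        z_out = a @ self.weights_[-1] + self.biases_[-1]
        cache.append((a, z_out, None))
        return _softmax(z_out), cache

    def _loss(self, proba: np.ndarray, Y: np.ndarray) -> float:
        eps = 1e-12
        return float(-(Y * np.log(proba + eps)).sum(axis=1).mean())

    def _backward(
        self, proba: np.ndarray, Y: np.ndarray, cache: list
    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        n = len(Y)
        grads_w = [None] * len(self.weights_)
        grads_b = [None] * len(self.biases_)
        delta = (proba - Y) / n  # softmax + cross-entropy
        for layer in range(len(self.weights_) - 1, -1, -1):
            a_in, z, mask = cache[layer]
            grads_w[layer] = a_in.T @ delta
            grads_b[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = delta @ self.weights_[layer].T
                _, z_prev, mask_prev = cache[layer - 1]
                if mask_prev is not None:
                    delta = delta * mask_prev
                delta = delta * (z_prev > 0)
        return grads_w, grads_b

    # -- training -----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPNet":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(self.seed)
        self._init_params(X.shape[1], rng)

        if self.validation_fraction > 0 and len(X) >= 10:
            strat = y if np.bincount(y).min() >= 2 else None
            X_tr, X_val, y_tr, y_val = train_test_split(
                X,
                y,
                test_size=self.validation_fraction,
                random_state=self.seed % (2**32),
                stratify=strat,
            )
        else:  # too little data for an inner split: monitor training loss
            X_tr, y_tr = X, y
            X_val, y_val = X, y

        Y_tr = _one_hot(y_tr, self.n_classes)
        Y_val = _one_hot(y_val, self.n_classes)

        # ADAM state
        m_w = [np.zeros_like(w) for w in self.weights_]
        v_w = [np.zeros_like(w) for w in self.weights_]
        m_b = [np.zeros_like(b) for b in self.biases_]
        v_b = [np.zeros_like(b) for b in self.biases_]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        history = TrainingHistory()
        best_val = np.inf
        best_params = None
        since_best = 0

        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(len(X_tr))
            epoch_losses = []
            for start in range(0, len(X_tr), self.batch_size):
                idx = order[start : start + self.batch_size]
                proba, cache = self._forward(X_tr[idx], rng=rng)
                loss = self._loss(proba, Y_tr[idx])
                if not np.isfinite(loss):
                    raise DivergenceError(f"non-finite loss at epoch {epoch}")
                epoch_losses.append(loss)
                grads_w, grads_b = self._backward(proba, Y_tr[idx], cache)
                t += 1
                for layer in range(len(self.weights_)):
                    for params, grads, ms, vs in (
                        (self.weights_, grads_w, m_w, v_w),
                        (self.biases_, grads_b, m_b, v_b),
                    ):
                        ms[layer] = beta1 * ms[layer] + (1 - beta1) * grads[layer]
                        vs[layer] = beta2 * vs[layer] + (1 - beta2) * grads[layer] ** 2
                        m_hat = ms[layer] / (1 - beta1**t)
                        v_hat = vs[layer] / (1 - beta2**t)
                        params[layer] -= self.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

            val_proba, _ = self._forward(X_val)
            val_loss = self._loss(val_proba, Y_val)
            history.train_loss.append(float(np.mean(epoch_losses)))
            history.val_loss.append(val_loss)

            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_params = (
                    [w.copy() for w in self.weights_],
                    [b.copy() for b in self.biases_],
                )
                history.best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
            if since_best >= self.patience:
                break

        history.stopped_epoch = epoch
        if best_params is not None:
            self.weights_, self.biases_ = best_params
        self.history_ = history
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.weights_ is None:
            raise DimensionError("network is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_:
            raise DimensionError(
                f"expected {self.n_features_} features, got matrix of shape {X.shape}"
            )
        proba, _ = self._forward(X)
        return proba

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    # -- persistence ----------------------------------------------------------

    def get_params_arrays(self) -> dict[str, np.ndarray]:
        arrays = {}
        for i, (w, b) in enumerate(zip(self.weights_, self.biases_)):
            arrays[f"W{i}"] = w
            arrays[f"b{i}"] = b
        return arrays

    def set_params_arrays(self, arrays: dict[str, np.ndarray], n_features: int) -> None:
        n_layers = len(self.hidden_sizes) + 1
        self.weights_ = [np.asarray(arrays[f"W{i}"]) for i in range(n_layers)]
        self.biases_ = [np.asarray(arrays[f"b{i}"]) for i in range(n_layers)]
        self.n_features_ = n_features
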