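"""Mini-batch training with Adam/SGD, validation hold-out and early stopping.

Training minimizes categorical cross-entropy.  A stratified, seeded
fraction of the training rows is held out as a validation set; training
stops once validation loss has failed to improve for ``patience``
consecutive epochs, and the weights from the best-validation-loss epoch
are restored.  When the validation fraction is zero (or leaves no rows)
the training loss is monitored instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import cross_entropy, softmax
from .model import RDCNNModel


class DegenerateLabelsError(ValueError):
    """Raised when training labels contain fewer than two classes."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (loss is categorical cross-entropy)."""

    optimizer: str = "adam"  # {"adam", "sgd"}
    learning_rate: float = 0.001
    batch_size: int = 64
    max_epochs: int = 10
    patience: int = 5
    validation_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in [0, 1)")


class _Adam:
    def __init__(self, lr: float, b1: float = 0.9, b2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, named_layers) -> None:
        self.t += 1
        for name, layer in named_layers:
            for key, param in layer.params.items():
                grad = layer.grads.get(key)
                if grad is None:
                    continue
                slot = f"{name}.{key}"
                m = self.m.setdefault(slot, np.zeros_like(param))
                v = self.v.setdefault(slot, np.zeros_like(param))
                m += (1 - self.b1) * (grad - m)
                v += (1 - self.b2) * (grad * grad - v)
                mhat = m / (1 - self.b1 ** self.t)
                vhat = v / (1 - self.b2 ** self.t)
                param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, lr: float) -> None:
        self.lr = lr

    def step(self, named_layers) -> None:
        for _, layer in named_layers:
            for key, param in layer.params.items():
                grad = layer.grads.get(key)
                if grad is not None:
                    param -= self.lr * grad


def _stratified_holdout(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class held-out indices: (train_idx, val_idx)."""
    train_idx, val_idx = [], []
    for c in np.unique(y):
        idx = rng.permutation(np.nonzero(y == c)[0])
        n_val = int(np.floor(fraction * idx.size))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.concatenate(train_idx), np.concatenate(val_idx)


def _evaluate(model: RDCNNModel, beats: np.ndarray, y: np.ndarray,
              batch_size: int) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, beats.shape[0], batch_size):
        logits = model.forward(beats[i : i + batch_size])
        loss, _ = cross_entropy(logits, y[i : i + batch_size])
        losses.append(loss * logits.shape[0])
        correct += int((logits.argmax(axis=1) == y[i : i + batch_size]).sum())
    n = beats.shape[0]
    return float(np.sum(losses) / n), correct / n


def train_model(
    model: RDCNNModel, beats: np.ndarray, labels: np.ndarray,
    config: TrainConfig | None = None,
) -> RDCNNModel:
    """Fit the network in place and return it (best-validation weights)."""
    if config is None:
        config = TrainConfig()
    config.validate()
    beats = np.asarray(beats, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise DegenerateLabelsError("training labels contain fewer than 2 classes")

    rng = np.random.default_rng(config.seed)
    if config.validation_fraction > 0:
        tr_idx, va_idx = _stratified_holdout(y, config.validation_fraction, rng)
    else:
        tr_idx, va_idx = np.arange(y.size), np.empty(0, dtype=int)
    has_val = va_idx.size > 0
    x_tr, y_tr = beats[tr_idx], y[tr_idx]
    x_va, y_va = beats[va_idx], y[va_idx]

    opt = (_Adam(config.learning_rate) if config.optimizer == "adam"
           else _SGD(config.learning_rate))
    layers = list(model.named_layers())

    best_loss = np.inf
    best_weights = model.get_weights()
    stall = 0
    for _ in range(config.max_epochs):
        order = rng.permutation(x_tr.shape[0])
        batch_losses = []
        batch_correct = 0
        for i in range(0, order.size, config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = model.forward(x_tr[idx], training=True, rng=rng)
            loss, glogits = cross_entropy(logits, y_tr[idx])
            model.backward(glogits)
            opt.step(layers)
            batch_losses.append(loss * idx.size)
            batch_correct += int((logits.argmax(axis=1) == y_tr[idx]).sum())
        train_loss = float(np.sum(batch_losses) / order.size)
        train_acc = batch_correct / order.size
        if has_val:
            val_loss, val_acc = _evaluate(model, x_va, y_va, config.batch_size)
        else:
            val_loss, val_acc = train_loss, train_acc
        model.history["train_loss"].append(train_loss)
        model.history["train_acc"].append(train_acc)
        model.history["val_loss"].append(val_loss)
        model.history["val_acc"].append(val_acc)

        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_weights = model.get_weights()
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    model.set_weights(best_weights)
    return model


def predict_classes(model: RDCNNModel, beats: np.ndarray) -> np.ndarray:
    """Argmax of the softmax output (utility for direct network inference)."""
    return model.predict_proba(beats).argmax(axis=1)
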