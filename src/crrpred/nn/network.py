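"""Sequential network container, BCE loss, and the training loop."""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .layers import Layer
from .optimizers import _Optimizer

__all__ = ["Sequential", "bce_loss", "TrainingHistory", "train_network", "DivergenceError"]

BCE_EPS = 1e-7


def bce_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean binary cross-entropy with predictions clipped to [eps, 1-eps]."""
    y = np.asarray(y, dtype=np.float64).ravel()
    p = np.clip(np.asarray(y_hat, dtype=np.float64).ravel(), BCE_EPS, 1.0 - BCE_EPS)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())


class DivergenceError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"non-finite training loss at epoch {epoch}")
        self.epoch = epoch


class Sequential:
    """A plain stack of layers ending in a single sigmoid unit."""

    def __init__(self, layers: list[Layer], input_shape: tuple[int, ...]):
        self.layers = layers
        self.input_shape = tuple(input_shape)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict(self, x: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        """Per-sample scores in (0, 1), shape (n,)."""
        x = self._check_input(x)
        outs = [
            self.forward(x[i:i + batch_size], train=False)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs).ravel()

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.shape[1:] != self.input_shape:
            raise ValueError(f"input shape {x.shape[1:]} != expected {self.input_shape}")
        return x

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w

    def summary(self) -> str:
        lines = [f"Input{self.input_shape}"]
        lines += [layer.summary() for layer in self.layers]
        lines.append(f"params: {self.n_params}")
        return "\n".join(lines)

    def clone_structure(self) -> "Sequential":
        return copy.deepcopy(self)


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    epochs_run: int = 0
    stopped_early: bool = False
    best_epoch: int = -1


def train_network(
    model: Sequential,
    optimizer: _Optimizer,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    batch_size: int = 32,
    max_epochs: int = 64,
    patience: int = 5,
    seed: int = 0,
) -> TrainingHistory:
    """Mini-batch training on the BCE loss with early stopping.

    Early stopping monitors validation loss with the given patience and
    restores the best weights; with no validation set the model trains
    for max_epochs. Deterministic given the seed (batch shuffling is the
    only stochastic element here; dropout layers carry their own seeded
    generators).
    """
    x_train = model._check_input(x_train)
    y_train = np.asarray(y_train, dtype=np.float32).reshape(-1, 1)
    if len(x_train) != len(y_train):
        raise ValueError("x_train / y_train length mismatch")
    rng = np.random.default_rng(seed)
    history = TrainingHistory()
    best_val = np.inf
    best_weights = None
    wait = 0
    for epoch in range(max_epochs):
        optimizer.start_epoch(epoch)
        order = rng.permutation(len(x_train))
        losses = []
        for lo in range(0, len(order), batch_size):
            sel = order[lo:lo + batch_size]
            xb, yb = x_train[sel], y_train[sel]
            out = model.forward(xb, train=True)
            p = np.clip(out, BCE_EPS, 1.0 - BCE_EPS)
            losses.append(float(-(yb * np.log(p) + (1 - yb) * np.log(1 - p)).mean()))
            grad = ((p - yb) / (p * (1.0 - p))).astype(np.float32) / len(yb)
            model.backward(grad)
            optimizer.update(model.params, model.grads)
        epoch_loss = float(np.mean(losses))
        if not np.isfinite(epoch_loss):
            raise DivergenceError(epoch)
        history.train_loss.append(epoch_loss)
        history.epochs_run = epoch + 1
        if x_val is not None:
            val = bce_loss(y_val, model.predict(x_val))
            history.val_loss.append(val)
            if val < best_val - 1e-12:
                best_val = val
                best_weights = model.get_weights()
                history.best_epoch = epoch
                wait = 0
            else:
                wait += 1
                if wait >= patience:
                    history.stopped_early = True
                    break
    if best_weights is not None:
        model.set_weights(best_weights)
    return history
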