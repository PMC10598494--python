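"""Sequential model container: losses, Adam, fit loop, early stopping.

Training is deterministic given the model seed: weight initialization,
epoch shuffling and dropout masks all derive from it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .layers import Layer

__all__ = ["Model", "Adam", "EarlyStopPolicy", "TrainingHistory"]

_EPS = 1e-7


# -------------------------------------------------------------------- losses

def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(p, _EPS, 1.0 - _EPS)


def loss_forward(name: str, p: np.ndarray, y: np.ndarray) -> float:
    if name == "bce":
        pc = _clip(p)
        return float(-(y * np.log(pc) + (1 - y) * np.log(1 - pc)).mean())
    if name == "mse":
        return float(((p - y) ** 2).mean())
    if name == "cce":
        pc = _clip(p)
        return float(-(y * np.log(pc)).sum(axis=-1).mean())
    raise ValueError(f"unknown loss {name!r}")


def loss_backward(name: str, p: np.ndarray, y: np.ndarray) -> np.ndarray:
    if name == "bce":
        pc = _clip(p)
        return (pc - y) / (pc * (1 - pc)) / p.size
    if name == "mse":
        return 2.0 * (p - y) / p.size
    if name == "cce":
        pc = _clip(p)
        n = p.shape[0]
        return -(y / pc) / n
    raise ValueError(f"unknown loss {name!r}")


def metric_value(name: str, p: np.ndarray, y: np.ndarray) -> float:
    """Accuracy-style metrics.

    ``pixel_accuracy``: agreement after binarizing prediction and target
    at 0.5 (used for the frame predictor, whose targets are intensities).
    """
    if name == "pixel_accuracy" or name == "binary_accuracy":
        return float(((p >= 0.5) == (y >= 0.5)).mean())
    if name == "categorical_accuracy":
        return float((p.argmax(axis=-1) == y.argmax(axis=-1)).mean())
    raise ValueError(f"unknown metric {name!r}")


# ----------------------------------------------------------------- optimizer

class Adam:
    """Adaptive-moment optimizer (beta1=0.9, beta2=0.999)."""

    def __init__(self, learning_rate: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self, layers: list[Layer]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for li, layer in enumerate(layers):
            for name, p in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                key = (li, name)
                m = self._m.setdefault(key, np.zeros_like(p))
                v = self._v.setdefault(key, np.zeros_like(p))
                m *= self.beta1
                m += (1 - self.beta1) * g
                v *= self.beta2
                v += (1 - self.beta2) * g * g
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ------------------------------------------------------------- bookkeeping

@dataclass
class EarlyStopPolicy:
    """Stop when the monitored metric fails to improve for ``patience`` epochs."""

    monitor: str = "val_loss"
    patience: int = 15
    restore_best: bool = True
    min_delta: float = 0.0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")

    @property
    def mode(self) -> str:
        return "max" if self.monitor.endswith("acc") else "min"


@dataclass
class TrainingHistory:
    """Per-epoch training and validation loss/accuracy."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)

    def record(self, key: str) -> list[float]:
        return getattr(self, key)


class Model:
    """A stack of layers mapping one input array to one output array."""

    def __init__(self, layers: list[Layer], input_shape: tuple[int, ...],
                 seed: int = 0) -> None:
        self.layers = layers
        self.input_shape = tuple(input_shape)
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        shape = self.input_shape
        for layer in layers:
            shape = layer.build(shape, self.rng)
        self.output_shape = shape

    # ------------------------------------------------------------ inference
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def predict(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        outs = [self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
        return np.concatenate(outs)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def count_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    # ------------------------------------------------------------- weights
    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params.values()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.layers:
            for name in layer.params:
                w = next(it)
                if w.shape != layer.params[name].shape:
                    raise ValueError("weight shape mismatch")
                layer.params[name] = w.copy()

    def save_weights(self, path) -> None:
        arrays = {f"p{i}": w for i, w in enumerate(self.get_weights())}
        stats = {}
        for li, layer in enumerate(self.layers):
            if hasattr(layer, "running_mean"):
                stats[f"rm{li}"] = layer.running_mean
                stats[f"rv{li}"] = layer.running_var
        np.savez(path, **arrays, **stats)

    def load_weights(self, path) -> None:
        data = np.load(path)
        n = len([k for k in data.files if k.startswith("p")])
        self.set_weights([data[f"p{i}"] for i in range(n)])
        for li, layer in enumerate(self.layers):
            if f"rm{li}" in data:
                layer.running_mean = data[f"rm{li}"]
                layer.running_var = data[f"rv{li}"]

    # ------------------------------------------------------------- training
    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int = 5,
        loss: str = "bce",
        metric: str = "pixel_accuracy",
        optimizer: Adam | None = None,
        validation_data: tuple[np.ndarray, np.ndarray] | None = None,
        validation_split: float = 0.0,
        early_stopping: EarlyStopPolicy | None = None,
        shuffle: bool = True,
        verbose: bool = False,
    ) -> TrainingHistory:
        """Mini-batch training; returns one history record per completed epoch.

        Data are shuffled before every epoch.  ``validation_split`` carves a
        validation set off the end of a seeded shuffle when no explicit
        ``validation_data`` is given.
        """
        if len(x) == 0:
            raise ValueError("training set is empty")
        if epochs < 1 or batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        opt = optimizer or Adam()
        if validation_data is None and validation_split > 0.0:
            idx = self.rng.permutation(len(x))
            n_val = max(1, int(round(validation_split * len(x))))
            val_idx, tr_idx = idx[:n_val], idx[n_val:]
            validation_data = (x[val_idx], y[val_idx])
            x, y = x[tr_idx], y[tr_idx]

        history = TrainingHistory()
        best_value = None
        best_weights = None
        wait = 0
        for epoch in range(epochs):
            order = self.rng.permutation(len(x)) if shuffle else np.arange(len(x))
            ep_loss = 0.0
            ep_acc = 0.0
            for start in range(0, len(x), batch_size):
                bi = order[start : start + batch_size]
                xb, yb = x[bi], y[bi]
                p = self.forward(xb, training=True)
                ep_loss += loss_forward(loss, p, yb) * len(bi)
                ep_acc += metric_value(metric, p, yb) * len(bi)
                self.backward(loss_backward(loss, p, yb))
                opt.step(self.layers)
            history.train_loss.append(ep_loss / len(x))
            history.train_acc.append(ep_acc / len(x))
            if validation_data is not None:
                pv = self.predict(validation_data[0], batch_size=batch_size)
                history.val_loss.append(loss_forward(loss, pv, validation_data[1]))
                history.val_acc.append(metric_value(metric, pv, validation_data[1]))
            if verbose:
                msg = f"epoch {epoch + 1}/{epochs} loss={history.train_loss[-1]:.4f}"
                if validation_data is not None:
                    msg += f" val_loss={history.val_loss[-1]:.4f}"
                print(msg)
            if early_stopping is not None:
                record = history.record(early_stopping.monitor)
                if not record:
                    raise ValueError(
                        f"early stopping monitors {early_stopping.monitor!r} "
                        "but no such record is being produced"
                    )
                value = record[-1]
                sign = 1.0 if early_stopping.mode == "max" else -1.0
                if best_value is None or sign * (value - best_value) > early_stopping.min_delta:
                    best_value = value
                    wait = 0
                    if early_stopping.restore_best:
                        best_weights = self.get_weights()
                else:
                    wait += 1
                    if wait >= early_stopping.patience:
                        if early_stopping.restore_best and best_weights is not None:
                            self.set_weights(best_weights)
                        break
        return history
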