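"""Metrics, training-history export, and class-imbalance resampling.

Accuracy alone misleads on imbalanced medical datasets, so the
sensitivity (true-positive rate) / fallout (false-positive rate) pair is
provided alongside, together with random under- and over-sampling that
equalize class counts before training.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .nn.model import TrainingHistory

__all__ = [
    "ConfusionCounts",
    "UndefinedMetricError",
    "confusion_from_predictions",
    "accuracy",
    "sensitivity",
    "fallout",
    "undersample_indices",
    "oversample_indices",
    "undersample",
    "oversample",
    "export_history",
    "read_history",
    "plot_history",
]

HISTORY_COLUMNS = ["epoch", "train_loss", "train_acc", "val_loss", "val_acc"]


class UndefinedMetricError(ZeroDivisionError):
    """The requested metric's denominator is zero."""


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    yt = np.asarray(y_true).astype(int).ravel()
    yp = np.asarray(y_pred).astype(int).ravel()
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must align")
    return ConfusionCounts(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
    )


def accuracy(counts: ConfusionCounts) -> float:
    """(tp + tn) / total."""
    if counts.total == 0:
        raise UndefinedMetricError("accuracy undefined on an empty set")
    return (counts.tp + counts.tn) / counts.total


def sensitivity(counts: ConfusionCounts) -> float:
    """True-positive rate tp / (tp + fn)."""
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("sensitivity undefined without positives")
    return counts.tp / (counts.tp + counts.fn)


def fallout(counts: ConfusionCounts) -> float:
    """False-positive rate fp / (fp + tn)."""
    if counts.fp + counts.tn == 0:
        raise UndefinedMetricError("fallout undefined without negatives")
    return counts.fp / (counts.fp + counts.tn)


# ------------------------------------------------------------- resampling

def _binary_class_indices(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(int).ravel()
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("resampling requires exactly two classes to be present")
    return np.flatnonzero(labels == classes[0]), np.flatnonzero(labels == classes[1])


def undersample_indices(labels, seed: int = 0) -> np.ndarray:
    """Indices keeping all minority samples and a random majority subset."""
    a, b = _binary_class_indices(labels)
    rng = np.random.default_rng(seed)
    minority, majority = (a, b) if len(a) <= len(b) else (b, a)
    kept = rng.choice(majority, size=len(minority), replace=False)
    return np.sort(np.concatenate([minority, kept]))


def oversample_indices(labels, seed: int = 0) -> np.ndarray:
    """Indices duplicating random minority samples up to the majority count."""
    a, b = _binary_class_indices(labels)
    rng = np.random.default_rng(seed)
    minority, majority = (a, b) if len(a) <= len(b) else (b, a)
    extra = rng.choice(minority, size=len(majority) - len(minority), replace=True)
    return np.sort(np.concatenate([np.arange(len(np.asarray(labels).ravel())), extra]))


def _take(data, idx):
    """Index a labeled container: (x, y) pair or an object with labels + payload."""
    if isinstance(data, tuple):
        x, y = data
        x = np.asarray(x)
        return x[idx], np.asarray(y)[idx]
    # duck-typed dataset objects (LabeledVolumeSet, LabeledSliceSet)
    from .slice_classifier import LabeledSliceSet
    from .synthgen import LabeledVolumeSet

    if isinstance(data, LabeledVolumeSet):
        return LabeledVolumeSet(
            volumes=[data.volumes[i] for i in idx],
            labels=data.labels[idx],
            class_names=data.class_names,
        )
    if isinstance(data, LabeledSliceSet):
        return LabeledSliceSet(
            slices=data.slices[idx],
            labels=data.labels[idx],
            task_name=data.task_name,
            class_names=data.class_names,
        )
    raise TypeError(f"cannot resample {type(data).__name__}")


def _labels_of(data):
    if isinstance(data, tuple):
        return np.asarray(data[1]).astype(int).ravel()
    return data.labels


def undersample(data, seed: int = 0):
    """Equalize class counts by randomly dropping majority samples.

    The output is a subset of the input; no minority sample is removed.
    """
    return _take(data, undersample_indices(_labels_of(data), seed))


def oversample(data, seed: int = 0):
    """Equalize class counts by duplicating random minority samples.

    Every added sample equals some original minority sample; the majority
    class is unchanged.
    """
    return _take(data, oversample_indices(_labels_of(data), seed))


# ------------------------------------------------------- history artifacts

def _history_frame(history: TrainingHistory) -> pd.DataFrame:
    if len(history) == 0:
        raise ValueError("history is empty")
    n = len(history)
    pad = lambda xs: list(xs) + [np.nan] * (n - len(xs))
    return pd.DataFrame(
        {
            "epoch": np.arange(1, n + 1),
            "train_loss": history.train_loss,
            "train_acc": history.train_acc,
            "val_loss": pad(history.val_loss),
            "val_acc": pad(history.val_acc),
        }
    )


def export_history(history: TrainingHistory, path) -> None:
    """Write the per-epoch record as CSV (columns: epoch, train_loss,
    train_acc, val_loss, val_acc)."""
    _history_frame(history).to_csv(path, index=False)


def read_history(path) -> TrainingHistory:
    df = pd.read_csv(path)
    if list(df.columns) != HISTORY_COLUMNS:
        raise ValueError(f"unexpected history columns {list(df.columns)}")
    drop = lambda xs: [float(v) for v in xs if not np.isnan(v)]
    return TrainingHistory(
        train_loss=[float(v) for v in df.train_loss],
        train_acc=[float(v) for v in df.train_acc],
        val_loss=drop(df.val_loss),
        val_acc=drop(df.val_acc),
    )


def plot_history(history: TrainingHistory, directory) -> list[Path]:
    """Write accuracy and loss curves as PNG files into ``directory``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = _history_frame(history)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for kind in ("acc", "loss"):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(df.epoch, df[f"train_{kind}"], label=f"train {kind}")
        if df[f"val_{kind}"].notna().any():
            ax.plot(df.epoch, df[f"val_{kind}"], label=f"validation {kind}")
        ax.set_xlabel("epoch")
        ax.set_ylabel("accuracy" if kind == "acc" else "loss")
        ax.legend()
        fig.tight_layout()
        out = directory / f"history_{'accuracy' if kind == 'acc' else 'loss'}.png"
        fig.savefig(out, dpi=100)
        plt.close(fig)
        written.append(out)
    return written
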