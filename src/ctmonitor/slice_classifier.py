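"""2D-CNN binary slice classifier and synthetic slice-task construction.

Two convolution blocks (128 then 64 filters at full scale, 3x3 kernels,
each followed by 2x2 max pooling), a flatten, and a 2-unit softmax head.
Tasks are proxies built from phantom geometry: the body-part task labels
axial slices inside the lung span 'ACT' against slices outside it
('OTHER'); the plane task labels axial slices 'AXIAL' against coronal and
sagittal re-slices ('OTHER').
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .nn.model import Adam, EarlyStopPolicy, TrainingHistory
from .preprocess import hu_window_normalize
from .synthgen import LabeledVolumeSet

__all__ = [
    "SliceClassifierSpec",
    "LabeledSliceSet",
    "build_slice_classifier",
    "make_slice_tasks",
    "train_slice_classifier",
    "predict_slice",
]

logger = logging.getLogger(__name__)


@dataclass
class SliceClassifierSpec:
    """Architecture hyper-parameters for the slice classifier."""

    input_size: int = 64
    filters: tuple[int, int] = (128, 64)
    kernel_size: int = 3
    pool_window: int = 2

    @classmethod
    def desk_scale(cls) -> "SliceClassifierSpec":
        return cls(filters=(16, 8))


@dataclass
class LabeledSliceSet:
    """2-D grayscale slices with binary labels for one task."""

    slices: np.ndarray  # (n, H, W)
    labels: np.ndarray  # (n,) in {0, 1}
    task_name: str = "plane"
    class_names: tuple[str, str] = ("OTHER", "AXIAL")

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.slices) != len(self.labels):
            raise ValueError("one label per slice required")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be 0 or 1")

    def __len__(self) -> int:
        return len(self.slices)


def build_slice_classifier(spec: SliceClassifierSpec | None = None,
                           seed: int = 0) -> nn.Model:
    """Build the classifier; maps (n, H, W, 1) -> (n, 2) softmax rows."""
    spec = spec or SliceClassifierSpec()
    min_size = spec.pool_window**2
    if spec.input_size < min_size:
        raise ValueError(f"input size must be at least {min_size} for two pooling stages")
    f1, f2 = spec.filters
    layers = [
        nn.Conv(f1, spec.kernel_size, ndim=2, activation="relu"),
        nn.MaxPool(spec.pool_window, ndim=2),
        nn.Conv(f2, spec.kernel_size, ndim=2, activation="relu"),
        nn.MaxPool(spec.pool_window, ndim=2),
        nn.Flatten(),
        nn.Dense(2, activation="softmax"),
    ]
    return nn.Model(layers, input_shape=(spec.input_size, spec.input_size, 1), seed=seed)


def _resize_slice(sl: np.ndarray, size: int) -> np.ndarray:
    if sl.shape == (size, size):
        return sl
    return _sk_resize(sl, (size, size), order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)


def make_slice_tasks(volumes: LabeledVolumeSet, task: str = "plane",
                     size: int = 64, slices_per_volume: int = 8,
                     seed: int = 0) -> LabeledSliceSet:
    """Build a binary slice task from phantom volumes.

    ``plane``: axial slices (taken along the depth axis) are labeled 1
    ('AXIAL'); coronal and sagittal re-slices are labeled 0 ('OTHER').
    ``body-part``: axial slices inside the lung depth span (from the
    phantom's geometry metadata) are labeled 1 ('ACT'); slices outside it
    0 ('OTHER').  Volumes too thin to yield both classes are skipped with
    a warning.  Slices are HU-windowed to [0, 1] and resized.
    """
    if len(volumes) == 0:
        raise ValueError("no volumes given")
    if task not in ("plane", "body-part"):
        raise ValueError(f"unknown task {task!r}")
    rng = np.random.default_rng(seed)
    slices, labels = [], []
    for vol in volumes.volumes:
        v = hu_window_normalize(vol.voxels)
        d, h, w = v.shape
        if task == "plane":
            for _ in range(slices_per_volume):
                axis = rng.integers(3)
                if axis == 0:
                    sl, lab = v[rng.integers(d // 4, 3 * d // 4)], 1
                elif axis == 1:
                    sl, lab = v[:, rng.integers(h // 4, 3 * h // 4), :], 0
                else:
                    sl, lab = v[:, :, rng.integers(w // 4, 3 * w // 4)], 0
                slices.append(_resize_slice(sl, size))
                labels.append(lab)
        else:
            span = vol.meta.get("lung_depth_span")
            if span is None:
                logger.warning("volume %s has no lung span metadata; skipped", vol.id)
                continue
            z0, z1 = span
            outside = [z for z in range(d) if z < z0 or z > z1]
            if z1 < z0 or not outside:
                logger.warning("volume %s too thin to yield both classes; skipped", vol.id)
                continue
            for _ in range(slices_per_volume):
                if rng.random() < 0.5:
                    z, lab = int(rng.integers(z0, z1 + 1)), 1
                else:
                    z, lab = int(outside[rng.integers(len(outside))]), 0
                slices.append(_resize_slice(v[z], size))
                labels.append(lab)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("task construction yielded a single class")
    names = ("OTHER", "AXIAL") if task == "plane" else ("OTHER", "ACT")
    return LabeledSliceSet(slices=np.stack(slices), labels=labels,
                           task_name=task, class_names=names)


def _one_hot(labels: np.ndarray) -> np.ndarray:
    out = np.zeros((len(labels), 2))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def train_slice_classifier(
    model: nn.Model,
    data: LabeledSliceSet,
    config=None,
    stop: EarlyStopPolicy | None = None,
    verbose: bool = False,
) -> TrainingHistory:
    """Train with 2-class cross-entropy; both classes must be present."""
    from .frame_predictor import TrainConfig

    if len(np.unique(data.labels)) < 2:
        raise ValueError("training set contains a single class")
    x = data.slices[..., None]
    y = _one_hot(data.labels)
    config = config or TrainConfig(epochs=10, metric="categorical_accuracy")
    return model.fit(
        x, y,
        epochs=config.epochs,
        batch_size=config.batch_size,
        loss="cce",
        metric="categorical_accuracy",
        optimizer=Adam(config.learning_rate),
        validation_split=config.validation_split,
        early_stopping=stop,
        verbose=verbose,
    )


def predict_slice(model: nn.Model, sl: np.ndarray) -> np.ndarray:
    """Class probabilities (2-vector summing to 1) for one slice."""
    x = np.asarray(sl, dtype=float)
    if x.ndim == 2:
        x = x[..., None]
    return model.forward(x[None])[0]
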