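"""3D-CNN binary classifier for CT volumes.

Four 3-D convolution blocks (3x3x3 kernels, ReLU; 64, 64, 128, 256
filters at full scale), each followed by 2x2x2 max pooling and batch
normalization, then global average pooling, a 512-unit dense layer with
dropout, and a single sigmoid output unit.  The model boundary uses the
(samples, width, height, depth, 1) convention; volumes stored
(depth, height, width) are adapted by :func:`volumes_to_tensor`.

The module also exposes the two pooling operators as standalone
functions, defined exactly as their windowed-maximum / channel-mean
semantics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import nn
from .nn.model import Adam, EarlyStopPolicy, TrainingHistory
from .preprocess import PreprocConfig, preprocess_volume
from .synthgen import LabeledVolumeSet

__all__ = [
    "VolumeClassifierSpec",
    "max_pool_3d",
    "global_average_pool",
    "build_volume_classifier",
    "volumes_to_tensor",
    "prepare_volume_dataset",
    "train_volume_classifier",
    "predict_volume",
]


@dataclass
class VolumeClassifierSpec:
    """Architecture hyper-parameters; ``input_size`` is (width, height, depth)."""

    input_size: tuple[int, int, int] = (128, 128, 64)
    filters: tuple[int, int, int, int] = (64, 64, 128, 256)
    kernel_size: int = 3
    pool_window: int = 2
    dense_units: int = 512
    dropout: float = 0.3

    @classmethod
    def desk_scale(cls, size: int = 32) -> "VolumeClassifierSpec":
        return cls(input_size=(size, size, size), filters=(8, 8, 16, 32), dense_units=32)


def max_pool_3d(feature_map: np.ndarray, window: tuple[int, int, int],
                stride: int | tuple[int, int, int] | None = None) -> np.ndarray:
    """Windowed maximum over a 3-D map (single channel or trailing channel axis).

    Output spatial dims are floor((in - K) / stride) + 1 per axis; stride
    defaults to the window (non-overlapping pooling).
    """
    x = np.asarray(feature_map, dtype=float)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[..., None]
    if x.ndim != 4:
        raise ValueError("expected a (D, H, W) or (D, H, W, C) map")
    window = tuple(window)
    stride = window if stride is None else (
        (stride,) * 3 if np.isscalar(stride) else tuple(stride))
    if any(k > d for k, d in zip(window, x.shape[:3])):
        raise ValueError(f"window {window} larger than input {x.shape[:3]}")
    if any(s < 1 for s in stride):
        raise ValueError("stride components must be >= 1")
    win = sliding_window_view(x, window, axis=(0, 1, 2))
    win = win[:: stride[0], :: stride[1], :: stride[2]]
    out = win.max(axis=(-3, -2, -1))
    return out[..., 0] if squeeze else out


def global_average_pool(feature_map: np.ndarray) -> np.ndarray:
    """Channel-wise spatial mean: an (M, M, N) map becomes a (1, N) row."""
    x = np.asarray(feature_map, dtype=float)
    if x.ndim < 2:
        raise ValueError("expected at least one spatial axis plus channels")
    return x.mean(axis=tuple(range(x.ndim - 1)))[None, :]


def build_volume_classifier(spec: VolumeClassifierSpec | None = None,
                            seed: int = 0) -> nn.Model:
    """Build the classifier; maps (n, W, H, D, 1) -> (n, 1) probabilities."""
    spec = spec or VolumeClassifierSpec()
    n_pools = len(spec.filters)
    min_size = spec.pool_window**n_pools
    if min(spec.input_size) < min_size:
        raise ValueError(
            f"input size {spec.input_size} too small for {n_pools} pooling "
            f"stages; each axis must be at least {min_size}"
        )
    layers: list[nn.Layer] = []
    for f in spec.filters:
        layers += [
            nn.Conv(f, spec.kernel_size, ndim=3, activation="relu"),
            nn.MaxPool(spec.pool_window, ndim=3),
            nn.BatchNorm(),
        ]
    layers += [
        nn.GlobalAveragePool(),
        nn.Dense(spec.dense_units, activation="relu"),
        nn.Dropout(spec.dropout),
        nn.Dense(1, activation="sigmoid"),
    ]
    return nn.Model(layers, input_shape=(*spec.input_size, 1), seed=seed)


def volumes_to_tensor(volumes: list[np.ndarray]) -> np.ndarray:
    """Stack preprocessed (depth, height, width) grids as (n, W, H, D, 1)."""
    return np.stack([np.transpose(np.asarray(v), (2, 1, 0))[..., None] for v in volumes])


def prepare_volume_dataset(data: LabeledVolumeSet, config: PreprocConfig | None = None,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Preprocess every volume and return (x, y) model-boundary tensors."""
    config = config or PreprocConfig()
    x = volumes_to_tensor([preprocess_volume(v, config) for v in data.volumes])
    return x, data.labels.astype(float)[:, None]


def train_volume_classifier(
    model: nn.Model,
    data: LabeledVolumeSet | tuple[np.ndarray, np.ndarray],
    config=None,
    stop: EarlyStopPolicy | None = None,
    preproc: PreprocConfig | None = None,
    epochs: int = 100,
    verbose: bool = False,
) -> TrainingHistory:
    """Train with per-epoch shuffling and early stopping (default 100 epochs).

    ``data`` is either a :class:`LabeledVolumeSet` (preprocessed through
    ``preproc``) or a ready (x, y) pair.  Both classes must be present.
    """
    from .frame_predictor import TrainConfig  # shared config type

    if isinstance(data, LabeledVolumeSet):
        x, y = prepare_volume_dataset(data, preproc)
    else:
        x, y = data
    if len(np.unique(np.round(y))) < 2:
        raise ValueError(
            "training set contains a single class; resample first "
            "(see ctmonitor.evaluation.undersample/oversample)"
        )
    config = config or TrainConfig(epochs=epochs, metric="binary_accuracy")
    stop = stop if stop is not None else EarlyStopPolicy(
        monitor="val_loss", patience=15, restore_best=True)
    return model.fit(
        x, y,
        epochs=config.epochs,
        batch_size=config.batch_size,
        loss="bce",
        metric="binary_accuracy",
        optimizer=Adam(config.learning_rate),
        validation_split=config.validation_split,
        early_stopping=stop,
        verbose=verbose,
    )


def predict_volume(model: nn.Model, vol: np.ndarray) -> float:
    """Probability that a preprocessed (D, H, W) volume contains an anomaly.

    The binary label is probability >= 0.5.
    """
    x = volumes_to_tensor([vol])
    expected = model.input_shape
    if x.shape[1:] != expected:
        raise ValueError(f"volume shape {x.shape[1:]} does not match model input {expected}")
    return float(model.forward(x)[0, 0])
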