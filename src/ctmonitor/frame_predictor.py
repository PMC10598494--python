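"""Next-frame prediction network and reconstruction-error anomaly scoring.

The architecture stacks three recurrent convolutional blocks (ConvLSTM,
kernels 5x5 / 3x3 / 1x1, all returning full sequences) with batch
normalization after the first two, and closes with a 3-D convolution
(3x3x3 kernel, single filter, sigmoid) over the (time, height, width)
stack, so the output is a frame sequence of the same shape as the input
with intensities in [0, 1].

Anomaly scoring follows the reconstruction principle: a model trained on
normal sequences reconstructs them with small error, while unusual events
(an appearing structure, sudden growth) produce large per-frame errors.
A sequence is flagged when its aggregate error exceeds
mean + k_sigma * sd of the errors on a clean calibration set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn.model import Adam, EarlyStopPolicy, TrainingHistory
from .preprocess import SequencePairSet, build_shifted_pairs
from .synthgen import FrameSequence

__all__ = [
    "PredictorSpec",
    "TrainConfig",
    "AnomalyReport",
    "TrainingHistory",
    "build_frame_predictor",
    "train_predictor",
    "predict_rollout",
    "reconstruction_error",
    "score_sequence",
    "detect_anomaly",
]


@dataclass
class PredictorSpec:
    """Architecture hyper-parameters.

    Defaults are the full-scale model (64 filters in each recurrent
    block); :meth:`desk_scale` gives a narrow profile that trains in
    minutes on one CPU and is used throughout the test suite.
    """

    frame_size: int = 64
    channels: int = 1
    filters: tuple[int, int, int] = (64, 64, 64)
    kernel_sizes: tuple[int, int, int] = (5, 3, 1)
    conv3d_kernel: tuple[int, int, int] = (3, 3, 3)
    candidate_activation: str = "tanh"
    output_activation: str = "relu"

    @classmethod
    def desk_scale(cls, frame_size: int = 32) -> "PredictorSpec":
        return cls(frame_size=frame_size, filters=(8, 8, 8))


@dataclass
class TrainConfig:
    """Training settings; batch size defaults to 5 for all models."""

    epochs: int = 5
    batch_size: int = 5
    seed: int = 0
    learning_rate: float = 1e-3
    loss: str = "bce"
    metric: str = "pixel_accuracy"
    validation_split: float = 0.2

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class AnomalyReport:
    """Per-frame reconstruction errors and the thresholded verdict."""

    per_frame_errors: np.ndarray
    aggregate: float
    threshold: float
    flag: bool


def build_frame_predictor(spec: PredictorSpec | None = None, n_steps: int = 19,
                          seed: int = 0) -> nn.Model:
    """Build the predictor; maps (n, T, H, W, 1) -> (n, T, H, W, 1) in [0, 1]."""
    spec = spec or PredictorSpec()
    f1, f2, f3 = spec.filters
    k1, k2, k3 = spec.kernel_sizes
    kw = dict(candidate_activation=spec.candidate_activation,
              output_activation=spec.output_activation)
    layers = [
        nn.ConvLSTM2D(f1, k1, return_sequences=True, **kw),
        nn.BatchNorm(),
        nn.ConvLSTM2D(f2, k2, return_sequences=True, **kw),
        nn.BatchNorm(),
        nn.ConvLSTM2D(f3, k3, return_sequences=True, **kw),
        nn.Conv(1, spec.conv3d_kernel, ndim=3, activation="sigmoid"),
    ]
    input_shape = (n_steps, spec.frame_size, spec.frame_size, spec.channels)
    return nn.Model(layers, input_shape=input_shape, seed=seed)


def train_predictor(model: nn.Model, pairs: SequencePairSet,
                    config: TrainConfig | None = None,
                    early_stopping: EarlyStopPolicy | None = None,
                    verbose: bool = False) -> TrainingHistory:
    """Teacher-forced training on shifted pairs."""
    config = config or TrainConfig()
    if len(pairs) == 0:
        raise ValueError("pair set is empty")
    return model.fit(
        pairs.inputs,
        pairs.targets,
        epochs=config.epochs,
        batch_size=config.batch_size,
        loss=config.loss,
        metric=config.metric,
        optimizer=Adam(config.learning_rate),
        validation_split=config.validation_split,
        early_stopping=early_stopping,
        verbose=verbose,
    )


def predict_rollout(model: nn.Model, seed_frames: FrameSequence | np.ndarray,
                    horizon: int) -> FrameSequence:
    """Autoregressive rollout: each predicted frame joins the context.

    With 10 seed frames and horizon 10 the result is the full 20-frame
    sequence (context plus predictions).
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    frames = seed_frames.frames if isinstance(seed_frames, FrameSequence) else np.asarray(seed_frames)
    if frames.shape[0] < 1:
        raise ValueError("seed_frames is empty")
    context = frames.copy()
    for _ in range(horizon):
        pred = model.forward(context[None])[0]
        context = np.concatenate([context, pred[-1:][...]], axis=0)
    return FrameSequence(frames=np.clip(context, 0.0, 1.0))


def reconstruction_error(predicted, actual) -> np.ndarray:
    """Per-frame mean squared error between two sequences (symmetric)."""
    p = predicted.frames if isinstance(predicted, FrameSequence) else np.asarray(predicted)
    a = actual.frames if isinstance(actual, FrameSequence) else np.asarray(actual)
    if p.shape != a.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {a.shape}")
    return ((p - a) ** 2).mean(axis=tuple(range(1, p.ndim)))


def score_sequence(model: nn.Model, seq: FrameSequence) -> tuple[np.ndarray, float]:
    """One-step reconstruction errors of a sequence under the model.

    Predicts frame t+1 from frames <= t (teacher-forced) and returns the
    per-step errors and their mean.
    """
    pairs = build_shifted_pairs([seq])
    pred = model.forward(pairs.inputs)
    errors = reconstruction_error(pred[0], pairs.targets[0])
    return errors, float(errors.mean())


def detect_anomaly(model: nn.Model, seq: FrameSequence,
                   calibration: list[FrameSequence], k_sigma: float = 3.0) -> AnomalyReport:
    """Flag ``seq`` when its aggregate error exceeds the calibration threshold.

    The threshold is mean + k_sigma * sd of aggregate errors over the
    clean calibration sequences.
    """
    if not calibration:
        raise ValueError("calibration set is empty")
    cal_scores = np.array([score_sequence(model, s)[1] for s in calibration])
    threshold = float(cal_scores.mean() + k_sigma * cal_scores.std())
    errors, aggregate = score_sequence(model, seq)
    return AnomalyReport(
        per_frame_errors=errors,
        aggregate=aggregate,
        threshold=threshold,
        flag=bool(aggregate > threshold),
    )
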