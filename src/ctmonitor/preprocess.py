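"""CT preprocessing chain and shifted-pair dataset construction.

The volume chain: an in-plane 90-degree rotation for orientation
consistency, Hounsfield-unit windowing to [0, 1], trilinear resizing to a
common grid, and (for training only) random in-plane rotation
augmentation.  The sequence side builds teacher-forcing pairs where the
input at timestep t is frame t and the target is frame t+1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .synthgen import CTVolume, FrameSequence

__all__ = [
    "PreprocConfig",
    "SequencePairSet",
    "hu_window_normalize",
    "rotate_volume_90",
    "resize_volume",
    "augment_random_rotation",
    "build_shifted_pairs",
    "preprocess_volume",
    "volume_to_frame_sequence",
]

DEFAULT_HU_WINDOW = (-1000.0, 400.0)
DEFAULT_ANGLES = (-20.0, -10.0, -5.0, 5.0, 10.0, 20.0)


@dataclass
class PreprocConfig:
    """Preprocessing settings.

    ``hu_min``/``hu_max`` bound the HU window ([-1000, 400] spans
    air to soft tissue, the standard lung window).  ``target_size`` is the
    resized (depth, height, width) grid; the default 64 x 128 x 128 suits
    full runs, while tests use a 32^3 desk-scale grid.
    """

    hu_min: float = DEFAULT_HU_WINDOW[0]
    hu_max: float = DEFAULT_HU_WINDOW[1]
    target_size: tuple[int, int, int] = (64, 128, 128)
    augment_angles: tuple[float, ...] = DEFAULT_ANGLES
    rotate90: bool = True

    def __post_init__(self) -> None:
        if self.hu_min >= self.hu_max:
            raise ValueError("hu_min must be < hu_max")
        if min(self.target_size) < 1:
            raise ValueError("target_size components must be >= 1")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "hu_min": float(self.hu_min),
                    "hu_max": float(self.hu_max),
                    "target_size": list(self.target_size),
                    "augment_angles": list(self.augment_angles),
                    "rotate90": bool(self.rotate90),
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "PreprocConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            hu_min=raw["hu_min"],
            hu_max=raw["hu_max"],
            target_size=tuple(raw["target_size"]),
            augment_angles=tuple(raw["augment_angles"]),
            rotate90=raw.get("rotate90", True),
        )


@dataclass
class SequencePairSet:
    """Shifted input/target pairs: inputs[s][t] is frame t, targets[s][t] is frame t+1."""

    inputs: np.ndarray
    targets: np.ndarray

    def __post_init__(self) -> None:
        if self.inputs.shape != self.targets.shape:
            raise ValueError("inputs and targets must share shape")
        if self.inputs.ndim != 5:
            raise ValueError("expected (nSamples, nSteps, H, W, 1) arrays")

    def __len__(self) -> int:
        return self.inputs.shape[0]


def _as_voxels(vol) -> np.ndarray:
    return vol.voxels if isinstance(vol, CTVolume) else np.asarray(vol, dtype=float)


def hu_window_normalize(vol, hu_min: float = DEFAULT_HU_WINDOW[0],
                        hu_max: float = DEFAULT_HU_WINDOW[1]) -> np.ndarray:
    """Clip to [hu_min, hu_max] and map affinely to [0, 1].

    Monotone non-decreasing in the input HU value.
    """
    if hu_min >= hu_max:
        raise ValueError("hu_min must be < hu_max")
    v = _as_voxels(vol)
    return (np.clip(v, hu_min, hu_max) - hu_min) / (hu_max - hu_min)


def rotate_volume_90(vol) -> np.ndarray:
    """Rotate every axial slice 90 degrees counter-clockwise (exact permutation)."""
    return np.rot90(_as_voxels(vol), k=1, axes=(1, 2)).copy()


def resize_volume(vol, target_size: tuple[int, int, int]) -> np.ndarray:
    """Trilinear resize to ``target_size`` (depth, height, width).

    Linear interpolation is convex, so output values stay within the
    input's [min, max].  Resizing to the identical size is the identity.
    """
    if min(target_size) < 1:
        raise ValueError("target_size components must be >= 1")
    v = _as_voxels(vol)
    if v.shape == tuple(target_size):
        return v.copy()
    return _sk_resize(v, target_size, order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)


def augment_random_rotation(vol, angles=DEFAULT_ANGLES,
                            rng: np.random.Generator | None = None) -> np.ndarray:
    """In-plane rotation by an angle drawn uniformly from ``angles`` (degrees).

    Bilinear interpolation, zero border fill; deterministic given the rng
    state.
    """
    angles = tuple(angles)
    if not angles:
        raise ValueError("angles must be non-empty")
    rng = rng or np.random.default_rng()
    angle = float(angles[rng.integers(len(angles))])
    v = _as_voxels(vol)
    if angle == 0.0:
        return v.copy()
    return ndimage.rotate(v, angle, axes=(1, 2), reshape=False, order=1,
                          mode="constant", cval=0.0)


def preprocess_volume(vol, config: PreprocConfig | None = None,
                      augment_rng: np.random.Generator | None = None) -> np.ndarray:
    """Full chain: rotate 90, HU-window to [0, 1], resize; optional augmentation."""
    config = config or PreprocConfig()
    v = _as_voxels(vol)
    if config.rotate90:
        v = rotate_volume_90(v)
    v = hu_window_normalize(v, config.hu_min, config.hu_max)
    v = resize_volume(v, config.target_size)
    if augment_rng is not None:
        v = np.clip(augment_random_rotation(v, config.augment_angles, augment_rng), 0.0, 1.0)
    return v


def build_shifted_pairs(seqs) -> SequencePairSet:
    """Teacher-forcing pairs: inputs are frames 0..T-2, targets frames 1..T-1.

    A 20-frame sequence yields 19 timesteps on both sides, and
    ``inputs[s][t+1] == targets[s][t]`` holds exactly.
    """
    arrays = [s.frames if isinstance(s, FrameSequence) else np.asarray(s, dtype=float)
              for s in seqs]
    if not arrays:
        raise ValueError("no sequences given")
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("all sequences must share the same shape")
    if shape[0] < 2:
        raise ValueError("sequences must have at least 2 frames")
    stack = np.stack(arrays)
    return SequencePairSet(inputs=stack[:, :-1].copy(), targets=stack[:, 1:].copy())


def volume_to_frame_sequence(vol, n_frames: int = 20, size: int = 64,
                             config: PreprocConfig | None = None) -> FrameSequence:
    """Treat a CT volume's depth axis as time: a slice stack becomes a sequence.

    The volume is HU-windowed and resized so that ``n_frames`` axial slices
    of ``size`` x ``size`` pixels come out, mirroring the conversion of
    volumetric studies into frame-prediction inputs.
    """
    config = config or PreprocConfig()
    v = hu_window_normalize(_as_voxels(vol), config.hu_min, config.hu_max)
    v = resize_volume(v, (n_frames, size, size))
    return FrameSequence(frames=np.clip(v, 0.0, 1.0)[..., None])
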