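"""Synthetic data: moving-glyph frame sequences and CT lung phantoms.

The moving-glyph generator emulates the classic bouncing-digit video
benchmark: procedurally drawn sprites (discs, rings, crosses, bars,
squares) translate with constant velocity and reflect elastically at the
frame borders.  The phantom generator produces Hounsfield-unit lung
volumes — air background (-1000 HU), a soft-tissue body ellipsoid
(+40 HU), two noisy lung ellipsoids (-800 HU) and, optionally, a
spherical nodule (+50 HU) inside a lung.  Both are pure functions of
their arguments including the seed.

On-disk formats: NIfTI-1 for volumes (via nibabel), ``frame_%03d.png``
series for sequences, JSON sidecars for labels.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "FrameSequence",
    "CTVolume",
    "LabeledVolumeSet",
    "GlyphState",
    "NoduleSpec",
    "FormatError",
    "generate_moving_glyphs",
    "generate_ct_phantom",
    "generate_labeled_volumes",
    "inject_sequence_anomaly",
    "reflect_position",
    "read_nifti",
    "write_nifti",
    "read_png_frames",
    "write_png_frames",
    "write_labels_json",
    "read_labels_json",
]

AIR_HU = -1000.0
BODY_HU = 40.0
LUNG_HU = -800.0
NODULE_HU = 50.0
LUNG_NOISE_SD = 20.0


class FormatError(ValueError):
    """A file could not be parsed; the message names the offending field."""


# ------------------------------------------------------------------- types

@dataclass
class FrameSequence:
    """Ordered stack of grayscale frames, shape (nFrames, H, W, 1), values in [0, 1]."""

    frames: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 1:
            raise ValueError(
                f"frames must be (nFrames, H, W, 1), got {self.frames.shape}"
            )
        if self.frames.min() < 0.0 or self.frames.max() > 1.0:
            raise ValueError("frame intensities must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def size(self) -> int:
        return self.frames.shape[1]


@dataclass
class CTVolume:
    """3-D voxel grid in Hounsfield units, axis order (depth, height, width).

    ``spacing`` is the physical voxel size in mm per axis, same order.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError(f"voxels must be a non-empty 3-D grid, got {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels contain non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class LabeledVolumeSet:
    """CT volumes with one binary label each (1 = anomaly/nodule present)."""

    volumes: list[CTVolume]
    labels: np.ndarray
    class_names: tuple[str, str] = ("Normal", "Abnormal")

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.volumes) != len(self.labels):
            raise ValueError("one label per volume required")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be 0 or 1")

    def __len__(self) -> int:
        return len(self.volumes)


@dataclass
class GlyphState:
    """Center position and per-frame velocity of one moving sprite."""

    position: tuple[float, float]
    velocity: tuple[float, float]
    shape_id: int = 0
    size_px: int = 12


@dataclass
class NoduleSpec:
    """Spherical nodule: center in (depth, height, width) voxels, radius, HU value."""

    center: tuple[int, int, int]
    radius: float
    hu: float = NODULE_HU


# ------------------------------------------------------------ moving glyphs

def reflect_position(p: float, v: float, lo: float, hi: float) -> tuple[float, float]:
    """One bounce step: advance ``p`` by ``v``, reflecting elastically at [lo, hi]."""
    p2 = p + v
    while p2 < lo or p2 > hi:
        if p2 > hi:
            p2 = 2 * hi - p2
        else:
            p2 = 2 * lo - p2
        v = -v
    return p2, v


def _sprite(shape_id: int, size_px: int) -> np.ndarray:
    """Procedural binary sprite on a size_px x size_px canvas."""
    s = size_px
    yy, xx = np.mgrid[0:s, 0:s]
    cy = cx = (s - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    if shape_id % 5 == 0:  # disc
        return (r <= s * 0.38).astype(float)
    if shape_id % 5 == 1:  # ring
        return ((r <= s * 0.42) & (r >= s * 0.22)).astype(float)
    if shape_id % 5 == 2:  # cross
        arm = max(1, s // 6)
        m = np.zeros((s, s))
        m[:, s // 2 - arm // 2 : s // 2 + (arm + 1) // 2] = 1.0
        m[s // 2 - arm // 2 : s // 2 + (arm + 1) // 2, :] = 1.0
        return m
    if shape_id % 5 == 3:  # vertical bar
        m = np.zeros((s, s))
        m[:, s // 2 - s // 6 : s // 2 + s // 6 + 1] = 1.0
        return m
    m = np.zeros((s, s))  # hollow square
    t = max(1, s // 6)
    m[1 : s - 1, 1 : s - 1] = 1.0
    m[1 + t : s - 1 - t, 1 + t : s - 1 - t] = 0.0
    return m


def _stamp(frame: np.ndarray, sprite: np.ndarray, center: tuple[float, float]) -> None:
    s = sprite.shape[0]
    top = int(round(center[0] - (s - 1) / 2.0))
    left = int(round(center[1] - (s - 1) / 2.0))
    frame[top : top + s, left : left + s] = np.maximum(
        frame[top : top + s, left : left + s], sprite
    )


def generate_moving_glyphs(
    n_samples: int,
    n_frames: int = 20,
    size: int = 64,
    glyphs_per_seq: int = 2,
    seed: int = 0,
    speed_range: tuple[float, float] = (1.0, 3.0),
    sprites: list[np.ndarray] | None = None,
) -> list[FrameSequence]:
    """Generate bouncing-sprite sequences.

    Each sequence has ``n_frames`` frames of ``size`` x ``size`` pixels in
    [0, 1].  Glyphs translate with a constant velocity (speed drawn from
    ``speed_range`` px/frame, direction uniform) and reflect elastically at
    the borders, so no glyph pixel ever leaves the frame.  ``sprites``
    optionally supplies external grayscale sprites (e.g. 28x28 digit
    images, values in [0, 1]) used instead of the procedural shapes.
    """
    if n_samples < 1 or glyphs_per_seq < 1:
        raise ValueError("n_samples and glyphs_per_seq must be positive")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if size < 16:
        raise ValueError("size must be >= 16")
    rng = np.random.default_rng(seed)
    sprite_px = max(8, size // 5)
    sequences = []
    for _ in range(n_samples):
        glyphs: list[GlyphState] = []
        drawn: list[np.ndarray] = []
        for _ in range(glyphs_per_seq):
            if sprites is not None:
                sp = np.asarray(sprites[rng.integers(len(sprites))], dtype=float)
                sid = -1
            else:
                sid = int(rng.integers(5))
                sp = _sprite(sid, sprite_px)
            margin = (sp.shape[0] - 1) / 2.0 + 0.5
            pos = tuple(rng.uniform(margin, size - 1 - margin, size=2))
            speed = rng.uniform(*speed_range)
            angle = rng.uniform(0, 2 * np.pi)
            vel = (speed * np.sin(angle), speed * np.cos(angle))
            glyphs.append(GlyphState(position=pos, velocity=vel, shape_id=sid,
                                     size_px=sp.shape[0]))
            drawn.append(sp)
        frames = np.zeros((n_frames, size, size, 1))
        for t in range(n_frames):
            for g, sp in zip(glyphs, drawn):
                _stamp(frames[t, :, :, 0], sp, g.position)
            for g, sp in zip(glyphs, drawn):
                margin = (sp.shape[0] - 1) / 2.0 + 0.5
                pr, vr = reflect_position(g.position[0], g.velocity[0], margin, size - 1 - margin)
                pc, vc = reflect_position(g.position[1], g.velocity[1], margin, size - 1 - margin)
                g.position = (pr, pc)
                g.velocity = (vr, vc)
        sequences.append(FrameSequence(frames=np.clip(frames, 0.0, 1.0)))
    return sequences


def inject_sequence_anomaly(
    seq: FrameSequence,
    onset: int,
    mode: str = "appear-blob",
    seed: int | None = None,
    blob_radius: int | None = None,
    blob_intensity: float = 0.9,
) -> FrameSequence:
    """Inject an anomalous event from frame ``onset`` onward.

    ``appear-blob`` overlays a bright soft-edged blob (pixelwise max) on
    every frame at or after the onset — the analogue of a nodule appearing
    during monitoring.  ``sudden-growth`` progressively dilates the frame
    content — the analogue of undue growth of an existing structure.
    Frames before the onset are returned bit-identical.
    """
    frames = seq.frames
    n, h, w, _ = frames.shape
    if not 0 <= onset < n:
        raise ValueError(f"onset {onset} outside [0, {n})")
    out = frames.copy()
    if mode == "appear-blob":
        radius = blob_radius if blob_radius is not None else max(3, h // 6)
        if seed is None:
            cy, cx = h / 2.0, w / 2.0
        else:
            r = np.random.default_rng(seed)
            cy = r.uniform(radius, h - 1 - radius)
            cx = r.uniform(radius, w - 1 - radius)
        yy, xx = np.mgrid[0:h, 0:w]
        d = np.hypot(yy - cy, xx - cx)
        blob = blob_intensity * np.clip(1.0 - (d / radius) ** 2, 0.0, 1.0)
        out[onset:, :, :, 0] = np.maximum(out[onset:, :, :, 0], blob)
    elif mode == "sudden-growth":
        for t in range(onset, n):
            k = 1 + 2 * min(t - onset + 1, 4)
            out[t, :, :, 0] = ndimage.grey_dilation(out[t, :, :, 0], size=(k, k))
    else:
        raise ValueError(f"unknown anomaly mode {mode!r}")
    return FrameSequence(frames=np.clip(out, 0.0, 1.0))


# ----------------------------------------------------------------- phantoms

def _ellipsoid_mask(shape, center, semi) -> np.ndarray:
    zz, yy, xx = np.ogrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    return (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _lung_geometry(shape):
    d, h, w = shape
    center_z, center_y = d / 2.0, h / 2.0
    semi = (0.38 * d, 0.26 * h, 0.15 * w)
    left = (center_z, center_y, 0.32 * w)
    right = (center_z, center_y, 0.68 * w)
    return left, right, semi


def default_nodule_spec(shape) -> NoduleSpec:
    """A nodule centred in the left lung, radius scaled to the volume."""
    left, _, _ = _lung_geometry(shape)
    radius = max(2.0, min(shape) / 8.0)
    return NoduleSpec(center=tuple(int(round(c)) for c in left), radius=radius)


def generate_ct_phantom(
    size: tuple[int, int, int] = (64, 64, 64),
    with_nodule: bool = False,
    nodule_spec: NoduleSpec | None = None,
    seed: int = 0,
) -> CTVolume:
    """Build an HU-valued lung phantom.

    Air background at -1000 HU, body ellipsoid at +40 HU, two lung
    ellipsoids at -800 HU with additive Gaussian noise (sd 20 HU), and —
    when ``with_nodule`` — a noise-free +50 HU sphere strictly inside a
    lung.  The noise field is drawn before the nodule is stamped, so the
    with/without-nodule volumes under the same seed differ exactly on the
    nodule sphere.
    """
    if min(size) < 8:
        raise ValueError("each size component must be >= 8")
    d, h, w = size
    rng = np.random.default_rng(seed)
    vol = np.full(size, AIR_HU)
    body = _ellipsoid_mask(size, (d / 2.0, h / 2.0, w / 2.0), (0.52 * d, 0.40 * h, 0.45 * w))
    vol[body] = BODY_HU
    left, right, semi = _lung_geometry(size)
    lungs = _ellipsoid_mask(size, left, semi) | _ellipsoid_mask(size, right, semi)
    lungs &= body
    noise = rng.normal(0.0, LUNG_NOISE_SD, size=size)
    vol[lungs] = LUNG_HU + noise[lungs]
    meta = {
        "lung_depth_span": (
            int(np.flatnonzero(lungs.any(axis=(1, 2)))[0]),
            int(np.flatnonzero(lungs.any(axis=(1, 2)))[-1]),
        ),
        "with_nodule": bool(with_nodule),
    }
    if with_nodule:
        spec = nodule_spec or default_nodule_spec(size)
        zz, yy, xx = np.ogrid[0:d, 0:h, 0:w]
        sphere = (
            (zz - spec.center[0]) ** 2
            + (yy - spec.center[1]) ** 2
            + (xx - spec.center[2]) ** 2
        ) <= spec.radius**2
        if not sphere.any():
            raise ValueError("nodule sphere contains no voxels")
        if not lungs[sphere].all():
            raise ValueError("nodule must lie entirely inside the lung region")
        vol[sphere] = spec.hu
        meta["nodule"] = {"center": list(spec.center), "radius": spec.radius, "hu": spec.hu}
    return CTVolume(voxels=vol, id=f"phantom-{seed}", meta=meta)


def generate_labeled_volumes(
    n: int,
    anomaly_rate: float = 0.5,
    size: tuple[int, int, int] = (64, 64, 64),
    seed: int = 0,
) -> LabeledVolumeSet:
    """Generate ``n`` phantoms; round(n * anomaly_rate) carry a nodule.

    The positive count uses round-half-even so label counts are
    reproducible.  Nodule centers and radii are jittered inside the left
    or right lung per volume, deterministically under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= anomaly_rate <= 1.0:
        raise ValueError("anomaly_rate must be in [0, 1]")
    n_pos = round(n * anomaly_rate)
    rng = np.random.default_rng(seed)
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)
    left, right, semi = _lung_geometry(size)
    volumes = []
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    for i in range(n):
        if labels[i]:
            r = np.random.default_rng(int(child_seeds[i]) + 1)
            lung = left if r.random() < 0.5 else right
            jitter_frac = r.uniform(-0.2, 0.2, size=3)
            desired = r.uniform(2.0, max(2.5, min(size) / 8.0))
            vol = None
            # shrink jitter and radius until the voxelized sphere fits the lung
            for _ in range(6):
                jitter = jitter_frac * np.array(semi)
                center = tuple(int(round(c + j)) for c, j in zip(lung, jitter))
                norm = float(np.sqrt((jitter_frac**2).sum()))
                r_max = (1.0 - norm) * min(semi) - 1.0
                radius = max(1.0, min(desired, r_max))
                try:
                    vol = generate_ct_phantom(
                        size, with_nodule=True,
                        nodule_spec=NoduleSpec(center=center, radius=radius),
                        seed=int(child_seeds[i]))
                    break
                except ValueError:
                    jitter_frac *= 0.5
                    desired *= 0.8
            if vol is None:
                raise ValueError(
                    f"cannot place a nodule inside the lungs of a {size} phantom"
                )
        else:
            vol = generate_ct_phantom(size, with_nodule=False, seed=int(child_seeds[i]))
        vol.id = f"vol-{i:03d}"
        volumes.append(vol)
    return LabeledVolumeSet(volumes=volumes, labels=labels)


# ----------------------------------------------------------------------- IO

def write_nifti(vol: CTVolume, path) -> None:
    """Write a volume as NIfTI-1; axes stored as (x=width, y=height, z=depth)."""
    data = np.transpose(vol.voxels, (2, 1, 0)).astype(np.float32)
    sd, sh, sw = vol.spacing
    affine = np.diag([sw, sh, sd, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((sw, sh, sd))
    nib.save(img, str(path))


def read_nifti(path) -> CTVolume:
    """Read a NIfTI volume into the (depth, height, width) convention.

    The on-disk (x, y, z) axes are reordered to (z, y, x); the original
    order is recorded in ``meta['source_axes']``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        zooms = img.header.get_zooms()[:3]
    except Exception as exc:  # nibabel raises several parse error types
        raise FormatError(f"{path}: cannot parse NIfTI header/data: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path}: field 'dim' describes a {data.ndim}-D image, expected 3-D")
    if not np.all(np.isfinite(data)):
        raise FormatError(f"{path}: field 'voxels' contains non-finite values")
    return CTVolume(
        voxels=np.transpose(data, (2, 1, 0)),
        spacing=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
        id=path.name.split(".")[0],
        meta={"source_axes": "xyz"},
    )


def write_png_frames(seq: FrameSequence, directory) -> list[Path]:
    """Write a sequence as 8-bit ``frame_%03d.png`` files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in range(seq.n_frames):
        frame = np.round(seq.frames[t, :, :, 0] * 255.0).astype(np.uint8)
        p = directory / f"frame_{t:03d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def read_png_frames(directory) -> FrameSequence:
    """Read a ``frame_*.png`` series back as a [0, 1] sequence."""
    directory = Path(directory)
    if not directory.exists():
        raise FileNotFoundError(directory)
    paths = sorted(directory.glob("frame_*.png"),
                   key=lambda p: int(re.findall(r"\d+", p.stem)[-1]))
    if not paths:
        raise FormatError(f"{directory}: no frame_*.png files found")
    frames = np.stack([np.asarray(iio.imread(p), dtype=float) / 255.0 for p in paths])
    if frames.ndim != 3:
        raise FormatError(f"{directory}: frames are not single-channel grayscale")
    return FrameSequence(frames=frames[..., None])


def write_labels_json(data: LabeledVolumeSet, path) -> None:
    Path(path).write_text(
        json.dumps({v.id: int(l) for v, l in zip(data.volumes, data.labels)}, indent=0)
    )


def read_labels_json(path) -> dict[str, int]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    out = {}
    for k, v in raw.items():
        if v not in (0, 1):
            raise FormatError(f"{path}: field {k!r} has non-binary label {v!r}")
        out[k] = int(v)
    return out
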