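"""Experiment presets and the reproducible experiment runner.

Presets 1.1-1.3 are the frame-prediction experiments (examples/epochs =
100/5, 1000/5, 1000/20; batch size 5 throughout).  The remaining presets
reproduce the experiment *shapes* of the CT studies on synthetic data —
the original datasets are hospital-confidential or external downloads —
and are suffixed ``-synthetic``.  For 3.2 the source table is garbled;
353 examples at the stated 100 epochs is the adopted reading.  Tables for
4.1/4.2 list 3532 examples with epochs read as 10 and 20.

``run_experiment`` writes a config snapshot, seed, history CSV, metrics
JSON and a checkpoint so a run can be reproduced from its manifest.
``scale`` shrinks the example count and the ``desk`` profile shrinks the
networks; both are recorded in the manifest.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .evaluation import (
    accuracy,
    confusion_from_predictions,
    export_history,
    fallout,
    sensitivity,
)
from .frame_predictor import (
    PredictorSpec,
    TrainConfig,
    build_frame_predictor,
    train_predictor,
)
from .preprocess import PreprocConfig, build_shifted_pairs
from .slice_classifier import (
    SliceClassifierSpec,
    build_slice_classifier,
    make_slice_tasks,
    train_slice_classifier,
)
from .synthgen import generate_labeled_volumes, generate_moving_glyphs
from .volume_classifier import (
    VolumeClassifierSpec,
    build_volume_classifier,
    prepare_volume_dataset,
    train_volume_classifier,
)

__all__ = ["ExperimentPreset", "PRESETS", "run_experiment"]


@dataclass(frozen=True)
class ExperimentPreset:
    name: str
    kind: str  # "frame" | "volume" | "slice"
    n_examples: int
    epochs: int
    batch_size: int = 5
    task: str = ""  # slice task name
    class_names: tuple[str, str] = ("", "")


PRESETS: dict[str, ExperimentPreset] = {
    p.name: p
    for p in [
        ExperimentPreset("1.1", "frame", 100, 5),
        ExperimentPreset("1.2", "frame", 1000, 5),
        ExperimentPreset("1.3", "frame", 1000, 20),
        ExperimentPreset("2.1-synthetic", "frame", 383, 5),
        ExperimentPreset("2.2-synthetic", "frame", 383, 20),
        ExperimentPreset("3.1-synthetic", "volume", 50, 100,
                         class_names=("Normal", "Abnormal")),
        ExperimentPreset("3.2-synthetic", "volume", 353, 100,
                         class_names=("Normal", "Abnormal")),
        ExperimentPreset("4.1-synthetic", "slice", 3532, 10, task="body-part",
                         class_names=("OTHER", "ACT")),
        ExperimentPreset("4.2-synthetic", "slice", 3532, 20, task="plane",
                         class_names=("OTHER", "AXIAL")),
    ]
}


def run_experiment(preset: ExperimentPreset | str, output_dir, seed: int = 0,
                   profile: str = "desk", scale: float = 1.0,
                   verbose: bool = False) -> dict:
    """Run one preset end to end and write its artifacts to ``output_dir``.

    Returns the metrics dict.  ``profile`` selects the network width
    ("full" = full-scale architecture, "desk" = narrow test-scale);
    ``scale`` multiplies the example count.  Outputs: config.yaml,
    history.csv, metrics.json, checkpoint.npz, manifest.json.
    """
    if isinstance(preset, str):
        if preset not in PRESETS:
            raise ValueError(
                f"unknown preset {preset!r}; valid: {sorted(PRESETS)}"
            )
        preset = PRESETS[preset]
    if profile not in ("full", "desk"):
        raise ValueError("profile must be 'full' or 'desk'")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = max(4, int(round(preset.n_examples * scale)))
    config = TrainConfig(epochs=preset.epochs, batch_size=preset.batch_size, seed=seed)

    if preset.kind == "frame":
        frame_size = 64 if profile == "full" else 32
        spec = PredictorSpec(frame_size=frame_size) if profile == "full" \
            else PredictorSpec.desk_scale(frame_size)
        seqs = generate_moving_glyphs(n, n_frames=20, size=frame_size, seed=seed)
        pairs = build_shifted_pairs(seqs)
        model = build_frame_predictor(spec, n_steps=pairs.inputs.shape[1], seed=seed)
        history = train_predictor(model, pairs, config, verbose=verbose)
        pred = model.predict(pairs.inputs, batch_size=preset.batch_size)
        metrics = {
            "final_train_loss": history.train_loss[-1],
            "final_train_acc": history.train_acc[-1],
            "mean_reconstruction_error": float(((pred - pairs.targets) ** 2).mean()),
        }
    elif preset.kind == "volume":
        size = 64 if profile == "full" else 32
        spec = (VolumeClassifierSpec(input_size=(size, size, size))
                if profile == "full" else VolumeClassifierSpec.desk_scale(size))
        data = generate_labeled_volumes(n, anomaly_rate=0.5, size=(size, size, size),
                                        seed=seed)
        preproc = PreprocConfig(target_size=(size, size, size))
        x, y = prepare_volume_dataset(data, preproc)
        model = build_volume_classifier(spec, seed=seed)
        history = train_volume_classifier(model, (x, y), config, verbose=verbose)
        yp = (model.predict(x, batch_size=preset.batch_size) >= 0.5).astype(int)
        counts = confusion_from_predictions(y, yp)
        metrics = {
            "accuracy": accuracy(counts),
            "sensitivity": sensitivity(counts),
            "fallout": fallout(counts),
            "confusion": {"tp": counts.tp, "fp": counts.fp,
                          "tn": counts.tn, "fn": counts.fn},
        }
    else:  # slice
        size = 32
        n_vol = max(2, n // 8)
        volumes = generate_labeled_volumes(n_vol, anomaly_rate=0.5,
                                           size=(size, size, size), seed=seed)
        data = make_slice_tasks(volumes, task=preset.task, size=64,
                                slices_per_volume=8, seed=seed)
        spec = SliceClassifierSpec() if profile == "full" \
            else SliceClassifierSpec.desk_scale()
        model = build_slice_classifier(spec, seed=seed)
        history = train_slice_classifier(model, data, config, verbose=verbose)
        yp = model.predict(data.slices[..., None],
                           batch_size=preset.batch_size).argmax(axis=-1)
        counts = confusion_from_predictions(data.labels, yp)
        metrics = {
            "accuracy": accuracy(counts),
            "sensitivity": sensitivity(counts),
            "fallout": fallout(counts),
            "confusion": {"tp": counts.tp, "fp": counts.fp,
                          "tn": counts.tn, "fn": counts.fn},
        }

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {"preset": json.loads(json.dumps(asdict(preset))), "seed": seed, "profile": profile,
             "scale": scale, "n_examples_used": n},
            fh,
        )
    export_history(history, out / "history.csv")
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    model.save_weights(out / "checkpoint.npz")
    manifest = {
        "preset": preset.name,
        "seed": seed,
        "profile": profile,
        "scale": scale,
        "files": ["config.yaml", "history.csv", "metrics.json", "checkpoint.npz"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return metrics
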