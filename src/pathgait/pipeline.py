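"""End-to-end pipeline: synth -> prep -> cycles -> templates -> fuse -> train -> eval.

``run_pipeline`` executes every stage in order under one run directory,
writing intermediates (sequences, cycle reports, templates, fused energy
images, metrics) and a manifest with content hashes; stages never mutate a
prior stage's outputs. ``synthetic_benchmark`` is the in-memory variant used
for quick evaluation: it returns the trained model's test metrics without
touching disk.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .cycles import aspect_ratio_series, detect_troughs, segment_cycles
from .fusion import default_fusion_target, fuse, optimize_fusion_weights
from .nn.model import ModelConfig, build_model, count_parameters
from .prep import preprocess_sequence
from .synthetic import GAIT_CLASSES, WalkerParams, generate_labeled_dataset
from .templates import compute_all_templates
from .training import (TrainConfig, compute_features, confusion_from_predictions,
                       metrics_from_confusion, predict, split_indices, train)


@dataclass
class SynthConfig:
    n_per_class: int = 10            # sequences per gait class
    n_cycles: int = 3                # gait cycles per sequence
    noise_rate: float = 0.01         # silhouette-noise pixel flip rate
    max_cycles_per_class: int | None = None  # cap on extracted cycle samples


@dataclass
class PrepConfig:
    threshold: int = 127
    open_radius: int = 1
    close_radius: int = 1
    margin: int = 0
    out_size: int = 256


@dataclass
class CycleConfig:
    smooth_window: int = 5
    min_separation: int = 3
    prominence: float = 0.02


@dataclass
class FusionConfig:
    target: str = "max"              # max | mean
    n_restarts: int = 5
    max_iter: int = 5000
    cost_tol: float = 1e-8


@dataclass
class PipelineConfig:
    """Full run configuration; every stage block validates up front."""

    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)
    prep: PrepConfig = field(default_factory=PrepConfig)
    cycles: CycleConfig = field(default_factory=CycleConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    model: ModelConfig = field(default_factory=lambda: ModelConfig(freeze_backbone=True))
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        learning_rate=1e-3, epochs=15))
    write_frames: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        blocks = {"synth": SynthConfig, "prep": PrepConfig, "cycles": CycleConfig,
                  "fusion": FusionConfig, "model": ModelConfig, "train": TrainConfig}
        kwargs: dict = {}
        for key, val in raw.items():
            if key in blocks:
                if not isinstance(val, dict):
                    raise ValueError(f"config block {key!r} must be a mapping")
                if key == "model" and isinstance(val.get("icbam"), dict):
                    from .nn.attention import IcbamConfig
                    val = {**val, "icbam": IcbamConfig(**val["icbam"])}
                kwargs[key] = blocks[key](**val)
            elif key in ("seed", "write_frames"):
                kwargs[key] = val
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def build_fei_dataset(config: PipelineConfig, out_dir: Path | None = None,
                      manifest: dict | None = None):
    """Stages synth..fuse: returns (X, y, class_names, records).

    X is (n_samples, 1, 256, 256) scaled to [0, 1]; records carry per-cycle
    provenance (sequence, cycle span, fusion weights and cost).
    """
    seed = config.seed
    base = WalkerParams(noise_rate=config.synth.noise_rate,
                        n_cycles=config.synth.n_cycles)
    data = generate_labeled_dataset(config.synth.n_per_class, base=base, seed=seed)

    cap = config.synth.max_cycles_per_class
    per_class: dict[str, int] = {c: 0 for c in GAIT_CLASSES}
    feis, labels, records = [], [], []
    for s_idx, (walk, label) in enumerate(data):
        if cap is not None and per_class[label] >= cap:
            continue
        seq_name = f"{label}_{s_idx:03d}"
        if out_dir is not None and config.write_frames:
            seq_dir = gio.save_walk(walk, out_dir / "sequences" / seq_name)
            if manifest is not None:
                manifest.setdefault("sequences", []).append(str(seq_dir))
        elif manifest is not None:
            manifest.setdefault("sequences", []).append(seq_name)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            seq = preprocess_sequence(
                [f.pixels for f in walk.sequence.frames],
                threshold=config.prep.threshold, open_radius=config.prep.open_radius,
                close_radius=config.prep.close_radius, margin=config.prep.margin,
                out_size=config.prep.out_size)
        series = aspect_ratio_series(seq, config.cycles.smooth_window)
        troughs = detect_troughs(series, config.cycles.min_separation,
                                 config.cycles.prominence)
        if out_dir is not None:
            csv_path = out_dir / "cycles" / f"{seq_name}_ratio.csv"
            csv_path.parent.mkdir(parents=True, exist_ok=True)
            pd.DataFrame({"ratio": series.values,
                          "smoothed": series.smoothed}).to_csv(csv_path, index=False)
        for c_idx, cyc in enumerate(segment_cycles(seq, troughs)):
            if cap is not None and per_class[label] >= cap:
                break
            gei, geni, aei = compute_all_templates(cyc)
            target = default_fusion_target(gei, geni, aei, config.fusion.target)
            fw = optimize_fusion_weights(
                gei, geni, aei, target, n_restarts=config.fusion.n_restarts,
                max_iter=config.fusion.max_iter, cost_tol=config.fusion.cost_tol,
                seed=seed)
            fei = fuse(gei, geni, aei, fw)
            if out_dir is not None:
                stem = out_dir / "templates" / seq_name / f"cycle{c_idx}"
                for img, name in ((gei, "gei"), (geni, "geni"), (aei, "aei"), (fei, "fei")):
                    gio.save_energy_image(img, stem.parent / f"{stem.name}_{name}")
                gio.write_json({"weights": fw.weights, "cost": fw.cost,
                                "n_iter": fw.n_iter, "restart_index": fw.restart_index,
                                "seed": seed},
                               stem.parent / f"{stem.name}_weights.json")
            feis.append(fei.pixels / 255.0)
            labels.append(label)
            records.append({"sequence": seq_name, "cycle": c_idx,
                            "span": [cyc.start_frame, cyc.end_frame],
                            "weights": fw.weights.tolist(), "cost": fw.cost})
            per_class[label] += 1

    X = np.asarray(feis)[:, None, :, :]
    y = np.asarray([GAIT_CLASSES.index(l) for l in labels])
    if manifest is not None:
        manifest["n_feis"] = len(feis)
        manifest["cycles_per_class"] = per_class
    return X, y, list(GAIT_CLASSES), records


def train_and_evaluate(X: np.ndarray, y: np.ndarray, class_names: list[str],
                       model_config: ModelConfig, train_config: TrainConfig):
    """Stratified split, training, and test-set evaluation.

    Returns (model, history, confusion matrix, metrics report).
    """
    tr_idx, te_idx = split_indices(y, train_config.test_fraction, train_config.seed)
    model = build_model(model_config)
    frozen = not any(p.trainable for p in model.backbone.parameters())
    feats = compute_features(model, X, train_config.batch_size) if frozen else None
    history = train(model, (X[tr_idx], y[tr_idx]), train_config,
                    cached_features=feats[tr_idx] if frozen else None)
    preds = predict(model, X[te_idx], train_config.batch_size,
                    cached_features=feats[te_idx] if frozen else None)
    cm = confusion_from_predictions(y[te_idx], preds, class_names)
    report = metrics_from_confusion(cm)
    return model, history, cm, report


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute all stages, writing artifacts and a manifest under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _config_dict(config)}

    X, y, class_names, records = build_fei_dataset(config, out, manifest)
    gio.write_json({"cycles": records}, out / "cycles" / "cycles.json")

    train_config = TrainConfig(**{**asdict(config.train), "seed": config.seed})
    model_config = config.model
    if model_config.seed != config.seed:
        d = asdict(model_config)
        d["seed"] = config.seed
        d["icbam"] = model_config.icbam
        model_config = ModelConfig(**d)
    model, history, cm, report = train_and_evaluate(
        X, y, class_names, model_config, train_config)

    pd.DataFrame({"epoch": np.arange(1, len(history.loss) + 1),
                  "loss": history.loss,
                  "accuracy": history.accuracy}).to_csv(out / "training_log.csv",
                                                        index=False)
    gio.write_json({"confusion_matrix": cm.counts, "class_names": class_names,
                    **report.as_dict()}, out / "metrics.json")
    manifest["trainable_parameters"] = count_parameters(model)
    manifest["metrics"] = str(out / "metrics.json")
    manifest["artifact_hashes"] = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*.json")) if p.name != "manifest.json"
    }
    gio.write_json(manifest, out / "manifest.json")
    return out


def synthetic_benchmark(n_cycles_per_class: int = 40, epochs: int = 15,
                        seed: int = 0, learning_rate: float = 1e-3):
    """In-memory end-to-end run on the synthetic five-class dataset.

    Generates enough walking passes for ``n_cycles_per_class`` cycle samples
    per class, builds FEIs, trains the frozen-backbone classifier and returns
    (metrics report, confusion matrix, history).
    """
    n_seq = int(np.ceil(n_cycles_per_class / 3)) + 1
    config = PipelineConfig(
        seed=seed,
        synth=SynthConfig(n_per_class=n_seq, max_cycles_per_class=n_cycles_per_class),
        train=TrainConfig(learning_rate=learning_rate, epochs=epochs, seed=seed),
        model=ModelConfig(freeze_backbone=True, seed=seed),
        write_frames=False,
    )
    X, y, class_names, _ = build_fei_dataset(config)
    _, history, cm, report = train_and_evaluate(X, y, class_names,
                                                config.model, config.train)
    return report, cm, history


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d
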