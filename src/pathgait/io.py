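"""Reading and writing sequences, templates and reports.

Silhouette sequences live on disk as a directory of zero-padded numbered
PNG/BMP frames (``frame_0001.png`` ...) with an optional ``sequence.json``
sidecar holding generation parameters and ground-truth trough indices.
Energy templates are written twice: rounded 8-bit PNG for inspection and
lossless float NPY for exact downstream math.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .prep import SilhouetteFrame, SilhouetteSequence
from .synthetic import SyntheticWalk
from .templates import EnergyImage

FRAME_PATTERN = "frame_{:04d}.png"
SIDECAR = "sequence.json"
_IMAGE_EXTS = (".png", ".bmp", ".jpg", ".jpeg")


def save_sequence(seq: SilhouetteSequence, out_dir: str | Path,
                  sidecar: dict | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(seq.frames, start=1):
        iio.imwrite(out / FRAME_PATTERN.format(i), frame.pixels)
    meta = {"n_frames": len(seq), "frame_rate": seq.frame_rate, **seq.metadata}
    if sidecar:
        meta.update(sidecar)
    (out / SIDECAR).write_text(json.dumps(meta, indent=2, default=str))
    return out


def save_walk(walk: SyntheticWalk, out_dir: str | Path) -> Path:
    """Save a synthetic walk with its params and ground-truth troughs."""
    return save_sequence(walk.sequence, out_dir, sidecar={
        "params": asdict(walk.params),
        "trough_indices": walk.trough_indices,
    })


def load_frames(path: str | Path, pattern: str | None = None) -> list[np.ndarray]:
    """Load raw grayscale frames from a directory (sorted lexicographically)."""
    path = Path(path)
    if pattern:
        files = sorted(path.glob(pattern))
    else:
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXTS)
    if not files:
        raise FileNotFoundError(f"no image frames found under {path}")
    frames = []
    for f in files:
        img = iio.imread(f)
        if img.ndim == 3:
            img = img.mean(axis=2)
        frames.append(np.asarray(img))
    return frames


def load_sequence(path: str | Path) -> SilhouetteSequence:
    """Load an already-binary silhouette sequence plus its sidecar metadata."""
    frames = [SilhouetteFrame(np.where(np.asarray(f) > 127, 255, 0).astype(np.uint8))
              for f in load_frames(path)]
    meta = {}
    sidecar = Path(path) / SIDECAR
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return SilhouetteSequence(frames, frame_rate=meta.get("frame_rate"), metadata=meta)


def save_energy_image(img: EnergyImage, stem: str | Path) -> tuple[Path, Path]:
    """Write ``<stem>.png`` (8-bit) and ``<stem>.npy`` (float64, lossless)."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    png, npy = stem.with_suffix(".png"), stem.with_suffix(".npy")
    iio.imwrite(png, img.to_uint8())
    np.save(npy, img.pixels)
    return png, npy


def load_energy_image(path: str | Path, kind: str) -> EnergyImage:
    path = Path(path)
    if path.suffix == ".npy":
        return EnergyImage(kind, np.load(path))
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    return EnergyImage(kind, arr.astype(float))


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=_json_default))
    return path


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")
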