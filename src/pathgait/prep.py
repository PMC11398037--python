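"""Silhouette preprocessing: binarization, cleaning, cropping and size normalization.

Raw person-segmentation output (grayscale masks of a walking person filmed
from the side) is converted here into the canonical representation used by
the rest of the package: strictly binary {0, 255} frames of 256 x 256 pixels
in which the silhouette's tight bounding box spans the full frame height and
is horizontally centered on its centroid.

Person *detection* is performed by keeping the largest 8-connected foreground
component; on clean silhouettes this agrees with a learned detector, and a
detector can be slotted in behind :func:`crop_to_person` without touching the
rest of the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

FOREGROUND = 255
DEFAULT_SIZE = 256


class EmptyForegroundError(ValueError):
    """Raised when an operation requires a non-empty silhouette."""


@dataclass
class SilhouetteFrame:
    """A single binary silhouette image with pixel values in {0, 255}."""

    pixels: np.ndarray
    empty_foreground: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("silhouette frame must be a 2-D array")
        vals = np.unique(self.pixels)
        if not np.all(np.isin(vals, (0, FOREGROUND))):
            raise ValueError("silhouette frame must be strictly binary {0, 255}")
        self.pixels = self.pixels.astype(np.uint8)
        self.empty_foreground = not bool(self.pixels.any())

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def foreground_mask(self) -> np.ndarray:
        return self.pixels > 0

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(row0, col0, row1, col1), inclusive, of the tight foreground box."""
        if self.empty_foreground:
            raise EmptyForegroundError("no person found: frame has empty foreground")
        rows = np.flatnonzero(self.pixels.any(axis=1))
        cols = np.flatnonzero(self.pixels.any(axis=0))
        return int(rows[0]), int(cols[0]), int(rows[-1]), int(cols[-1])


@dataclass
class SilhouetteSequence:
    """An ordered walking pass of silhouette frames sharing one frame size."""

    frames: list[SilhouetteFrame]
    frame_rate: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("a silhouette sequence needs at least 2 frames")
        shape = self.frames[0].pixels.shape
        for f in self.frames:
            if f.pixels.shape != shape:
                raise ValueError("all frames in a sequence must share dimensions")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, idx):
        return self.frames[idx]

    def as_array(self) -> np.ndarray:
        """Stack into a (n_frames, H, W) uint8 array."""
        return np.stack([f.pixels for f in self.frames])

    @classmethod
    def from_array(cls, arr: np.ndarray, frame_rate: float | None = None,
                   metadata: dict | None = None) -> "SilhouetteSequence":
        frames = [SilhouetteFrame(a) for a in arr]
        return cls(frames, frame_rate=frame_rate, metadata=metadata or {})


def binarize_and_clean(frame: np.ndarray, threshold: int = 127,
                       open_radius: int = 1, close_radius: int = 1) -> SilhouetteFrame:
    """Threshold a grayscale frame and remove speckle with opening then closing.

    Opening with a square (2r+1) x (2r+1) structuring element removes
    foreground specks smaller than the element (and, being a square, leaves
    rectangular silhouette regions untouched); the subsequent closing fills
    holes and gaps of comparable size. The open-then-close composition is an
    alternating filter and hence idempotent. The result is strictly binary.
    An all-empty result is returned with ``empty_foreground=True`` rather
    than raising, so that callers can drop the frame.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("binarize_and_clean expects a single-channel image")
    if not 0 < threshold < 255:
        raise ValueError("threshold must be in (0, 255)")
    mask = frame > threshold
    if open_radius > 0:
        se = np.ones((2 * open_radius + 1,) * 2, dtype=bool)
        mask = ndi.binary_opening(mask, structure=se)
    if close_radius > 0:
        se = np.ones((2 * close_radius + 1,) * 2, dtype=bool)
        mask = ndi.binary_closing(mask, structure=se)
    out = SilhouetteFrame(np.where(mask, FOREGROUND, 0).astype(np.uint8))
    if out.empty_foreground:
        warnings.warn("empty foreground after cleaning", stacklevel=2)
    return out


def crop_to_person(frame: SilhouetteFrame, margin: int = 0) -> SilhouetteFrame:
    """Crop to the bounding box of the largest 8-connected foreground component.

    The box is expanded by ``margin`` pixels on every side and clipped to the
    image bounds. Raises :class:`EmptyForegroundError` on an empty frame.
    """
    if frame.empty_foreground:
        raise EmptyForegroundError("no person found")
    labels, n = ndi.label(frame.foreground_mask(), structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise EmptyForegroundError("no person found")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    mask = labels == keep
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0 = max(0, rows[0] - margin)
    c0 = max(0, cols[0] - margin)
    r1 = min(frame.height - 1, rows[-1] + margin)
    c1 = min(frame.width - 1, cols[-1] + margin)
    crop = np.where(mask[r0:r1 + 1, c0:c1 + 1], FOREGROUND, 0)
    return SilhouetteFrame(crop.astype(np.uint8))


def normalize_silhouette(frame: SilhouetteFrame, out_size: int = DEFAULT_SIZE) -> SilhouetteFrame:
    """Scale a cropped silhouette so its height fills ``out_size`` and center it.

    Scaling is isotropic, nearest-neighbor (no gray halos on a binary mask),
    and the silhouette is horizontally centered on its foreground centroid.
    The tight bounding box of the output spans rows 0..out_size-1 exactly.
    """
    if frame.empty_foreground:
        raise EmptyForegroundError("no person found")
    r0, c0, r1, c1 = frame.bounding_box()
    crop = frame.pixels[r0:r1 + 1, c0:c1 + 1]
    h, w = crop.shape
    if h < 2:
        raise ValueError("degenerate silhouette: less than 2 pixels tall")
    out_w = max(1, round(w * out_size / h))
    # Explicit index maps guarantee the output box is exactly out_size tall:
    # row i samples source row floor(i * h / out_size), which hits both 0 and h-1.
    rows = (np.arange(out_size) * h) // out_size
    cols = (np.arange(out_w) * h) // out_size  # isotropic: same scale factor
    cols = np.clip(cols, 0, w - 1)
    scaled = crop[np.ix_(rows, cols)]

    canvas = np.zeros((out_size, out_size), dtype=np.uint8)
    ys, xs = np.nonzero(scaled)
    centroid_x = xs.mean()
    left = int(round(out_size / 2 - centroid_x))
    src0 = max(0, -left)
    dst0 = max(0, left)
    n = min(scaled.shape[1] - src0, out_size - dst0)
    if n <= 0:
        raise ValueError("silhouette does not fit the output frame")
    canvas[:, dst0:dst0 + n] = scaled[:, src0:src0 + n]
    return SilhouetteFrame(canvas)


def preprocess_sequence(raw_frames: list[np.ndarray], threshold: int = 127,
                        open_radius: int = 1, close_radius: int = 1,
                        margin: int = 0, out_size: int = DEFAULT_SIZE,
                        frame_rate: float | None = None) -> SilhouetteSequence:
    """Full preprocessing chain on a list of grayscale frames.

    Frames whose foreground vanishes after cleaning are dropped with a warning.
    """
    out = []
    for i, raw in enumerate(raw_frames):
        f = binarize_and_clean(raw, threshold, open_radius, close_radius)
        if f.empty_foreground:
            warnings.warn(f"dropping frame {i}: empty after cleaning", stacklevel=2)
            continue
        out.append(normalize_silhouette(crop_to_person(f, margin), out_size))
    if len(out) < 2:
        raise ValueError("fewer than 2 usable frames after preprocessing")
    return SilhouetteSequence(out, frame_rate=frame_rate)
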