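"""Gait-cycle segmentation from silhouette aspect-ratio periodicity.

A walking person's height is constant while their width oscillates with the
leg swing, so the width-to-height ratio of the silhouette contour's smallest
outer (axis-aligned) rectangle is periodic: local minima (troughs) occur at
legs-together poses, and two adjacent troughs span half a gait cycle. A full
cycle therefore runs across three consecutive troughs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import find_peaks

from .prep import SilhouetteFrame, SilhouetteSequence


@dataclass
class AspectRatioSeries:
    """Per-frame width/height ratios and their moving-average smoothing."""

    values: np.ndarray
    smoothed: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class GaitCycle:
    """One full gait period: frames spanning three consecutive troughs."""

    start_frame: int
    end_frame: int   # inclusive
    frames: SilhouetteSequence

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError("a gait cycle must span at least 2 frames")

    def __len__(self) -> int:
        return self.end_frame - self.start_frame + 1


def contour_extract(frame: SilhouetteFrame) -> np.ndarray:
    """Binary boundary map of the silhouette via Sobel gradient magnitude.

    The gradient is thresholded at > 0 and restricted to foreground pixels,
    yielding the silhouette's own one-pixel boundary ring. An empty frame
    gives an empty edge map.
    """
    img = frame.pixels.astype(float)
    gx = ndi.sobel(img, axis=1)
    gy = ndi.sobel(img, axis=0)
    mag = np.hypot(gx, gy)
    return (mag > 0) & frame.foreground_mask()


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, edge-value padded.

    Edge-value padding keeps a monotone approach to either boundary monotone
    after smoothing (reflection would turn it into a spurious boundary
    maximum), so boundary troughs stay detectable.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    if window == 1:
        return x.astype(float).copy()
    half = window // 2
    padded = np.pad(x.astype(float), half, mode="edge")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def aspect_ratio_series(seq: SilhouetteSequence, smooth_window: int = 5) -> AspectRatioSeries:
    """Width/height of each frame's tight contour bounding rectangle.

    Frames with empty foreground get a missing value that is linearly
    interpolated from their neighbors before smoothing.
    """
    values = np.full(len(seq), np.nan)
    for t, frame in enumerate(seq.frames):
        edges = contour_extract(frame)
        if not edges.any():
            continue
        rows = np.flatnonzero(edges.any(axis=1))
        cols = np.flatnonzero(edges.any(axis=0))
        h = rows[-1] - rows[0] + 1
        w = cols[-1] - cols[0] + 1
        values[t] = w / h
    if np.isnan(values).all():
        raise ValueError("every frame has empty foreground")
    if np.isnan(values).any():
        idx = np.arange(len(values))
        good = ~np.isnan(values)
        values = np.interp(idx, idx[good], values[good])
    return AspectRatioSeries(values=values, smoothed=_moving_average(values, smooth_window))


def detect_troughs(series: AspectRatioSeries, min_separation: int = 3,
                   prominence: float = 0.02) -> list[int]:
    """Trough (legs-together) frame indices of the smoothed ratio series.

    Interior local minima are found with the given prominence and pairwise
    separation. The two boundary frames are additionally accepted as troughs
    when the series rises strictly away from them by at least ``prominence``
    before the nearest interior trough — a walking pass routinely starts or
    ends at (or just short of) a legs-together pose, and those boundary poses
    delimit the first and last recoverable half-cycles.

    Raises ``ValueError`` when fewer than 3 troughs are found (the sequence
    does not contain one full gait cycle).
    """
    x = series.smoothed
    interior, _ = find_peaks(-x, prominence=prominence, distance=max(1, min_separation))
    troughs = [int(i) for i in interior]

    def _edge_ok(edge: int, neighbor: int, inner: int | None) -> bool:
        if x[edge] >= x[neighbor]:
            return False
        lo, hi = (edge, inner) if inner is not None else (None, None)
        if inner is None:
            seg = x
        else:
            seg = x[min(lo, hi):max(lo, hi) + 1]
        if seg.max() - x[edge] < prominence:
            return False
        return inner is None or abs(edge - inner) >= min_separation

    n = len(x)
    first = troughs[0] if troughs else None
    if n >= 2 and _edge_ok(0, 1, first):
        troughs.insert(0, 0)
    last = troughs[-1] if troughs else None
    if n >= 2 and _edge_ok(n - 1, n - 2, last if last != 0 else None):
        troughs.append(n - 1)

    if len(troughs) < 3:
        raise ValueError(
            f"sequence too short for one full cycle: {len(troughs)} trough(s) found")
    return troughs


def segment_cycles(seq: SilhouetteSequence, troughs: list[int]) -> list[GaitCycle]:
    """Split a sequence into full cycles, each spanning three consecutive troughs.

    Cycle ``k`` runs from ``troughs[2k]`` to ``troughs[2k+2]`` inclusive; the
    shared boundary frame belongs to both adjacent cycles. Partial leading or
    trailing half-cycles are discarded.
    """
    if len(troughs) < 3:
        raise ValueError("need at least 3 troughs for one full cycle")
    cycles = []
    for k in range((len(troughs) - 1) // 2):
        start, end = troughs[2 * k], troughs[2 * k + 2]
        sub = SilhouetteSequence(seq.frames[start:end + 1], frame_rate=seq.frame_rate)
        cycles.append(GaitCycle(start_frame=start, end_frame=end, frames=sub))
    return cycles


def segment_sequence(seq: SilhouetteSequence, smooth_window: int = 5,
                     min_separation: int = 3, prominence: float = 0.02) -> list[GaitCycle]:
    """Convenience chain: ratio series -> troughs -> cycles."""
    series = aspect_ratio_series(seq, smooth_window)
    troughs = detect_troughs(series, min_separation, prominence)
    return segment_cycles(seq, troughs)
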