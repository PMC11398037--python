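"""Gait energy templates computed over one gait cycle.

Three classic single-image summaries of a binary silhouette cycle:

- GEI  (gait energy image): per-pixel temporal mean of the {0, 255} frames;
  mixes static shape (torso, head) and dynamic energy (limbs).
- GEnI (gait entropy image): per-pixel Shannon entropy of the foreground
  occupancy across the cycle, min-max scaled to [0, 255]; static pixels
  (always on or always off) carry zero entropy, maximally intermittent
  pixels (on half the time) carry one bit.
- AEI  (active energy image): mean absolute difference between consecutive
  frames; a pure motion template that zeroes everything static.

All three are computed per gait cycle — one cycle yields one sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cycles import GaitCycle

TemplateKind = str  # one of {"GEI", "GEnI", "AEI", "FEI"}


@dataclass
class EnergyImage:
    """A single-channel gait template with pixel values in [0, 255]."""

    kind: TemplateKind
    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("an energy image is a 2-D array")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 255 + 1e-9:
            raise ValueError("energy image pixels must lie in [0, 255]")

    @property
    def size(self) -> tuple[int, int]:
        return self.pixels.shape

    def to_uint8(self) -> np.ndarray:
        return np.clip(np.rint(self.pixels), 0, 255).astype(np.uint8)


@dataclass
class EntropyField:
    """Per-pixel Shannon entropy in bits; for binary frames H is in [0, 1]."""

    values: np.ndarray
    h_min: float
    h_max: float


def _cycle_array(cycle: GaitCycle) -> np.ndarray:
    arr = cycle.frames.as_array().astype(np.float64)
    if arr.shape[0] < 2:
        raise ValueError("a cycle must contain at least 2 frames")
    return arr


def compute_gei(cycle: GaitCycle) -> EnergyImage:
    """GEI(x, y) = (1/N) * sum_t F_t(x, y), with F_t in {0, 255}."""
    arr = _cycle_array(cycle)
    return EnergyImage("GEI", arr.mean(axis=0))


def compute_entropy_field(cycle: GaitCycle) -> EntropyField:
    """Per-pixel binary Shannon entropy of foreground occupancy.

    p1 is the fraction of the cycle's frames in which the pixel is
    foreground; H = -sum_j p_j log2 p_j with the 0*log2(0) := 0 convention.
    """
    arr = _cycle_array(cycle)
    p1 = (arr > 0).mean(axis=0)
    h = np.zeros_like(p1)
    for p in (p1, 1.0 - p1):
        nz = p > 0
        h[nz] -= p[nz] * np.log2(p[nz])
    return EntropyField(values=h, h_min=float(h.min()), h_max=float(h.max()))


def compute_geni(cycle: GaitCycle) -> EnergyImage:
    """GEnI: the entropy field min-max scaled to [0, 255].

    When the field is constant (e.g. every frame identical, so all entropies
    are equal) the output is all zeros and a degenerate-field warning is
    emitted.
    """
    field = compute_entropy_field(cycle)
    span = field.h_max - field.h_min
    if span == 0.0:
        warnings.warn("degenerate entropy field (H_max == H_min); GEnI is all zeros",
                      stacklevel=2)
        return EnergyImage("GEnI", np.zeros_like(field.values))
    return EnergyImage("GEnI", (field.values - field.h_min) * 255.0 / span)


def compute_aei(cycle: GaitCycle) -> EnergyImage:
    """AEI: mean absolute difference of consecutive frames.

    AEI(x, y) = (1/(N-1)) * sum_{t=2..N} |F_t - F_{t-1}|; normalizing over
    the N-1 frame pairs lets a fully alternating pixel reach 255.
    """
    arr = _cycle_array(cycle)
    if arr.shape[0] < 2:
        raise ValueError("AEI needs at least 2 frames")
    return EnergyImage("AEI", np.abs(np.diff(arr, axis=0)).mean(axis=0))


def compute_all_templates(cycle: GaitCycle) -> tuple[EnergyImage, EnergyImage, EnergyImage]:
    """(GEI, GEnI, AEI) of one cycle."""
    return compute_gei(cycle), compute_geni(cycle), compute_aei(cycle)
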