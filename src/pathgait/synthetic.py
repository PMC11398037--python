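"""Parametric side-view walker silhouettes with known gait period.

The generator renders a stick-figure-with-volume walker (head disc, torso
ellipse, two articulated legs drawn as capsules hip->knee->foot) on a
256 x 256 binary canvas. The legs swing in anti-phase with horizontal foot
offsets proportional to ``sin(2*pi*t / cycle_frames)``, so the silhouette's
width-to-height ratio has exact local minima (legs-together poses) every
``cycle_frames / 2`` frames: two troughs per full gait cycle, exactly as a
real side-view walking pass. Because geometry is closed-form, the trough
frame indices are known and emitted as ground truth, which makes the cycle
detector exactly testable.

Five gait styles are modeled as caricatures of their clinical descriptions,
differing in stride length, cadence, trunk lean, foot clearance, left/right
asymmetry and leg crossing:

- ``normal``       — upright, long stride, clear foot lift
- ``festinating``  — forward-leaning trunk, short quick steps
- ``scissor``      — knees pulled toward and across the midline
- ``hemiparetic``  — one leg swings with markedly reduced amplitude
- ``shuffling``    — short dragged steps with almost no foot clearance

The styles are tuned for class separability of the resulting energy
templates, not for biomechanical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .prep import SilhouetteSequence

CANVAS = 256
GAIT_CLASSES = ("festinating", "scissor", "hemiparetic", "shuffling", "normal")

# Fixed body geometry (pixels, on the 256x256 canvas).
_GROUND_Y = 238.0
_HIP = np.array([128.0, 140.0])
_TORSO_OFFSET = 43.0          # hip -> torso center, along the body axis
_TORSO_AXES = (14.0, 46.0)    # (horizontal, vertical) semi-axes
_HEAD_OFFSET = 97.0           # hip -> head center, along the body axis
_HEAD_RADIUS = 13.0
_LEG_RADIUS = 5.5
_KNEE_CROSS_GAIN = 18.0       # px of inward knee shift at crossing=1, |s|=1


@dataclass(frozen=True)
class WalkerParams:
    """Parameters of one synthetic walking pass.

    ``cycle_frames`` must be an even integer >= 8 so that the legs-together
    troughs fall exactly on frame indices (they occur every half cycle).
    """

    class_label: str = "normal"
    cycle_frames: int = 20
    n_cycles: int = 3
    stride_amplitude: float = 70.0   # max horizontal foot separation, px
    trunk_lean: float = 0.0          # forward lean, degrees
    step_height: float = 12.0        # swing-foot clearance, px
    asymmetry: float = 0.0           # in [0,1]; scales down one leg's swing
    crossing: float = 0.0            # in [0,1]; knees converge/cross
    noise_rate: float = 0.0          # per-pixel flip probability, in [0, 0.05]
    seed: int = 0

    def validate(self) -> None:
        if self.class_label not in GAIT_CLASSES:
            raise ValueError(f"unknown gait class {self.class_label!r}")
        if self.cycle_frames < 8:
            raise ValueError("cycle_frames must be >= 8")
        if self.cycle_frames % 2:
            raise ValueError(
                "cycle_frames must be even: troughs occur every half cycle "
                "and must land on integer frame indices")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not 0.0 <= self.noise_rate <= 0.05:
            raise ValueError("noise_rate must be in [0, 0.05]")
        if not 0.0 <= self.asymmetry <= 1.0:
            raise ValueError("asymmetry must be in [0, 1]")
        if not 0.0 <= self.crossing <= 1.0:
            raise ValueError("crossing must be in [0, 1]")
        if self.stride_amplitude <= 0 or self.step_height < 0:
            raise ValueError("stride_amplitude must be > 0 and step_height >= 0")


#: Per-class style presets (caricatured clinical descriptions, see module doc).
CLASS_STYLES: dict[str, WalkerParams] = {
    "normal": WalkerParams("normal", cycle_frames=20, stride_amplitude=70,
                           trunk_lean=0, step_height=12),
    "festinating": WalkerParams("festinating", cycle_frames=16, stride_amplitude=52,
                                trunk_lean=14, step_height=8),
    "scissor": WalkerParams("scissor", cycle_frames=22, stride_amplitude=50,
                            trunk_lean=2, step_height=10, crossing=0.7),
    "hemiparetic": WalkerParams("hemiparetic", cycle_frames=22, stride_amplitude=60,
                                trunk_lean=3, step_height=10, asymmetry=0.5),
    "shuffling": WalkerParams("shuffling", cycle_frames=26, stride_amplitude=26,
                              trunk_lean=6, step_height=2),
}


@dataclass
class SyntheticWalk:
    """A generated sequence plus its ground truth."""

    sequence: SilhouetteSequence
    trough_indices: list[int]
    params: WalkerParams


def _capsule_mask(xx: np.ndarray, yy: np.ndarray, p: np.ndarray, q: np.ndarray,
                  radius: float) -> np.ndarray:
    """Pixels within ``radius`` of the segment p->q."""
    d = q - p
    len2 = float(d @ d)
    if len2 == 0.0:
        return (xx - p[0]) ** 2 + (yy - p[1]) ** 2 <= radius ** 2
    t = ((xx - p[0]) * d[0] + (yy - p[1]) * d[1]) / len2
    t = np.clip(t, 0.0, 1.0)
    cx = p[0] + t * d[0]
    cy = p[1] + t * d[1]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2


def _render_frame(params: WalkerParams, phase: float,
                  grid: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Render one pose. ``phase`` is 2*pi*t/cycle_frames."""
    xx, yy = grid
    lean = np.deg2rad(params.trunk_lean)
    # body axis unit vector, rotated forward (toward +x) by the trunk lean
    ax = np.array([np.sin(lean), -np.cos(lean)])

    torso_c = _HIP + _TORSO_OFFSET * ax
    head_c = _HIP + _HEAD_OFFSET * ax

    # torso: ellipse with vertical axis along the leaned body axis
    u = (xx - torso_c[0]) * ax[1] * -1 + (yy - torso_c[1]) * ax[0]   # horizontal coord
    v = (xx - torso_c[0]) * ax[0] + (yy - torso_c[1]) * ax[1]        # along-axis coord
    mask = (u / _TORSO_AXES[0]) ** 2 + (v / _TORSO_AXES[1]) ** 2 <= 1.0
    mask |= (xx - head_c[0]) ** 2 + (yy - head_c[1]) ** 2 <= _HEAD_RADIUS ** 2

    s = np.sin(phase)
    half = params.stride_amplitude / 2.0
    # leg 0 swings with full amplitude; leg 1 is attenuated by asymmetry
    offs = (half * s, -half * s * (1.0 - params.asymmetry))
    lifts = (params.step_height * max(0.0, s), params.step_height * max(0.0, -s))
    inward = (-1.0, 1.0)  # knee shift direction toward the midline/other leg
    for i in range(2):
        foot = np.array([_HIP[0] + offs[i], _GROUND_Y - lifts[i]])
        knee = (_HIP + foot) / 2.0
        knee = knee + np.array([inward[i] * params.crossing * _KNEE_CROSS_GAIN * abs(s), 0.0])
        mask |= _capsule_mask(xx, yy, _HIP, knee, _LEG_RADIUS)
        mask |= _capsule_mask(xx, yy, knee, foot, _LEG_RADIUS)
    return mask


def generate_walker_sequence(params: WalkerParams) -> SyntheticWalk:
    """Render a full walking pass of ``n_cycles * cycle_frames`` frames.

    The legs are together (aspect-ratio trough) at frame 0 and every
    ``cycle_frames/2`` frames thereafter. The returned ground-truth trough
    list includes frame 0 and the final frame (the truncated approach to the
    next legs-together pose), so the pass contains exactly ``n_cycles``
    recoverable full cycles.

    Identical params (including seed) give bit-identical output.
    """
    params.validate()
    n_frames = params.n_cycles * params.cycle_frames
    xx, yy = np.meshgrid(np.arange(CANVAS, dtype=float),
                         np.arange(CANVAS, dtype=float))
    rng = np.random.default_rng(params.seed)
    frames = np.empty((n_frames, CANVAS, CANVAS), dtype=np.uint8)
    for t in range(n_frames):
        mask = _render_frame(params, 2.0 * np.pi * t / params.cycle_frames, (xx, yy))
        if params.noise_rate > 0:
            flips = rng.random((CANVAS, CANVAS)) < params.noise_rate
            mask = mask ^ flips
        frames[t] = np.where(mask, 255, 0)

    half = params.cycle_frames // 2
    troughs = list(range(0, n_frames, half)) + [n_frames - 1]
    seq = SilhouetteSequence.from_array(
        frames, metadata={"class_label": params.class_label,
                          "cycle_frames": params.cycle_frames})
    return SyntheticWalk(seq, troughs, params)


def _jitter(style: WalkerParams, base: WalkerParams, rng: np.random.Generator,
            seed: int) -> WalkerParams:
    """Per-sample variation around a class style (seeded, bounded)."""
    cf = style.cycle_frames + 2 * int(rng.integers(-1, 2))
    return replace(
        style,
        cycle_frames=max(8, cf),
        n_cycles=base.n_cycles,
        noise_rate=base.noise_rate,
        stride_amplitude=style.stride_amplitude * rng.uniform(0.9, 1.1),
        trunk_lean=style.trunk_lean * rng.uniform(0.85, 1.15),
        step_height=style.step_height * rng.uniform(0.8, 1.2),
        asymmetry=min(1.0, style.asymmetry * rng.uniform(0.85, 1.15)),
        crossing=min(1.0, style.crossing * rng.uniform(0.85, 1.15)),
        seed=seed,
    )


def generate_labeled_dataset(n_per_class: int, base: WalkerParams | None = None,
                             seed: int = 0) -> list[tuple[SyntheticWalk, str]]:
    """Generate ``5 * n_per_class`` walks with per-sample jitter, class-balanced.

    ``base`` contributes the shared acquisition settings (``n_cycles`` and
    ``noise_rate``); stride, cadence, lean, clearance, asymmetry and crossing
    come from each class's style preset, jittered per sample by the seeded
    generator. Two calls with identical arguments produce identical data.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if base is None:
        base = WalkerParams(noise_rate=0.01)
    rng = np.random.default_rng(seed)
    out: list[tuple[SyntheticWalk, str]] = []
    for label in GAIT_CLASSES:
        style = CLASS_STYLES[label]
        for _ in range(n_per_class):
            sample_seed = int(rng.integers(0, 2**31 - 1))
            p = _jitter(style, base, rng, sample_seed)
            out.append((generate_walker_sequence(p), label))
    return out
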