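"""Shared fixtures: toy cycles and small synthetic walks."""

from __future__ import annotations

import numpy as np
import pytest

from pathgait.cycles import GaitCycle
from pathgait.prep import SilhouetteSequence
from pathgait.synthetic import WalkerParams, generate_walker_sequence


def make_cycle(frames: np.ndarray) -> GaitCycle:
    """Wrap a (N, H, W) binary {0,255} stack as a GaitCycle."""
    seq = SilhouetteSequence.from_array(frames.astype(np.uint8))
    return GaitCycle(start_frame=0, end_frame=len(seq) - 1, frames=seq)


def random_binary_cycle(rng: np.random.Generator, n_frames: int = 8,
                        size: int = 16) -> GaitCycle:
    frames = (rng.random((n_frames, size, size)) < 0.5).astype(np.uint8) * 255
    return make_cycle(frames)


@pytest.fixture(scope="session")
def clean_walk():
    """Noise-free 3-cycle normal walk with ground-truth troughs."""
    return generate_walker_sequence(WalkerParams(cycle_frames=20, n_cycles=3,
                                                 noise_rate=0.0, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
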