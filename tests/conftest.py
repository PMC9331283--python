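"""Shared fixtures: small seeded signals and landmark builders."""
from __future__ import annotations

import numpy as np
import pytest

from readtask.datatypes import AudioSignal, LandmarkSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def sine_signal():
    """1.5 s pure 200 Hz tone at 22.05 kHz."""
    rate = 22050
    t = np.arange(int(1.5 * rate)) / rate
    return AudioSignal(samples=0.5 * np.sin(2 * np.pi * 200.0 * t), rate=rate)


def make_landmarks(positions: np.ndarray, fps: float = 30.0) -> LandmarkSequence:
    """A landmark sequence whose whole face sits at the given per-frame offsets.

    ``positions`` is (n_frames, 2); a fixed 68-point template is translated
    rigidly by each offset.
    """
    base = np.zeros((68, 2))
    base[:, 0] = np.linspace(0.0, 67.0, 68) + 100.0
    base[:, 1] = np.linspace(0.0, 33.5, 68) + 80.0
    pts = base[None, :, :] + np.asarray(positions, dtype=float)[:, None, :]
    return LandmarkSequence(points=pts, fps=fps)


@pytest.fixture
def landmark_builder():
    return make_landmarks
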