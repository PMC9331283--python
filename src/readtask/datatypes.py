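"""Shared domain containers for the reading-task pipeline.

Lightweight dataclasses around numpy arrays; validation happens at
construction so downstream feature code can assume well-formed input.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AudioSignal",
    "FrameParams",
    "IntensityTrack",
    "LandmarkSequence",
    "HeadTrajectory",
    "ReadingMeta",
    "MARSequence",
    "FluencyImage",
]


@dataclass
class AudioSignal:
    """Mono audio: normalized float samples (≈ [-1, 1]) plus sampling rate in Hz."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("AudioSignal.samples must be a non-empty 1-D vector")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("AudioSignal.samples contains non-finite values")
        if int(self.rate) <= 0:
            raise ValueError(f"AudioSignal.rate must be positive, got {self.rate}")
        self.rate = int(self.rate)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate


@dataclass(frozen=True)
class FrameParams:
    """Short-time analysis framing: frame length and hop, both in samples."""

    frame_len: int
    hop: int

    def __post_init__(self) -> None:
        if self.frame_len <= 0:
            raise ValueError(f"frame_len must be positive, got {self.frame_len}")
        if not (0 < self.hop <= self.frame_len):
            raise ValueError(
                f"hop must satisfy 0 < hop <= frame_len, got hop={self.hop}, "
                f"frame_len={self.frame_len}"
            )

    @classmethod
    def from_seconds(cls, rate: int, frame_s: float = 0.025, hop_s: float = 0.010) -> "FrameParams":
        return cls(frame_len=int(round(frame_s * rate)), hop=int(round(hop_s * rate)))


@dataclass
class IntensityTrack:
    """Per-frame mean intensity values (non-negative under the power convention)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("IntensityTrack.values must be a non-empty 1-D vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("IntensityTrack.values contains non-finite values")

    @property
    def num_frames(self) -> int:
        return self.values.size


@dataclass
class LandmarkSequence:
    """Per-video-frame 68-point 2-D facial landmarks at a fixed frame rate.

    ``points`` has shape (n_frames, 68, 2) in pixel coordinates with standard
    image axes (x rightward, y downward).  Point indices are 0-based in the
    array; the conventional 1-based landmark numbering is used in accessor
    helpers (e.g. the jaw contour is points 1-17, mouth corners 49/55).
    NaN coordinates mark frames where landmark detection failed; consumers
    either interpolate (mouth aspect ratio) or reject them.
    """

    points: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[1:] != (68, 2):
            raise ValueError(
                f"LandmarkSequence.points must have shape (n_frames, 68, 2), "
                f"got {self.points.shape}"
            )
        if self.points.shape[0] == 0:
            raise ValueError("LandmarkSequence needs at least one frame")
        if float(self.fps) <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        self.fps = float(self.fps)

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    def landmark(self, one_based_index: int) -> np.ndarray:
        """(n_frames, 2) trajectory of a landmark given its 1-based index."""
        if not 1 <= one_based_index <= 68:
            raise ValueError(f"landmark index must be in 1..68, got {one_based_index}")
        return self.points[:, one_based_index - 1, :]


@dataclass
class HeadTrajectory:
    """Per-frame-step mean landmark displacement of the jaw contour.

    ``hm_r`` is the horizontal (repeated-reading, Rr) component and ``hm_u``
    the vertical (unconscious-movement, Um) component, both signed and in
    pixels per frame step; each has length n_frames - 1.
    """

    hm_r: np.ndarray
    hm_u: np.ndarray

    def __post_init__(self) -> None:
        self.hm_r = np.asarray(self.hm_r, dtype=float)
        self.hm_u = np.asarray(self.hm_u, dtype=float)
        if self.hm_r.shape != self.hm_u.shape or self.hm_r.ndim != 1:
            raise ValueError("hm_r and hm_u must be 1-D vectors of equal length")


@dataclass(frozen=True)
class ReadingMeta:
    """Reading-task metadata: the number of text lines in the read passage."""

    n_lines: int

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ValueError(f"n_lines must be >= 1, got {self.n_lines}")


@dataclass
class MARSequence:
    """Per-frame mouth aspect ratio (mouth width / mouth length), dimensionless."""

    values: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("MARSequence.values must be a non-empty 1-D vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("MARSequence.values contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("mouth aspect ratios must be non-negative")
        if float(self.fps) <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        self.fps = float(self.fps)


@dataclass
class FluencyImage:
    """8-bit RGB rendering of a mouth-movement sequence (time map or spectrogram)."""

    pixels: np.ndarray
    kind: str = field(default="time_map")

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be uint8 (0-255)")
        if self.kind not in ("time_map", "spectrogram"):
            raise ValueError(f"kind must be 'time_map' or 'spectrogram', got {self.kind!r}")
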