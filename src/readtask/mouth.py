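"""Mouth-movement fluency representations.

The mouth aspect ratio (MAR) — mouth width (landmarks 52-58) over mouth
length (landmarks 49-55) — oscillates at syllable rate during fluent
reading and stalls during hesitations.  Two deterministic image encodings
of the MAR sequence feed the transfer-learning feature extractor:

* a **time-domain map**: sequence values written row-major into a square
  grid, the red channel carrying 200 x value (clipped to 0-255), green and
  blue zero;
* a **3-D spectrogram**: short-time Fourier magnitudes over 3 s segments
  hopped every 1 s, rendered as a fixed-viewpoint 3-D surface.
"""
from __future__ import annotations

import math

import numpy as np
import scipy.fft

import matplotlib

matplotlib.use("Agg", force=False)
from matplotlib.backends.backend_agg import FigureCanvasAgg  # noqa: E402
from matplotlib.figure import Figure  # noqa: E402

from .datatypes import FluencyImage, LandmarkSequence, MARSequence

__all__ = [
    "mar_sequence",
    "time_domain_map",
    "stft_segments",
    "spectrogram_3d",
    "segment_count",
]

# 0-based indices of the 1-based mouth landmarks used by the aspect ratio
_P49, _P52, _P55, _P58 = 48, 51, 54, 57


def mar_sequence(lm: LandmarkSequence) -> MARSequence:
    """Per-frame mouth aspect ratio from the 68-point landmarks.

    MAR = |P52 - P58| / |P49 - P55| (mouth width over mouth length).
    Frames whose mouth landmarks contain NaN (failed detection) are filled
    by linear interpolation from neighbouring valid frames; leading and
    trailing gaps replicate the nearest valid value.  A frame with
    coincident mouth corners (zero length) is an error.
    """
    pts = lm.points
    width = np.linalg.norm(pts[:, _P52] - pts[:, _P58], axis=1)
    length = np.linalg.norm(pts[:, _P49] - pts[:, _P55], axis=1)
    valid = np.isfinite(width) & np.isfinite(length)
    zero_len = valid & (length == 0)
    if np.any(zero_len):
        raise ValueError(
            f"zero mouth length (coincident corners) at frame {int(np.argmax(zero_len))}"
        )
    if not np.any(valid):
        raise ValueError("no frame has valid mouth landmarks")
    values = np.empty(lm.n_frames)
    values[valid] = width[valid] / length[valid]
    if not np.all(valid):
        idx = np.arange(lm.n_frames)
        values[~valid] = np.interp(idx[~valid], idx[valid], values[valid])
    return MARSequence(values=values, fps=lm.fps)


def _nearest_resize(img: np.ndarray, out_side: int) -> np.ndarray:
    """Nearest-neighbour resize of a square (or rectangular) 2-D/3-D image."""
    h, w = img.shape[:2]
    rows = (np.arange(out_side) * h) // out_side
    cols = (np.arange(out_side) * w) // out_side
    return img[rows][:, cols]


def time_domain_map(seq: MARSequence, out_size: int = 224) -> FluencyImage:
    """Encode a MAR sequence as an RGB time-domain map.

    Values fill a ceil(sqrt(L))-sided square row-major (zero padded); the
    red channel is round(200 * value) clipped to [0, 255] (round half up, so
    any two values differing by >= 1/200 stay distinguishable); green and
    blue are zero.  The grid is then nearest-neighbour resized to
    ``out_size`` so every element of the sequence survives as long as the
    grid is not larger than the output.
    """
    v = seq.values
    side = int(math.ceil(math.sqrt(v.size)))
    flat = np.zeros(side * side)
    flat[: v.size] = v
    red = np.clip(np.floor(200.0 * flat + 0.5), 0, 255).astype(np.uint8)
    grid = red.reshape(side, side)
    resized = _nearest_resize(grid, out_size)
    pixels = np.zeros((out_size, out_size, 3), dtype=np.uint8)
    pixels[:, :, 0] = resized
    return FluencyImage(pixels=pixels, kind="time_map")


def segment_count(n_values: int, fps: float, segment_s: float = 3.0, hop_s: float = 1.0) -> int:
    """Number of short-time segments: floor((L - seg_len) / hop) + 1."""
    seg_len = int(round(segment_s * fps))
    hop = int(round(hop_s * fps))
    if n_values < seg_len:
        raise ValueError(
            f"sequence of {n_values} frames shorter than one {segment_s} s segment "
            f"({seg_len} frames at {fps} fps)"
        )
    return (n_values - seg_len) // hop + 1


def stft_segments(
    seq: MARSequence,
    segment_s: float = 3.0,
    hop_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Short-time Fourier magnitudes of a MAR sequence.

    The sequence is cut into ``segment_s``-long pieces every ``hop_s``
    seconds; each segment is Hamming-windowed and transformed in one FFT
    (no intra-segment sub-windowing).  Returns (freqs, magnitudes) with
    magnitudes of shape (n_segments, n_freq_bins).
    """
    seg_len = int(round(segment_s * seq.fps))
    hop = int(round(hop_s * seq.fps))
    n_seg = segment_count(seq.values.size, seq.fps, segment_s, hop_s)
    idx = np.arange(seg_len)[None, :] + hop * np.arange(n_seg)[:, None]
    segments = seq.values[idx] * np.hamming(seg_len)
    mags = np.abs(scipy.fft.rfft(segments, axis=1))
    freqs = np.asarray(scipy.fft.rfftfreq(seg_len, d=1.0 / seq.fps))
    return freqs, mags


def spectrogram_3d(
    seq: MARSequence,
    out_size: int = 224,
    segment_s: float = 3.0,
    hop_s: float = 1.0,
    cmap: str = "viridis",
    elev: float = 35.0,
    azim: float = -60.0,
) -> FluencyImage:
    """Render the time x frequency x magnitude surface as a fixed-view image.

    Magnitudes are normalized by their global maximum over the recording so
    the rendering is deterministic for a given sequence and configuration.
    Axes decorations are omitted: the image is consumed by a convolutional
    network, not a human reader.
    """
    freqs, mags = stft_segments(seq, segment_s, hop_s)
    peak = mags.max()
    norm = mags / peak if peak > 0 else mags
    t = np.arange(norm.shape[0]) * hop_s
    tt, ff = np.meshgrid(t, freqs, indexing="ij")

    fig = Figure(figsize=(3, 3), dpi=100)
    canvas = FigureCanvasAgg(fig)
    ax = fig.add_subplot(projection="3d")
    ax.plot_surface(tt, ff, norm, cmap=cmap, rstride=1, cstride=1,
                    linewidth=0, antialiased=False)
    ax.view_init(elev=elev, azim=azim)
    ax.set_axis_off()
    ax.set_zlim(0.0, 1.0)
    fig.subplots_adjust(left=0, right=1, bottom=0, top=1)
    canvas.draw()
    rgba = np.asarray(canvas.buffer_rgba())
    rgb = rgba[:, :, :3].copy()
    resized = np.stack(
        [_nearest_resize(rgb[:, :, c], out_size) for c in range(3)], axis=2
    ).astype(np.uint8)
    return FluencyImage(pixels=resized, kind="spectrogram")
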