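"""Acoustic features of speech emotional flatness.

Two proposed features quantify how *flat* a speaker's prosody is:

* **PIVD** (phonatory intensity variation diversity) — the standard
  deviation of the first-order difference of the per-frame mean intensity
  track.  Monotonous loudness gives a narrow difference distribution and a
  small PIVD.
* **AFVC** (auditory frequency variation coefficient) — the coefficient of
  variation of the 24 per-filter means formed by the 12 MFCC column means
  followed by the 12 second-order delta-MFCC column means.  Flat perceived
  pitch variation gives a small AFVC.

Alongside these, conventional comparator statistics (pitch mean/SD from an
autocorrelation tracker, intensity summary statistics) are provided as
baselines.
"""
from __future__ import annotations

import numpy as np
import scipy.fft

from .datatypes import AudioSignal, FrameParams, IntensityTrack

__all__ = [
    "frame_signal",
    "intensity_means",
    "pivd",
    "mel_filterbank",
    "mfcc",
    "delta2_mfcc",
    "afvc",
    "baseline_pitch_stats",
    "baseline_intensity_stats",
    "acoustic_features",
    "DegenerateInputError",
]

# Eq. kernel for the second-order delta cepstrum over five adjacent frames;
# the denominator is 3 by definition here (not the conventional sum of
# squared offsets), see docs/methods.md.
_DELTA2_KERNEL = np.array([-2.0, -1.0, 0.0, 1.0, 2.0]) / 3.0


class DegenerateInputError(ValueError):
    """Raised when an input is degenerate for the requested statistic."""


def frame_signal(signal: AudioSignal, params: FrameParams) -> np.ndarray:
    """Slice a signal into overlapping frames (num_frames, frame_len).

    Frames start every ``hop`` samples; a trailing remainder shorter than one
    frame is dropped.  Raises if the signal is shorter than a single frame.
    """
    x = signal.samples
    if x.size < params.frame_len:
        raise ValueError(
            f"signal has {x.size} samples but one frame needs {params.frame_len}"
        )
    num_f = 1 + (x.size - params.frame_len) // params.hop
    idx = np.arange(params.frame_len)[None, :] + params.hop * np.arange(num_f)[:, None]
    return x[idx]


def intensity_means(frames: np.ndarray, convention: str = "power") -> IntensityTrack:
    """Per-frame mean intensity.

    ``convention`` selects the per-sample intensity definition: "power"
    (squared amplitude, the default) or "amplitude" (absolute amplitude).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 2 or frames.shape[1] == 0:
        raise ValueError("frames must be a non-empty 2-D array (num_frames, frame_len)")
    if convention == "power":
        per_sample = frames ** 2
    elif convention == "amplitude":
        per_sample = np.abs(frames)
    else:
        raise ValueError(f"unknown intensity convention {convention!r}")
    return IntensityTrack(per_sample.mean(axis=1))


def pivd(track: IntensityTrack) -> float:
    """Phonatory intensity variation diversity.

    Standard deviation of the first-order difference of the per-frame mean
    intensity sequence.  With ``num_f`` frames the difference sequence has
    ``num_f - 1`` elements and the deviation sum is divided by ``num_f - 1``
    (the length of the difference sequence), so this is the population SD
    of the differences.
    """
    num_f = track.num_frames
    if num_f < 3:
        raise ValueError(f"PIVD needs at least 3 frames, got {num_f}")
    diffs = np.diff(track.values)
    return float(np.sqrt(np.sum((diffs - diffs.mean()) ** 2) / (num_f - 1)))


def _hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, n_fft: int, rate: int) -> np.ndarray:
    """Triangular mel filterbank (n_filters, n_fft//2 + 1) spanning 0..Nyquist."""
    n_bins = n_fft // 2 + 1
    mel_pts = np.linspace(_hz_to_mel(0.0), _hz_to_mel(rate / 2.0), n_filters + 2)
    hz_pts = np.asarray(_mel_to_hz(mel_pts))
    bin_freqs = np.arange(n_bins) * rate / n_fft
    fb = np.zeros((n_filters, n_bins))
    for k in range(n_filters):
        lo, mid, hi = hz_pts[k], hz_pts[k + 1], hz_pts[k + 2]
        rising = (bin_freqs - lo) / max(mid - lo, 1e-12)
        falling = (hi - bin_freqs) / max(hi - mid, 1e-12)
        fb[k] = np.clip(np.minimum(rising, falling), 0.0, None)
    return fb


def mfcc(
    signal: AudioSignal,
    params: FrameParams | None = None,
    n_filters: int = 12,
    n_coeffs: int = 12,
    log_floor: float = 1e-10,
) -> np.ndarray:
    """Mel-frequency cepstral coefficients, (num_frames, n_coeffs).

    Each frame is Hamming-windowed, transformed to a power spectrum,
    aggregated by ``n_filters`` triangular mel filters spanning 0 Hz to
    Nyquist, floored and logged, then cosine-transformed (orthonormal
    DCT-II) keeping ``n_coeffs`` coefficients.  Requires enough signal for
    at least 5 frames so that the second-order delta context exists.
    """
    if params is None:
        params = FrameParams.from_seconds(signal.rate)
    min_len = params.frame_len + 4 * params.hop
    if signal.samples.size < min_len:
        raise ValueError(
            f"signal too short for MFCC analysis: need >= {min_len} samples "
            f"(5 frames), got {signal.samples.size}"
        )
    frames = frame_signal(signal, params)
    window = np.hamming(params.frame_len)
    spectrum = np.abs(scipy.fft.rfft(frames * window, axis=1)) ** 2
    fb = mel_filterbank(n_filters, params.frame_len, signal.rate)
    energies = spectrum @ fb.T
    log_e = np.log(np.maximum(energies, log_floor))
    cepstra = scipy.fft.dct(log_e, type=2, norm="ortho", axis=1)
    return cepstra[:, :n_coeffs]


def delta2_mfcc(m: np.ndarray) -> np.ndarray:
    """Second-order differential cepstral parameters over five adjacent frames.

    For interior frame i (per column):
    ``diff_m(i) = (-2 m(i-2) - m(i-1) + m(i+1) + 2 m(i+2)) / 3``.
    Boundary frames replicate the first/last rows before applying the kernel.
    Output has the same shape as the input; requires at least 5 frames.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2:
        raise ValueError("MFCC matrix must be 2-D (frames x coefficients)")
    n = m.shape[0]
    if n < 5:
        raise ValueError(f"delta computation needs >= 5 frames, got {n}")
    padded = np.pad(m, ((2, 2), (0, 0)), mode="edge")
    out = np.zeros_like(m)
    for j, w in enumerate(_DELTA2_KERNEL):
        if w != 0.0:
            out += w * padded[j : j + n]
    return out


def afvc(m: np.ndarray, dm: np.ndarray, mean_eps: float = 1e-9) -> float:
    """Auditory frequency variation coefficient.

    The parameter sequence is the 12 column means of the MFCC matrix followed
    by the 12 column means of the second-order delta matrix (24 values).
    AFVC is the population SD of those 24 values divided by the absolute
    value of their mean.  A near-zero mean (|mean| < ``mean_eps``) makes the
    coefficient of variation meaningless and raises DegenerateInputError.
    """
    m = np.asarray(m, dtype=float)
    dm = np.asarray(dm, dtype=float)
    if m.shape != dm.shape:
        raise ValueError(f"shape mismatch: mfcc {m.shape} vs delta {dm.shape}")
    if m.ndim != 2 or m.shape[0] < 1:
        raise ValueError("need at least one frame")
    ps = np.concatenate([m.mean(axis=0), dm.mean(axis=0)])
    mean_ps = ps.mean()
    if abs(mean_ps) < mean_eps:
        raise DegenerateInputError(
            f"|mean of parameter sequence| = {abs(mean_ps):.3e} < {mean_eps:.1e}; "
            "coefficient of variation is undefined"
        )
    sd = np.sqrt(np.mean((ps - mean_ps) ** 2))
    return float(sd / abs(mean_ps))


def baseline_pitch_stats(
    signal: AudioSignal,
    fmin: float = 60.0,
    fmax: float = 400.0,
    frame_s: float = 0.040,
    hop_s: float = 0.010,
    voicing_threshold: float = 0.3,
) -> tuple[float, float]:
    """Mean and SD of the fundamental frequency over voiced frames.

    A plain short-time autocorrelation tracker: per frame the normalized
    autocorrelation is searched for its peak in the lag range corresponding
    to [fmin, fmax]; frames whose peak falls below ``voicing_threshold`` are
    treated as unvoiced.  The peak lag is refined by parabolic
    interpolation.  Raises if no frame is voiced.
    """
    params = FrameParams.from_seconds(signal.rate, frame_s, hop_s)
    if signal.samples.size < params.frame_len:
        raise ValueError("signal shorter than one pitch analysis frame")
    frames = frame_signal(signal, params)
    frames = frames - frames.mean(axis=1, keepdims=True)
    n = params.frame_len
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = scipy.fft.rfft(frames, n=nfft, axis=1)
    acorr = scipy.fft.irfft(np.abs(spec) ** 2, n=nfft, axis=1)[:, :n]
    lag_min = max(2, int(np.floor(signal.rate / fmax)))
    lag_max = min(n - 2, int(np.ceil(signal.rate / fmin)))
    if lag_max <= lag_min:
        raise ValueError("frame too short for the requested pitch search range")
    f0s = []
    for row in acorr:
        r0 = row[0]
        if r0 <= 0:
            continue
        seg = row[lag_min : lag_max + 1] / r0
        k = int(np.argmax(seg))
        if seg[k] < voicing_threshold:
            continue
        lag = lag_min + k
        # parabolic refinement around the integer-lag peak
        ym1, y0, yp1 = row[lag - 1] / r0, seg[k], row[lag + 1] / r0
        denom = ym1 - 2 * y0 + yp1
        delta = 0.0 if denom == 0 else 0.5 * (ym1 - yp1) / denom
        f0s.append(signal.rate / (lag + float(np.clip(delta, -0.5, 0.5))))
    if not f0s:
        raise ValueError("no voiced frames found; pitch statistics undefined")
    f0s = np.asarray(f0s)
    sd = float(f0s.std(ddof=1)) if f0s.size > 1 else 0.0
    return float(f0s.mean()), sd


def baseline_intensity_stats(track: IntensityTrack) -> tuple[float, float, float, float]:
    """(mean, min, max, sample SD) of the per-frame intensity means."""
    if track.num_frames < 2:
        raise ValueError("intensity statistics need at least 2 frames")
    v = track.values
    return float(v.mean()), float(v.min()), float(v.max()), float(v.std(ddof=1))


def acoustic_features(
    signal: AudioSignal,
    params: FrameParams | None = None,
    intensity_convention: str = "power",
) -> dict[str, float]:
    """All acoustic features of one segment as a flat name -> value mapping.

    Columns follow the shared feature-table schema: pivd, afvc, pitch_mean,
    pitch_sd, int_mean, int_min, int_max, int_sd.
    """
    if params is None:
        params = FrameParams.from_seconds(signal.rate)
    frames = frame_signal(signal, params)
    track = intensity_means(frames, convention=intensity_convention)
    m = mfcc(signal, params)
    dm = delta2_mfcc(m)
    pitch_mean, pitch_sd = baseline_pitch_stats(signal)
    int_mean, int_min, int_max, int_sd = baseline_intensity_stats(track)
    return {
        "pivd": pivd(track),
        "afvc": afvc(m, dm),
        "pitch_mean": pitch_mean,
        "pitch_sd": pitch_sd,
        "int_mean": int_mean,
        "int_min": int_min,
        "int_max": int_max,
        "int_sd": int_sd,
    }
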