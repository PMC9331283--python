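"""Head-movement features from facial-landmark trajectories.

During line-by-line reading the head sweeps rightward along each text line
and snaps back leftward at line ends; re-reading inserts extra sweeps.  The
jaw-contour landmarks (points 1-17) track the head, and their mean
frame-to-frame displacement gives a two-channel head-movement trajectory:
the horizontal repeated-reading dimension (Rr) and the vertical
unconscious-movement dimension (Um).

* **RHR** — number of head-rotation events (leftward returns ending a
  rightward sweep, extracted from the binarized Rr trajectory) divided by
  the number of text lines; ≈ 1 for straight-through reading, > 1 with
  re-reading.
* **UHD** — summed absolute vertical displacement per text line.
* **MEA motion energy** — a trajectory-blind comparator: thresholded
  gray-level frame differencing inside a head region of interest.
"""
from __future__ import annotations

import numpy as np

from .datatypes import HeadTrajectory, LandmarkSequence, ReadingMeta

__all__ = [
    "head_trajectory",
    "binarize_rr",
    "count_rotations",
    "rhr",
    "uhd",
    "mea_motion_energy",
    "head_roi_from_landmarks",
    "head_features",
]

N_CONTOUR = 17  # jaw-contour landmarks 1..17 (1-based)


def head_trajectory(lm: LandmarkSequence) -> HeadTrajectory:
    """Mean frame-difference of the 17 jaw-contour landmarks.

    hm_r[i] / hm_u[i] are the mean x / y displacement of points 1-17 between
    frame i and frame i+1.  Needs at least 2 frames.
    """
    if lm.n_frames < 2:
        raise ValueError(f"head trajectory needs >= 2 frames, got {lm.n_frames}")
    contour = lm.points[:, :N_CONTOUR, :]
    if not np.all(np.isfinite(contour)):
        raise ValueError("jaw-contour landmarks contain non-finite coordinates")
    step = np.diff(contour, axis=0).mean(axis=1)
    return HeadTrajectory(hm_r=step[:, 0], hm_u=step[:, 1])


def binarize_rr(hm_r: np.ndarray, dead_band: float = 0.2) -> np.ndarray:
    """Binarize the Rr trajectory: rightward motion -> 1, leftward -> 0.

    Displacements within ±``dead_band`` pixels carry the previously emitted
    state; leading dead-band frames take the first decisive direction.  If
    the whole trajectory stays inside the dead band the sequence is the
    constant 1 (reading is assumed to start with a rightward sweep).
    """
    hm_r = np.asarray(hm_r, dtype=float)
    if hm_r.ndim != 1 or hm_r.size == 0:
        raise ValueError("hm_r must be a non-empty 1-D vector")
    out = np.empty(hm_r.size, dtype=int)
    state = -1  # unresolved
    for i, v in enumerate(hm_r):
        if v > dead_band:
            state = 1
        elif v < -dead_band:
            state = 0
        out[i] = state
    # backfill leading unresolved frames with the first decisive direction
    if out[0] == -1:
        decisive = out[out != -1]
        first = decisive[0] if decisive.size else 1
        k = int(np.argmax(out != -1)) if decisive.size else out.size
        out[:k] = first
    return out


def _runs(binary: np.ndarray) -> list[list[int]]:
    """Run-length encode as mutable [state, length] pairs."""
    runs: list[list[int]] = []
    for b in binary:
        if runs and runs[-1][0] == b:
            runs[-1][1] += 1
        else:
            runs.append([int(b), 1])
    return runs


def count_rotations(binary: np.ndarray, min_run: int = 3) -> int:
    """Number of head-rotation events in a binarized Rr trajectory.

    Runs shorter than ``min_run`` frames are treated as landmark jitter and
    absorbed into the preceding run (the following one if there is no
    preceding run).  A rotation is a 1 -> 0 transition of the filtered
    sequence: the leftward return ending a rightward reading sweep.
    """
    binary = np.asarray(binary)
    if binary.ndim != 1 or binary.size == 0:
        raise ValueError("binary trajectory must be a non-empty 1-D vector")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    runs = _runs(binary)
    while len(runs) > 1:
        short = next((i for i, r in enumerate(runs) if r[1] < min_run), None)
        if short is None:
            break
        target = short - 1 if short > 0 else short + 1
        runs[target][1] += runs[short][1]
        del runs[short]
        # coalesce neighbours that now share a state
        merged: list[list[int]] = []
        for r in runs:
            if merged and merged[-1][0] == r[0]:
                merged[-1][1] += r[1]
            else:
                merged.append(r)
        runs = merged
    states = [r[0] for r in runs]
    return sum(1 for a, b in zip(states, states[1:]) if a == 1 and b == 0)


def rhr(n_rotations: int, meta: ReadingMeta) -> float:
    """Repeated-reading head-rotation ratio: rotations per text line."""
    if n_rotations < 0:
        raise ValueError("rotation count cannot be negative")
    return n_rotations / meta.n_lines


def uhd(hm_u: np.ndarray, meta: ReadingMeta) -> float:
    """Unconscious head-movement degree: summed |vertical step| per text line."""
    hm_u = np.asarray(hm_u, dtype=float)
    if hm_u.ndim != 1 or hm_u.size == 0:
        raise ValueError("hm_u must be a non-empty 1-D vector")
    return float(np.sum(np.abs(hm_u)) / meta.n_lines)


def head_roi_from_landmarks(lm: LandmarkSequence, dilate: float = 0.2) -> tuple[slice, slice]:
    """Bounding box of the jaw contour over all frames, dilated by a fraction.

    Returned as (row_slice, col_slice) for indexing a grayscale frame stack.
    """
    contour = lm.points[:, :N_CONTOUR, :]
    x0, y0 = np.nanmin(contour, axis=(0, 1))
    x1, y1 = np.nanmax(contour, axis=(0, 1))
    dx, dy = (x1 - x0) * dilate, (y1 - y0) * dilate
    return (
        slice(max(0, int(np.floor(y0 - dy))), int(np.ceil(y1 + dy)) + 1),
        slice(max(0, int(np.floor(x0 - dx))), int(np.ceil(x1 + dx)) + 1),
    )


def mea_motion_energy(
    frames: np.ndarray,
    threshold: float = 10.0,
    roi: tuple[slice, slice] | None = None,
) -> float:
    """Motion-energy-analysis head-movement amount.

    For every consecutive frame pair, absolute gray-level differences above
    ``threshold`` (in the same units as the frames, default 10 gray levels
    on a 0-255 scale) are summed inside the region of interest; the feature
    is the per-pair mean of that sum divided by the ROI pixel count.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (n_frames, H, W) stack with >= 2 frames")
    if roi is not None:
        frames = frames[:, roi[0], roi[1]]
    if frames.shape[1] == 0 or frames.shape[2] == 0:
        raise ValueError("region of interest is empty")
    area = frames.shape[1] * frames.shape[2]
    diffs = np.abs(np.diff(frames, axis=0))
    diffs[diffs <= threshold] = 0.0
    return float(diffs.sum(axis=(1, 2)).mean() / area)


def head_features(
    lm: LandmarkSequence,
    meta: ReadingMeta,
    dead_band: float = 0.2,
    min_run: int = 3,
) -> dict[str, float]:
    """RHR and UHD of one landmark sequence as a name -> value mapping."""
    traj = head_trajectory(lm)
    binary = binarize_rr(traj.hm_r, dead_band=dead_band)
    n_rot = count_rotations(binary, min_run=min_run)
    return {"rhr": rhr(n_rot, meta), "uhd": uhd(traj.hm_u, meta)}
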