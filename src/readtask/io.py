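"""Readers and writers for the pipeline's on-disk formats.

WAV audio (PCM16/float), landmark sequences (CSV with ``frame_idx,
x1,y1,...,x68,y68`` columns or a JSON alternative), feature tables and
evaluation reports (CSV/JSON), and PNG fluency images.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io.wavfile

from .datatypes import AudioSignal, FluencyImage, LandmarkSequence

__all__ = [
    "read_wav",
    "write_wav",
    "read_landmarks",
    "write_landmarks",
    "write_fluency_image",
    "read_feature_table",
    "write_feature_table",
]

log = logging.getLogger(__name__)


def read_wav(path: str | Path) -> AudioSignal:
    """Read a WAV file as normalized mono float samples.

    Integer PCM is scaled to [-1, 1]; stereo is downmixed to mono with a
    logged warning.  Missing or unreadable files raise with the path named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such audio file: {path}")
    try:
        rate, data = scipy.io.wavfile.read(path)
    except Exception as exc:  # corrupt container
        raise ValueError(f"cannot read WAV file {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        log.warning("downmixing %d-channel audio in %s to mono", data.shape[1], path)
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    return AudioSignal(samples=data.astype(float), rate=int(rate))


def write_wav(path: str | Path, signal: AudioSignal) -> None:
    """Write an AudioSignal as 16-bit PCM."""
    samples = np.clip(signal.samples, -1.0, 1.0)
    scipy.io.wavfile.write(
        Path(path), signal.rate, (samples * np.iinfo(np.int16).max).astype(np.int16)
    )


def _landmark_columns() -> list[str]:
    cols = []
    for i in range(1, 69):
        cols += [f"x{i}", f"y{i}"]
    return cols


def write_landmarks(path: str | Path, lm: LandmarkSequence) -> None:
    """Write a landmark sequence; format chosen by suffix (.csv or .json)."""
    path = Path(path)
    if path.suffix == ".json":
        payload = {"fps": lm.fps, "frames": lm.points.tolist()}
        path.write_text(json.dumps(payload))
        return
    flat = lm.points.reshape(lm.n_frames, 136)
    df = pd.DataFrame(flat, columns=_landmark_columns())
    df.insert(0, "frame_idx", np.arange(lm.n_frames))
    with open(path, "w") as fh:
        fh.write(f"# fps={lm.fps}\n")
        df.to_csv(fh, index=False)


def read_landmarks(path: str | Path, fps: float | None = None) -> LandmarkSequence:
    """Read a landmark CSV or JSON file, validating 68 points per frame.

    For CSV, fps comes from a ``# fps=...`` header line unless overridden.
    A frame with the wrong point count raises naming the frame index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such landmark file: {path}")
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        frames = payload["frames"]
        for i, frame in enumerate(frames):
            if len(frame) != 68:
                raise ValueError(f"frame {i} has {len(frame)} points, expected 68")
        return LandmarkSequence(
            points=np.asarray(frames, dtype=float),
            fps=fps if fps is not None else float(payload["fps"]),
        )
    header_fps = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "fps=" in first:
            header_fps = float(first.split("fps=")[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    cols = _landmark_columns()
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"landmark CSV {path} lacks columns {missing[:4]}...")
    bad = df[cols].isna().all(axis=1)
    if bad.any():
        raise ValueError(f"frame {int(np.argmax(bad.to_numpy()))} has no landmark data")
    pts = df[cols].to_numpy(dtype=float).reshape(len(df), 68, 2)
    use_fps = fps if fps is not None else header_fps
    if use_fps is None:
        raise ValueError(f"no fps header in {path}; pass fps explicitly")
    return LandmarkSequence(points=pts, fps=use_fps)


def write_fluency_image(path: str | Path, image: FluencyImage) -> None:
    """Write a fluency image as a lossless PNG."""
    import matplotlib.image

    matplotlib.image.imsave(Path(path), image.pixels, format="png")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for key in ("subject", "segment", "label"):
        if key not in df.columns:
            raise ValueError(f"feature table {path} lacks required column {key!r}")
    return df


def write_feature_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(Path(path), index=False)
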