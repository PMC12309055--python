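"""WAV, CSV and JSON readers/writers for signals, trajectories and results."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .core import SignalRecord

__all__ = [
    "read_wav",
    "write_wav",
    "trajectory_to_csv",
    "trajectory_from_csv",
    "save_json",
    "load_json",
]

_INT_SCALE = {np.dtype(np.int16): 32768.0, np.dtype(np.int32): 2147483648.0}


def read_wav(path) -> SignalRecord:
    """Read a mono PCM16/PCM32/float32 RIFF WAV into a SignalRecord.

    Integer samples are scaled to [-1, 1); float samples pass through.
    """
    path = Path(path)
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path.name}: expected mono audio, got {data.shape[1]} channels")
    if data.dtype in _INT_SCALE:
        samples = data.astype(float) / _INT_SCALE[data.dtype]
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(float)
    else:
        raise ValueError(f"{path.name}: unsupported WAV encoding {data.dtype}")
    return SignalRecord(samples, sample_rate_hz=float(rate), id=path.stem)


def write_wav(path, signal: SignalRecord) -> None:
    """Write a SignalRecord as a float32 WAV (bit-stable round trip)."""
    wavfile.write(Path(path), int(signal.sample_rate_hz),
                  signal.samples.astype(np.float32))


def trajectory_to_csv(path, trajectory: np.ndarray) -> None:
    """Write a coefficient trajectory with columns n, c_1, ..., c_p."""
    trajectory = np.atleast_2d(trajectory)
    p = trajectory.shape[1]
    df = pd.DataFrame(trajectory, columns=[f"c_{i}" for i in range(1, p + 1)])
    df.insert(0, "n", np.arange(trajectory.shape[0]))
    df.to_csv(path, index=False)


def trajectory_from_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[[c for c in df.columns if c != "n"]].to_numpy()


def save_json(path, obj: dict) -> None:
    """Full-precision JSON (numpy arrays become lists via repr('%.17g'))."""
    Path(path).write_text(json.dumps(obj, default=_jsonable, indent=1))


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")
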