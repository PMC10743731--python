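"""WAV input/output and analysis-window slicing.

Audio is carried as float64 samples normalized to [-1, 1]. Files are
written as 16-bit PCM mono WAV; other PCM encodings are converted on
read with a warning. Timestamps are naive local civil time, because the
device schedule is defined in local hours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "AudioRecording",
    "read_wav",
    "write_wav",
    "frame_windows",
    "read_manifest",
    "write_manifest",
]

MANIFEST_COLUMNS = ["path", "device_id", "site_id", "start_time"]

# full-scale value used for the 16-bit round trip
_INT16_SCALE = 32767.0


@dataclass
class AudioRecording:
    """A mono waveform plus the metadata needed to place it in a deployment.

    Parameters
    ----------
    samples
        Amplitude sequence, dimensionless, normalized to [-1, 1].
    sample_rate
        Sampling rate in Hz; must be positive.
    start_time
        Wall-clock start of the recording (naive local time), or None for
        anonymous clips.
    device_id, site_id
        Deployment tags; free-form strings.
    """

    samples: np.ndarray
    sample_rate: float
    start_time: datetime | None = None
    device_id: str = ""
    site_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional (mono)")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def duration_seconds(self) -> float:
        return len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


def _to_float(data: np.ndarray) -> np.ndarray:
    """Scale integer PCM to [-1, 1]; pass floats through."""
    if data.dtype == np.int16:
        return data.astype(np.float64) / 32768.0
    if data.dtype == np.int32:
        return data.astype(np.float64) / 2147483648.0
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned, midpoint 128
        return (data.astype(np.float64) - 128.0) / 128.0
    if np.issubdtype(data.dtype, np.floating):
        return data.astype(np.float64)
    raise ValueError(f"unsupported WAV sample format: {data.dtype}")


def read_wav(
    path: str | Path,
    *,
    start_time: datetime | None = None,
    device_id: str = "",
    site_id: str = "",
) -> AudioRecording:
    """Read a PCM WAV file into an :class:`AudioRecording`.

    Multi-channel files are averaged to mono with a warning. Raises
    ``FileNotFoundError`` for missing files and ``ValueError`` for
    non-WAV payloads or zero-length audio.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # scipy raises bare ValueError on bad RIFF
        raise ValueError(f"{path} is not a readable PCM WAV file: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"{path} contains no audio frames")
    if data.ndim == 2:
        warnings.warn(
            f"{path}: {data.shape[1]} channels averaged to mono", stacklevel=2
        )
        data = _to_float(data).mean(axis=1)
    else:
        data = _to_float(data)
    return AudioRecording(
        samples=data,
        sample_rate=float(rate),
        start_time=start_time,
        device_id=device_id,
        site_id=site_id,
    )


def write_wav(rec: AudioRecording, path: str | Path) -> None:
    """Write a recording as 16-bit PCM mono WAV.

    Samples outside [-1, 1] are clipped with a warning; ``read_wav``
    inverts the file up to one quantization step (2**-15).
    """
    path = Path(path)
    samples = rec.samples
    peak = np.max(np.abs(samples)) if len(samples) else 0.0
    if peak > 1.0:
        warnings.warn(
            f"samples exceed full scale (peak {peak:.3f}); clipping to [-1, 1]",
            stacklevel=2,
        )
        samples = np.clip(samples, -1.0, 1.0)
    pcm = np.round(samples * _INT16_SCALE).astype(np.int16)
    wavfile.write(str(path), int(rec.sample_rate), pcm)


def frame_windows(
    rec: AudioRecording, window_seconds: float, hop_seconds: float
) -> Iterator[tuple[float, np.ndarray]]:
    """Slice a recording into fixed-length analysis windows.

    Yields ``(start_offset_seconds, sample_view)`` pairs, ordered by
    time, each exactly ``window_seconds`` long; a trailing partial
    window is dropped. Raises ``ValueError`` if the recording is
    shorter than one window or ``hop_seconds <= 0``.
    """
    if hop_seconds <= 0:
        raise ValueError("hop_seconds must be positive")
    window_samples = int(round(window_seconds * rec.sample_rate))
    hop_samples = int(round(hop_seconds * rec.sample_rate))
    if window_samples <= 0:
        raise ValueError("window_seconds too short for the sample rate")
    if hop_samples <= 0:
        raise ValueError("hop_seconds too short for the sample rate")
    if window_samples > len(rec.samples):
        raise ValueError(
            f"recording of {rec.duration_seconds:.3f} s is shorter than one "
            f"{window_seconds:.3f} s window"
        )
    for start in range(0, len(rec.samples) - window_samples + 1, hop_samples):
        yield start / rec.sample_rate, rec.samples[start : start + window_samples]


def n_frames(duration: float, window_seconds: float, hop_seconds: float) -> int:
    """Closed-form frame count for ``frame_windows``: floor((d-w)/h)+1."""
    if duration < window_seconds:
        raise ValueError("duration shorter than one window")
    # guard float fuzz: compute in samples as frame_windows does at fs=1
    return int(np.floor((duration - window_seconds) / hop_seconds + 1e-9)) + 1


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a recording manifest CSV (`path,device_id,site_id,start_time`).

    start_time is parsed as naive local time; duplicate paths and empty
    device ids are rejected.
    """
    df = pd.read_csv(path, comment="#", dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["path"].duplicated().any():
        dup = df.loc[df["path"].duplicated(), "path"].iloc[0]
        raise ValueError(f"duplicate manifest path: {dup}")
    if df["device_id"].isna().any() or (df["device_id"].str.len() == 0).any():
        raise ValueError("manifest contains empty device_id")
    df["start_time"] = pd.to_datetime(df["start_time"])
    return df[MANIFEST_COLUMNS]


def write_manifest(rows: pd.DataFrame, path: str | Path) -> None:
    rows = rows[MANIFEST_COLUMNS].copy()
    rows["start_time"] = pd.to_datetime(rows["start_time"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    rows.to_csv(path, index=False)
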