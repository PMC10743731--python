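"""Band-limited power spectra of analysis windows.

Each window of ``round(sample_rate / bin_width)`` samples is Hann-tapered
and Fourier-transformed, giving bins spaced exactly ``bin_width`` Hz
apart (5 Hz by default). Power is expressed in dB relative to full
scale, so a full-scale sine reads ~0 dB in its bin; all detection
thresholds downstream are relative to the frame's noise floor, which
makes the pipeline invariant to global gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import get_window

from buzzpam.audio_io import AudioRecording, frame_windows

__all__ = [
    "SpectralFrame",
    "compute_frames",
    "noise_floor",
    "export_spectrogram",
]

DEFAULT_BIN_WIDTH = 5.0
DEFAULT_BAND = (4.0, 3000.0)

_DB_FLOOR = -140.0  # numerical floor for log of zero power


@dataclass
class SpectralFrame:
    """Power spectrum of one analysis window.

    freqs are bin centers in Hz, strictly increasing and spaced by
    ``bin_width``; power is in dB relative to full scale, one value per
    bin, restricted to the analysis band.
    """

    time_offset: float
    freqs: np.ndarray
    power: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if len(self.freqs) != len(self.power):
            raise ValueError("freqs and power length mismatch")
        if len(self.freqs) == 0:
            raise ValueError("empty spectral frame")
        if not np.all(np.isfinite(self.power)):
            raise ValueError("non-finite power values")


def compute_frames(
    rec: AudioRecording,
    bin_width: float = DEFAULT_BIN_WIDTH,
    band: tuple[float, float] = DEFAULT_BAND,
    hop_fraction: float = 0.5,
) -> list[SpectralFrame]:
    """Short-time spectra of a recording at the requested bin spacing.

    The window length is ``round(sample_rate / bin_width)`` samples so
    FFT bins land exactly ``bin_width`` Hz apart; hop is
    ``hop_fraction`` of the window. Output is truncated to ``band``.
    Raises ``ValueError`` if the sample rate cannot cover the band
    (``sample_rate < 2 * band[1]``) or the recording is shorter than one
    window.
    """
    low, high = band
    if rec.sample_rate < 2 * high:
        raise ValueError(
            f"sample_rate {rec.sample_rate} Hz cannot represent content up to "
            f"{high} Hz (needs >= {2 * high} Hz)"
        )
    if not 0 < hop_fraction <= 1:
        raise ValueError("hop_fraction must be in (0, 1]")
    n = int(round(rec.sample_rate / bin_width))
    window_seconds = n / rec.sample_rate
    hop_seconds = max(1, int(round(n * hop_fraction))) / rec.sample_rate
    taper = get_window("hann", n, fftbins=True)
    coherent_gain = taper.sum()
    freqs = np.fft.rfftfreq(n, d=1.0 / rec.sample_rate)
    mask = (freqs >= low) & (freqs <= high)
    band_freqs = freqs[mask]

    frames = []
    for offset, chunk in frame_windows(rec, window_seconds, hop_seconds):
        spec = np.fft.rfft(chunk * taper)
        # amplitude estimate of a coherent sine in each bin; full-scale
        # sine -> amplitude 1 -> 0 dB
        amp = 2.0 * np.abs(spec) / coherent_gain
        with np.errstate(divide="ignore"):
            power_db = 20.0 * np.log10(amp)
        power_db = np.maximum(power_db, _DB_FLOOR)
        frames.append(
            SpectralFrame(
                time_offset=offset,
                freqs=band_freqs,
                power=power_db[mask],
                bin_width=bin_width,
            )
        )
    return frames


def noise_floor(frame: SpectralFrame) -> float:
    """Median in-band power (dB); robust while < 50% of bins are signal."""
    return float(np.median(frame.power))


def export_spectrogram(
    frames: Sequence[SpectralFrame],
    path: str | Path,
    image_path: str | Path | None = None,
    dynamic_range_db: float = 70.0,
) -> None:
    """Write frames as a frequency x time CSV matrix for diagnostics.

    First column is frequency (Hz); each subsequent column is one frame,
    with a header row of time offsets in seconds. Values are clipped at
    ``dynamic_range_db`` below the matrix maximum. If ``image_path`` is
    given a raster image is rendered as well (requires matplotlib).
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    freqs = frames[0].freqs
    mat = np.column_stack([f.power for f in frames])
    floor = mat.max() - dynamic_range_db
    mat = np.maximum(mat, floor)

    path = Path(path)
    header = "freq_hz," + ",".join(f"{f.time_offset:.6g}" for f in frames)
    body = np.column_stack([freqs, mat])
    np.savetxt(path, body, delimiter=",", header=header, comments="", fmt="%.4f")

    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        times = [f.time_offset for f in frames]
        fig, ax = plt.subplots(figsize=(8, 4))
        pcm = ax.pcolormesh(times, freqs, mat, shading="nearest", cmap="magma")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("frequency (Hz)")
        fig.colorbar(pcm, ax=ax, label="power (dBFS)")
        fig.tight_layout()
        fig.savefig(image_path, dpi=120)
        plt.close(fig)
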