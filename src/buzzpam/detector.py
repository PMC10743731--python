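"""Harmonic buzz-pattern detection and event segmentation.

A frame is classified as containing a buzz when a spectral peak in the
fundamental range is accompanied by peaks near its integer multiples
(harmonic-comb verification). Candidate frames are then merged into
events: short gaps are bridged, the fundamental must stay near the
running median of the run, and runs shorter than a minimum length are
discarded. ``count_buzzes`` is the end-to-end entry point producing the
per-recording event count.

All thresholds are relative to the per-frame noise floor, so detection
is invariant under global gain changes of the waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from buzzpam.audio_io import AudioRecording
from buzzpam.spectral import (
    DEFAULT_BAND,
    DEFAULT_BIN_WIDTH,
    SpectralFrame,
    compute_frames,
    noise_floor,
)

__all__ = [
    "DetectorConfig",
    "FrameCandidate",
    "BuzzEvent",
    "find_peaks",
    "classify_frame",
    "segment_events",
    "count_buzzes",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable thresholds of the buzz detector.

    Defaults target wingbeat fundamentals of flying Hymenoptera/Diptera
    (50-1000 Hz) with at least two verified harmonics; all values are
    exposed so they can be tuned per deployment.
    """

    f0_range: tuple[float, float] = (50.0, 1000.0)
    min_harmonics: int = 2
    harmonic_tol: float = 7.5
    peak_threshold: float = 10.0
    min_event_frames: int = 2
    max_gap_frames: int = 1
    f0_track_tol: float = 15.0

    def __post_init__(self) -> None:
        lo, hi = self.f0_range
        if not (4.0 < lo < hi < 3000.0):
            raise ValueError(f"f0_range {self.f0_range} must lie within (4, 3000) Hz")
        if self.min_harmonics < 1:
            raise ValueError("min_harmonics must be >= 1")
        for name in ("harmonic_tol", "peak_threshold", "f0_track_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_event_frames < 1:
            raise ValueError("min_event_frames must be >= 1")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        d = dict(d)
        if "f0_range" in d:
            d["f0_range"] = tuple(d["f0_range"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "DetectorConfig":
        """Load from a YAML/JSON file mirroring the field names."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of config fields")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["f0_range"] = list(d["f0_range"])
        return d


@dataclass(frozen=True)
class FrameCandidate:
    """One frame that passed the buzz-pattern check."""

    time_offset: float
    f0: float
    n_harmonics: int
    snr: float


@dataclass(frozen=True)
class BuzzEvent:
    """A contiguous run of candidate frames counted as one buzz."""

    start: float
    end: float
    f0_median: float
    n_frames: int
    peak_snr: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("event end must exceed start")


def find_peaks(
    frame: SpectralFrame, threshold: float
) -> list[tuple[float, float]]:
    """Local spectral maxima exceeding ``noise_floor + threshold`` dB.

    A peak is a bin strictly greater than both neighbors (band-edge bins
    cannot peak). Returns ``(freq_hz, power_db)`` sorted by frequency.
    """
    p = frame.power
    floor = noise_floor(frame)
    if len(p) < 3:
        return []
    interior = np.arange(1, len(p) - 1)
    is_peak = (p[interior] > p[interior - 1]) & (p[interior] > p[interior + 1])
    loud = p[interior] > floor + threshold
    idx = interior[is_peak & loud]
    return [(float(frame.freqs[i]), float(p[i])) for i in idx]


def _harmonic_score(
    f0: float,
    peaks: Sequence[tuple[float, float]],
    band_top: float,
    tol: float,
) -> tuple[int, float]:
    """Count peaks near k*f0 (k >= 2) and sum their linear power."""
    freqs = np.array([f for f, _ in peaks])
    powers = np.array([p for _, p in peaks])
    n = 0
    power_sum = 0.0
    k = 2
    while k * f0 <= band_top + tol:
        target = k * f0
        close = np.abs(freqs - target) <= tol
        if close.any():
            n += 1
            power_sum += float(10 ** (powers[close].max() / 10.0))
        k += 1
    return n, power_sum


def classify_frame(
    frame: SpectralFrame, cfg: DetectorConfig
) -> FrameCandidate | None:
    """Test one frame for a buzz pattern.

    Among peaks inside ``f0_range``, the fundamental is the candidate
    maximizing the number of verified harmonics (peaks within
    ``harmonic_tol`` of k*f0, k = 2, 3, ... up to the band edge), ties
    broken by larger summed harmonic power. Returns None unless the
    winner verifies at least ``min_harmonics`` harmonics.
    """
    peaks = find_peaks(frame, cfg.peak_threshold)
    if not peaks:
        return None
    lo, hi = cfg.f0_range
    band_top = float(frame.freqs[-1])
    best: tuple[int, float, float, float] | None = None  # (n, score, f0, power)
    for f, p in peaks:
        if not lo <= f <= hi:
            continue
        n, score = _harmonic_score(f, peaks, band_top, cfg.harmonic_tol)
        key = (n, score, p)
        if best is None or key > (best[0], best[1], best[3]):
            best = (n, score, f, p)
    if best is None or best[0] < cfg.min_harmonics:
        return None
    n, _, f0, power = best
    return FrameCandidate(
        time_offset=frame.time_offset,
        f0=f0,
        n_harmonics=n,
        snr=power - noise_floor(frame),
    )


def segment_events(
    cands: Iterable[tuple[int, FrameCandidate | None]],
    cfg: DetectorConfig,
    hop_seconds: float,
    window_seconds: float | None = None,
) -> list[BuzzEvent]:
    """Merge a time-ordered candidate sequence into buzz events.

    Consecutive candidate frames extend the current run while their f0
    stays within ``f0_track_tol`` of the run's median; gaps of up to
    ``max_gap_frames`` non-candidate frames are bridged. Runs with fewer
    than ``min_event_frames`` candidates are dropped. Event end extends
    one window length past the last member frame's start.
    """
    if window_seconds is None:
        window_seconds = 2.0 * hop_seconds  # 50% overlap convention
    events: list[BuzzEvent] = []
    run: list[FrameCandidate] = []
    last_idx: int | None = None
    prev_idx: int | None = None

    def close_run() -> None:
        if len(run) >= cfg.min_event_frames:
            f0s = [c.f0 for c in run]
            events.append(
                BuzzEvent(
                    start=run[0].time_offset,
                    end=run[-1].time_offset + window_seconds,
                    f0_median=float(np.median(f0s)),
                    n_frames=len(run),
                    peak_snr=max(c.snr for c in run),
                )
            )
        run.clear()

    for idx, cand in cands:
        if prev_idx is not None and idx <= prev_idx:
            raise ValueError("frame indices must be strictly increasing")
        prev_idx = idx
        if cand is None:
            continue
        if run:
            gap = idx - last_idx - 1
            f0_ok = abs(cand.f0 - float(np.median([c.f0 for c in run]))) <= cfg.f0_track_tol
            if gap > cfg.max_gap_frames or not f0_ok:
                close_run()
        run.append(cand)
        last_idx = idx
    close_run()
    return events


def count_buzzes(
    rec: AudioRecording,
    cfg: DetectorConfig | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    band: tuple[float, float] = DEFAULT_BAND,
    hop_fraction: float = 0.5,
) -> tuple[int, list[BuzzEvent]]:
    """Detect and count buzz events in one recording.

    Deterministic for fixed input and configuration: returns
    ``(count, events)`` with ``count == len(events)``.
    """
    if cfg is None:
        cfg = DetectorConfig()
    frames = compute_frames(rec, bin_width=bin_width, band=band, hop_fraction=hop_fraction)
    window_seconds = int(round(rec.sample_rate / bin_width)) / rec.sample_rate
    hop_seconds = window_seconds * hop_fraction
    cands = [(i, classify_frame(f, cfg)) for i, f in enumerate(frames)]
    events = segment_events(cands, cfg, hop_seconds, window_seconds)
    return len(events), events
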