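import numpy as np
import pytest

from buzzpam.audio_io import AudioRecording
from buzzpam.schedule import DutyCycleSchedule
from buzzpam.synth import BuzzSpec, synth_buzz

FS = 8000


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_schedule():
    return DutyCycleSchedule.default()


def make_noise(seconds: float, level_db: float = -45.0, seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, 10 ** (level_db / 20.0), size=int(round(seconds * FS)))


def make_buzz_recording(
    f0: float = 220.0,
    seconds: float = 2.0,
    buzz_at: float = 0.7,
    snr_db: float = 25.0,
    noise_db: float = -45.0,
    seed: int = 0,
    n_harmonics: int = 4,
) -> AudioRecording:
    """Noise background with one buzz injected at a known offset."""
    samples = make_noise(seconds, noise_db, seed)
    buzz = synth_buzz(
        BuzzSpec(f0=f0, n_harmonics=n_harmonics, amplitude_db=noise_db + snr_db),
        FS,
        seed=seed + 1,
    )
    start = int(buzz_at * FS)
    samples[start : start + len(buzz)] += buzz
    return AudioRecording(samples, FS)


@pytest.fixture
def buzz_recording():
    return make_buzz_recording()
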