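import numpy as np
import pytest

from roihmm.audio import AudioClip


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_clip(rng):
    """One second of Gaussian noise at the canonical rate."""
    return AudioClip(0.05 * rng.standard_normal(44100), 44100)


def tone_clip(freq_hz, duration_s=1.0, sample_rate=44100, amplitude=0.5):
    t = np.arange(int(duration_s * sample_rate)) / sample_rate
    return AudioClip(amplitude * np.sin(2 * np.pi * freq_hz * t), sample_rate)
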