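import numpy as np
import pytest

from neoegg.recording import EggRecording


def make_tone(freq_cpm: float, duration_min: float = 30.0, fs: float = 8.0,
              amp: float = 1.0, subject_id: str = "tone") -> EggRecording:
    """Pure sinusoid at a gastric frequency, stage-tagged as filtered."""
    t = np.arange(int(duration_min * 60 * fs)) / fs
    x = amp * np.sin(2 * np.pi * (freq_cpm / 60.0) * t)
    return EggRecording(x, fs, subject_id=subject_id, stage_tag="filtered")


@pytest.fixture
def tone_3cpm() -> EggRecording:
    return make_tone(3.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
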