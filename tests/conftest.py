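import numpy as np
import pytest

from anaspec.audio_io import Waveform


@pytest.fixture
def sine_100hz() -> Waveform:
    """1 s of a unit 100 Hz sine at 1000 Hz."""
    t = np.arange(1000) / 1000.0
    return Waveform(np.sin(2 * np.pi * 100 * t), 1000)


@pytest.fixture
def random_waveform() -> Waveform:
    rng = np.random.default_rng(42)
    return Waveform(rng.uniform(-1, 1, 1024), 8000)
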