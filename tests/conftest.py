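import numpy as np
import pytest

from doaflow import EEGRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_recording(rng):
    """10 s of 3-channel independent white noise at 256 Hz."""
    data = rng.standard_normal((2560, 3)) * 20.0
    return EEGRecording(["Fp1", "F3", "P3"], 256.0, data)


@pytest.fixture
def long_noise_recording(rng):
    """140 min of 3-channel noise at a reduced 8 Hz rate (window math)."""
    n = 140 * 60 * 8
    return EEGRecording(["a", "b", "c"], 8.0, rng.standard_normal((n, 3)))
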