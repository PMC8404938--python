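import numpy as np
import pytest

from neovitals import ROIBox, SceneConfig

FS = 30.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def time_10s():
    """10 s sample grid at 30 Hz (300 samples)."""
    return np.arange(300) / FS


@pytest.fixture
def small_scene():
    """Desk-speed scene config: quarter-size frame, proportional ROI."""
    return SceneConfig(
        frame_size=(120, 160),
        roi=ROIBox(50, 30, 110, 90),
        hr_bpm=150.0,
        rr_bpm=40.0,
        seed=7,
    )


def tone(freq_hz, n=300, fs=FS, amp=1.0, phase=0.0):
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq_hz * t + phase)
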