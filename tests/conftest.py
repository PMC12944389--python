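import numpy as np
import pytest

from semgdenoise.signal_model import Signal

FS = 1500.0


@pytest.fixture(scope="session")
def two_tone() -> Signal:
    """3-second 50 + 200 Hz two-tone at 1500 Hz: the standard VMD probe."""
    t = np.arange(int(3 * FS)) / FS
    x = np.sin(2 * np.pi * 50 * t) + np.sin(2 * np.pi * 200 * t)
    return Signal(x, FS)


def tone(freq: float, seconds: float = 2.0, fs: float = FS, amp: float = 1.0) -> Signal:
    t = np.arange(int(seconds * fs)) / fs
    return Signal(amp * np.sin(2 * np.pi * freq * t), fs)
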