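import numpy as np
import pytest

from sleepsig.tfa import SignalSegment


@pytest.fixture
def tone():
    """Factory for pure-tone segments: tone(f0, duration, fs, amp, phase)."""
    def make(f0=1.2, duration=20.0, fs=200.0, amp=1.0, phase=0.0):
        t = np.arange(int(duration * fs)) / fs
        return SignalSegment(amp * np.cos(2 * np.pi * f0 * t + phase), fs)
    return make


@pytest.fixture
def interior():
    """Slice excluding the first/last 5% of samples (cone of influence)."""
    def make(n, frac=0.05):
        k = int(frac * n)
        return slice(k, n - k)
    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
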