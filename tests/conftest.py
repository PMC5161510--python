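import numpy as np
import pytest

from vocsketch.signals import Waveform


@pytest.fixture
def tone():
    """Factory for pure-tone waveforms."""

    def _tone(freq=440.0, duration=1.0, rate=8000, amplitude=0.5):
        t = np.arange(int(round(duration * rate))) / rate
        return Waveform(amplitude * np.sin(2 * np.pi * freq * t), rate)

    return _tone


@pytest.fixture
def noise():
    """Factory for seeded white-noise waveforms."""

    def _noise(duration=1.0, rate=8000, amplitude=0.3, seed=0):
        rng = np.random.default_rng(seed)
        return Waveform(amplitude * rng.standard_normal(int(round(duration * rate))), rate)

    return _noise


def third_octave_levels(x: np.ndarray, rate: int, f_lo=100.0, f_hi=None):
    """Third-octave band levels (dB) of a signal's Welch spectrum.

    Band-averaging removes periodogram ripple so that long-term spectral
    comparisons test coloration, not estimator variance.
    """
    from scipy.signal import welch

    f, P = welch(x, rate, nperseg=min(1024, len(x)))
    f_hi = f_hi or rate / 2 / 1.2
    edges = [f_lo]
    while edges[-1] < f_hi:
        edges.append(edges[-1] * 2 ** (1 / 3))
    levels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (f >= lo) & (f < hi)
        if m.sum() >= 2:
            levels.append(10 * np.log10(P[m].mean() + 1e-20))
    return np.array(levels)
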