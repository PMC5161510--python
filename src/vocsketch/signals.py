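"""Core waveform container, WAV I/O, resampling, time-stretching, level control.

All audio inside the package is float64 in [-1, 1], mono, with times in
seconds.  Stereo WAV files are down-mixed by channel averaging on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from ._stft import istft, stft

__all__ = [
    "Waveform",
    "read_wav",
    "write_wav",
    "resample",
    "time_stretch",
    "equalize_level",
    "rms_dbfs",
]


@dataclass(frozen=True)
class Waveform:
    """Sampled mono audio.

    Parameters
    ----------
    samples
        Amplitudes, nominally within [-1, 1].
    rate
        Sampling rate in Hz; must be positive.
    """

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional (mono)")
        if not np.all(np.isfinite(samples)):
            raise ValueError("Waveform samples must be finite")
        if self.rate <= 0:
            raise ValueError("Sampling rate must be positive")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "rate", int(self.rate))

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return len(self.samples) / self.rate

    def __len__(self) -> int:
        return len(self.samples)


def read_wav(path) -> Waveform:
    """Read a WAV file as a mono float waveform.

    Integer PCM is scaled to [-1, 1]; multi-channel audio is down-mixed by
    averaging channels.
    """
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # wavfile raises bare ValueError on bad headers
        raise ValueError(f"unreadable or unsupported WAV file: {path!r}: {exc}") from exc
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV sample format: {data.dtype}")
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return Waveform(samples, rate)


def write_wav(path, w: Waveform, bit_depth: int = 16) -> None:
    """Write a waveform as 16-bit PCM (default) or 32-bit float WAV."""
    if bit_depth == 16:
        # scale by 2**15 and clip the top code so the read-back error stays
        # within one quantization step across the full [-1, 1] range
        data = np.clip(np.round(w.samples * 32768.0), -32768, 32767).astype(np.int16)
    elif bit_depth == 32:
        data = w.samples.astype(np.float32)
    else:
        raise ValueError("bit_depth must be 16 (PCM) or 32 (float)")
    wavfile.write(path, w.rate, data)


def resample(w: Waveform, target_rate: int) -> Waveform:
    """Band-limited (polyphase) resampling preserving duration."""
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == w.rate:
        return w
    frac = Fraction(int(target_rate), int(w.rate))
    out = resample_poly(w.samples, frac.numerator, frac.denominator)
    return Waveform(out, target_rate)


def time_stretch(w: Waveform, target_duration_s: float) -> Waveform:
    """Stretch or compress a signal to a target duration without pitch shift.

    Standard phase vocoder: STFT magnitudes are resampled along the time
    axis and phases re-accumulated from the measured per-bin instantaneous
    frequency.  Window is 1024 samples at rates <= 16 kHz (2048 above),
    75% overlap.
    """
    if target_duration_s <= 0:
        raise ValueError("target duration must be positive")
    win = 1024 if w.rate <= 16000 else 2048
    hop = win // 4
    if len(w.samples) < win:
        raise ValueError(
            f"input too short for time-stretching: need at least {win} samples"
        )
    target_len = int(round(target_duration_s * w.rate))
    speed = len(w.samples) / target_len
    if abs(speed - 1.0) < 1e-9:
        return w

    X = stft(w.samples, win, hop)
    nf, nb = X.shape
    # fractional analysis positions for each synthesis frame
    steps = np.arange(0, nf - 1, speed)
    mag = np.abs(X)
    phase = np.angle(X)
    omega = 2 * np.pi * np.arange(nb) * hop / win  # expected phase advance/hop

    out = np.empty((len(steps), nb), dtype=complex)
    acc = phase[0].copy()
    for i, s in enumerate(steps):
        j = int(np.floor(s))
        frac = s - j
        m = (1 - frac) * mag[j] + frac * mag[min(j + 1, nf - 1)]
        out[i] = m * np.exp(1j * acc)
        dphi = phase[min(j + 1, nf - 1)] - phase[j] - omega
        dphi -= 2 * np.pi * np.round(dphi / (2 * np.pi))
        acc = acc + omega + dphi

    y = istft(out, win, hop, length=target_len)
    return Waveform(y, w.rate)


def rms_dbfs(w: Waveform) -> float:
    """RMS level in dB relative to full scale (RMS of 1.0)."""
    r = float(np.sqrt(np.mean(w.samples**2)))
    if r == 0.0:
        return -np.inf
    return 20.0 * np.log10(r)


def equalize_level(w: Waveform, target_dbfs: float = -20.0) -> Waveform:
    """Scale a waveform so its RMS sits at ``target_dbfs`` dB re full scale.

    A simplified stand-in for loudness equalization: downstream stages need
    equal levels, not phon-accurate loudness.
    """
    current = rms_dbfs(w)
    if not np.isfinite(current):
        raise ValueError("cannot equalize an all-zero signal (undefined gain)")
    gain = 10.0 ** ((target_dbfs - current) / 20.0)
    return Waveform(w.samples * gain, w.rate)
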