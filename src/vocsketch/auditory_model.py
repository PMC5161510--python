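"""Cochlear-like auditory spectrogram and its approximate inversion.

The analysis chain models peripheral auditory processing at 8 kHz:

1. short-time spectral analysis (32-ms Hann window, 8-ms frames);
2. a bank of 128 constant-Q channels (24 per octave from 90 Hz), each a
   Gaussian weighting of spectral magnitude around its center frequency —
   cochlear filtering plus hair-cell envelope extraction;
3. partial lateral inhibition across adjacent channels, half-wave
   rectified, which sharpens spectral contrast;
4. leaky temporal integration with a 128-ms time constant, sampled at the
   8-ms frame rate.

Every stage is homogeneous of degree one in the input, so spectrogram
values scale linearly with input gain.  At the defaults, one second of
audio yields 125 frames x 128 channels = 16000 coefficients.

Inversion reverses the chain where it is exactly invertible (integration,
inhibition off the rectification floor), maps channel values back to a
non-negative spectral-magnitude estimate through the filterbank
pseudo-inverse, and recovers a waveform by iterative magnitude projection
(Griffin-Lim) from a seeded random-phase start.  The iterate whose
re-analysis best matches the target spectrogram is returned, so
reconstruction error is non-increasing in the iteration budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._stft import istft, n_frames, stft
from .signals import Waveform

__all__ = [
    "AuditoryConfig",
    "AuditorySpectrogram",
    "channel_center_frequencies",
    "auditory_spectrogram",
    "invert_auditory_spectrogram",
    "DEFAULT_CONFIG",
]


def channel_center_frequencies(
    n_channels: int = 128, f_low: float = 90.0, channels_per_octave: float = 24.0
) -> np.ndarray:
    """Geometric (constant-Q) progression of channel center frequencies.

    CF(k) = f_low * 2**(k / channels_per_octave).  With the defaults the
    top channel sits near 3526 Hz and its upper edge near 3629 Hz.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if f_low <= 0:
        raise ValueError("f_low must be positive")
    k = np.arange(n_channels)
    return f_low * 2.0 ** (k / channels_per_octave)


@dataclass(frozen=True)
class AuditoryConfig:
    """Frozen defaults of the peripheral model."""

    sample_rate: int = 8000
    n_channels: int = 128
    f_low: float = 90.0
    channels_per_octave: float = 24.0
    frame_length: float = 0.008  # s
    time_constant: float = 0.128  # s
    window_length: float = 0.032  # s; 75% overlap at the 8-ms hop
    inhibition: float = 0.5  # lateral-inhibition coefficient

    @property
    def hop(self) -> int:
        return int(round(self.frame_length * self.sample_rate))

    @property
    def win(self) -> int:
        return int(round(self.window_length * self.sample_rate))

    @property
    def leak(self) -> float:
        return float(np.exp(-self.frame_length / self.time_constant))

    def center_frequencies(self) -> np.ndarray:
        return channel_center_frequencies(
            self.n_channels, self.f_low, self.channels_per_octave
        )

    def filterbank(self) -> np.ndarray:
        """Channel x FFT-bin weight matrix, rows normalized to unit sum.

        Channel bandwidth is constant-Q (half-octave-scaled by the channel
        density) but floored at three quarters of an FFT bin so that the
        lowest channels, narrower than the spectral resolution, still pool
        a full bin.
        """
        cfs = self.center_frequencies()
        nb = self.win // 2 + 1
        freqs = np.arange(nb) * self.sample_rate / self.win
        q_width = cfs * (2.0 ** (1.0 / (2.0 * self.channels_per_octave)) - 1.0) * 2.0
        bin_width = self.sample_rate / self.win
        sigma = np.maximum(q_width, 0.75 * bin_width)
        W = np.exp(-0.5 * ((freqs[None, :] - cfs[:, None]) / sigma[:, None]) ** 2)
        return W / W.sum(axis=1, keepdims=True)


DEFAULT_CONFIG = AuditoryConfig()


@dataclass
class AuditorySpectrogram:
    """Time x channel output of the peripheral model; values >= 0."""

    values: np.ndarray  # (frames, channels)
    config: AuditoryConfig = field(default_factory=AuditoryConfig)
    source_length: int | None = None  # samples of the analyzed waveform

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("spectrogram values must be 2-D (frames x channels)")
        if self.values.shape[1] != self.config.n_channels:
            raise ValueError(
                f"expected {self.config.n_channels} channels, got {self.values.shape[1]}"
            )

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def channel_cfs(self) -> np.ndarray:
        return self.config.center_frequencies()

    @property
    def coefficients_per_second(self) -> float:
        """Coefficient budget of the full representation."""
        return self.config.n_channels / self.config.frame_length


def auditory_spectrogram(
    w: Waveform, config: AuditoryConfig = DEFAULT_CONFIG
) -> AuditorySpectrogram:
    """Analyze a waveform into its auditory spectrogram.

    The model runs at a fixed rate (8 kHz by default); callers resample
    first.
    """
    if w.rate != config.sample_rate:
        raise ValueError(
            f"auditory model runs at {config.sample_rate} Hz; "
            f"got {w.rate} Hz — resample first"
        )
    X = np.abs(stft(w.samples, config.win, config.hop))
    W = config.filterbank()
    Y = X @ W.T
    L = _lateral_inhibition(Y, config.inhibition)
    S = _leaky_integrate(L, config.leak)
    return AuditorySpectrogram(S, config, source_length=len(w.samples))


def _lateral_inhibition(Y: np.ndarray, c: float) -> np.ndarray:
    L = Y.copy()
    L[:, 1:] = np.maximum(Y[:, 1:] - c * Y[:, :-1], 0.0)
    return L


def _undo_lateral_inhibition(L: np.ndarray, c: float) -> np.ndarray:
    Y = L.copy()
    for k in range(1, Y.shape[1]):
        Y[:, k] = L[:, k] + c * Y[:, k - 1]
    return Y


def _leaky_integrate(L: np.ndarray, a: float) -> np.ndarray:
    S = np.empty_like(L)
    state = np.zeros(L.shape[1])
    for t in range(L.shape[0]):
        state = a * state + (1.0 - a) * L[t]
        S[t] = state
    return S


def _undo_leaky_integrate(S: np.ndarray, a: float) -> np.ndarray:
    L = np.empty_like(S)
    L[0] = S[0] / (1.0 - a)
    L[1:] = (S[1:] - a * S[:-1]) / (1.0 - a)
    return np.maximum(L, 0.0)


def _magnitude_estimate(Y: np.ndarray, W: np.ndarray, n_iter: int = 30) -> np.ndarray:
    """Non-negative spectral magnitudes M with M @ W.T ~ Y.

    The filterbank is wide and nearly rank-deficient at the low end (many
    narrow channels pool the same bins), so a pseudo-inverse blows up;
    multiplicative (Richardson-Lucy style) updates keep the estimate
    non-negative and stable instead.
    """
    M = np.maximum(Y @ W, 1e-12)
    colsum = W.sum(axis=0)  # for the update normalization
    for _ in range(n_iter):
        pred = M @ W.T
        ratio = Y / np.maximum(pred, 1e-12)
        M *= (ratio @ W) / np.maximum(colsum, 1e-12)
    return M


def reconstruction_error(s: AuditorySpectrogram, w: Waveform) -> float:
    """Relative Frobenius distance between ``s`` and the spectrogram of ``w``."""
    S2 = auditory_spectrogram(w, s.config).values
    t = min(len(S2), s.n_frames)
    ref = np.linalg.norm(s.values[:t])
    if ref == 0.0:
        return float(np.linalg.norm(S2[:t]))
    return float(np.linalg.norm(S2[:t] - s.values[:t]) / ref)


def invert_auditory_spectrogram(
    s: AuditorySpectrogram, n_iterations: int = 50, seed: int = 0
) -> Waveform:
    """Resynthesize a waveform whose auditory spectrogram approximates ``s``.

    Deterministic given ``seed``.  Iteration stops early once the relative
    improvement of the reconstruction error falls below 1e-4; the best
    iterate seen is returned.
    """
    if s.n_frames == 0 or not np.any(s.values):
        if s.n_frames == 0:
            raise ValueError("cannot invert an empty spectrogram")
        # silence analyzes to (numerically) zero; return silence directly
        length = s.source_length or s.n_frames * s.config.hop
        return Waveform(np.zeros(length), s.config.sample_rate)
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    cfg = s.config
    L = _undo_leaky_integrate(s.values, cfg.leak)
    Y = _undo_lateral_inhibition(L, cfg.inhibition)
    W = cfg.filterbank()
    M = _magnitude_estimate(Y, W)

    length = s.source_length or s.n_frames * cfg.hop
    rng = np.random.default_rng(seed)
    phase = rng.uniform(-np.pi, np.pi, size=M.shape)
    x = istft(M * np.exp(1j * phase), cfg.win, cfg.hop, length=length)

    best_x = x
    best_err = reconstruction_error(s, Waveform(x, cfg.sample_rate))
    prev_err = best_err
    for _ in range(n_iterations - 1):
        X = stft(x, cfg.win, cfg.hop)[: M.shape[0]]
        mag = np.abs(X)
        X = np.where(mag > 1e-12, X / np.maximum(mag, 1e-12), 1.0)
        x = istft(M * X, cfg.win, cfg.hop, length=length)
        err = reconstruction_error(s, Waveform(x, cfg.sample_rate))
        if err < best_err:
            best_err, best_x = err, x
        if prev_err > 0 and (prev_err - err) / prev_err < 1e-4 and err <= best_err:
            break
        prev_err = err
    return Waveform(best_x, cfg.sample_rate)
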