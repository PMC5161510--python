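"""Short-time Fourier transform helpers shared across the package.

Framing convention: frame ``t`` covers samples ``[t*hop, t*hop + win)``;
the number of frames is ``ceil(n / hop)`` and the signal is zero-padded at
the end so every frame is complete.  With a Hann window and hop = win/4
(75% overlap) the analysis/synthesis pair is exactly invertible up to the
end padding, which callers crop with the ``length`` argument of `istft`.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import get_window

__all__ = ["n_frames", "stft", "istft"]


def n_frames(n_samples: int, hop: int) -> int:
    return max(1, int(np.ceil(n_samples / hop)))


def _frame(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    nf = n_frames(len(x), hop)
    pad = (nf - 1) * hop + win - len(x)
    xp = np.pad(x, (0, pad))
    idx = np.arange(win)[None, :] + hop * np.arange(nf)[:, None]
    return xp[idx]


def stft(x: np.ndarray, win: int, hop: int, window: str = "hann") -> np.ndarray:
    """Complex STFT, shape (n_frames, win // 2 + 1)."""
    w = get_window(window, win, fftbins=True)
    return np.fft.rfft(_frame(np.asarray(x, dtype=np.float64), win, hop) * w, axis=1)


def istft(
    X: np.ndarray,
    win: int,
    hop: int,
    length: int | None = None,
    window: str = "hann",
) -> np.ndarray:
    """Overlap-add inverse of `stft` with window-square normalization."""
    w = get_window(window, win, fftbins=True)
    frames = np.fft.irfft(X, n=win, axis=1) * w
    nf = X.shape[0]
    out_len = (nf - 1) * hop + win
    y = np.zeros(out_len)
    wsum = np.zeros(out_len)
    for t in range(nf):
        y[t * hop : t * hop + win] += frames[t]
        wsum[t * hop : t * hop + win] += w * w
    # floor the normalizer relative to its interior value: for modified
    # spectra (masking, magnitude substitution) the raw w/sum(w^2)
    # normalization amplifies the first/last fraction of a window without
    # bound, since the numerator no longer carries a matching window factor
    y = y / np.maximum(wsum, 0.01 * wsum.max())
    if length is not None:
        if length <= out_len:
            y = y[:length]
        else:
            y = np.pad(y, (0, length - out_len))
    return y
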