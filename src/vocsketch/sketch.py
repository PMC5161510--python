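"""Scalable auditory sketches: sparse tonal resynthesis + LPC noise model.

A sketch is built in four steps: (1) split the referent into tonal and
noise components; (2) sparsify the tonal component's auditory spectrogram
with maximum-picking at a coefficient budget and invert it; (3) model the
noise component frame-by-frame with an all-pole (LPC) filter driven by
white noise; (4) mix the two sketched components back at the referent's
tonal/noise energy ratio.

Quality presets (coefficients per second, LPC order, LPC hop):

    Q1: ( 160,  7, 44 ms)     Q2: ( 800, 16, 20 ms)     Q3: (4000, 36, 9 ms)

Between adjacent qualities the total budget divides by five, split evenly
between the two paths: the LPC hop grows by ~sqrt(5) while the order
shrinks by ~sqrt(5).  LPC frames overlap by 75% regardless of hop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_toeplitz
from scipy.signal import get_window, lfilter

from .auditory_model import (
    DEFAULT_CONFIG,
    AuditoryConfig,
    AuditorySpectrogram,
    auditory_spectrogram,
    invert_auditory_spectrogram,
)
from .decompose import Decomposition, TrackingConfig, separate
from .signals import Waveform, resample

__all__ = [
    "SketchParams",
    "quality_presets",
    "max_pick",
    "sketch_tonal",
    "sketch_noise",
    "sketch_components",
    "make_sketch",
]


@dataclass(frozen=True)
class SketchParams:
    quality: str
    coeffs_per_second: int  # tonal-path budget
    lpc_order: int
    lpc_hop: float  # s
    lpc_overlap: float = 0.75

    @property
    def realized_lpc_rate(self) -> float:
        """LPC coefficients per second actually delivered by the preset."""
        return self.lpc_order / self.lpc_hop


_PRESETS = {
    "Q1": SketchParams("Q1", 160, 7, 0.044),
    "Q2": SketchParams("Q2", 800, 16, 0.020),
    "Q3": SketchParams("Q3", 4000, 36, 0.009),
}


def quality_presets() -> dict[str, SketchParams]:
    """The three quality presets, keyed Q1 (coarsest) to Q3 (finest)."""
    return dict(_PRESETS)


def max_pick(s: AuditorySpectrogram, coeffs_per_second: float) -> AuditorySpectrogram:
    """Keep only the largest spectrogram cells, at a per-second budget.

    Selection runs over non-overlapping 1-s blocks of frames; each block
    keeps its ``round(budget * block_duration)`` largest cells (ties broken
    by lower time then lower channel index).  A budget at or above the full
    representation returns the input unchanged.
    """
    if coeffs_per_second < 1:
        raise ValueError("coeffs_per_second must be >= 1")
    cfg = s.config
    frames_per_block = max(1, int(round(1.0 / cfg.frame_length)))
    out = np.zeros_like(s.values)
    for start in range(0, s.n_frames, frames_per_block):
        block = s.values[start : start + frames_per_block]
        block_duration = block.shape[0] * cfg.frame_length
        k = int(round(coeffs_per_second * block_duration))
        if k >= block.size:
            out[start : start + frames_per_block] = block
            continue
        t_idx, c_idx = np.unravel_index(np.arange(block.size), block.shape)
        order = np.lexsort((c_idx, t_idx, -block.ravel()))
        keep = order[:k]
        sel = np.zeros_like(block)
        sel[t_idx[keep], c_idx[keep]] = block[t_idx[keep], c_idx[keep]]
        out[start : start + frames_per_block] = sel
    return AuditorySpectrogram(out, cfg, source_length=s.source_length)


def sketch_tonal(
    tonal: Waveform,
    params: SketchParams,
    seed: int = 0,
    config: AuditoryConfig = DEFAULT_CONFIG,
    n_iterations: int = 50,
) -> Waveform:
    """Sparse analysis-resynthesis of the tonal component.

    Input must already be at the model rate (8 kHz by default).
    """
    s = auditory_spectrogram(tonal, config)
    sparse = max_pick(s, params.coeffs_per_second)
    return invert_auditory_spectrogram(sparse, n_iterations=n_iterations, seed=seed)


def sketch_noise(noise: Waveform, params: SketchParams, seed: int = 0) -> Waveform:
    """Resynthesize the noise component through frame-wise LPC filters.

    Each frame (length = hop / (1 - overlap)) is fitted with an all-pole
    filter of order ``params.lpc_order`` (autocorrelation method,
    Levinson-type Toeplitz solve); seeded unit white noise is filtered,
    gain-matched to the frame RMS, and the frames are overlap-added with
    incoherent (window-power) normalization so stationary levels are
    preserved.
    """
    if len(noise) == 0:
        raise ValueError("empty input")
    rate = noise.rate
    hop = max(1, int(round(params.lpc_hop * rate)))
    win = int(round(hop / (1.0 - params.lpc_overlap)))
    p = params.lpc_order
    if win < 2 * p:
        raise ValueError(
            f"LPC frame of {win} samples is shorter than 2*order={2 * p}; "
            "use a larger hop or a smaller order"
        )
    x = noise.samples
    nf = max(1, int(np.ceil(len(x) / hop)))
    xp = np.pad(x, (0, (nf - 1) * hop + win - len(x)))
    w = get_window("hann", win, fftbins=True)
    rng = np.random.default_rng(seed)

    out = np.zeros(len(xp))
    norm = np.zeros(len(xp))
    for t in range(nf):
        frame = xp[t * hop : t * hop + win]
        fw = frame * w
        target = float(np.linalg.norm(fw))
        norm[t * hop : t * hop + win] += w**2
        if target < 1e-10:
            rng.standard_normal(win)  # keep the stream position deterministic
            continue
        a = _lpc(fw, p)
        exc = rng.standard_normal(win)
        yw = lfilter([1.0], a, exc) * w
        e = float(np.linalg.norm(yw))
        if e > 0:
            yw *= target / e  # exact windowed-energy match per frame
        out[t * hop : t * hop + win] += yw
    out = out / np.sqrt(np.maximum(norm, 1e-12))
    # final gain-matching pass: pin each hop-frame's RMS to the input's,
    # smoothing the correction between frame centers
    gains = np.ones(nf)
    for t in range(nf):
        sl = slice(t * hop, min((t + 1) * hop, len(xp)))
        r_in = np.sqrt(np.mean(xp[sl] ** 2))
        r_out = np.sqrt(np.mean(out[sl] ** 2))
        if r_in > 1e-10 and r_out > 1e-10:
            gains[t] = r_in / r_out
        elif r_in <= 1e-10:
            gains[t] = 0.0
    centers = (np.arange(nf) + 0.5) * hop
    out *= np.interp(np.arange(len(out)), centers, gains)
    return Waveform(out[: len(x)], rate)


def _lpc(frame: np.ndarray, order: int) -> np.ndarray:
    """LPC polynomial [1, -a1, ..., -ap] via the autocorrelation method."""
    n = len(frame)
    r = np.correlate(frame, frame, mode="full")[n - 1 : n + order]
    r = r.astype(np.float64)
    r[0] += 1e-9 * r[0] + 1e-12
    a = solve_toeplitz((r[:order], r[:order]), r[1 : order + 1])
    return np.concatenate(([1.0], -a))


def make_sketch(
    w: Waveform,
    quality: str,
    seed: int = 0,
    tracking: TrackingConfig = TrackingConfig(),
    config: AuditoryConfig = DEFAULT_CONFIG,
    decomposition: Decomposition | None = None,
) -> Waveform:
    """Full sketch of a referent sound at a quality preset.

    The tonal path runs at the auditory-model rate; the noise path runs at
    the input rate to keep broadband character.  The sketched components
    are mixed so their energy ratio matches the referent decomposition's,
    and the overall RMS matches the input's.
    """
    ts, ns = sketch_components(w, quality, seed, tracking, config, decomposition)
    mix = ts.samples + ns.samples
    e_mix = float(np.sum(mix**2))
    e_in = float(np.sum(w.samples**2))
    if e_mix > 0 and e_in > 0:
        mix *= np.sqrt(e_in / e_mix)
    return Waveform(mix, w.rate)


def sketch_components(
    w: Waveform,
    quality: str,
    seed: int = 0,
    tracking: TrackingConfig = TrackingConfig(),
    config: AuditoryConfig = DEFAULT_CONFIG,
    decomposition: Decomposition | None = None,
) -> tuple[Waveform, Waveform]:
    """Gain-adjusted tonal and noise sketch components of a referent.

    Each component is rescaled to the energy of the corresponding referent
    component, so their energy ratio equals the referent's exactly.
    """
    if quality not in _PRESETS:
        raise ValueError(f"unknown quality {quality!r}; expected one of {sorted(_PRESETS)}")
    params = _PRESETS[quality]
    d = decomposition if decomposition is not None else separate(w, tracking)

    e_tonal = float(np.sum(d.tonal.samples**2))
    e_noise = float(np.sum(d.noise.samples**2))

    ts = np.zeros(len(w.samples))
    if e_tonal > 0:
        tonal_lo = resample(d.tonal, config.sample_rate)
        sk = sketch_tonal(tonal_lo, params, seed=seed, config=config)
        sk = resample(sk, w.rate).samples
        ts[: min(len(ts), len(sk))] = sk[: len(ts)]
    ns = np.zeros(len(w.samples))
    if e_noise > 0:
        nsk = sketch_noise(d.noise, params, seed=seed + 1).samples
        ns[: min(len(ns), len(nsk))] = nsk[: len(ns)]

    # restore the referent's tonal/noise energy ratio
    est, esn = float(np.sum(ts**2)), float(np.sum(ns**2))
    if est > 0:
        ts *= np.sqrt(e_tonal / est)
    if esn > 0:
        ns *= np.sqrt(e_noise / esn)
    return Waveform(ts, w.rate), Waveform(ns, w.rate)
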