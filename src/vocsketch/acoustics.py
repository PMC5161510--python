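"""Acoustic distance models: DTW auditory distance and 13-feature distance.

The auditory distance time-stretches both sounds to a common duration
(default 4.6 s), computes their auditory spectrograms, and takes the
dynamic-time-warping alignment cost between the frame sequences.  Costs
are normalized so that the distance between a 4.6-s seeded white noise and
a 4.6-s 1-kHz pure tone equals 1.

The feature distance summarizes each sound by 13 descriptors of its
temporal and spectral evolution, standardizes them over the stimulus set
under analysis, and takes the Euclidean norm of the difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np
from scipy.spatial.distance import cdist

from ._stft import stft
from .auditory_model import AuditoryConfig, auditory_spectrogram
from .decompose import Decomposition
from .signals import Waveform, resample, time_stretch

__all__ = [
    "FeatureVector",
    "Standardizer",
    "DistanceConfig",
    "two_piece_fit",
    "extract_features",
    "feature_distance",
    "auditory_distance",
    "dtw_cost",
]

FEATURE_NAMES = (
    "n_active_regions",
    "absolute_duration",
    "relative_duration",
    "median_noisiness",
    "median_zcr",
    "median_pitch_strength",
    "median_pitch",
    "median_loudness",
    "sd_pitch",
    "sd_spectral_centroid",
    "amp_slope2",
    "specpeak_slope2",
    "amp_fit_r2",
)


@dataclass(frozen=True)
class FeatureVector:
    """The 13 summary features used by the feature distance."""

    n_active_regions: float
    absolute_duration: float  # s of active signal
    relative_duration: float  # active / total, in [0, 1]
    median_noisiness: float  # noise / harmonic energy ratio
    median_zcr: float  # zero crossings per second
    median_pitch_strength: float  # [0, 1]
    median_pitch: float  # Hz
    median_loudness: float  # frame RMS in dB
    sd_pitch: float  # Hz
    sd_spectral_centroid: float  # Hz
    amp_slope2: float  # amplitude envelope, second-piece slope (1/s)
    specpeak_slope2: float  # main spectral peak, second-piece slope (Hz/s)
    amp_fit_r2: float  # goodness of the two-piece amplitude fit, [0, 1]

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)


def two_piece_fit(
    series: np.ndarray, x: np.ndarray | None = None
) -> tuple[float, float, int, float]:
    """Two-piece linear regression with exhaustive breakpoint search.

    Each candidate breakpoint splits the points into [0, b) and [b, n);
    both pieces get independent OLS lines and the breakpoint minimizing the
    total squared error wins (first minimum on ties).  Returns
    (slope1, slope2, breakpoint_index, r2).  A constant series returns
    slopes 0 and r2 = 1.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("two-piece fit needs at least 4 points")
    x = np.arange(n, dtype=float) if x is None else np.asarray(x, dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return 0.0, 0.0, n // 2, 1.0

    def ols(xs, ys):
        xm, ym = xs.mean(), ys.mean()
        den = np.sum((xs - xm) ** 2)
        slope = float(np.sum((xs - xm) * (ys - ym)) / den) if den > 0 else 0.0
        resid = ys - (ym + slope * (xs - xm))
        return slope, float(np.sum(resid**2))

    best = None
    for b in range(2, n - 1):
        s1, e1 = ols(x[:b], y[:b])
        s2, e2 = ols(x[b:], y[b:])
        err = e1 + e2
        if best is None or err < best[0] - 1e-12:
            best = (err, s1, s2, b)
    err, s1, s2, b = best
    r2 = max(0.0, 1.0 - err / sst)
    return s1, s2, b, r2


@dataclass
class _FrameAnalysis:
    times: np.ndarray
    loudness_db: np.ndarray
    amplitude: np.ndarray
    zcr: np.ndarray
    centroid: np.ndarray
    peak_freq: np.ndarray
    pitch: np.ndarray
    strength: np.ndarray
    noisiness: np.ndarray


def _pitch_autocorr(frame: np.ndarray, rate: int, f_lo=70.0, f_hi=1000.0):
    """Autocorrelation pitch with parabolic lag refinement.

    Returns (pitch_hz, strength) with strength the normalized
    autocorrelation peak in [0, 1].
    """
    frame = frame - frame.mean()
    e0 = float(np.dot(frame, frame))
    if e0 <= 0:
        return 0.0, 0.0
    n = len(frame)
    r = np.correlate(frame, frame, mode="full")[n - 1 :]
    lo = max(2, int(rate / f_hi))
    hi = min(n - 2, int(rate / f_lo))
    if hi <= lo:
        return 0.0, 0.0
    seg = r[lo : hi + 1]
    i = int(np.argmax(seg)) + lo
    # parabolic refinement of the lag
    a0, a1, a2 = r[i - 1], r[i], r[i + 1]
    denom = a0 - 2 * a1 + a2
    delta = 0.5 * (a0 - a2) / denom if abs(denom) > 1e-12 else 0.0
    lag = i + float(np.clip(delta, -0.5, 0.5))
    strength = float(np.clip(r[i] / r[0], 0.0, 1.0))
    return rate / lag, strength


def _analyze_frames(
    w: Waveform, d: Decomposition | None, window_s=0.046, overlap=0.75
) -> _FrameAnalysis:
    rate = w.rate
    win = max(16, int(round(window_s * rate)))
    hop = max(1, int(round(win * (1 - overlap))))
    X = np.abs(stft(w.samples, win, hop))
    nf = X.shape[0]
    freqs = np.arange(X.shape[1]) * rate / win
    xp = np.pad(w.samples, (0, (nf - 1) * hop + win - len(w.samples)))

    if d is not None:
        tp = np.pad(d.tonal.samples, (0, max(0, len(xp) - len(d.tonal.samples))))
        np_ = np.pad(d.noise.samples, (0, max(0, len(xp) - len(d.noise.samples))))

    amp = np.empty(nf)
    zcr = np.empty(nf)
    pitch = np.empty(nf)
    strength = np.empty(nf)
    noisiness = np.full(nf, np.nan)
    for t in range(nf):
        seg = xp[t * hop : t * hop + win]
        amp[t] = np.sqrt(np.mean(seg**2))
        zcr[t] = np.sum(np.abs(np.diff(np.signbit(seg)))) / (win / rate)
        pitch[t], strength[t] = _pitch_autocorr(seg, rate)
        if d is not None:
            et = np.sum(tp[t * hop : t * hop + win] ** 2)
            en = np.sum(np_[t * hop : t * hop + win] ** 2)
            noisiness[t] = en / et if et > 0 else np.inf

    loud = 20 * np.log10(np.maximum(amp, 1e-10))
    tot = X.sum(axis=1)
    centroid = np.where(tot > 0, (X * freqs).sum(axis=1) / np.maximum(tot, 1e-12), 0.0)
    peak = freqs[np.argmax(X, axis=1)]
    times = np.arange(nf) * hop / rate
    return _FrameAnalysis(times, loud, amp, zcr, centroid, peak, pitch, strength, noisiness)


def extract_features(
    w: Waveform,
    d: Decomposition | None = None,
    active_threshold_db: float = 40.0,
    pitch_strength_gate: float = 0.2,
) -> FeatureVector:
    """Compute the 13 summary features of a waveform.

    ``d`` supplies the tonal/noise split for the noisiness feature; without
    it noisiness is reported as NaN.  "Active" frames are those within
    ``active_threshold_db`` dB of the loudest frame; medians and SDs are
    taken over active frames only, and pitch statistics over active frames
    whose pitch strength clears ``pitch_strength_gate``.
    """
    fa = _analyze_frames(w, d)
    nf = len(fa.times)
    active = fa.loudness_db > fa.loudness_db.max() - active_threshold_db
    hop_s = fa.times[1] - fa.times[0] if nf > 1 else w.duration

    edges = np.diff(active.astype(int))
    n_regions = int(active[0]) + int(np.sum(edges == 1))
    abs_dur = float(np.sum(active) * hop_s)
    rel_dur = float(np.sum(active) / nf)

    act = np.flatnonzero(active)
    pitched = act[fa.strength[act] > pitch_strength_gate]
    med_pitch = float(np.median(fa.pitch[pitched])) if len(pitched) else 0.0
    sd_pitch = float(np.std(fa.pitch[pitched])) if len(pitched) else 0.0

    nois = fa.noisiness[act]
    nois = nois[np.isfinite(nois)]
    med_nois = float(np.median(nois)) if len(nois) else float("nan")

    amp_s1, amp_s2, _, amp_r2 = two_piece_fit(fa.amplitude, fa.times)
    _, peak_s2, _, _ = two_piece_fit(fa.peak_freq[act], fa.times[act]) if len(act) >= 4 else (
        0.0,
        0.0,
        0,
        1.0,
    )

    return FeatureVector(
        n_active_regions=float(n_regions),
        absolute_duration=abs_dur,
        relative_duration=min(1.0, rel_dur),
        median_noisiness=med_nois,
        median_zcr=float(np.median(fa.zcr[act])),
        median_pitch_strength=float(np.median(fa.strength[act])),
        median_pitch=med_pitch,
        median_loudness=float(np.median(fa.loudness_db[act])),
        sd_pitch=sd_pitch,
        sd_spectral_centroid=float(np.std(fa.centroid[act])),
        amp_slope2=amp_s2,
        specpeak_slope2=peak_s2,
        amp_fit_r2=amp_r2,
    )


@dataclass
class Standardizer:
    """Per-feature mean/SD fitted over a stimulus set.

    Features whose SD is zero (or undefined) over the set are dropped from
    the distance with a warning.
    """

    mean: np.ndarray
    sd: np.ndarray
    valid: np.ndarray  # boolean mask of usable features

    @classmethod
    def fit(cls, vectors: list[FeatureVector]) -> "Standardizer":
        M = np.array([v.as_array() for v in vectors])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(M, axis=0)
            sd = np.nanstd(M, axis=0, ddof=0)
        valid = np.isfinite(sd) & (sd > 0) & np.isfinite(mean)
        if not np.all(valid):
            dropped = [FEATURE_NAMES[i] for i in np.flatnonzero(~valid)]
            warnings.warn(
                f"degenerate features dropped from the distance: {dropped}",
                RuntimeWarning,
            )
        return cls(mean=mean, sd=sd, valid=valid)

    def transform(self, v: FeatureVector) -> np.ndarray:
        a = v.as_array()[self.valid]
        return (a - self.mean[self.valid]) / self.sd[self.valid]


def feature_distance(a: FeatureVector, b: FeatureVector, z: Standardizer) -> float:
    """Euclidean distance between standardized 13-feature vectors."""
    return float(np.linalg.norm(z.transform(a) - z.transform(b)))


def dtw_cost(A: np.ndarray, B: np.ndarray) -> float:
    """Dynamic-time-warping alignment cost between two frame sequences.

    Steps {(1,0), (0,1), (1,1)}, local cost = Euclidean distance between
    frames, no warping window; the cost is the sum of local costs along the
    optimal path (including both endpoints).
    """
    C = cdist(np.atleast_2d(A), np.atleast_2d(B))
    n, m = C.shape
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        Di, Dp = D[i], D[i - 1]
        Ci = C[i - 1]
        for j in range(1, m + 1):
            Di[j] = Ci[j - 1] + min(Dp[j], Di[j - 1], Dp[j - 1])
    return float(D[n, m])


@dataclass(frozen=True)
class DistanceConfig:
    common_duration: float = 4.6  # s; all sounds stretched here first
    normalize: bool = True  # scale by the noise-vs-1kHz-tone reference
    path_normalize: bool = False  # divide DTW cost by path length
    reference_seed: int = 12345
    auditory: AuditoryConfig = field(default_factory=AuditoryConfig)


_REF_CACHE: dict[tuple, float] = {}


def _prepare(w: Waveform, cfg: DistanceConfig) -> np.ndarray:
    w8 = resample(w, cfg.auditory.sample_rate)
    if abs(w8.duration - cfg.common_duration) * cfg.auditory.sample_rate > 1:
        w8 = time_stretch(w8, cfg.common_duration)
    return auditory_spectrogram(w8, cfg.auditory).values


def _reference_cost(cfg: DistanceConfig) -> float:
    key = (cfg.common_duration, cfg.reference_seed, cfg.auditory)
    if key not in _REF_CACHE:
        rate = cfg.auditory.sample_rate
        n = int(round(cfg.common_duration * rate))
        rng = np.random.default_rng(cfg.reference_seed)
        noise = Waveform(0.5 * rng.standard_normal(n) / 3.0, rate)
        t = np.arange(n) / rate
        tone = Waveform(0.5 * np.sin(2 * np.pi * 1000.0 * t), rate)
        A = auditory_spectrogram(noise, cfg.auditory).values
        B = auditory_spectrogram(tone, cfg.auditory).values
        cost = dtw_cost(A, B)
        if cfg.path_normalize:
            cost /= max(A.shape[0], B.shape[0])
        _REF_CACHE[key] = cost
    return _REF_CACHE[key]


def auditory_distance(a: Waveform, b: Waveform, cfg: DistanceConfig = DistanceConfig()) -> float:
    """DTW alignment cost between auditory spectrograms, unit-normalized.

    Both inputs are time-stretched to the common duration so short and
    long sounds land on the same scale; with ``normalize`` a distance of 1
    corresponds to the white-noise / 1-kHz-tone reference pair.
    """
    A = _prepare(a, cfg)
    B = _prepare(b, cfg)
    cost = dtw_cost(A, B)
    if cfg.path_normalize:
        cost /= max(A.shape[0], B.shape[0])
    if cfg.normalize:
        cost /= _reference_cost(cfg)
    return cost
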