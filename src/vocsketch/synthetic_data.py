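"""Synthetic stimuli and observers for end-to-end pipeline testing.

The generators stand in for a recorded corpus: referent-like sounds for
each of the four morphological profiles (impulsive, slow-onset/repeated,
stationary, complex), in tonal and noisy variants; imitation-like
degradations that keep selected features (temporal envelope, pitch track,
spectral trajectory) while replacing the carrier with a voice-like source;
and equal-variance Gaussian yes/no observers with specified sensitivity
and criterion for parameter-recovery studies.

Everything is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import butter, lfilter, sosfilt

from .signals import Waveform, write_wav
from .sketch import make_sketch

__all__ = [
    "CategorySpec",
    "ObserverSpec",
    "CorpusConfig",
    "ImitationFidelity",
    "gen_referent",
    "gen_imitation",
    "gen_corpus",
    "simulate_observer",
    "PROFILES",
]

PROFILES = ("impulsive", "repeated", "stationary", "complex")


@dataclass(frozen=True)
class CategorySpec:
    """Parameters of one synthetic sound category.

    Defaults per profile: impulsive = a single sharp burst (<= 0.5 s,
    ~30-ms decay); repeated = regular bursts with gradual onsets;
    stationary = steady hum or noise; complex = many overlapping
    micro-events with a drifting spectral center.
    """

    profile: str = "stationary"
    tonality: str = "tonal"  # or "noisy"
    seed: int = 0
    rate: int = 16000
    duration: float | None = None  # profile default if None
    fundamental: float = 220.0  # Hz, tonal carriers
    center: float = 1200.0  # Hz, noisy carriers
    burst_rate: float = 3.0  # bursts/s, repeated profile
    n_bursts: int = 4
    decay: float = 0.03  # s, impulsive decay constant
    event_density: float = 8.0  # events/s, complex profile
    spectral_drift: float = 800.0  # Hz over the duration, complex profile

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.tonality not in ("tonal", "noisy"):
            raise ValueError(f"tonality must be 'tonal' or 'noisy'")
        if self.duration is not None and self.duration <= 0:
            raise ValueError("duration must be positive")


_DEFAULT_DURATIONS = {
    "impulsive": 0.5,
    "repeated": 2.0,
    "stationary": 2.0,
    "complex": 2.5,
}


def _harmonic(t: np.ndarray, f0: float, rate: int, n_partials: int = 6) -> np.ndarray:
    """Harmonic complex with 1/k amplitude rolloff, band-limited."""
    out = np.zeros_like(t)
    for k in range(1, n_partials + 1):
        f = k * f0
        if f < rate / 2 * 0.9:
            out += np.sin(2 * np.pi * f * t + 0.7 * k) / k
    return out / np.max(np.abs(out))


def _bandnoise(n: int, center: float, rate: int, rng, rel_bw: float = 0.5) -> np.ndarray:
    lo = max(30.0, center * (1 - rel_bw / 2))
    hi = min(rate / 2 * 0.95, center * (1 + rel_bw / 2))
    sos = butter(4, [lo, hi], btype="band", fs=rate, output="sos")
    x = sosfilt(sos, rng.standard_normal(n))
    peak = np.max(np.abs(x))
    return x / peak if peak > 0 else x


def _carrier(spec: CategorySpec, t: np.ndarray, rng) -> np.ndarray:
    if spec.tonality == "tonal":
        return _harmonic(t, spec.fundamental, spec.rate)
    return _bandnoise(len(t), spec.center, spec.rate, rng)


def _burst_envelope(t: np.ndarray, onset: float, attack: float, decay: float) -> np.ndarray:
    """Gradual attack then exponential decay, zero before onset."""
    tt = t - onset
    env = np.where(tt >= 0, np.minimum(tt / max(attack, 1e-4), 1.0) * np.exp(-np.maximum(tt - attack, 0) / decay), 0.0)
    return env


def gen_referent(spec: CategorySpec) -> Waveform:
    """Synthesize one referent-like sound for a category."""
    rng = np.random.default_rng(spec.seed)
    dur = spec.duration if spec.duration is not None else _DEFAULT_DURATIONS[spec.profile]
    n = int(round(dur * spec.rate))
    t = np.arange(n) / spec.rate

    if spec.profile == "impulsive":
        if dur > 0.5:
            raise ValueError("impulsive referents must be at most 0.5 s")
        env = np.exp(-t / spec.decay)
        x = _carrier(spec, t, rng) * env
    elif spec.profile == "repeated":
        period = 1.0 / spec.burst_rate
        n_bursts = max(3, spec.n_bursts)
        if n_bursts * period > dur + 1e-9:
            raise ValueError("burst count and rate do not fit the duration")
        env = np.zeros(n)
        # attack/decay scale with the period so inter-burst gaps are silent
        attack = min(0.06, period / 6)
        decay = min(0.05, period / 12)
        for k in range(n_bursts):
            env += _burst_envelope(t, k * period, attack=attack, decay=decay)
        x = _carrier(spec, t, rng) * env
    elif spec.profile == "stationary":
        am = 1.0 + 0.05 * np.sin(2 * np.pi * 1.3 * t)  # faint slow ripple
        x = _carrier(spec, t, rng) * am
        fade = min(n // 20, int(0.02 * spec.rate))
        if fade > 0:
            ramp = np.linspace(0, 1, fade)
            x[:fade] *= ramp
            x[-fade:] *= ramp[::-1]
    else:  # complex
        n_events = max(10, int(round(spec.event_density * dur)))
        x = np.zeros(n)
        onsets = np.sort(rng.uniform(0, dur * 0.9, size=n_events))
        for i, onset in enumerate(onsets):
            frac = onset / dur
            ev_dur = rng.uniform(0.08, 0.3)
            m = int(ev_dur * spec.rate)
            tt = np.arange(m) / spec.rate
            env = _burst_envelope(tt, 0.0, attack=0.02, decay=ev_dur / 3)
            center = spec.center + spec.spectral_drift * frac
            if spec.tonality == "tonal":
                f0 = spec.fundamental * (1.0 + 1.5 * frac) * rng.uniform(0.95, 1.05)
                ev = _harmonic(tt, f0, spec.rate, n_partials=4) * env
            else:
                ev = _bandnoise(m, center * rng.uniform(0.9, 1.1), spec.rate, rng) * env
            j = int(onset * spec.rate)
            seg = min(m, n - j)
            x[j : j + seg] += ev[:seg] * rng.uniform(0.5, 1.0)

    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.7 * x / peak
    return Waveform(x, spec.rate)


@dataclass(frozen=True)
class ImitationFidelity:
    """How faithfully an imitation preserves each referent feature.

    1.0 = preserved exactly, 0.0 = ignored (replaced by a flat default).
    Intermediate values add seeded jitter to the preserved trajectory.
    """

    envelope: float = 1.0
    pitch: float = 1.0
    spectral: float = 1.0


def _frame_track(x: np.ndarray, rate: int, hop_s: float = 0.01):
    hop = max(1, int(hop_s * rate))
    nf = max(1, len(x) // hop)
    rms = np.array([np.sqrt(np.mean(x[i * hop : i * hop + hop] ** 2)) for i in range(nf)])
    return rms, hop


def _jitter(track: np.ndarray, fidelity: float, rng, rel: float = 0.5) -> np.ndarray:
    """Blend a track toward its mean and add noise as fidelity drops."""
    if fidelity >= 1.0:
        return track
    flat = np.full_like(track, track.mean())
    mixed = fidelity * track + (1 - fidelity) * flat
    noise = rng.standard_normal(len(track)) * (1 - fidelity) * rel * (np.abs(track).mean() + 1e-12)
    out = mixed + noise
    return np.maximum(out, 0.0) if np.all(track >= 0) else out


def gen_imitation(
    referent: Waveform,
    fidelity: ImitationFidelity = ImitationFidelity(),
    seed: int = 0,
    voice_f0: float = 140.0,
) -> Waveform:
    """Feature-selective vocal-like rendering of a referent.

    Not a vocal-tract model: the referent's temporal envelope, pitch
    contour, and spectral-center trajectory are measured and re-imposed
    (with jitter controlled by the fidelity knobs) on a voice-like carrier
    — a pulse train for tonal referents, filtered noise otherwise.
    """
    from .acoustics import _pitch_autocorr  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    rate = referent.rate
    x = referent.samples
    env, hop = _frame_track(x, rate)
    n = len(x)

    # measure per-frame pitch and pitch strength on the referent
    win = max(2 * hop, int(0.03 * rate))
    nf = len(env)
    pitch = np.zeros(nf)
    strength = np.zeros(nf)
    for i in range(nf):
        seg = x[i * hop : i * hop + win]
        if len(seg) >= 32 and np.any(seg):
            pitch[i], strength[i] = _pitch_autocorr(seg, rate)
    tonal = float(np.median(strength[env > 0.1 * env.max()])) > 0.4 if np.any(env > 0) else False

    env_used = _jitter(env, fidelity.envelope, rng)
    if tonal:
        p = np.where(strength > 0.2, pitch, voice_f0)
        p_used = _jitter(p, fidelity.pitch, rng, rel=0.2)
        p_used = np.clip(p_used, 60.0, 2000.0)
        inst = np.repeat(p_used, hop)[:n]
        phase = np.cumsum(2 * np.pi * inst / rate)
        # soft pulse train: a few harmonics of the (time-varying) pitch
        carrier = sum(np.sin(k * phase) / k for k in range(1, 5))
    else:
        centroid = _spectral_track(x, rate, hop)
        c_used = np.clip(_jitter(centroid, fidelity.spectral, rng, rel=0.3), 100.0, rate / 2 * 0.8)
        carrier = _tv_bandnoise(n, c_used, hop, rate, rng)

    gain = np.repeat(env_used, hop)[:n]
    if len(gain) < n:
        gain = np.pad(gain, (0, n - len(gain)))
    y = carrier[:n] * gain
    peak = np.max(np.abs(y))
    if peak > 0:
        y = 0.7 * y / peak
    return Waveform(y, rate)


def _spectral_track(x: np.ndarray, rate: int, hop: int) -> np.ndarray:
    from ._stft import stft

    win = 4 * hop
    X = np.abs(stft(x, win, hop))
    freqs = np.arange(X.shape[1]) * rate / win
    tot = X.sum(axis=1)
    return np.where(tot > 0, (X * freqs).sum(axis=1) / np.maximum(tot, 1e-12), 500.0)


def _tv_bandnoise(n: int, centers: np.ndarray, hop: int, rate: int, rng) -> np.ndarray:
    out = np.zeros(n)
    white = rng.standard_normal(n)
    for i, c in enumerate(centers):
        lo, hi = i * hop, min((i + 1) * hop, n)
        if lo >= n:
            break
        b, a = butter(2, [max(50.0, c * 0.7), min(rate / 2 * 0.95, c * 1.3)], btype="band", fs=rate)
        seg = lfilter(b, a, white[max(0, lo - 4 * hop) : hi])
        out[lo:hi] = seg[-(hi - lo) :]
    peak = np.max(np.abs(out))
    return out / peak if peak > 0 else out


@dataclass(frozen=True)
class CorpusConfig:
    """Shape of a synthetic corpus.

    The full-scale default mirrors a two-family, four-profile design with
    target and distractor categories, two exemplars per category (32
    referents), ten imitators, and three sketch qualities (so 320
    imitations and 96 sketches).
    """

    families: tuple[str, ...] = ("product", "interaction")
    profiles: tuple[str, ...] = PROFILES
    roles: tuple[str, ...] = ("target", "distractor")
    n_exemplars: int = 2
    n_imitators: int = 10
    qualities: tuple[str, ...] = ("Q1", "Q2", "Q3")
    rate: int = 16000


def _category_specs(config: CorpusConfig, seed: int):
    """One CategorySpec per (family, profile, role); tonality alternates."""
    specs = []
    i = 0
    for fam in config.families:
        for prof in config.profiles:
            for role in config.roles:
                tonality = "tonal" if i % 2 == 0 else "noisy"
                specs.append(
                    (
                        fam,
                        prof,
                        role,
                        CategorySpec(
                            profile=prof,
                            tonality=tonality,
                            rate=config.rate,
                            seed=seed * 100003 + i,
                            fundamental=180.0 + 60.0 * (i % 5),
                            center=700.0 + 300.0 * (i % 4),
                        ),
                    )
                )
                i += 1
    return specs


def gen_corpus(
    config: CorpusConfig = CorpusConfig(),
    seed: int = 0,
    outdir: str | Path | None = None,
    materialize: bool = True,
) -> tuple[pd.DataFrame, dict[str, Waveform]]:
    """Generate a corpus manifest and (optionally) its audio.

    Returns ``(manifest, sounds)``; with ``materialize=False`` only the
    manifest is built (audio synthesis — especially the sketches — is by
    far the expensive part).  With ``outdir`` set, WAVs are written there.
    """
    rows = []
    sounds: dict[str, Waveform] = {}
    rng = np.random.default_rng(seed)
    for fam, prof, role, spec in _category_specs(config, seed):
        for ex in range(1, config.n_exemplars + 1):
            ref_id = f"ref_{fam}_{prof}_{role}_{ex}"
            ref_spec = replace(spec, seed=spec.seed + 7 * ex, fundamental=spec.fundamental * (1 + 0.08 * (ex - 1)))
            base = {
                "family": fam,
                "profile": prof,
                "category": role,
                "tonality": spec.tonality,
                "exemplar": ex,
            }
            rows.append({"file": f"{ref_id}.wav", "role": "referent", **base, "quality": "", "imitator": "", "seed": ref_spec.seed})
            ref = gen_referent(ref_spec) if materialize else None
            if ref is not None:
                sounds[ref_id] = ref
            for im in range(1, config.n_imitators + 1):
                im_seed = int(rng.integers(0, 2**31 - 1))
                rows.append({"file": f"imit_{fam}_{prof}_{role}_{ex}_I{im:02d}.wav", "role": "imitation", **base, "quality": "", "imitator": f"I{im:02d}", "seed": im_seed})
                if materialize:
                    fid = ImitationFidelity(
                        envelope=float(np.clip(rng.uniform(0.6, 1.0), 0, 1)),
                        pitch=float(np.clip(rng.uniform(0.5, 1.0), 0, 1)),
                        spectral=float(np.clip(rng.uniform(0.5, 1.0), 0, 1)),
                    )
                    sounds[f"imit_{fam}_{prof}_{role}_{ex}_I{im:02d}"] = gen_imitation(ref, fid, seed=im_seed)
            for q in config.qualities:
                sk_seed = int(rng.integers(0, 2**31 - 1))
                rows.append({"file": f"sketch_{fam}_{prof}_{role}_{ex}_{q}.wav", "role": "sketch", **base, "quality": q, "imitator": "", "seed": sk_seed})
                if materialize:
                    sounds[f"sketch_{fam}_{prof}_{role}_{ex}_{q}"] = make_sketch(ref, q, seed=sk_seed)
    manifest = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for key, wv in sounds.items():
            write_wav(outdir / f"{key}.wav", wv)
        manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest, sounds


@dataclass(frozen=True)
class ObserverSpec:
    """Equal-variance Gaussian yes/no observer.

    ``dprime`` may be a scalar or a {(type_of_sound, profile): d'} mapping;
    ``criterion`` is the distance of the decision criterion from the
    midpoint between the two distributions (positive = conservative).
    """

    dprime: float | dict = 1.0
    criterion: float = 0.0
    seed: int = 0

    def dprime_for(self, type_of_sound: str, profile: str) -> float:
        if isinstance(self.dprime, dict):
            return float(self.dprime[(type_of_sound, profile)])
        return float(self.dprime)


def simulate_observer(trials: pd.DataFrame, obs: ObserverSpec = ObserverSpec()) -> np.ndarray:
    """Simulate yes/no responses for every row of a trial table.

    P(yes) = Phi(d'/2 - c) on target trials and Phi(-d'/2 - c) on
    distractor trials.
    """
    rng = np.random.default_rng(obs.seed)
    d = np.array([obs.dprime_for(ty, pr) for ty, pr in zip(trials["type_of_sound"], trials["profile"])])
    sign = np.where(trials["category"].to_numpy() == "target", 1.0, -1.0)
    p_yes = stats.norm.cdf(sign * d / 2.0 - obs.criterion)
    return rng.random(len(trials)) < p_yes
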