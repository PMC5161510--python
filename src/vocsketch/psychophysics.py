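"""Yes/no identification experiment: design, simulation-ready trial tables,
and signal-detection statistics.

Sensitivity and bias are computed per 12-trial cell (one morphological
profile x one type of sound: 6 target and 6 distractor trials).  Perfect
scores are handled with the log-linear correction — 0.5 added to hit and
false-alarm counts, 1 to the trial counts — under which perfect
discrimination of a 6/6 cell maps to d' = 2.93.

Sign convention for the bias: ln(beta) is positive for a liberal
("yes"-prone) observer and negative for a conservative one.  Note this is
the *negative* of the textbook Gaussian likelihood-ratio log-beta, which
is negative at liberal criteria; the sign is flipped here to follow the
convention used in the identification analysis this module supports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExperimentDesign",
    "ResponseCounts",
    "SDTResult",
    "build_trial_table",
    "dprime_yesno",
    "ln_beta",
    "unbiased_pc",
    "pearson_critical_r",
    "correlate",
    "paired_ttest",
    "analyze_responses",
    "PROFILES",
    "SKETCH_QUALITIES",
    "BONFERRONI_ALPHA",
]

PROFILES = ("impulsive", "repeated", "stationary", "complex")
SKETCH_QUALITIES = ("Q1", "Q2", "Q3")
LEVEL_OFFSETS_DB = (0, -5, -10)

#: family-wise alpha for the four planned best-imitator comparisons
BONFERRONI_ALPHA = 0.05 / 4


@dataclass(frozen=True)
class ExperimentDesign:
    """One participant's yes/no session.

    Five blocks: the ten imitators in one block, one block per sketch
    quality (Q1, Q2, Q3 in that order), referent sounds always last.  Each
    (profile, type of sound) cell holds 12 trials: {2 target + 2
    distractor exemplars} x 3 repetitions, the repetitions played at 0, -5
    and -10 dB relative to baseline.
    """

    family: str = "product"
    profiles: tuple[str, ...] = PROFILES
    n_imitators: int = 10
    n_exemplars: int = 2
    repetitions: int = 3
    level_offsets: tuple[int, ...] = LEVEL_OFFSETS_DB
    imitations_first: bool = True

    @property
    def types_of_sound(self) -> list[str]:
        return (
            [f"I{i + 1:02d}" for i in range(self.n_imitators)]
            + list(SKETCH_QUALITIES)
            + ["referent"]
        )

    @property
    def blocks(self) -> list[list[str]]:
        imit = [f"I{i + 1:02d}" for i in range(self.n_imitators)]
        sketches = [[q] for q in SKETCH_QUALITIES]
        if self.imitations_first:
            order = [imit, *sketches]
        else:
            order = [*sketches, imit]
        return order + [["referent"]]

    @property
    def n_trials(self) -> int:
        per_cell = 2 * self.n_exemplars * self.repetitions
        return per_cell * len(self.profiles) * len(self.types_of_sound)


def build_trial_table(design: ExperimentDesign = ExperimentDesign(), seed: int = 0) -> pd.DataFrame:
    """Expand a design into a randomized per-participant trial table.

    Rows carry block index, type of sound, profile, category
    (target/distractor), exemplar, repetition, level offset and a global
    presentation index.  Order is shuffled within each block; the referent
    block stays last.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for b, types in enumerate(design.blocks):
        block_rows = []
        for ty in types:
            for prof in design.profiles:
                for cat in ("target", "distractor"):
                    for ex in range(1, design.n_exemplars + 1):
                        for rep, lvl in enumerate(design.level_offsets[: design.repetitions], 1):
                            block_rows.append(
                                {
                                    "block": b,
                                    "type_of_sound": ty,
                                    "profile": prof,
                                    "category": cat,
                                    "exemplar": ex,
                                    "repetition": rep,
                                    "level_offset_db": lvl,
                                }
                            )
        order = rng.permutation(len(block_rows))
        rows.extend(block_rows[i] for i in order)
    df = pd.DataFrame(rows)
    df["presentation"] = np.arange(len(df))
    return df


@dataclass(frozen=True)
class ResponseCounts:
    """Yes/no tallies of one analysis cell."""

    n_hit: int
    n_signal: int
    n_fa: int
    n_noise: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_hit <= self.n_signal):
            raise ValueError("need 0 <= n_hit <= n_signal")
        if not (0 <= self.n_fa <= self.n_noise):
            raise ValueError("need 0 <= n_fa <= n_noise")
        if self.n_signal < 1 or self.n_noise < 1:
            raise ValueError("need at least one signal and one noise trial")


@dataclass(frozen=True)
class SDTResult:
    dprime: float
    ln_beta: float
    upc: float  # unbiased percent correct, in (0, 100)


def _corrected_rates(c: ResponseCounts) -> tuple[float, float]:
    h = (c.n_hit + 0.5) / (c.n_signal + 1.0)
    f = (c.n_fa + 0.5) / (c.n_noise + 1.0)
    return h, f


def dprime_yesno(c: ResponseCounts) -> float:
    """Sensitivity d' with the log-linear correction.

    d' = z(H) - z(F) on corrected rates; a perfect 6-hit / 0-false-alarm
    cell yields 2.93 rather than infinity.
    """
    h, f = _corrected_rates(c)
    return float(stats.norm.ppf(h) - stats.norm.ppf(f))


def ln_beta(c: ResponseCounts) -> float:
    """Response bias ln(beta), positive = liberal (see module docstring)."""
    h, f = _corrected_rates(c)
    zh, zf = stats.norm.ppf(h), stats.norm.ppf(f)
    return float((zh**2 - zf**2) / 2.0)


def unbiased_pc(dprime: float) -> float:
    """Percent correct implied by d' at a symmetric (no-bias) criterion.

    With false alarms = 1 - hit rate, d' = 2 z(H), so upc = 100 Phi(d'/2).
    """
    return float(100.0 * stats.norm.cdf(dprime / 2.0))


def pearson_critical_r(n: int, alpha: float = 0.05) -> float:
    """Two-tailed critical |r| for a Pearson correlation with n points."""
    if n < 3:
        raise ValueError("need n >= 3")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n - 2
    t = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t / np.sqrt(df + t**2))


def correlate(x, y) -> tuple[float, float]:
    """Pearson r with its two-tailed t-based p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def paired_ttest(x, y) -> tuple[float, int, float]:
    """Paired t-test; returns (t, df, two-tailed p)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    d = x - y
    if np.std(d, ddof=1) == 0:
        return 0.0 if d.mean() == 0 else np.inf, len(x) - 1, 1.0 if d.mean() == 0 else 0.0
    res = stats.ttest_rel(x, y)
    return float(res.statistic), len(x) - 1, float(res.pvalue)


def analyze_responses(trials: pd.DataFrame, responses) -> pd.DataFrame:
    """Tally yes/no responses and compute SDT statistics per cell.

    ``responses`` is a boolean sequence (or Series aligned on the trial
    index; NaN = missing) with one "yes" judgment per trial.  Cells are
    (participant if present, type_of_sound, profile); target-trial yeses
    count as hits, distractor-trial yeses as false alarms.  Cells with
    missing responses are kept and flagged via ``n_missing``.
    """
    df = trials.copy()
    resp = pd.Series(responses, index=df.index, dtype="object")
    df["_yes"] = resp
    keys = [k for k in ("participant", "type_of_sound", "profile") if k in df.columns]
    out = []
    for key, cell in df.groupby(keys, sort=False):
        tgt = cell[cell["category"] == "target"]["_yes"]
        dis = cell[cell["category"] == "distractor"]["_yes"]
        n_missing = int(tgt.isna().sum() + dis.isna().sum())
        c = ResponseCounts(
            n_hit=int(sum(bool(v) for v in tgt if pd.notna(v))),
            n_signal=int(tgt.notna().sum()) or 1,
            n_fa=int(sum(bool(v) for v in dis if pd.notna(v))),
            n_noise=int(dis.notna().sum()) or 1,
        )
        d = dprime_yesno(c)
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rec.update(
            n_hit=c.n_hit,
            n_signal=c.n_signal,
            n_fa=c.n_fa,
            n_noise=c.n_noise,
            n_missing=n_missing,
            dprime=d,
            ln_beta=ln_beta(c),
            upc=unbiased_pc(d),
        )
        out.append(rec)
    return pd.DataFrame(out)
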