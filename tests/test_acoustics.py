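import itertools
import warnings

import numpy as np
import pytest

from vocsketch.acoustics import (
    FEATURE_NAMES,
    DistanceConfig,
    FeatureVector,
    Standardizer,
    auditory_distance,
    dtw_cost,
    extract_features,
    feature_distance,
    two_piece_fit,
)
from vocsketch.decompose import separate
from vocsketch.signals import Waveform


def brute_force_dtw(C: np.ndarray) -> float:
    """Exhaustive enumeration of monotone warping paths on a tiny grid."""
    n, m = C.shape
    best = [np.inf]

    def walk(i, j, cost):
        cost += C[i, j]
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            if i + di < n and j + dj < m:
                walk(i + di, j + dj, cost)

    walk(0, 0, 0.0)
    return best[0]


def random_feature_vector(rng) -> FeatureVector:
    return FeatureVector(*rng.uniform(0.1, 5.0, size=13))


class TestTwoPieceFit:
    def test_exact_piecewise_input(self):
        x = np.arange(20.0)
        y = np.where(x < 10, 5.0, 5.0 - 2 * (x - 10))
        s1, s2, b, r2 = two_piece_fit(y)
        assert s2 == pytest.approx(-2.0)
        assert r2 == pytest.approx(1.0)

    def test_straight_line_gives_equal_slopes(self):
        s1, s2, _, r2 = two_piece_fit(3.0 * np.arange(15.0))
        assert s1 == pytest.approx(3.0)
        assert s2 == pytest.approx(3.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_series_perfect_fit(self):
        s1, s2, _, r2 = two_piece_fit(np.full(10, 2.5))
        assert (s1, s2, r2) == (0.0, 0.0, 1.0)

    def test_breakpoint_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(6)
        x = np.arange(30.0)
        y = np.where(x < 17, 0.3 * x, 0.3 * 17 - 1.5 * (x - 17)) + 0.3 * rng.standard_normal(30)
        _, _, b, _ = two_piece_fit(y)

        # independent oracle: polyfit-based exhaustive breakpoint search
        def sse(xs, ys):
            if np.ptp(xs) == 0:
                return float(np.sum((ys - ys.mean()) ** 2))
            c = np.polyfit(xs, ys, 1)
            return float(np.sum((ys - np.polyval(c, xs)) ** 2))

        errs = {bb: sse(x[:bb], y[:bb]) + sse(x[bb:], y[bb:]) for bb in range(2, 29)}
        assert b == min(errs, key=errs.get)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            two_piece_fit(np.array([1.0, 2.0, 3.0]))


class TestExtractFeatures:
    def test_unbroken_tone(self, tone):
        w = tone(440, duration=1.0, rate=16000)
        fv = extract_features(w, separate(w))
        assert fv.n_active_regions == 1
        assert fv.relative_duration > 0.95
        assert abs(fv.median_pitch - 440) / 440 < 0.02
        assert fv.median_pitch_strength > 0.5
        assert fv.median_noisiness < 0.1

    def test_two_bursts(self):
        rate = 16000
        sig = np.zeros(int(0.9 * rate))
        burst = 0.5 * np.sin(2 * np.pi * 600 * np.arange(int(0.2 * rate)) / rate)
        sig[: len(burst)] = burst
        sig[int(0.7 * rate) : int(0.7 * rate) + len(burst)] = burst
        fv = extract_features(Waveform(sig, rate))
        assert fv.n_active_regions == 2
        assert abs(fv.absolute_duration - 0.4) < 0.1

    def test_has_exactly_13_features(self):
        assert len(FEATURE_NAMES) == 13
        rng = np.random.default_rng(0)
        assert len(random_feature_vector(rng).as_array()) == 13


class TestFeatureDistance:
    def test_zero_on_identical_vectors(self):
        rng = np.random.default_rng(1)
        vs = [random_feature_vector(rng) for _ in range(6)]
        z = Standardizer.fit(vs)
        assert feature_distance(vs[0], vs[0], z) == 0.0

    def test_one_sd_difference_in_one_feature_is_unit_distance(self):
        rng = np.random.default_rng(2)
        vs = [random_feature_vector(rng) for _ in range(8)]
        z = Standardizer.fit(vs)
        a = vs[0].as_array()
        b = a.copy()
        b[4] += z.sd[4]
        fa = FeatureVector(*a)
        fb = FeatureVector(*b)
        assert feature_distance(fa, fb, z) == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        vs = [random_feature_vector(rng) for _ in range(10)]
        z = Standardizer.fit(vs)
        for a, b in itertools.combinations(vs[:5], 2):
            za = (a.as_array() - z.mean) / z.sd
            zb = (b.as_array() - z.mean) / z.sd
            assert feature_distance(a, b, z) == pytest.approx(np.sqrt(np.sum((za - zb) ** 2)))

    def test_triangle_inequality(self):
        rng = np.random.default_rng(4)
        vs = [random_feature_vector(rng) for _ in range(12)]
        z = Standardizer.fit(vs)
        for a, b, c in itertools.combinations(vs[:6], 3):
            assert feature_distance(a, c, z) <= (
                feature_distance(a, b, z) + feature_distance(b, c, z) + 1e-12
            )

    def test_degenerate_feature_dropped_with_warning(self):
        rng = np.random.default_rng(5)
        vs = [random_feature_vector(rng) for _ in range(6)]
        frozen = [FeatureVector(*np.where(np.arange(13) == 2, 1.0, v.as_array())) for v in vs]
        with pytest.warns(RuntimeWarning, match="dropped"):
            z = Standardizer.fit(frozen)
        assert not z.valid[2]
        assert feature_distance(frozen[0], frozen[1], z) >= 0.0


class TestDTW:
    def test_matches_brute_force_on_toy_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            A = rng.uniform(0, 1, size=(rng.integers(2, 5), 3))
            B = rng.uniform(0, 1, size=(rng.integers(2, 5), 3))
            from scipy.spatial.distance import cdist

            C = cdist(A, B)
            assert dtw_cost(A, B) == pytest.approx(brute_force_dtw(C))

    def test_zero_on_identical_sequences(self):
        A = np.random.default_rng(8).uniform(0, 1, size=(10, 4))
        assert dtw_cost(A, A) == pytest.approx(0.0)


class TestAuditoryDistance:
    def test_self_distance_zero(self, tone):
        w = tone(440, duration=2.0, rate=8000)
        assert auditory_distance(w, w) == pytest.approx(0.0, abs=1e-9)

    def test_reference_pair_defines_the_unit(self):
        cfg = DistanceConfig()
        rate = cfg.auditory.sample_rate
        n = int(round(cfg.common_duration * rate))
        rng = np.random.default_rng(cfg.reference_seed)
        noise = Waveform(0.5 * rng.standard_normal(n) / 3.0, rate)
        t = np.arange(n) / rate
        tone1k = Waveform(0.5 * np.sin(2 * np.pi * 1000.0 * t), rate)
        assert auditory_distance(noise, tone1k, cfg) == pytest.approx(1.0)

    def test_symmetric_and_nonnegative(self, tone, noise):
        a = tone(300, duration=1.5, rate=8000)
        b = noise(duration=2.0, rate=8000, seed=11)
        dab = auditory_distance(a, b)
        dba = auditory_distance(b, a)
        assert dab >= 0
        assert dab == pytest.approx(dba, rel=1e-6)


def test_two_distance_models_positively_correlated():
    """The DTW auditory distance and the 13-feature distance agree in
    direction across a synthetic corpus spanning all four profiles."""
    from vocsketch.experiments import distance_correlation

    r, n = distance_correlation(seed=50)
    assert n >= 28
    assert r > 0
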