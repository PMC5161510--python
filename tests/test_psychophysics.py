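import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from vocsketch.psychophysics import (
    ExperimentDesign,
    ResponseCounts,
    analyze_responses,
    build_trial_table,
    correlate,
    dprime_yesno,
    ln_beta,
    paired_ttest,
    pearson_critical_r,
    unbiased_pc,
)


class TestDPrime:
    def test_perfect_discrimination_anchor(self):
        assert dprime_yesno(ResponseCounts(6, 6, 0, 6)) == pytest.approx(2.93, abs=0.01)

    def test_chance_performance_is_zero(self):
        assert dprime_yesno(ResponseCounts(3, 6, 3, 6)) == pytest.approx(0.0)

    def test_corrected_quantile_oracle(self):
        # corrected rates 5.5/7 and 1.5/7 through the normal quantile
        expected = stats.norm.ppf(5.5 / 7) - stats.norm.ppf(1.5 / 7)
        assert dprime_yesno(ResponseCounts(5, 6, 1, 6)) == pytest.approx(expected)
        assert expected == pytest.approx(1.58, abs=0.01)

    def test_antisymmetric_under_hit_fa_swap(self):
        for h, f in [(6, 0), (5, 2), (4, 1)]:
            a = dprime_yesno(ResponseCounts(h, 6, f, 6))
            b = dprime_yesno(ResponseCounts(f, 6, h, 6))
            assert a == pytest.approx(-b)

    def test_monotone_in_hits(self):
        ds = [dprime_yesno(ResponseCounts(h, 6, 2, 6)) for h in range(7)]
        assert np.all(np.diff(ds) > 0)

    def test_bounded_by_perfect_score(self):
        bound = dprime_yesno(ResponseCounts(6, 6, 0, 6))
        for h in range(7):
            for f in range(7):
                assert abs(dprime_yesno(ResponseCounts(h, 6, f, 6))) <= bound + 1e-12

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            ResponseCounts(7, 6, 0, 6)

    @settings(derandomize=True, max_examples=50)
    @given(h=st.integers(0, 6), f=st.integers(0, 6))
    def test_antisymmetry_and_bounds_hold_for_all_counts(self, h, f):
        d = dprime_yesno(ResponseCounts(h, 6, f, 6))
        assert d == pytest.approx(-dprime_yesno(ResponseCounts(f, 6, h, 6)))
        assert abs(d) <= dprime_yesno(ResponseCounts(6, 6, 0, 6)) + 1e-12
        # upc is a strictly monotone transform of d'
        assert 0.0 < unbiased_pc(d) < 100.0

    @settings(derandomize=True, max_examples=50)
    @given(
        h=st.integers(0, 6),
        f=st.integers(0, 6),
        swap=st.booleans(),
    )
    def test_ln_beta_sign_follows_total_yes_rate(self, h, f, swap):
        if swap:
            h, f = f, h
        lb = ln_beta(ResponseCounts(h, 6, f, 6))
        hr, fr = (h + 0.5) / 7, (f + 0.5) / 7
        zh, zf = stats.norm.ppf(hr), stats.norm.ppf(fr)
        # positive iff z(H) + z(F) and d' share a sign (liberal at d' > 0)
        expected_sign = np.sign((zh + zf) * (zh - zf))
        assert np.sign(lb) == pytest.approx(expected_sign)


class TestLnBeta:
    def test_symmetric_criterion_is_unbiased(self):
        # H = 1 - F on corrected rates: 4/6 hits vs 2/6 false alarms
        assert ln_beta(ResponseCounts(4, 6, 2, 6)) == pytest.approx(0.0)

    def test_liberal_responding_is_positive(self):
        assert ln_beta(ResponseCounts(6, 6, 4, 6)) > 0

    def test_matches_gaussian_likelihood_ratio_oracle(self):
        # numerical SDT oracle: the likelihood ratio of the signal and
        # noise densities at the implied criterion, sign-flipped to the
        # liberal-positive convention
        for h, f in [(5, 1), (6, 2), (2, 4), (3, 1)]:
            c = ResponseCounts(h, 6, f, 6)
            hr = (h + 0.5) / 7
            fr = (f + 0.5) / 7
            d = stats.norm.ppf(hr) - stats.norm.ppf(fr)
            k = -stats.norm.ppf(fr)  # criterion on the noise distribution
            lr = np.log(stats.norm.pdf(k - d) / stats.norm.pdf(k))
            assert ln_beta(c) == pytest.approx(-lr)


class TestUnbiasedPC:
    def test_chance_is_50_percent(self):
        assert unbiased_pc(0.0) == pytest.approx(50.0)

    def test_perfect_cell_value(self):
        d = dprime_yesno(ResponseCounts(6, 6, 0, 6))
        assert unbiased_pc(d) == pytest.approx(92.9, abs=0.1)

    def test_strictly_increasing(self):
        ds = np.linspace(-3, 3, 25)
        assert np.all(np.diff([unbiased_pc(d) for d in ds]) > 0)


class TestCriticalR:
    def test_n14_thresholds(self):
        assert pearson_critical_r(14, 0.05) == pytest.approx(0.53, abs=0.005)
        assert pearson_critical_r(14, 0.01) == pytest.approx(0.66, abs=0.005)

    def test_vanishes_for_large_n(self):
        assert pearson_critical_r(100000, 0.05) < 0.01

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            pearson_critical_r(2, 0.05)


class TestCorrelationAndTTest:
    def test_identity_gives_r_of_one(self):
        x = np.arange(10.0)
        r, p = correlate(x, x)
        assert r == pytest.approx(1.0)

    def test_paired_t_zero_on_identical_vectors(self):
        x = np.arange(10.0)
        t, df, p = paired_ttest(x, x)
        assert t == 0.0
        assert df == 9

    def test_matches_direct_formulas_on_random_vectors(self):
        rng = np.random.default_rng(9)
        x, y = rng.standard_normal(10), rng.standard_normal(10)
        r, _ = correlate(x, y)
        rr = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(rr)
        t, df, _ = paired_ttest(x, y)
        d = x - y
        tt = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert t == pytest.approx(tt)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            correlate(np.ones(5), np.arange(5.0))


class TestTrialTable:
    def test_total_trial_count(self):
        assert len(build_trial_table(ExperimentDesign(), seed=0)) == 672

    def test_twelve_trials_per_cell_six_six_split(self):
        tbl = build_trial_table(ExperimentDesign(), seed=1)
        cells = tbl.groupby(["profile", "type_of_sound"])
        assert (cells.size() == 12).all()
        targets = tbl[tbl.category == "target"].groupby(["profile", "type_of_sound"]).size()
        assert (targets == 6).all()

    def test_each_exemplar_gets_every_level_once(self):
        tbl = build_trial_table(ExperimentDesign(), seed=2)
        levels = tbl.groupby(["profile", "type_of_sound", "category", "exemplar"])[
            "level_offset_db"
        ].apply(lambda s: tuple(sorted(s)))
        assert (levels == (-10, -5, 0)).all()

    def test_referent_block_is_last(self):
        tbl = build_trial_table(ExperimentDesign(imitations_first=False), seed=3)
        last = tbl[tbl.block == tbl.block.max()]
        assert set(last.type_of_sound) == {"referent"}

    def test_block_structure_is_five_blocks(self):
        tbl = build_trial_table(ExperimentDesign(), seed=4)
        assert tbl.block.nunique() == 5

    def test_shuffle_is_deterministic_per_seed(self):
        a = build_trial_table(ExperimentDesign(), seed=5)
        b = build_trial_table(ExperimentDesign(), seed=5)
        c = build_trial_table(ExperimentDesign(), seed=6)
        assert a.equals(b)
        assert not a.equals(c)


class TestAnalyzeResponses:
    def test_all_yes_responder_has_zero_sensitivity_and_zero_beta(self):
        """An indiscriminate "yes" responder has d' = 0; the
        likelihood-ratio bias is 0 too, since beta cannot express a
        criterion shift when the two distributions coincide (H = F)."""
        tbl = build_trial_table(ExperimentDesign(), seed=0)
        res = analyze_responses(tbl, np.ones(len(tbl), dtype=bool))
        assert np.allclose(res.dprime, 0.0)
        assert np.allclose(res.ln_beta, 0.0)

    def test_liberal_high_sensitivity_responder_has_positive_beta(self):
        tbl = build_trial_table(ExperimentDesign(), seed=0)
        # always yes on targets, yes on most distractors: liberal criterion
        rng = np.random.default_rng(0)
        resp = ((tbl.category == "target") | (rng.random(len(tbl)) < 0.6)).to_numpy()
        res = analyze_responses(tbl, resp)
        assert res.ln_beta.mean() > 0

    def test_perfect_responder_hits_the_ceiling(self):
        tbl = build_trial_table(ExperimentDesign(), seed=0)
        res = analyze_responses(tbl, (tbl.category == "target").to_numpy())
        assert np.allclose(res.dprime, 2.93, atol=0.01)

    def test_hand_tallied_cell(self):
        rows = []
        for cat, n in (("target", 6), ("distractor", 6)):
            for i in range(n):
                rows.append({"type_of_sound": "referent", "profile": "impulsive", "category": cat})
        tbl = pd.DataFrame(rows)
        # 5 hits out of 6, 2 false alarms out of 6 — tallied by hand
        resp = [True, True, True, True, True, False, True, True, False, False, False, False]
        res = analyze_responses(tbl, resp)
        assert len(res) == 1
        assert res.loc[0, "n_hit"] == 5
        assert res.loc[0, "n_fa"] == 2
        expected = stats.norm.ppf(5.5 / 7) - stats.norm.ppf(2.5 / 7)
        assert res.loc[0, "dprime"] == pytest.approx(expected)

    def test_missing_responses_flagged_not_dropped(self):
        tbl = build_trial_table(ExperimentDesign(), seed=0)
        resp = pd.Series(True, index=tbl.index, dtype="object")
        resp.iloc[0] = None
        res = analyze_responses(tbl, resp)
        assert res.n_missing.sum() == 1
        assert len(res) == tbl.groupby(["type_of_sound", "profile"]).ngroups
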