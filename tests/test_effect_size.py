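import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialqc import (
    OneSampleContrast,
    PairedContrast,
    ResampleConfig,
    SyntheticSpec,
    cohens_d_one_sample,
    cohens_d_paired,
    effect_size_curve,
    effect_size_overall,
    generate_trial_table,
)
from trialqc.errors import UndefinedEffectError

from conftest import make_table


class TestOneSample:
    def test_direct_computation(self):
        d, t = cohens_d_one_sample([1, 2, 3], 0.0)
        assert d == pytest.approx(2.0)
        assert t == pytest.approx(2 * np.sqrt(3))

    def test_symmetric_scores_give_zero(self):
        d, _ = cohens_d_one_sample([-1, 1], 0.0)
        assert d == 0.0

    def test_zero_sd_undefined(self):
        with pytest.raises(UndefinedEffectError):
            cohens_d_one_sample([5, 5, 5], 0.0)

    def test_single_score_rejected(self):
        with pytest.raises(ValueError):
            cohens_d_one_sample([1.0], 0.0)


class TestPaired:
    def test_pooled_direct_computation(self):
        d, t = cohens_d_paired([2, 4, 6], [1, 3, 5])
        assert d == pytest.approx((4 - 3) / np.sqrt((4 + 4) / 2))
        # constant difference of 1 -> infinite paired t
        assert np.isinf(t)

    def test_identical_vectors_give_zero_d(self):
        d, t = cohens_d_paired([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and t == 0.0

    def test_matches_independent_formula_on_random_vectors(self, rng):
        s1 = rng.normal(1.0, 2.0, 10)
        s2 = rng.normal(0.5, 1.5, 10)
        d, t = cohens_d_paired(s1, s2)
        pooled = np.sqrt((np.var(s1, ddof=1) + np.var(s2, ddof=1)) / 2)
        assert d == pytest.approx((s1.mean() - s2.mean()) / pooled, rel=1e-12)
        diff = s1 - s2
        assert t == pytest.approx(
            diff.mean() / (diff.std(ddof=1) / np.sqrt(10)), rel=1e-12
        )

    def test_dz_standardizer_uses_difference_sd(self, rng):
        s1 = rng.normal(1.0, 2.0, 8)
        s2 = rng.normal(0.0, 1.0, 8)
        d, _ = cohens_d_paired(s1, s2, standardizer="dz")
        diff = s1 - s2
        assert d == pytest.approx(diff.mean() / diff.std(ddof=1), rel=1e-12)

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(ValueError):
            cohens_d_paired([1, 2, 3], [1, 2])

    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=12),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=60, deadline=None)
    def test_sign_antisymmetry(self, s1, seed):
        s2 = np.random.default_rng(seed).normal(size=len(s1))
        try:
            d12, _ = cohens_d_paired(s1, s2)
            d21, _ = cohens_d_paired(s2, s1)
        except UndefinedEffectError:
            return
        assert d12 == pytest.approx(-d21, rel=1e-9, abs=1e-12)


class TestOverall:
    def test_point_estimate_from_all_trial_means(self):
        table = make_table(
            [(f"P{i}", "A", t, v) for i, v in enumerate([1.0, 2.0, 3.0], 1)
             for t in (1, 2)]
        )
        res = effect_size_overall(
            table, OneSampleContrast("A", 0.0), ResampleConfig(200, seed=1)
        )
        assert res.point_estimate == pytest.approx(2.0)
        assert res.t_statistic == pytest.approx(2 * np.sqrt(3))

    def test_bootstrap_ci_brackets_bootstrap_median(self):
        spec = SyntheticSpec(n_subjects=40, n_trials=10, mu=0.5, sigma_b=1,
                             sigma_w=1, seed=8)
        table = generate_trial_table(spec)
        cfg = ResampleConfig(400, seed=2, retain_draws=True)
        res = effect_size_overall(table, OneSampleContrast("A"), cfg)
        s = res.summary
        assert s.ci_low <= np.median(s.draws) <= s.ci_high

    def test_null_effect_is_small(self):
        spec = SyntheticSpec(n_subjects=200, n_trials=10, mu=0.0, sigma_b=1,
                             sigma_w=1, seed=9)
        table = generate_trial_table(spec)
        res = effect_size_overall(table, OneSampleContrast("A"), ResampleConfig(100, seed=3))
        assert abs(res.point_estimate) < 0.2


class TestCurve:
    def test_zero_trial_noise_gives_constant_d(self):
        spec = SyntheticSpec(n_subjects=30, n_trials=16, mu=1.0, sigma_b=1.0,
                             sigma_w=0.0, seed=10)
        table = generate_trial_table(spec)
        cfg = ResampleConfig(50, seed=4, grid=(2, 4, 8, 16))
        results = effect_size_curve(table, OneSampleContrast("A"), cfg)
        scores = np.array([table.trials(p, "A").mean() for p in table.participants()])
        expected = scores.mean() / scores.std(ddof=1)
        for r in results:
            assert r.summary.mean_estimate == pytest.approx(expected)

    def test_null_paired_contrast_ci_covers_zero(self):
        spec = SyntheticSpec(
            n_subjects=60, n_trials=12, mu=0.4, sigma_b=1.0, sigma_w=1.0,
            conditions=("A", "B"), seed=13,
        )
        table = generate_trial_table(spec)
        # at n == all trials the iteration distribution collapses to the
        # sample d, so only proper subsample sizes have spread around it
        cfg = ResampleConfig(200, seed=5, grid=(4, 8))
        for r in effect_size_curve(table, PairedContrast("A", "B"), cfg):
            assert r.summary.ci_low <= 0.0 <= r.summary.ci_high
            assert abs(r.summary.mean_estimate) < 0.2

    def test_paired_eligibility_needs_both_conditions(self):
        # P3 has too few trials in B: excluded from the n=4 point
        recs = []
        for p, na, nb in [("P1", 6, 6), ("P2", 6, 6), ("P3", 6, 2)]:
            recs += [(p, "A", t, float(t)) for t in range(1, na + 1)]
            recs += [(p, "B", t, float(t) / 2) for t in range(1, nb + 1)]
        table = make_table(recs)
        cfg = ResampleConfig(20, seed=6, grid=(4,))
        (res,) = effect_size_curve(table, PairedContrast("A", "B"), cfg)
        assert res.summary.n_participants_used == 2

    def test_same_seed_reproduces_curve(self):
        spec = SyntheticSpec(n_subjects=20, n_trials=8, mu=0.5, sigma_b=1,
                             sigma_w=1, seed=14)
        table = generate_trial_table(spec)
        cfg = ResampleConfig(50, seed=7, grid=(4, 8))
        a = effect_size_curve(table, OneSampleContrast("A"), cfg)
        b = effect_size_curve(table, OneSampleContrast("A"), cfg)
        assert a == b
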