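import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialqc import (
    ResampleConfig,
    SyntheticSpec,
    generate_trial_table,
    reliability_curve,
    reliability_overall,
    spearman_brown,
    split_half_estimate,
    substream,
)
from trialqc.errors import InsufficientSampleError

from conftest import make_table


class TestSpearmanBrown:
    @pytest.mark.parametrize(
        "r_half,expected",
        [(0.5, 2 / 3), (1.0, 1.0), (0.0, 0.0), (-1 / 3, -1.0)],
    )
    def test_direct_substitution(self, r_half, expected):
        assert spearman_brown(r_half) == pytest.approx(expected, rel=1e-12)

    def test_undefined_at_minus_one(self):
        with pytest.raises(ZeroDivisionError):
            spearman_brown(-1.0)

    @pytest.mark.parametrize("bad", [1.5, -2.0])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            spearman_brown(bad)

    @given(st.floats(-0.999, 0.999), st.floats(-0.999, 0.999))
    @settings(max_examples=100, deadline=None)
    def test_monotone_increasing(self, r1, r2):
        lo, hi = sorted([r1, r2])
        assert spearman_brown(lo) <= spearman_brown(hi)


class TestSplitHalfEstimate:
    def test_constant_participants_give_perfect_reliability(
        self, constant_participants_table, rng
    ):
        r = split_half_estimate(constant_participants_table, "A", rng, n=4)
        assert r == pytest.approx(1.0)

    def test_two_participants_insufficient(self, rng):
        table = make_table(
            [("P1", "A", t, v) for t, v in [(1, 0.0), (2, 1.0)]]
            + [("P2", "A", t, v) for t, v in [(1, 2.0), (2, 3.0)]]
        )
        with pytest.raises(InsufficientSampleError):
            split_half_estimate(table, "A", rng)

    def test_identical_participants_yield_undefined_iteration(self, rng):
        # all bin-mean vectors are constant across participants: zero variance
        table = make_table(
            [(f"P{i}", "A", t, 1.0) for i in range(1, 4) for t in (1, 2)]
        )
        assert np.isnan(split_half_estimate(table, "A", rng))


def exhaustive_two_trial_oracle(cells):
    """Average corrected split-half estimate over all 2^P bin assignments
    for participants with exactly 2 trials each (one trial per bin)."""
    estimates = []
    for picks in itertools.product((0, 1), repeat=len(cells)):
        a = np.array([c[p] for c, p in zip(cells, picks)])
        b = np.array([c[1 - p] for c, p in zip(cells, picks)])
        r = np.corrcoef(a, b)[0, 1]
        estimates.append(spearman_brown(r))
    return float(np.mean(estimates))


class TestExhaustiveOracle:
    def test_monte_carlo_converges_to_enumeration(self):
        cells = [np.array([0.0, 1.0]), np.array([2.0, 4.0]), np.array([5.0, 9.0])]
        expected = exhaustive_two_trial_oracle(cells)
        table = make_table(
            [(f"P{i + 1}", "A", t + 1, cells[i][t]) for i in range(3) for t in (0, 1)]
        )
        cfg = ResampleConfig(n_iterations=4000, seed=9, retain_draws=True)
        result = reliability_overall(table, "A", cfg)
        assert result.summary.mean_estimate == pytest.approx(expected, abs=0.02)


class TestReliabilityOverall:
    def test_zero_noise_synthetic_gives_exactly_one(self):
        spec = SyntheticSpec(n_subjects=10, n_trials=6, sigma_b=1.0, sigma_w=0.0, seed=4)
        table = generate_trial_table(spec)
        result = reliability_overall(table, "A", ResampleConfig(n_iterations=50, seed=1))
        assert result.summary.mean_estimate == pytest.approx(1.0)

    def test_same_seed_reproduces_result(self, small_table):
        cfg = ResampleConfig(n_iterations=100, seed=42)
        a = reliability_overall(small_table, "A", cfg)
        b = reliability_overall(small_table, "A", cfg)
        assert a == b

    def test_ragged_trial_sets_are_used_in_full(self, small_table):
        # participants with 2 and 3 trials are all eligible for overall scope
        result = reliability_overall(small_table, "A", ResampleConfig(10, seed=0))
        assert result.summary.n_participants_used == 3


class TestReliabilityCurve:
    def test_monotone_trend_on_variance_components_data(self):
        spec = SyntheticSpec(
            n_subjects=150, n_trials=32, sigma_b=1.0, sigma_w=2.0, seed=21
        )
        table = generate_trial_table(spec)
        cfg = ResampleConfig(n_iterations=150, seed=2, grid=(4, 8, 16, 32))
        curve = reliability_curve(table, "A", cfg)
        means = [r.summary.mean_estimate for r in curve]
        assert all(b >= a - 0.03 for a, b in zip(means, means[1:]))

    def test_zero_noise_curve_is_one_everywhere(self):
        spec = SyntheticSpec(n_subjects=8, n_trials=10, sigma_b=1.0, sigma_w=0.0, seed=3)
        table = generate_trial_table(spec)
        cfg = ResampleConfig(n_iterations=20, seed=0, grid=(2, 5, 10))
        for r in reliability_curve(table, "A", cfg):
            assert r.summary.mean_estimate == pytest.approx(1.0)

    def test_unavailable_grid_point_is_flagged_not_fatal(self):
        spec = SyntheticSpec(n_subjects=6, n_trials=8, sigma_b=1.0, sigma_w=1.0, seed=5)
        table = generate_trial_table(spec)
        cfg = ResampleConfig(n_iterations=20, seed=0, grid=(5, 10))
        curve = reliability_curve(table, "A", cfg)
        assert curve[0].available and curve[0].summary.n_trials == 5
        assert not curve[1].available
        assert curve[1].to_rows() == []

    def test_grid_point_streams_are_independent(self):
        # adding a grid point must not perturb estimates at existing points
        spec = SyntheticSpec(n_subjects=30, n_trials=12, sigma_b=1, sigma_w=1, seed=6)
        table = generate_trial_table(spec)
        short = reliability_curve(table, "A", ResampleConfig(50, seed=7, grid=(4, 8)))
        long = reliability_curve(table, "A", ResampleConfig(50, seed=7, grid=(4, 6, 8)))
        assert short[0].summary == long[0].summary
        assert short[1].summary == long[2].summary


def test_negative_r_half_passes_through_uncorrected(rng):
    # two anti-correlated participant pairs plus a third: estimates may be
    # negative and must be reported as computed, not clamped at zero
    table = make_table(
        [
            ("P1", "A", 1, 0.0), ("P1", "A", 2, 10.0),
            ("P2", "A", 1, 10.0), ("P2", "A", 2, 0.0),
            ("P3", "A", 1, 4.0), ("P3", "A", 2, 6.0),
        ]
    )
    cfg = ResampleConfig(n_iterations=300, seed=11, retain_draws=True)
    result = reliability_overall(table, "A", cfg)
    assert (result.summary.draws < 0).any()
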