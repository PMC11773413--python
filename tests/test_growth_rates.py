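"""Rate estimators: resampling, smoothing, and the three-level pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from microlineage.rates import (
    DEFAULT_RATE_PARAMS,
    RateParams,
    generation_time,
    instantaneous_rate,
    moving_mean,
    period_grid,
    rate_cell,
    rate_cell_mean,
    rate_lineage,
    rate_subtree,
    resample_area,
    subtree_size,
    subtree_size_series,
)

from _oracles import naive_rate_cell, naive_rate_lineage, naive_rate_subtree
from conftest import cousin_forest, small_sim, two_generation_forest


class TestRateParams:
    def test_lag_must_divide(self):
        with pytest.raises(ValueError):
            RateParams(10.0, 25.0, 3)

    def test_df_must_be_odd(self):
        with pytest.raises(ValueError):
            RateParams(10.0, 30.0, 2)


class TestResample:
    def test_on_grid_is_identity(self):
        t = np.arange(0, 100, 10.0)
        a = np.linspace(2, 3, len(t))
        assert np.array_equal(resample_area(t, a, t), a)

    def test_downsample_20_to_40_keeps_every_other_frame(self):
        t = np.arange(360, 1000, 20.0)
        a = np.arange(len(t), dtype=float)
        grid = np.arange(360, 1000, 40.0)
        out = resample_area(t, a, grid)
        assert np.array_equal(out, a[::2])

    def test_gap_flags_missing_frame(self):
        t = np.array([0.0, 10.0, 50.0])
        out = resample_area(t, np.array([1.0, 2.0, 3.0]), np.arange(0, 60, 10.0))
        assert np.isnan(out[2:4]).all() and np.isfinite(out[[0, 1, 5]]).all()

    def test_jittered_times_match_bruteforce_nearest(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 200, 10.0) + rng.uniform(-3, 3, 20)
        a = rng.uniform(1, 5, 20)
        grid = np.arange(0, 200, 10.0)
        out = resample_area(t, a, grid)
        for g, o in zip(grid, out):
            d = np.abs(t - g)
            expect = a[np.argmin(d)] if d.min() <= 5.0 else np.nan
            assert (np.isnan(o) and np.isnan(expect)) or o == expect


class TestInstantAndSmooth:
    def test_closed_form_log_ratio(self):
        areas = np.array([2.0, np.nan, np.nan, 4.0])
        r = instantaneous_rate(areas, RateParams(10.0, 30.0, 1))
        assert r[0] == pytest.approx(np.log(2.0) / 30.0, rel=1e-12)

    def test_constant_area_gives_zero(self):
        r = instantaneous_rate(np.full(10, 3.3), DEFAULT_RATE_PARAMS["high"])
        assert np.all(r[np.isfinite(r)] == 0.0)

    @pytest.mark.parametrize("params", [RateParams(10, 30, 3), RateParams(40, 400, 9)])
    def test_exact_exponential_any_lag(self, params):
        t = np.arange(0, 50 * params.dt_prime, params.dt_prime)
        r = instantaneous_rate(2.0 * np.exp(0.005 * t), params)
        assert np.allclose(r[np.isfinite(r)], 0.005, rtol=1e-9)

    def test_moving_mean_truncated_edges(self):
        out = moving_mean(np.array([1.0, 2, 3, 4, 5]), 3)
        assert np.allclose(out, [1.5, 2, 3, 4, 4.5])

    def test_df1_is_identity_and_constant_unchanged(self):
        v = np.array([1.0, np.nan, 3.0])
        assert np.array_equal(moving_mean(v, 1), v, equal_nan=True)
        c = np.full(7, 2.5)
        assert np.allclose(moving_mean(c, 5), c)

    @given(a=st.floats(-1, 1), b=st.floats(-0.1, 0.1),
           n=st.integers(5, 40), df=st.sampled_from([3, 5, 7]))
    @settings(deadline=None, max_examples=60)
    def test_truncated_smoothing_preserves_mean_of_linear_series(self, a, b, n, df):
        # symmetric edge truncation balances front and back, so a linear
        # trend keeps its global mean through the moving mean
        v = a + b * np.arange(n)
        sm = moving_mean(v, df)
        assert np.mean(sm) == pytest.approx(np.mean(v), rel=1e-9, abs=1e-12)


class TestCellRate:
    def test_exponential_recovers_rate_exactly(self, schedule3):
        f = two_generation_forest(rate=0.005)
        r = rate_cell_mean(f, "r", schedule3, "high")
        assert r == pytest.approx(0.005, rel=1e-12)

    def test_mid_window_birth_uses_post_birth_frames_only(self, schedule3):
        f = two_generation_forest()
        rs = rate_cell(f, "c0", schedule3, "high")
        assert rs.times[0] == f["c0"].birth_time

    def test_no_usable_frames_is_nan_not_zero(self, schedule3):
        f = two_generation_forest()
        assert np.isnan(rate_cell_mean(f, "r", schedule3, "low"))

    def test_generation_time(self):
        f = cousin_forest()
        assert generation_time(f["p0"]) == 120.0
        assert generation_time(f["p0c0"]) is None


class TestSubtreeRate:
    def test_single_cell_subtree_equals_cell(self, schedule3):
        f = two_generation_forest()
        rs = rate_subtree(f, "c0", schedule3, "high")
        rc = rate_cell(f, "c0", schedule3, "high")
        assert rs.window_mean == pytest.approx(rc.window_mean, rel=1e-12)

    def test_additivity_after_division(self, schedule3):
        f = two_generation_forest()
        grid = period_grid(schedule3, "high", 10.0)
        S = subtree_size_series(f, "r", grid)
        S0 = subtree_size_series(f, "c0", grid)
        S1 = subtree_size_series(f, "c1", grid)
        after = grid >= 120.0
        assert np.allclose(S[after], S0[after] + S1[after], rtol=1e-12)

    def test_point_evaluation(self, schedule3):
        f = two_generation_forest()
        s = subtree_size(f, "r", 200.0, schedule3)
        assert s == pytest.approx(f["c0"].area_series[8, 1] + f["c1"].area_series[8, 1])

    def test_equal_rate_cells_give_the_common_rate(self, schedule3):
        f = two_generation_forest(rate=0.004)
        # whole-tree S(t) is a sum of equal-rate exponentials after division
        rs = rate_subtree(f, "r", schedule3, "high", window=(130.0, 350.0))
        assert rs.window_mean == pytest.approx(0.004, rel=1e-9)


class TestLineageRate:
    def test_single_cell_chain_equals_cell(self, schedule3):
        f = two_generation_forest()
        rl = rate_lineage(f, "r", schedule3, "high", window=(0.0, 110.0))
        rc = rate_cell(f, "r", schedule3, "high", window=(0.0, 110.0))
        assert rl.window_mean == pytest.approx(rc.window_mean, rel=1e-12)

    def test_division_halving_is_excluded(self, schedule3):
        f = two_generation_forest(rate=0.005)
        rl = rate_lineage(f, "c0", schedule3, "high")
        assert rl.window_mean == pytest.approx(0.005, rel=1e-9)

    def test_arbitrary_division_jump_leaves_rate_unchanged(self, schedule3):
        base = two_generation_forest(rate=0.005)
        r_base = rate_lineage(base, "c0", schedule3, "high").window_mean
        jumped = two_generation_forest(rate=0.005)
        jumped.cells["c0"].area_series[:, 1] *= 7.3  # inject a size jump at division
        r_jump = rate_lineage(jumped, "c0", schedule3, "high").window_mean
        assert r_jump == r_base


@pytest.mark.parametrize("seed", [3, 4])
def test_oracle_equivalence_on_simulated_colonies(seed):
    """The vectorized pipeline agrees with naive loop re-implementations."""
    forest, schedule, _ = small_sim(seed)
    cells = sorted(forest.cells)[:12]
    for period in ("high", "low"):
        for cid in cells:
            got = rate_cell_mean(forest, cid, schedule, period)
            expect = naive_rate_cell(forest, cid, schedule, period)
            if expect is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expect, rel=1e-12)
    onset = sorted(forest.alive_at(schedule.low[0]))[:4]
    for root in onset:
        got = rate_subtree(forest, root, schedule, "low").window_mean
        expect = naive_rate_subtree(forest, root, schedule, "low")
        assert got == pytest.approx(expect, rel=1e-12)
    starters = sorted(forest.alive_at(schedule.recovery[0]))[:4]
    for sid in starters:
        got = rate_lineage(forest, sid, schedule, "low").window_mean
        expect = naive_rate_lineage(forest, sid, schedule, "low")
        assert got == pytest.approx(expect, rel=1e-12)
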