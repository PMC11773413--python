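"""Starter identification, lag/progeny statistics, and heterogeneity summaries."""

import numpy as np
import pytest
from scipy import stats

from microlineage.lineage import LineageForest
from microlineage.regrowth import (
    RegrowthRecord,
    classify_regrowers,
    compare_groups,
    cousin_reference_window,
    cousin_sets,
    cousin_subtree_cv,
    cumulative_progeny_curve,
    cv_within_microcolony,
    identify_starters,
    lag_time,
    mean_pairwise_CR,
    p_recovery,
    regrowth_records,
    tau_start,
)

from _oracles import naive_p_recovery
from conftest import cousin_forest, exp_series, make_cell, small_sim


def _rec(p, tau=None, sid="s", colony="m0"):
    return RegrowthRecord(sid, colony, tau if p > 0 else None, p)


class TestStarters:
    def test_undivided_root_is_sole_starter(self, schedule1):
        cells = [make_cell("a", series=exp_series(0, 2400, 2.0, 1e-4, dt=10.0))]
        f = LineageForest("m0", cells)
        assert identify_starters(f, schedule1) == ["a"]

    def test_lysed_colony_has_no_starters(self, schedule1):
        cells = [make_cell("a", fate="lysed", series=exp_series(0, 800, 2.0, 1e-4, dt=10.0))]
        f = LineageForest("m0", cells)
        assert identify_starters(f, schedule1) == []

    def test_matches_aliveness_filter(self, sim_colony):
        forest, schedule, _ = sim_colony
        t_r = schedule.recovery[0]
        expect = sorted(
            c.cell_id for c in forest.cells.values() if c.alive_at(t_r)
        )
        assert identify_starters(forest, schedule) == expect


class TestLagAndProgeny:
    def test_lag_is_offset_from_resupply(self, schedule1):
        t_r = schedule1.recovery[0]
        cells = [
            make_cell("a", division=t_r + 90.0, fate="divided",
                      series=exp_series(0, t_r + 90, 2.0, 1e-4, dt=10.0)),
            make_cell("a0", parent="a", birth=t_r + 90.0,
                      series=exp_series(t_r + 90, 2400, 2.0, 1e-4, dt=10.0, end_exclusive=False)),
            make_cell("a1", parent="a", birth=t_r + 90.0,
                      series=exp_series(t_r + 90, 2400, 2.0, 1e-4, dt=10.0, end_exclusive=False)),
        ]
        f = LineageForest("m0", cells)
        assert lag_time(f, "a", schedule1) == 90.0
        assert p_recovery(f, "a", schedule1) == 2

    def test_no_division_gives_absent_lag_and_zero_progeny(self, schedule1):
        cells = [make_cell("a", series=exp_series(0, 2400, 2.0, 1e-4, dt=10.0))]
        f = LineageForest("m0", cells)
        assert lag_time(f, "a", schedule1) is None
        assert p_recovery(f, "a", schedule1) == 0

    def test_progeny_matches_exhaustive_scan(self, sim_colony):
        forest, schedule, _ = sim_colony
        for sid in identify_starters(forest, schedule):
            assert p_recovery(forest, sid, schedule) == naive_p_recovery(
                forest, sid, schedule
            )

    def test_reciprocal_lag_correlates_with_progeny(self):
        taus, ps = [], []
        for seed in range(6):
            forest, schedule, _ = small_sim(seed=40 + seed)
            for r in regrowth_records(forest, schedule):
                if r.tau is not None:
                    taus.append(1.0 / r.tau)
                    ps.append(r.p_recovery)
        rho = stats.spearmanr(taus, ps).statistic
        assert rho > 0.5


class TestClassification:
    def test_fixed_thresholds_follow_published_cuts(self):
        recs = [_rec(0), _rec(3, 100.0), _rec(8, 100.0), _rec(7, 100.0)]
        classify_regrowers(recs, mode="fixed_threshold")
        assert [r.regrower_class for r in recs] == ["non", "normal", "hyper", "normal"]

    def test_partition_is_complete(self, sim_colony):
        forest, schedule, _ = sim_colony
        recs = classify_regrowers(regrowth_records(forest, schedule))
        counts = {k: sum(r.regrower_class == k for r in recs) for k in ("non", "normal", "hyper")}
        assert sum(counts.values()) == len(recs)
        assert all(r.regrower_class is not None for r in recs)

    def test_all_zero_cohort_is_all_non(self):
        recs = [_rec(0, sid=f"s{i}") for i in range(5)]
        classify_regrowers(recs, mode="fixed_threshold")
        assert {r.regrower_class for r in recs} == {"non"}

    def test_top_fraction_includes_ties_above_cut(self):
        recs = [_rec(p, 100.0, sid=f"s{i}") for i, p in enumerate([1, 2, 3, 4, 5, 6, 7, 8, 9, 9])]
        classify_regrowers(recs, mode="top_fraction", top_fraction=0.10)
        hyper = [r.p_recovery for r in recs if r.regrower_class == "hyper"]
        assert hyper == [9, 9]


class TestCumulativeCurve:
    def test_single_regrower_jumps_to_one(self):
        curve = cumulative_progeny_curve([_rec(5, 100.0), _rec(0)])
        assert curve[0] == 1.0

    def test_equal_counts_linear(self):
        curve = cumulative_progeny_curve([_rec(4, 100.0, sid=f"s{i}") for i in range(4)])
        assert np.allclose(curve, [0.25, 0.5, 0.75, 1.0])

    def test_monotone_concave_ends_at_one(self, sim_colony):
        forest, schedule, _ = sim_colony
        recs = regrowth_records(forest, schedule)
        curve = cumulative_progeny_curve(recs)
        assert np.all(np.diff(curve) >= -1e-12)
        assert np.all(np.diff(curve, 2) <= 1e-12)  # concave for sorted input
        assert curve[-1] == pytest.approx(1.0)


class TestHeterogeneity:
    def test_identical_cells_have_zero_cv(self, schedule3):
        f = cousin_forest()
        assert cv_within_microcolony(f, schedule3, "high", "rate") == pytest.approx(0.0, abs=1e-9)

    def test_cv_uses_sample_sd_convention(self, schedule3):
        # two cells with exact rates 0.001 and 0.003: CV = sd/mean = sqrt(2)/2
        cells = [
            make_cell("a", series=exp_series(0, 360, 2.0, 0.001), birth=0.0),
            make_cell("b", series=exp_series(0, 360, 2.0, 0.003), birth=0.0),
        ]
        f = LineageForest("m0", cells)
        cv = cv_within_microcolony(f, schedule3, "high", "rate")
        assert cv == pytest.approx(np.sqrt(2) / 2, rel=1e-9)

    def test_mean_cr_of_two_sisters(self, schedule3):
        from conftest import two_generation_forest

        f = two_generation_forest()
        assert mean_pairwise_CR(f, 300.0) == 0.5

    def test_mean_cr_of_four_grandchildren(self):
        f = cousin_forest()
        assert mean_pairwise_CR(f, 300.0) == pytest.approx(1.0 / 3.0)

    def test_mean_cr_dilutes_with_generations(self):
        f = cousin_forest()
        assert mean_pairwise_CR(f, 300.0) < mean_pairwise_CR(f, 200.0)


class TestTauStart:
    def test_offset_from_last_high_division(self, schedule3):
        f = cousin_forest()  # divisions at 120 and 240, low onset at 360
        assert tau_start(f, "p0c0", schedule3) == 120.0

    def test_absent_without_high_division(self, schedule3):
        cells = [make_cell("a", series=exp_series(0, 4800, 2.0, 1e-4, dt=10.0))]
        f = LineageForest("m0", cells)
        assert tau_start(f, "a", schedule3) is None

    def test_matches_bruteforce_chain_scan(self, sim_colony):
        forest, schedule, _ = sim_colony
        from _oracles import naive_ancestor_chain

        for sid in identify_starters(forest, schedule)[:20]:
            chain = naive_ancestor_chain(forest, sid, 0.0, schedule.low[0] + 1e-9)
            divs = [forest[c].division_time for c in chain
                    if forest[c].division_time is not None
                    and forest[c].division_time <= schedule.low[0]]
            expect = schedule.low[0] - max(divs) if divs else None
            assert tau_start(forest, sid, schedule) == expect


class TestCousinSubtrees:
    def test_identical_cousins_have_zero_cv(self, schedule3):
        f = cousin_forest(rate=0.005)
        t_ref, w = 240.0, 120.0
        cvs = cousin_subtree_cv(f, schedule3, "high", t_ref=t_ref, window_length=w)
        assert len(cvs) == 1
        assert cvs[0] == pytest.approx(0.0, abs=1e-9)

    def test_sets_are_first_cousins(self, sim_colony):
        from microlineage.lineage import generations_to_common_ancestor

        forest, schedule, _ = sim_colony
        t_ref = schedule.low[0]
        for a, b in cousin_sets(forest, t_ref):
            assert generations_to_common_ancestor(forest, a, b) == 2

    def test_reference_window_is_twice_median_gentime(self):
        forest, schedule, _ = small_sim(seed=12)  # colony with low-period divisions
        from microlineage.regrowth import median_generation_time

        t_ref, w = cousin_reference_window([forest], schedule, "low")
        med = median_generation_time([forest], schedule, "low")
        assert t_ref == schedule.low[0]
        assert w == pytest.approx(min(2 * med, schedule.low[1] - schedule.low[0]))


class TestCompareGroups:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=50)
        out = compare_groups({"a": v, "b": v.copy(), "c": v.copy()})
        assert len(set(out["letters"].values())) == 1

    def test_separated_groups_all_distinct(self):
        rng = np.random.default_rng(1)
        out = compare_groups(
            {
                "a": rng.normal(0, 1, 50),
                "b": rng.normal(5, 1, 50),
                "c": rng.normal(10, 1, 50),
            }
        )
        assert out["omnibus"]["p"] < 0.05
        assert len(set(out["letters"].values())) == 3

    def test_null_calibration_of_posthoc(self):
        rng = np.random.default_rng(2)
        rejections = 0
        n_rep = 120
        for _ in range(n_rep):
            v = rng.normal(size=60)
            out = compare_groups({"a": v[:30], "b": v[30:]})
            rejections += out["posthoc"]["pairs"]["a|b"] < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.05)

    def test_small_group_dropped_with_warning(self):
        out = compare_groups({"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0], "c": [1.0]})
        assert out["dropped_groups"] == ["c"]
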