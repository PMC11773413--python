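"""Shared fixtures and forest builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from microlineage.lineage import CellRecord, LineageForest, PeriodSchedule
from microlineage.simulate import SimConfig, simulate_colony


def exp_series(t0: float, t1: float, a0: float, rate: float, dt: float = 10.0,
               end_exclusive: bool = True) -> np.ndarray:
    """Noiseless exponential area series on a dt grid over [t0, t1)."""
    t = np.arange(t0, t1 - 1e-9 if end_exclusive else t1 + 1e-9, dt)
    return np.column_stack([t, a0 * np.exp(rate * (t - t0))])


def make_cell(cid, colony="m0", parent=None, birth=None, division=None, fate="censored",
              series=None, x=0.0, y=0.0) -> CellRecord:
    series = np.asarray(series, float)
    cent = np.column_stack(
        [series[:, 0], np.full(len(series), x), np.full(len(series), y)]
    )
    return CellRecord(cid, colony, parent, birth, division, fate, series, cent)


def two_generation_forest(rate: float = 0.005, gen: float = 120.0) -> LineageForest:
    """Root dividing once at t=gen into two exponentially growing daughters."""
    a_div = 2.0 * np.exp(rate * gen)
    cells = [
        make_cell("r", parent=None, birth=None, division=gen, fate="divided",
                  series=exp_series(0, gen, 2.0, rate)),
        make_cell("c0", parent="r", birth=gen, fate="censored",
                  series=exp_series(gen, 360, a_div / 2, rate), x=-1.0),
        make_cell("c1", parent="r", birth=gen, fate="censored",
                  series=exp_series(gen, 360, a_div / 2, rate), x=1.0),
    ]
    return LineageForest("m0", cells)


def cousin_forest(rate: float = 0.005) -> LineageForest:
    """Grandparent -> two parents -> four grandchildren (two cousin pairs)."""
    g1, g2 = 120.0, 240.0
    a1 = 2.0 * np.exp(rate * g1)
    a2 = (a1 / 2) * np.exp(rate * (g2 - g1))
    cells = [
        make_cell("g", birth=None, division=g1, fate="divided",
                  series=exp_series(0, g1, 2.0, rate)),
        make_cell("p0", parent="g", birth=g1, division=g2, fate="divided",
                  series=exp_series(g1, g2, a1 / 2, rate)),
        make_cell("p1", parent="g", birth=g1, division=g2, fate="divided",
                  series=exp_series(g1, g2, a1 / 2, rate)),
    ]
    for i, p in enumerate(("p0", "p1")):
        for j in range(2):
            cells.append(
                make_cell(f"{p}c{j}", parent=p, birth=g2, fate="censored",
                          series=exp_series(g2, 360, a2 / 2, rate),
                          x=2.0 * i - 1.0, y=float(j))
            )
    return LineageForest("m0", cells)


def small_sim(seed: int, **overrides):
    """One fast simulated microcolony (1-day variant, no spatial layout)."""
    defaults = dict(low_days=1, spatial=False)
    defaults.update(overrides)
    cfg = SimConfig(n_colonies=1, seed=seed, **defaults)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    forest, truth = simulate_colony(cfg, rng, "m0")
    return forest, cfg.schedule, truth


@pytest.fixture(scope="session")
def schedule3() -> PeriodSchedule:
    return PeriodSchedule.three_day()


@pytest.fixture(scope="session")
def schedule1() -> PeriodSchedule:
    return PeriodSchedule.one_day()


@pytest.fixture(scope="session")
def sim_colony():
    """A single simulated 1-day colony shared across read-only tests."""
    forest, schedule, truth = small_sim(seed=11)
    return forest, schedule, truth
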