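"""Size-increase-rate estimators at the cell, subtree, and lineage level.

All three estimators share one pipeline built on the assumption of
exponential area growth, s(t) = s0 * exp(r t):

1. instantaneous rate      r(t) = ln(s(t + dt) / s(t)) / dt
2. centered moving mean over ``df`` frames (window truncated at edges to
   the frames that exist)
3. window average: the arithmetic mean of the smoothed values over the
   frames actually included in [t_start, t_end] (both endpoints inclusive).

The cell-level estimator applies this to a single cell's area series, the
subtree estimator to the summed area S(t) of all live descendants of a
root, and the lineage estimator to a retrospective chain of ancestors,
where each log-ratio is taken strictly within one ancestor's own series so
that the size drop at division never enters the estimate.

Frames live on a per-period grid anchored at the period start with spacing
``dt_prime``; log-ratios never straddle a period boundary (each period has
its own parameters and is processed independently).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lineage import (
    CellRecord,
    DataError,
    LineageForest,
    PeriodSchedule,
    ancestors_of,
    descendants_of,
)

__all__ = [
    "RateParams",
    "RateSeries",
    "DEFAULT_RATE_PARAMS",
    "period_grid",
    "resample_area",
    "instantaneous_rate",
    "moving_mean",
    "rate_cell",
    "rate_cell_mean",
    "subtree_size_series",
    "subtree_size",
    "rate_subtree",
    "rate_lineage",
    "generation_time",
]


@dataclass(frozen=True)
class RateParams:
    """Frame interval, log-ratio lag, and smoothing window for one period.

    ``dt`` must be a positive integer multiple of ``dt_prime``; ``df`` is an
    odd frame count (1 disables smoothing).
    """

    dt_prime: float
    dt: float
    df: int

    def __post_init__(self) -> None:
        if self.dt_prime <= 0 or self.dt <= 0:
            raise ValueError("dt_prime and dt must be positive")
        ratio = self.dt / self.dt_prime
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError("dt must be a positive integer multiple of dt_prime")
        if self.df < 1 or self.df % 2 == 0:
            raise ValueError("df must be odd and >= 1")

    @property
    def lag_frames(self) -> int:
        return int(round(self.dt / self.dt_prime))


#: Parameter sets used for the published analysis: 10/30/3 in the
#: high-nutrient and recovery periods, 40/400/9 in the low-nutrient period.
DEFAULT_RATE_PARAMS: dict[str, RateParams] = {
    "high": RateParams(10.0, 30.0, 3),
    "low": RateParams(40.0, 400.0, 9),
    "recovery": RateParams(10.0, 30.0, 3),
}


@dataclass
class RateSeries:
    """Instantaneous, smoothed, and window-averaged rates for one entity."""

    entity_id: str
    times: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray
    window_mean: float

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.raw) == len(self.smoothed)):
            raise ValueError("times, raw and smoothed must be aligned")


def period_grid(schedule: PeriodSchedule, period: str, dt_prime: float) -> np.ndarray:
    """Analysis frame grid for one period, anchored at the period start.

    The right endpoint belongs to the next period, except for the recovery
    period which owns the observation end.
    """
    t0, t1 = schedule.span(period)
    n = int(np.floor((t1 - t0) / dt_prime + 1e-9))
    grid = t0 + dt_prime * np.arange(n)
    if period == "recovery" and (t1 - (grid[-1] if n else t0)) > 1e-9:
        if abs((t1 - t0) / dt_prime - round((t1 - t0) / dt_prime)) < 1e-9:
            grid = np.append(grid, t1)
    return grid


def resample_area(
    times: np.ndarray, areas: np.ndarray, grid: np.ndarray, tol: float | None = None
) -> np.ndarray:
    """Snap an observed area series onto a frame grid by nearest neighbour.

    No interpolation of area values: each grid point takes the nearest
    observed frame within ``tol`` (default half the grid spacing), and is
    NaN (missing-frame flag) otherwise.  Downstream rates at missing frames
    are undefined, never zero.
    """
    times = np.asarray(times, float)
    areas = np.asarray(areas, float)
    grid = np.asarray(grid, float)
    if len(times) == 0:
        raise DataError("empty area series")
    if tol is None:
        if len(grid) > 1:
            tol = 0.5 * float(np.min(np.diff(grid)))
        else:
            tol = np.inf
    idx = np.searchsorted(times, grid)
    idx_lo = np.clip(idx - 1, 0, len(times) - 1)
    idx_hi = np.clip(idx, 0, len(times) - 1)
    d_lo = np.abs(grid - times[idx_lo])
    d_hi = np.abs(times[idx_hi] - grid)
    pick = np.where(d_lo <= d_hi, idx_lo, idx_hi)
    dist = np.minimum(d_lo, d_hi)
    out = areas[pick].astype(float)
    out[dist > tol + 1e-9] = np.nan
    return out


def instantaneous_rate(areas: np.ndarray, params: RateParams) -> np.ndarray:
    """Per-frame rate ln(s(t+dt)/s(t))/dt on a gridded series (NaN-padded)."""
    areas = np.asarray(areas, float)
    k = params.lag_frames
    out = np.full(len(areas), np.nan)
    if len(areas) > k:
        a0 = areas[:-k]
        a1 = areas[k:]
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:-k] = np.log(a1 / a0) / params.dt
    return out


def moving_mean(values: np.ndarray, df: int) -> np.ndarray:
    """Centered moving mean over ``df`` frames, truncated to existing frames.

    Output is defined exactly where the input is defined; NaN entries inside
    the window are simply skipped (they are missing frames, not zeros).
    """
    if df < 1 or df % 2 == 0:
        raise ValueError("df must be odd and >= 1")
    v = np.asarray(values, float)
    if df == 1 or len(v) == 0:
        return v.copy()
    finite = np.isfinite(v)
    filled = np.where(finite, v, 0.0)
    kernel = np.ones(df)
    h = (df - 1) // 2
    sums = np.convolve(filled, kernel, mode="full")[h : h + len(v)]
    counts = np.convolve(finite.astype(float), kernel, mode="full")[h : h + len(v)]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[~finite] = np.nan
    return out


# ---------------------------------------------------------------------------
# cell level


def _cell_frames(cell: CellRecord, grid: np.ndarray) -> np.ndarray:
    """Indices of grid points at which the cell is alive."""
    lo = cell.start_time
    if cell.fate == "divided":
        mask = (grid >= lo - 1e-9) & (grid < cell.division_time - 1e-9)
    else:
        mask = (grid >= lo - 1e-9) & (grid <= cell.end_time + 1e-9)
    return np.nonzero(mask)[0]


def _window_mean(times: np.ndarray, smoothed: np.ndarray, window: tuple[float, float]) -> float:
    t0, t1 = window
    sel = (times >= t0 - 1e-9) & (times <= t1 + 1e-9) & np.isfinite(smoothed)
    if not np.any(sel):
        return float("nan")
    return float(np.mean(smoothed[sel]))


def rate_cell(
    forest: LineageForest,
    cell_id: str,
    schedule: PeriodSchedule,
    period: str,
    params: RateParams | None = None,
    window: tuple[float, float] | None = None,
) -> RateSeries:
    """Instantaneous/smoothed/window-mean pipeline for one cell in one period.

    Raw and smoothed series cover the cell's whole life inside the period;
    ``window_mean`` averages the smoothed values over ``window`` (default:
    the full period).  An unusable window gives ``window_mean = nan``.
    """
    params = params or DEFAULT_RATE_PARAMS[period]
    cell = forest[cell_id]
    grid = period_grid(schedule, period, params.dt_prime)
    idx = _cell_frames(cell, grid)
    if len(idx) == 0:
        return RateSeries(cell_id, np.array([]), np.array([]), np.array([]), float("nan"))
    times = grid[idx]
    areas = resample_area(cell.area_series[:, 0], cell.area_series[:, 1], times)
    raw = instantaneous_rate(areas, params)
    smoothed = moving_mean(raw, params.df)
    if window is None:
        window = schedule.span(period)
    return RateSeries(cell_id, times, raw, smoothed, _window_mean(times, smoothed, window))


def rate_cell_mean(
    forest: LineageForest,
    cell_id: str,
    schedule: PeriodSchedule,
    period: str,
    params: RateParams | None = None,
    window: tuple[float, float] | None = None,
) -> float:
    """Scalar window-mean r_cell; nan when no usable frame exists."""
    return rate_cell(forest, cell_id, schedule, period, params, window).window_mean


# ---------------------------------------------------------------------------
# subtree level


def subtree_size_series(
    forest: LineageForest, root_id: str, grid: np.ndarray
) -> np.ndarray:
    """Total area S(t) of the subtree under ``root_id`` on a frame grid.

    S is defined at a frame when every member alive there contributes a
    gridded area; a missing member frame propagates as NaN.  Frames before
    the root exists are NaN.
    """
    grid = np.asarray(grid, float)
    total = np.zeros(len(grid))
    covered = np.zeros(len(grid), dtype=int)
    alive = np.zeros(len(grid), dtype=int)
    root = forest[root_id]
    for cid in descendants_of(forest, root_id):
        cell = forest[cid]
        idx = _cell_frames(cell, grid)
        if len(idx) == 0:
            continue
        alive[idx] += 1
        vals = resample_area(cell.area_series[:, 0], cell.area_series[:, 1], grid[idx])
        ok = np.isfinite(vals)
        total[idx[ok]] += vals[ok]
        covered[idx[ok]] += 1
    out = np.where((alive > 0) & (covered == alive), total, np.nan)
    out[grid < root.start_time - 1e-9] = np.nan
    return out


def subtree_size(
    forest: LineageForest,
    root_id: str,
    t: float,
    schedule: PeriodSchedule,
    params: RateParams | None = None,
) -> float:
    """Total subtree area S(t) at a single frame time."""
    period = schedule.period_of(t)
    params = params or DEFAULT_RATE_PARAMS[period]
    grid = period_grid(schedule, period, params.dt_prime)
    j = int(np.argmin(np.abs(grid - t)))
    if abs(grid[j] - t) > 1e-6:
        raise DataError(f"t = {t} is not on the {period} analysis grid")
    return float(subtree_size_series(forest, root_id, grid[j : j + 1])[0])


def rate_subtree(
    forest: LineageForest,
    root_id: str,
    schedule: PeriodSchedule,
    period: str,
    params: RateParams | None = None,
    window: tuple[float, float] | None = None,
) -> RateSeries:
    """The cell-rate pipeline applied to the summed subtree area S(t)."""
    params = params or DEFAULT_RATE_PARAMS[period]
    grid = period_grid(schedule, period, params.dt_prime)
    S = subtree_size_series(forest, root_id, grid)
    # restrict to the contiguous span where the subtree exists
    exist = np.nonzero(np.isfinite(S))[0]
    if len(exist) == 0:
        return RateSeries(root_id, np.array([]), np.array([]), np.array([]), float("nan"))
    lo, hi = exist[0], exist[-1]
    times = grid[lo : hi + 1]
    S = S[lo : hi + 1]
    raw = instantaneous_rate(S, params)
    smoothed = moving_mean(raw, params.df)
    if window is None:
        window = schedule.span(period)
    return RateSeries(root_id, times, raw, smoothed, _window_mean(times, smoothed, window))


# ---------------------------------------------------------------------------
# lineage level


def rate_lineage(
    forest: LineageForest,
    cell_id: str,
    schedule: PeriodSchedule,
    period: str,
    params: RateParams | None = None,
    window: tuple[float, float] | None = None,
) -> RateSeries:
    """Retrospective size-increase rate along an ancestor chain.

    Each frame's rate is the instantaneous rate of whichever ancestor is
    alive at that frame, with the log-ratio and the moving mean confined to
    that ancestor's own series, so the size reset at division is excluded
    by construction.  The scalar is the mean of the smoothed values over
    the window frames, which weights the per-ancestor segment sums exactly
    as the chained-sum formulation does.
    """
    params = params or DEFAULT_RATE_PARAMS[period]
    p0, p1 = schedule.span(period)
    if window is None:
        window = (p0, p1)
    t0, t1 = window
    if t0 < p0 - 1e-9 or t1 > p1 + 1e-9:
        raise DataError(f"window {window} extends beyond the {period} period")
    chain = ancestors_of(forest, cell_id, t0, t1)
    grid = period_grid(schedule, period, params.dt_prime)
    seg_times: list[np.ndarray] = []
    seg_raw: list[np.ndarray] = []
    seg_smooth: list[np.ndarray] = []
    for aid in chain.cells:
        cell = forest[aid]
        idx = _cell_frames(cell, grid)
        if len(idx) == 0:
            continue
        times = grid[idx]
        areas = resample_area(cell.area_series[:, 0], cell.area_series[:, 1], times)
        raw = instantaneous_rate(areas, params)
        smoothed = moving_mean(raw, params.df)
        keep = (times >= t0 - 1e-9) & (times <= t1 + 1e-9)
        if not np.any(keep):
            continue
        seg_times.append(times[keep])
        seg_raw.append(raw[keep])
        seg_smooth.append(smoothed[keep])
    if not seg_times:
        return RateSeries(cell_id, np.array([]), np.array([]), np.array([]), float("nan"))
    times = np.concatenate(seg_times)
    raw = np.concatenate(seg_raw)
    smoothed = np.concatenate(seg_smooth)
    order = np.argsort(times, kind="stable")
    times, raw, smoothed = times[order], raw[order], smoothed[order]
    finite = np.isfinite(smoothed)
    mean = float(np.mean(smoothed[finite])) if np.any(finite) else float("nan")
    return RateSeries(cell_id, times, raw, smoothed, mean)


def generation_time(cell: CellRecord) -> float | None:
    """Duration from birth to division (min); None if either is unobserved."""
    if cell.birth_time is None or cell.division_time is None:
        return None
    return float(cell.division_time - cell.birth_time)
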