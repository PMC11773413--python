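"""Independent brute-force reference implementations.

Deliberately naive re-implementations of the tree queries and rate
estimators, written with explicit Python loops and no shared code with the
package internals, used as oracles in equivalence tests.
"""

from __future__ import annotations

import math

from microlineage.lineage import LineageForest, PeriodSchedule
from microlineage.rates import RateParams, DEFAULT_RATE_PARAMS


# ---------------------------------------------------------------------------
# tree queries


def naive_ancestor_chain(forest: LineageForest, cell_id: str, t_start: float,
                         t_end: float | None = None) -> list[str]:
    cell = forest[cell_id]
    if t_end is None:
        t_end = cell.end_time
    cur = cell
    while cur.start_time >= t_end and cur.parent_id is not None:
        cur = forest[cur.parent_id]
    chain = [cur.cell_id]
    while True:
        front = forest[chain[0]]
        if front.start_time <= t_start or front.parent_id is None:
            break
        chain = [front.parent_id] + chain
    return chain


def naive_subtree_at(forest: LineageForest, root_id: str, t: float) -> set[str]:
    out = set()
    for cid in forest.cells:
        cur = cid
        related = False
        while cur is not None:
            if cur == root_id:
                related = True
                break
            cur = forest[cur].parent_id
        if related and forest[cid].alive_at(t):
            out.add(cid)
    return out


def naive_generations_to_lca(forest: LineageForest, a: str, b: str) -> int | None:
    def ancestors(cid):
        out = {}
        cur, g = cid, 0
        while cur is not None:
            out[cur] = g
            cur = forest[cur].parent_id
            g += 1
        return out

    ua, ub = ancestors(a), ancestors(b)
    common = set(ua) & set(ub)
    if not common:
        return None
    return min(max(ua[c], ub[c]) for c in common)


def naive_generation_count(forest: LineageForest, cell_id: str,
                           window: tuple[float, float]) -> int:
    t0, t1 = window
    chain = naive_ancestor_chain(forest, cell_id, t0, t1)
    n = 0
    for cid in chain:
        d = forest[cid].division_time
        if d is not None and t0 < d < t1:
            n += 1
    return n


def naive_p_recovery(forest: LineageForest, starter: str, schedule: PeriodSchedule) -> int:
    rec0, rec1 = schedule.recovery
    d = forest[starter].division_time
    if d is None or not (rec0 <= d <= rec1):
        return 0
    return len(naive_subtree_at(forest, starter, rec1) - {starter})


# ---------------------------------------------------------------------------
# rates


def _grid(schedule: PeriodSchedule, period: str, dtp: float) -> list[float]:
    t0, t1 = schedule.span(period)
    out = []
    k = 0
    while t0 + k * dtp < t1 - 1e-9:
        out.append(t0 + k * dtp)
        k += 1
    if period == "recovery" and abs((t1 - t0) / dtp - round((t1 - t0) / dtp)) < 1e-9:
        out.append(t1)
    return out


def _alive(cell, t: float) -> bool:
    if t < cell.start_time - 1e-9:
        return False
    if cell.fate == "divided":
        return t < cell.division_time - 1e-9
    return t <= cell.end_time + 1e-9


def _lookup(cell, t: float, tol: float) -> float | None:
    best, bd = None, None
    for tt, aa in cell.area_series:
        d = abs(tt - t)
        if bd is None or d < bd:
            best, bd = aa, d
    if bd is None or bd > tol + 1e-9:
        return None
    return float(best)


def _pipeline(values: list[float | None], params: RateParams) -> list[float | None]:
    """raw log-ratio rates then truncated centered moving mean."""
    k = params.lag_frames
    n = len(values)
    raw: list[float | None] = [None] * n
    for i in range(n - k):
        if values[i] is not None and values[i + k] is not None:
            raw[i] = math.log(values[i + k] / values[i]) / params.dt
    h = (params.df - 1) // 2
    smooth: list[float | None] = [None] * n
    for i in range(n):
        if raw[i] is None:
            continue
        window = [raw[j] for j in range(max(0, i - h), min(n, i + h + 1)) if raw[j] is not None]
        smooth[i] = sum(window) / len(window)
    return smooth


def _window_mean(times: list[float], smooth: list[float | None],
                 window: tuple[float, float]) -> float | None:
    t0, t1 = window
    vals = [s for t, s in zip(times, smooth)
            if s is not None and t0 - 1e-9 <= t <= t1 + 1e-9]
    if not vals:
        return None
    return sum(vals) / len(vals)


def naive_rate_cell(forest: LineageForest, cell_id: str, schedule: PeriodSchedule,
                    period: str, params: RateParams | None = None,
                    window: tuple[float, float] | None = None) -> float | None:
    params = params or DEFAULT_RATE_PARAMS[period]
    cell = forest[cell_id]
    times = [t for t in _grid(schedule, period, params.dt_prime) if _alive(cell, t)]
    if not times:
        return None
    vals = [_lookup(cell, t, params.dt_prime / 2) for t in times]
    smooth = _pipeline(vals, params)
    return _window_mean(times, smooth, window or schedule.span(period))


def naive_rate_subtree(forest: LineageForest, root_id: str, schedule: PeriodSchedule,
                       period: str, params: RateParams | None = None,
                       window: tuple[float, float] | None = None) -> float | None:
    params = params or DEFAULT_RATE_PARAMS[period]
    grid = _grid(schedule, period, params.dt_prime)
    S: list[float | None] = []
    for t in grid:
        members = [forest[c] for c in naive_subtree_at(forest, root_id, t)]
        if not members or t < forest[root_id].start_time - 1e-9:
            S.append(None)
            continue
        areas = [_lookup(m, t, params.dt_prime / 2) for m in members]
        S.append(None if any(a is None for a in areas) else sum(areas))
    defined = [i for i, s in enumerate(S) if s is not None]
    if not defined:
        return None
    lo, hi = defined[0], defined[-1]
    times = grid[lo : hi + 1]
    smooth = _pipeline(S[lo : hi + 1], params)
    return _window_mean(times, smooth, window or schedule.span(period))


def naive_rate_lineage(forest: LineageForest, cell_id: str, schedule: PeriodSchedule,
                       period: str, params: RateParams | None = None,
                       window: tuple[float, float] | None = None) -> float | None:
    params = params or DEFAULT_RATE_PARAMS[period]
    window = window or schedule.span(period)
    t0, t1 = window
    grid = _grid(schedule, period, params.dt_prime)
    collected: list[float] = []
    for aid in naive_ancestor_chain(forest, cell_id, t0, t1):
        cell = forest[aid]
        times = [t for t in grid if _alive(cell, t)]
        if not times:
            continue
        vals = [_lookup(cell, t, params.dt_prime / 2) for t in times]
        smooth = _pipeline(vals, params)
        for t, s in zip(times, smooth):
            if s is not None and t0 - 1e-9 <= t <= t1 + 1e-9:
                collected.append(s)
    if not collected:
        return None
    return sum(collected) / len(collected)
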