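"""Starter-cell regrowth analysis and colony heterogeneity statistics.

A *starter cell* is a cell alive at the beginning of the recovery period;
its lag time tau is the delay to its first division after nutrient
resupply, and p_recovery counts the progeny it leaves at the end of the
recovery window (0 for undivided starters).  Starters are classed as
non-regrowers (p = 0), normal-regrowers (0 < p <= 7) or hyper-regrowers
(p > 7; empirically the top ~10% of starters).

The module also provides the per-colony heterogeneity summaries used to
compare the nutrient periods: CV of per-cell rates and generation times,
the mean pairwise coefficient of relationship, the lysis fraction, and the
cousin-subtree rate CV (pairs of subtrees whose roots are first cousins,
so that relatedness is held at CR = 0.25 while growth is compared).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .lineage import (
    LineageForest,
    PeriodSchedule,
    ancestors_of,
    coefficient_of_relationship,
    generations_to_common_ancestor,
    NoCommonAncestorError,
)
from .rates import RateParams, generation_time, rate_cell_mean, rate_subtree

__all__ = [
    "RegrowthRecord",
    "HeterogeneitySummary",
    "identify_starters",
    "lag_time",
    "p_recovery",
    "tau_start",
    "regrowth_records",
    "classify_regrowers",
    "cumulative_progeny_curve",
    "cv_within_microcolony",
    "heterogeneity_summary",
    "mean_pairwise_CR",
    "median_generation_time",
    "cousin_sets",
    "cousin_reference_window",
    "cousin_subtree_cv",
    "compare_groups",
]

REGROWER_CLASSES = ("non", "normal", "hyper")


@dataclass
class RegrowthRecord:
    """Per-starter summary: lag time, progeny count, class, cell-cycle phase."""

    starter_id: str
    microcolony_id: str
    tau: float | None
    p_recovery: int
    regrower_class: str | None = None
    tau_start: float | None = None

    def __post_init__(self) -> None:
        if (self.tau is None) != (self.p_recovery == 0):
            raise ValueError(
                f"starter {self.starter_id}: tau must be absent iff p_recovery = 0"
            )


@dataclass
class HeterogeneitySummary:
    microcolony_id: str
    period: str
    cv_rate: float
    cv_gentime: float
    mean_CR: float
    lysis_fraction: float


# ---------------------------------------------------------------------------
# starters


def identify_starters(forest: LineageForest, schedule: PeriodSchedule) -> list[str]:
    """Cells alive at the start of the recovery period, in deterministic order."""
    t_r = schedule.recovery[0]
    return sorted(cid for cid in forest.alive_at(t_r))


def lag_time(forest: LineageForest, starter_id: str, schedule: PeriodSchedule) -> float | None:
    """Time from nutrient resupply to the starter's first division, or None."""
    t_r0, t_r1 = schedule.recovery
    d = forest[starter_id].division_time
    if d is None or not (t_r0 <= d <= t_r1):
        return None
    return float(d - t_r0)


def p_recovery(forest: LineageForest, starter_id: str, schedule: PeriodSchedule) -> int:
    """Progeny cells alive at recovery end; 0 for an undivided starter."""
    if lag_time(forest, starter_id, schedule) is None:
        return 0
    t_end = schedule.recovery[1]
    from .lineage import subtree_cells_at

    alive = subtree_cells_at(forest, starter_id, t_end)
    alive.discard(starter_id)
    return len(alive)


def tau_start(forest: LineageForest, starter_id: str, schedule: PeriodSchedule) -> float | None:
    """Minutes from the lineage's last high-nutrient division to the downshift.

    Estimates the cell-cycle phase at the nutrient downshift; None when the
    lineage recorded no division during the high-nutrient period.
    """
    t_low = schedule.low[0]
    chain = ancestors_of(forest, starter_id, schedule.high[0], t_low)
    last = None
    for cid in chain.cells:
        d = forest[cid].division_time
        if d is not None and d <= t_low and (last is None or d > last):
            last = d
    if last is None:
        return None
    return float(t_low - last)


def regrowth_records(forest: LineageForest, schedule: PeriodSchedule) -> list[RegrowthRecord]:
    """Build one :class:`RegrowthRecord` per starter cell of a colony."""
    out = []
    for sid in identify_starters(forest, schedule):
        tau = lag_time(forest, sid, schedule)
        p = p_recovery(forest, sid, schedule)
        if p == 0:
            tau = None  # divided but left no live progeny: counts as non-regrower
        out.append(
            RegrowthRecord(
                starter_id=sid,
                microcolony_id=forest.microcolony_id,
                tau=tau,
                p_recovery=p,
                tau_start=tau_start(forest, sid, schedule),
            )
        )
    return out


def classify_regrowers(
    records: list[RegrowthRecord],
    mode: str = "fixed_threshold",
    threshold: int = 7,
    top_fraction: float = 0.10,
) -> list[RegrowthRecord]:
    """Assign non/normal/hyper classes in place (and return the records).

    ``fixed_threshold`` uses the published cuts (non: p = 0; normal:
    0 < p <= threshold; hyper: p > threshold).  ``top_fraction`` sets the
    hyper cut at the empirical (1 - q) quantile of p_recovery, ties
    included above the cut; non-regrowers are always p = 0.
    """
    if not records:
        raise ValueError("no starter records to classify")
    if mode == "fixed_threshold":
        theta = float(threshold)
        strict = True
    elif mode == "top_fraction":
        p = np.array([r.p_recovery for r in records], float)
        theta = float(np.quantile(p, 1.0 - top_fraction))
        strict = False  # ties at the quantile are included above the cut
    else:
        raise ValueError(f"unknown classification mode {mode!r}")
    for r in records:
        if r.p_recovery == 0:
            r.regrower_class = "non"
        elif (r.p_recovery > theta) if strict else (r.p_recovery >= theta):
            r.regrower_class = "hyper"
        else:
            r.regrower_class = "normal"
    return records


def cumulative_progeny_curve(records: list[RegrowthRecord]) -> np.ndarray:
    """Cumulative progeny fraction with starters sorted by descending p_recovery."""
    p = np.sort(np.array([r.p_recovery for r in records], float))[::-1]
    total = p.sum()
    if total <= 0:
        raise ValueError("total progeny is zero; curve undefined")
    return np.cumsum(p) / total


# ---------------------------------------------------------------------------
# heterogeneity statistics


def _eligible_rate_cells(
    forest: LineageForest, schedule: PeriodSchedule, period: str
) -> list[str]:
    """Cells whose r_cell is estimated in a period.

    Lysed cells are excluded from rate statistics (they still contribute to
    S(t) until lysis); cells born before the observation start are excluded
    from the first period, as their birth is left-censored.
    """
    t0, t1 = schedule.span(period)
    out = []
    first_period = period == schedule.PERIODS[0]
    for cid, c in forest.cells.items():
        if c.fate == "lysed":
            continue
        if first_period and c.birth_time is None:
            continue
        if c.start_time < t1 and c.end_time > t0:
            out.append(cid)
    return sorted(out)


def cv_within_microcolony(
    forest: LineageForest,
    schedule: PeriodSchedule,
    period: str,
    quantity: str = "rate",
    params: RateParams | None = None,
) -> float:
    """CV (sample sd / mean) of r_cell or generation time within one colony."""
    if quantity == "rate":
        vals = [
            rate_cell_mean(forest, cid, schedule, period, params)
            for cid in _eligible_rate_cells(forest, schedule, period)
        ]
    elif quantity == "gentime":
        t0, t1 = schedule.span(period)
        vals = []
        for c in forest.cells.values():
            g = generation_time(c)
            if g is not None and c.birth_time >= t0 and c.division_time <= t1:
                vals.append(g)
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    vals = np.array([v for v in vals if v is not None and np.isfinite(v)], float)
    if len(vals) < 2:
        return float("nan")
    m = vals.mean()
    if m <= 0:
        return float("nan")
    return float(vals.std(ddof=1) / m)


def mean_pairwise_CR(forest: LineageForest, t: float) -> float:
    """Average coefficient of relationship over unordered pairs alive at ``t``.

    Pairs in different trees of the forest have no common ancestor and
    contribute CR = 0.
    """
    alive = sorted(forest.alive_at(t))
    if len(alive) < 2:
        raise ValueError("need at least two cells alive")
    crs = []
    for a, b in itertools.combinations(alive, 2):
        try:
            n = generations_to_common_ancestor(forest, a, b)
            crs.append(coefficient_of_relationship(n))
        except NoCommonAncestorError:
            crs.append(0.0)
    return float(np.mean(crs))


def lysis_fraction(forest: LineageForest) -> float:
    n = len(forest)
    return sum(1 for c in forest.cells.values() if c.fate == "lysed") / n


def heterogeneity_summary(
    forest: LineageForest, schedule: PeriodSchedule, period: str
) -> HeterogeneitySummary:
    t0, t1 = schedule.span(period)
    return HeterogeneitySummary(
        microcolony_id=forest.microcolony_id,
        period=period,
        cv_rate=cv_within_microcolony(forest, schedule, period, "rate"),
        cv_gentime=cv_within_microcolony(forest, schedule, period, "gentime"),
        mean_CR=mean_pairwise_CR(forest, 0.5 * (t0 + t1)),
        lysis_fraction=lysis_fraction(forest),
    )


def median_generation_time(
    forests: list[LineageForest], schedule: PeriodSchedule, period: str
) -> float:
    """Median generation time over all cells born and divided within a period."""
    t0, t1 = schedule.span(period)
    vals = []
    for f in forests:
        for c in f.cells.values():
            g = generation_time(c)
            if g is not None and c.birth_time >= t0 and c.division_time <= t1:
                vals.append(g)
    if not vals:
        return float("nan")
    return float(np.median(vals))


# ---------------------------------------------------------------------------
# cousin subtrees


def cousin_sets(forest: LineageForest, t_ref: float) -> list[tuple[str, str]]:
    """Pairs of first-cousin subtree roots alive at ``t_ref``.

    For every cell g whose two children both divided, the alive-at-t_ref
    grandchildren on each side are candidate roots; a qualifying set takes
    the earliest-born root from each side, so that relatedness within the
    set is exactly CR = 0.25.  Sides with no live grandchild disqualify g.
    """
    out = []
    for gid in sorted(forest.cells):
        kids = forest.children_of(gid)
        if len(kids) != 2:
            continue
        sides = []
        for kid in kids:
            cand = [c for c in forest.children_of(kid) if forest[c].alive_at(t_ref)]
            if not cand:
                break
            cand.sort(key=lambda c: (forest[c].start_time, c))
            sides.append(cand[0])
        if len(sides) == 2:
            out.append((sides[0], sides[1]))
    return out


def cousin_reference_window(
    forests: list[LineageForest], schedule: PeriodSchedule, period: str
) -> tuple[float, float]:
    """Reference time and window length for cousin-subtree growth comparison.

    The window is twice the dataset's median generation time of the period
    (clamped to the period length).  In the low-nutrient period the window
    starts at the downshift; in the high-nutrient period it is right-aligned
    so that it ends at the downshift.
    """
    t0, t1 = schedule.span(period)
    med = median_generation_time(forests, schedule, period)
    w = 2.0 * med if np.isfinite(med) else (t1 - t0)
    w = min(w, t1 - t0)
    t_ref = t0 if period != "high" else max(t0, t1 - w)
    return t_ref, w


def cousin_subtree_cv(
    forest: LineageForest,
    schedule: PeriodSchedule,
    period: str,
    t_ref: float | None = None,
    window_length: float | None = None,
    params: RateParams | None = None,
) -> list[float]:
    """Within-set CV of r_subtree for each qualifying cousin pair of a colony."""
    if t_ref is None or window_length is None:
        t_ref, window_length = cousin_reference_window([forest], schedule, period)
    t1 = min(t_ref + window_length, schedule.span(period)[1])
    out = []
    for a, b in cousin_sets(forest, t_ref):
        ra = rate_subtree(forest, a, schedule, period, params, window=(t_ref, t1))
        rb = rate_subtree(forest, b, schedule, period, params, window=(t_ref, t1))
        vals = np.array([ra.window_mean, rb.window_mean])
        if not np.all(np.isfinite(vals)) or vals.mean() <= 0:
            continue
        out.append(float(vals.std(ddof=1) / vals.mean()))
    return out


# ---------------------------------------------------------------------------
# group comparisons


def compare_groups(values_by_class: dict[str, np.ndarray], alpha: float = 0.05) -> dict:
    """Omnibus Kruskal-Wallis plus all-pairs Mann-Whitney with Holm correction.

    Returns test statistics, adjusted p-values, and compact significance
    letters (groups sharing a letter are not significantly different).  The
    all-pairs rank-sum + Holm post hoc stands in for Steel-Dwass and is
    named in the output metadata.
    """
    groups = {
        k: np.asarray(v, float)
        for k, v in values_by_class.items()
        if len(np.asarray(v, float)) >= 2
    }
    dropped = sorted(set(values_by_class) - set(groups))
    if len(groups) < 2:
        raise ValueError("need at least two groups with >= 2 values")
    names = sorted(groups)
    H, p_omni = stats.kruskal(*[groups[k] for k in names])
    pairs = list(itertools.combinations(names, 2))
    raw_p = []
    for a, b in pairs:
        if np.ptp(np.concatenate([groups[a], groups[b]])) == 0:
            raw_p.append(1.0)
        else:
            raw_p.append(float(stats.mannwhitneyu(groups[a], groups[b]).pvalue))
    # Holm step-down adjustment
    order = np.argsort(raw_p)
    m = len(raw_p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * raw_p[i])
        adj[i] = min(1.0, running)
    sig = {pairs[i]: adj[i] < alpha for i in range(m)}
    letters = _significance_letters(names, sig)
    return {
        "omnibus": {"test": "kruskal-wallis", "H": float(H), "p": float(p_omni)},
        "posthoc": {
            "test": "mann-whitney + holm (steel-dwass substitute)",
            "pairs": {f"{a}|{b}": float(adj[i]) for i, (a, b) in enumerate(pairs)},
        },
        "letters": letters,
        "dropped_groups": dropped,
        "alpha": alpha,
    }


def _significance_letters(names: list[str], sig: dict[tuple[str, str], bool]) -> dict[str, str]:
    """Compact letter display: groups share a letter iff not significantly different."""
    def differs(a: str, b: str) -> bool:
        return sig.get((a, b), sig.get((b, a), False))

    blocks: list[set[str]] = []
    for name in names:
        placed = False
        for block in blocks:
            if all(not differs(name, other) for other in block):
                block.add(name)
                placed = True
        if not placed:
            blocks.append({name})
    # drop blocks fully contained in another
    blocks = [b for b in blocks if not any(b < other for other in blocks)]
    letters = {n: "" for n in names}
    for i, block in enumerate(blocks):
        ch = chr(ord("a") + i)
        for n in sorted(block):
            letters[n] += ch
    return letters
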