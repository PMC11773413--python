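"""Permutation test for genealogical clustering of reproductive success.

Starter cells are grouped into *subtrees*: the subpopulations descending
from single cells alive at the low-nutrient onset.  Each subtree's
normalized p_recovery is its total recovery progeny divided by its number
of starters.  Highly reproductive subtrees are outliers above
Q3 + 1.5 * IQR of the observed normalized values.  The null distribution
is built by randomly reassigning the (starter, p_recovery) units to the
starter slots within each microcolony while keeping the subtree slot
structure fixed, pooling subtrees across colonies, and counting outliers
against the cutoff computed once from the observed data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .lineage import (
    LineageForest,
    PeriodSchedule,
    ancestors_of,
    generations_to_common_ancestor,
    NoCommonAncestorError,
)
from .regrowth import RegrowthRecord, regrowth_records

__all__ = [
    "SubtreeStats",
    "ShuffleResult",
    "subtree_stats",
    "outlier_threshold",
    "ColonySlots",
    "colony_slots",
    "shuffle_once",
    "shuffle_null",
    "relatedness_correlation",
]


@dataclass
class SubtreeStats:
    """One subtree rooted at a cell alive at the low-nutrient onset."""

    microcolony_id: str
    subtree_root: str
    n_starters: int
    total_progeny: int

    def __post_init__(self) -> None:
        if self.n_starters < 1:
            raise ValueError("retained subtrees need >= 1 starter")

    @property
    def normalized_p(self) -> float:
        return self.total_progeny / self.n_starters


@dataclass
class ShuffleResult:
    observed_outlier_count: int
    null_counts: np.ndarray
    n_trials: int
    threshold_value: float
    threshold_mode: str
    empirical_p: float
    degenerate_threshold: bool = False


def _subtree_root_of(forest: LineageForest, starter_id: str, t_onset: float) -> str:
    """The starter's ancestor alive at the low-nutrient onset."""
    chain = ancestors_of(forest, starter_id, t_onset, t_onset + 1e-9)
    return chain.cells[0]


def subtree_stats(
    forest: LineageForest,
    schedule: PeriodSchedule,
    records: list[RegrowthRecord] | None = None,
) -> list[SubtreeStats]:
    """Per-subtree starter counts and total progeny for one colony.

    Every starter is assigned to exactly one subtree (its unique ancestor
    alive at the onset); onset cells whose descendants all lysed leave no
    entry.
    """
    if records is None:
        records = regrowth_records(forest, schedule)
    t_onset = schedule.low[0]
    agg: dict[str, list[int]] = {}
    for r in records:
        root = _subtree_root_of(forest, r.starter_id, t_onset)
        agg.setdefault(root, []).append(r.p_recovery)
    return [
        SubtreeStats(
            microcolony_id=forest.microcolony_id,
            subtree_root=root,
            n_starters=len(ps),
            total_progeny=int(sum(ps)),
        )
        for root, ps in sorted(agg.items())
    ]


def outlier_threshold(normalized_p: np.ndarray) -> tuple[float, bool]:
    """Tukey cutoff Q3 + 1.5 * IQR (linear-interpolation quantiles).

    Returns ``(cutoff, degenerate)``; with IQR = 0 the cutoff degenerates
    to Q3 and is flagged.
    """
    v = np.asarray(normalized_p, float)
    if len(v) < 4:
        raise ValueError("need >= 4 subtrees for an IQR-based cutoff")
    q1, q3 = np.quantile(v, [0.25, 0.75])  # numpy default: linear, "type 7"
    iqr = q3 - q1
    return float(q3 + 1.5 * iqr), bool(iqr == 0)


@dataclass
class ColonySlots:
    """Flat shuffle arrays for one microcolony.

    ``slot[i]`` is the subtree index of starter slot ``i``; ``p[i]`` the
    progeny count currently occupying that slot; ``sizes`` the starter
    count per subtree.  Shuffling permutes ``p`` while ``slot`` stays put.
    """

    microcolony_id: str
    p: np.ndarray
    slot: np.ndarray
    sizes: np.ndarray

    def normalized(self, p: np.ndarray | None = None) -> np.ndarray:
        p = self.p if p is None else p
        return np.bincount(self.slot, weights=p, minlength=len(self.sizes)) / self.sizes


def colony_slots(
    forest: LineageForest,
    schedule: PeriodSchedule,
    records: list[RegrowthRecord] | None = None,
) -> ColonySlots:
    if records is None:
        records = regrowth_records(forest, schedule)
    t_onset = schedule.low[0]
    roots = []
    p = []
    for r in records:
        roots.append(_subtree_root_of(forest, r.starter_id, t_onset))
        p.append(r.p_recovery)
    uniq = sorted(set(roots))
    index = {r: i for i, r in enumerate(uniq)}
    slot = np.array([index[r] for r in roots], dtype=int)
    return ColonySlots(
        microcolony_id=forest.microcolony_id,
        p=np.array(p, dtype=float),
        slot=slot,
        sizes=np.bincount(slot, minlength=len(uniq)).astype(float),
    )


def shuffle_once(slots: ColonySlots, rng: np.random.Generator) -> np.ndarray:
    """One within-colony shuffle; returns the shuffled normalized_p values.

    Single-starter colonies are returned unchanged (nothing to permute).
    """
    if len(slots.p) < 2:
        return slots.normalized()
    return slots.normalized(rng.permutation(slots.p))


def shuffle_null(
    forests: list[LineageForest],
    schedule: PeriodSchedule,
    n_trials: int = 10_000,
    threshold: str = "fixed",
    seed: int | np.random.Generator = 0,
    records_by_colony: dict[str, list[RegrowthRecord]] | None = None,
) -> ShuffleResult:
    """Shuffling null for the number of highly reproductive subtrees.

    Per trial every microcolony is shuffled independently, subtrees are
    pooled across colonies, and those with normalized p_recovery strictly
    above the cutoff are counted.  ``threshold='fixed'`` (default) holds
    the observed-data cutoff across trials; ``'recomputed'`` re-derives it
    per trial (sensitivity mode).  The empirical p-value uses the
    (b + 1) / (n + 1) convention.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if threshold not in ("fixed", "recomputed"):
        raise ValueError(f"unknown threshold mode {threshold!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    slots = [
        colony_slots(
            f, schedule, records_by_colony.get(f.microcolony_id) if records_by_colony else None
        )
        for f in forests
    ]
    slots = [s for s in slots if len(s.p) > 0]
    observed = np.concatenate([s.normalized() for s in slots])
    cutoff, degenerate = outlier_threshold(observed)
    observed_count = int(np.sum(observed > cutoff))
    null_counts = np.empty(n_trials, dtype=int)
    for i in range(n_trials):
        pooled = np.concatenate([shuffle_once(s, rng) for s in slots])
        cut = cutoff if threshold == "fixed" else outlier_threshold(pooled)[0]
        null_counts[i] = int(np.sum(pooled > cut))
    b = int(np.sum(null_counts >= observed_count))
    return ShuffleResult(
        observed_outlier_count=observed_count,
        null_counts=null_counts,
        n_trials=n_trials,
        threshold_value=cutoff,
        threshold_mode=threshold,
        empirical_p=(b + 1) / (n_trials + 1),
        degenerate_threshold=degenerate,
    )


def relatedness_correlation(
    records: list[RegrowthRecord],
    forest: LineageForest,
    min_pairs: int = 10,
    max_n: int = 8,
) -> dict[int, dict]:
    """Rank correlation of p_recovery between starter pairs, binned by CR.

    For each generation count n (CR = 2^-n) with at least ``min_pairs``
    starter pairs, the Spearman correlation is computed over the
    symmetrized pair list.  Bins with constant phenotype are flagged
    (correlation undefined).
    """
    ids = [r.starter_id for r in records]
    p = {r.starter_id: r.p_recovery for r in records}
    bins: dict[int, list[tuple[float, float]]] = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            try:
                n = generations_to_common_ancestor(forest, ids[i], ids[j])
            except NoCommonAncestorError:
                continue
            if n <= max_n:
                bins.setdefault(n, []).append((p[ids[i]], p[ids[j]]))
    out: dict[int, dict] = {}
    for n, pairs in sorted(bins.items()):
        if len(pairs) < min_pairs:
            continue
        x = np.array([a for a, b in pairs] + [b for a, b in pairs], float)
        y = np.array([b for a, b in pairs] + [a for a, b in pairs], float)
        entry = {"cr": 2.0 ** (-n), "n_pairs": len(pairs)}
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            entry.update(rho=float("nan"), undefined=True)
        else:
            entry.update(rho=float(stats.spearmanr(x, y).statistic), undefined=False)
        out[n] = entry
    return out
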