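"""Triplet decomposition of phenotype similarity: genealogy vs. space.

Closely related cells tend to be spatial neighbours in a microcolony, so a
raw correlation between relatedness and phenotype similarity confounds the
two.  The decomposition compares each focal starter against matched
partners at a single reference snapshot (the end of the low-nutrient
period):

* genealogy contrast, delta_ED - delta_CR: the closest relative (CR) and a
  cell at the *same distance* but lower relatedness (ED).  A positive
  median means relatives are more similar than equally distant non-relatives.
* spatial contrast, delta_ER - delta_NB: the closest adjacent neighbour
  (NB) and the most distant cell at the *same relatedness* (ER).  A
  positive median means neighbours are more similar than equally related
  distant cells.

delta_* = |X_focal - X_partner| with X = p_recovery by default.  Triplets
whose partners cannot be constructed are dropped with a machine-readable
reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lineage import (
    LineageForest,
    PeriodSchedule,
    generations_to_common_ancestor,
    NoCommonAncestorError,
)
from .regrowth import RegrowthRecord

__all__ = [
    "SpatialSnapshot",
    "build_snapshot",
    "closest_relative",
    "closest_neighbor",
    "equidistant_cell",
    "equally_related_cell",
    "triplet_contrasts",
    "contrast_tests",
]

#: rod aspect ratio (length : width) used to derive cell width from area
DEFAULT_ASPECT = 4.0

#: default tolerance on |d_ED - d_CR| as a fraction of d_CR
DEFAULT_TOLERANCE = 0.15

#: adjacency rule: boundary gap within this multiple of the mean cell width
ADJACENCY_WIDTH_FACTOR = 0.75


@dataclass
class SpatialSnapshot:
    """Starter positions and effective widths at a single reference time."""

    time: float
    ids: list[str]
    pos: np.ndarray    # (m, 2) centroids, um
    width: np.ndarray  # (m,) effective rod widths, um

    def __post_init__(self) -> None:
        self.index = {cid: i for i, cid in enumerate(self.ids)}

    def distance(self, a: str, b: str) -> float:
        return float(np.linalg.norm(self.pos[self.index[a]] - self.pos[self.index[b]]))


def build_snapshot(
    forest: LineageForest,
    cell_ids: list[str],
    t: float,
    aspect: float = DEFAULT_ASPECT,
) -> SpatialSnapshot:
    """Snapshot of the given cells at time ``t``.

    Positions come from the centroid frame nearest to ``t``; the effective
    width assumes a rod with the given length:width aspect, so
    ``width = sqrt(area / aspect)``.
    """
    pos = np.empty((len(cell_ids), 2))
    width = np.empty(len(cell_ids))
    for i, cid in enumerate(cell_ids):
        c = forest[cid]
        if c.centroid_series is None:
            raise ValueError(f"cell {cid!r} has no centroid series")
        j = int(np.argmin(np.abs(c.centroid_series[:, 0] - t)))
        pos[i] = c.centroid_series[j, 1:3]
        ja = int(np.argmin(np.abs(c.area_series[:, 0] - t)))
        width[i] = np.sqrt(c.area_series[ja, 1] / aspect)
    return SpatialSnapshot(time=t, ids=list(cell_ids), pos=pos, width=width)


def _relatedness(forest: LineageForest, a: str, b: str) -> int | None:
    try:
        return generations_to_common_ancestor(forest, a, b)
    except NoCommonAncestorError:
        return None


def closest_relative(
    forest: LineageForest, snapshot: SpatialSnapshot, focal: str
) -> str | None:
    """The genealogically closest other starter (smallest n; ties by distance).

    When both members of a literal sister pair are starters this returns
    the sister; otherwise it generalizes to the starter with the smallest
    generation count to the focal.  None if no other starter shares an
    ancestor.
    """
    best: tuple[int, float, str] | None = None
    for other in snapshot.ids:
        if other == focal:
            continue
        n = _relatedness(forest, focal, other)
        if n is None:
            continue
        key = (n, snapshot.distance(focal, other), other)
        if best is None or key < best:
            best = key
    return best[2] if best else None


def _adjacent(snapshot: SpatialSnapshot, cell: str) -> list[str]:
    """Cells directly adjacent to ``cell``: boundary gap (center distance
    minus the two half-widths) within 3/4 of the pair's mean width."""
    i = snapshot.index[cell]
    d = np.linalg.norm(snapshot.pos - snapshot.pos[i], axis=1)
    halfw = 0.5 * (snapshot.width + snapshot.width[i])
    gap = d - halfw
    limit = ADJACENCY_WIDTH_FACTOR * 0.5 * (snapshot.width + snapshot.width[i])
    out = [snapshot.ids[j] for j in np.nonzero(gap <= limit)[0] if snapshot.ids[j] != cell]
    return out


def closest_neighbor(snapshot: SpatialSnapshot, focal: str) -> str | None:
    """The adjacent cell with the smallest center-to-center distance."""
    cand = _adjacent(snapshot, focal)
    if not cand:
        return None
    return min(cand, key=lambda c: (snapshot.distance(focal, c), c))


def equidistant_cell(
    snapshot: SpatialSnapshot,
    focal: str,
    relative: str,
    tolerance: float = DEFAULT_TOLERANCE,
) -> str | None:
    """A neighbour of the closest relative at distance ~d_CR from the focal.

    Among cells adjacent to the relative (excluding the focal and the
    relative), the one minimizing |d_ED - d_CR|, accepted only when the
    mismatch is within ``tolerance * d_CR``.
    """
    d_cr = snapshot.distance(focal, relative)
    cand = [c for c in _adjacent(snapshot, relative) if c not in (focal, relative)]
    if not cand:
        return None
    best = min(cand, key=lambda c: (abs(snapshot.distance(focal, c) - d_cr), c))
    if abs(snapshot.distance(focal, best) - d_cr) > tolerance * d_cr:
        return None
    return best


def equally_related_cell(
    forest: LineageForest, snapshot: SpatialSnapshot, focal: str, neighbor: str
) -> str | None:
    """The most distant starter with the same relatedness to the focal as
    the closest neighbour; None when the neighbour is the only such cell."""
    n_ref = _relatedness(forest, focal, neighbor)
    if n_ref is None:
        return None
    best: tuple[float, str] | None = None
    for other in snapshot.ids:
        if other in (focal, neighbor):
            continue
        if _relatedness(forest, focal, other) != n_ref:
            continue
        key = (-snapshot.distance(focal, other), other)
        if best is None or key < best:
            best = key
    return best[1] if best else None


def triplet_contrasts(
    records: list[RegrowthRecord],
    forest: LineageForest,
    schedule: PeriodSchedule,
    snapshot: SpatialSnapshot | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
    aspect: float = DEFAULT_ASPECT,
) -> pd.DataFrame:
    """Per-focal genealogy and spatial triplets for one colony.

    Returns a tidy table with one row per (focal, kind) attempt; dropped
    triplets carry a ``drop_reason`` and NaN contrast.  ``kind`` is
    ``genealogy`` (delta_ED - delta_CR) or ``spatial`` (delta_ER - delta_NB).
    """
    ids = [r.starter_id for r in records]
    X = {r.starter_id: float(r.p_recovery) for r in records}
    if snapshot is None:
        snapshot = build_snapshot(forest, ids, schedule.low[1], aspect)
    rows = []

    def row(focal, kind, partner_a, partner_b, reason):
        da = abs(X[focal] - X[partner_a]) if partner_a else np.nan
        db = abs(X[focal] - X[partner_b]) if partner_b else np.nan
        rows.append(
            {
                "microcolony_id": forest.microcolony_id,
                "focal": focal,
                "kind": kind,
                "partner_a": partner_a,
                "partner_b": partner_b,
                "delta_a": da,
                "delta_b": db,
                "contrast": db - da if partner_a and partner_b else np.nan,
                "drop_reason": reason,
            }
        )

    for focal in ids:
        rel = closest_relative(forest, snapshot, focal)
        if rel is None:
            row(focal, "genealogy", None, None, "no_related_starter")
        else:
            ed = equidistant_cell(snapshot, focal, rel, tolerance)
            if ed is None:
                row(focal, "genealogy", rel, None, "no_equidistant_candidate")
            else:
                row(focal, "genealogy", rel, ed, "")
        nb = closest_neighbor(snapshot, focal)
        if nb is None:
            row(focal, "spatial", None, None, "no_adjacent_cell")
        else:
            er = equally_related_cell(forest, snapshot, focal, nb)
            if er is None:
                row(focal, "spatial", nb, None, "no_equally_related_cell")
            else:
                row(focal, "spatial", nb, er, "")
    return pd.DataFrame(rows)


def contrast_tests(triplets: pd.DataFrame, alpha: float = 0.05) -> dict:
    """One-sample signed-rank tests of the two contrast families.

    The genealogy contrast is tested one-sided for median > 0 (relatives
    more similar than equidistant cells); the spatial contrast two-sided
    against 0.  All-zero contrast vectors give p = 1 (no signal).
    """
    out = {}
    for kind, alternative in (("genealogy", "greater"), ("spatial", "two-sided")):
        v = triplets.loc[
            (triplets["kind"] == kind) & triplets["contrast"].notna(), "contrast"
        ].to_numpy(float)
        entry = {"n": int(len(v)), "median": float(np.median(v)) if len(v) else float("nan")}
        nonzero = v[v != 0]
        if len(nonzero) == 0:
            entry.update(p=1.0, statistic=float("nan"))
        else:
            res = stats.wilcoxon(v, alternative=alternative, zero_method="wilcox")
            entry.update(p=float(res.pvalue), statistic=float(res.statistic))
        entry["significant"] = entry["p"] < alpha
        out[kind] = entry
    out["alpha"] = alpha
    return out
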