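"""Core data model for tracked cells and lineage forests.

A microcolony observed by time-lapse microscopy is represented as a forest of
strict binary trees: each tracked cell is a node holding its parentage, birth
and division times, fate, and per-frame area / centroid series.  Every
downstream stage (growth-rate estimation, regrowth analysis, permutation
tests, spatial decomposition) queries the forest through the functions in
this module.

Conventions
-----------
* Time is a real-valued minute axis.  A cell present at observation start has
  ``birth_time = None``; its effective start is its first observed frame.
* A cell is *alive* at time ``t`` if ``start <= t`` and, for divided cells,
  ``t < division_time``; lysed and censored cells count as alive up to and
  including their last observed frame.
* Division is strictly binary: a divided cell has exactly two children whose
  birth time equals the parent's division time.  Tracking artifacts that
  violate this are rejected at ingest, never repaired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "FATES",
    "LineageError",
    "StructuralError",
    "DataError",
    "NoCommonAncestorError",
    "CellRecord",
    "PeriodSchedule",
    "LineageForest",
    "build_forest",
    "AncestorChain",
    "ancestors_of",
    "subtree_cells_at",
    "descendants_of",
    "generations_to_common_ancestor",
    "coefficient_of_relationship",
    "number_of_generations",
]

FATES = ("divided", "lysed", "censored")


class LineageError(ValueError):
    """Base class for lineage data problems."""


class StructuralError(LineageError):
    """Forest topology violates the strict-binary-tree contract."""


class DataError(LineageError):
    """Per-cell fields or time series violate their invariants."""


class NoCommonAncestorError(LineageError):
    """Two cells share no ancestor (different roots).

    Callers computing a coefficient of relationship treat this as CR = 0.
    """


@dataclass
class CellRecord:
    """One tracked cell: a branch of the lineage tree from birth to division.

    ``area_series`` is an ``(n, 2)`` array of ``(time_min, area_um2)`` rows;
    ``centroid_series`` is ``(n, 3)`` of ``(time_min, x_um, y_um)`` or ``None``
    when positions were not tracked.
    """

    cell_id: str
    microcolony_id: str
    parent_id: str | None
    birth_time: float | None
    division_time: float | None
    fate: str
    area_series: np.ndarray
    centroid_series: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.area_series = np.asarray(self.area_series, dtype=float)
        if self.area_series.ndim != 2 or self.area_series.shape[1] != 2:
            raise DataError(f"cell {self.cell_id}: area_series must be (n, 2)")
        if self.centroid_series is not None:
            self.centroid_series = np.asarray(self.centroid_series, dtype=float)
            if self.centroid_series.ndim != 2 or self.centroid_series.shape[1] != 3:
                raise DataError(f"cell {self.cell_id}: centroid_series must be (n, 3)")

    # -- lifetime -----------------------------------------------------------

    @property
    def start_time(self) -> float:
        """Birth time, or the first observed frame for cells present at start."""
        if self.birth_time is not None:
            return float(self.birth_time)
        return float(self.area_series[0, 0])

    @property
    def end_time(self) -> float:
        """Division time for divided cells, last observed frame otherwise."""
        if self.fate == "divided":
            return float(self.division_time)
        return float(self.area_series[-1, 0])

    def alive_at(self, t: float) -> bool:
        if t < self.start_time:
            return False
        if self.fate == "divided":
            return t < self.division_time
        return t <= self.end_time

    def validate(self) -> None:
        if self.fate not in FATES:
            raise DataError(f"cell {self.cell_id}: unknown fate {self.fate!r}")
        if len(self.area_series) == 0:
            raise DataError(f"cell {self.cell_id}: empty area series")
        times = self.area_series[:, 0]
        if np.any(np.diff(times) <= 0):
            raise DataError(f"cell {self.cell_id}: area_series times not strictly increasing")
        if np.any(self.area_series[:, 1] <= 0):
            raise DataError(f"cell {self.cell_id}: non-positive area")
        if self.fate == "divided" and self.division_time is None:
            raise DataError(f"cell {self.cell_id}: divided but no division_time")
        if self.fate != "divided" and self.division_time is not None:
            raise DataError(f"cell {self.cell_id}: fate {self.fate} with a division_time")
        if self.birth_time is not None and self.division_time is not None:
            if not self.birth_time < self.division_time:
                raise DataError(f"cell {self.cell_id}: birth_time >= division_time")
        if self.birth_time is not None and times[0] < self.birth_time - 1e-9:
            raise DataError(f"cell {self.cell_id}: observed before birth")
        if self.division_time is not None and times[-1] > self.division_time + 1e-9:
            raise DataError(f"cell {self.cell_id}: observed after division")
        if self.centroid_series is not None and len(self.centroid_series) != len(times):
            raise DataError(f"cell {self.cell_id}: centroid/area series length mismatch")


@dataclass(frozen=True)
class PeriodSchedule:
    """The nutrient schedule: contiguous high -> low -> recovery windows (min).

    Each period is a half-open interval ``[t_start, t_end)``; the recovery
    period additionally owns its right endpoint (observation end).
    """

    high: tuple[float, float]
    low: tuple[float, float]
    recovery: tuple[float, float]

    PERIODS = ("high", "low", "recovery")

    def __post_init__(self) -> None:
        spans = [self.high, self.low, self.recovery]
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if not (a0 < a1 and b0 < b1 and a1 == b0):
                raise DataError("periods must be contiguous, non-overlapping, increasing")

    @classmethod
    def three_day(cls) -> "PeriodSchedule":
        return cls(high=(0.0, 360.0), low=(360.0, 4680.0), recovery=(4680.0, 5280.0))

    @classmethod
    def one_day(cls) -> "PeriodSchedule":
        return cls(high=(0.0, 360.0), low=(360.0, 1800.0), recovery=(1800.0, 2400.0))

    def span(self, period: str) -> tuple[float, float]:
        if period not in self.PERIODS:
            raise KeyError(f"unknown period {period!r}")
        return getattr(self, period)

    def period_of(self, t: float) -> str:
        for name in self.PERIODS:
            t0, t1 = self.span(name)
            if t0 <= t < t1:
                return name
        if t == self.recovery[1]:
            return "recovery"
        raise DataError(f"t = {t} outside the observation window")

    @property
    def start(self) -> float:
        return self.high[0]

    @property
    def end(self) -> float:
        return self.recovery[1]

    def day_windows(self) -> list[tuple[float, float]]:
        """Consecutive 24-h (1440-min) windows tiling the low-nutrient period."""
        t0, t1 = self.low
        out = []
        t = t0
        while t < t1 - 1e-9:
            out.append((t, min(t + 1440.0, t1)))
            t += 1440.0
        return out


class LineageForest:
    """Per-microcolony forest of :class:`CellRecord` with genealogy queries."""

    def __init__(self, microcolony_id: str, cells: Iterable[CellRecord], validate: bool = True):
        self.microcolony_id = microcolony_id
        self.cells: dict[str, CellRecord] = {}
        for c in cells:
            if c.cell_id in self.cells:
                raise StructuralError(f"duplicate cell_id {c.cell_id!r}")
            self.cells[c.cell_id] = c
        self.children: dict[str, list[str]] = {cid: [] for cid in self.cells}
        self.roots: list[str] = []
        for cid, c in self.cells.items():
            if c.parent_id is None:
                self.roots.append(cid)
            else:
                if c.parent_id not in self.cells:
                    raise StructuralError(
                        f"cell {cid!r} references missing parent {c.parent_id!r}"
                    )
                self.children[c.parent_id].append(cid)
        for kids in self.children.values():
            kids.sort()
        if validate:
            self.validate()

    def __len__(self) -> int:
        return len(self.cells)

    def __contains__(self, cell_id: str) -> bool:
        return cell_id in self.cells

    def __getitem__(self, cell_id: str) -> CellRecord:
        return self.cells[cell_id]

    def parent_of(self, cell_id: str) -> str | None:
        return self.cells[cell_id].parent_id

    def children_of(self, cell_id: str) -> list[str]:
        return self.children[cell_id]

    def sister_of(self, cell_id: str) -> str | None:
        pid = self.cells[cell_id].parent_id
        if pid is None:
            return None
        sibs = [k for k in self.children[pid] if k != cell_id]
        return sibs[0] if sibs else None

    @property
    def observation_window(self) -> tuple[float, float]:
        lo = min(c.start_time for c in self.cells.values())
        hi = max(c.end_time for c in self.cells.values())
        return lo, hi

    def alive_at(self, t: float) -> list[str]:
        return [cid for cid, c in self.cells.items() if c.alive_at(t)]

    def validate(self) -> None:
        """Check every forest invariant; raise Structural/DataError on failure."""
        for c in self.cells.values():
            c.validate()
            if c.microcolony_id != self.microcolony_id:
                raise StructuralError(
                    f"cell {c.cell_id!r} belongs to colony {c.microcolony_id!r}, "
                    f"not {self.microcolony_id!r}"
                )
        if not self.roots:
            raise StructuralError("forest has no root")
        for cid, kids in self.children.items():
            c = self.cells[cid]
            if c.fate == "divided":
                if len(kids) != 2:
                    raise StructuralError(
                        f"divided cell {cid!r} has {len(kids)} children (need 2)"
                    )
                for k in kids:
                    kb = self.cells[k].birth_time
                    if kb is None or abs(kb - c.division_time) > 1e-6:
                        raise StructuralError(
                            f"child {k!r} birth_time does not equal parent "
                            f"{cid!r} division_time"
                        )
            elif kids:
                raise StructuralError(f"non-divided cell {cid!r} has children")
        # cycle check: walking up from any cell must terminate at a root
        for cid in self.cells:
            seen = set()
            cur: str | None = cid
            while cur is not None:
                if cur in seen:
                    raise StructuralError(f"cycle through cell {cid!r}")
                seen.add(cur)
                cur = self.cells[cur].parent_id


def build_forest(
    cell_table: pd.DataFrame,
    series_table: pd.DataFrame | None = None,
    microcolony_id: str | None = None,
    validate: bool = True,
) -> LineageForest:
    """Assemble a validated :class:`LineageForest` from interchange tables.

    ``cell_table`` needs columns ``cell_id, microcolony_id, parent_id,
    birth_time_min, division_time_min, fate``; ``series_table`` (long format)
    needs ``cell_id, time_min, area_um2`` and optionally ``x_um, y_um``.
    """
    required = {"cell_id", "microcolony_id", "parent_id", "birth_time_min",
                "division_time_min", "fate"}
    missing = required - set(cell_table.columns)
    if missing:
        raise DataError(f"cell table missing columns: {sorted(missing)}")
    if microcolony_id is None:
        ids = cell_table["microcolony_id"].unique()
        if len(ids) != 1:
            raise DataError("cell table spans multiple microcolonies; pass microcolony_id")
        microcolony_id = str(ids[0])

    has_xy = series_table is not None and {"x_um", "y_um"} <= set(series_table.columns)
    series_by_cell: dict[str, pd.DataFrame] = {}
    if series_table is not None:
        need = {"cell_id", "time_min", "area_um2"}
        if not need <= set(series_table.columns):
            raise DataError(f"series table missing columns: {sorted(need - set(series_table.columns))}")
        series_by_cell = {str(k): g for k, g in series_table.groupby("cell_id", sort=False)}

    def _opt(v) -> float | None:
        return None if pd.isna(v) else float(v)

    records = []
    for row in cell_table.itertuples(index=False):
        cid = str(row.cell_id)
        g = series_by_cell.get(cid)
        if g is None:
            raise DataError(f"cell {cid!r} has no area series")
        g = g.sort_values("time_min")
        area = np.column_stack([g["time_min"].to_numpy(float), g["area_um2"].to_numpy(float)])
        cent = None
        if has_xy:
            cent = np.column_stack(
                [g["time_min"].to_numpy(float), g["x_um"].to_numpy(float), g["y_um"].to_numpy(float)]
            )
        records.append(
            CellRecord(
                cell_id=cid,
                microcolony_id=str(row.microcolony_id),
                parent_id=None if pd.isna(row.parent_id) or row.parent_id == "" else str(row.parent_id),
                birth_time=_opt(row.birth_time_min),
                division_time=_opt(row.division_time_min),
                fate=str(row.fate),
                area_series=area,
                centroid_series=cent,
            )
        )
    return LineageForest(microcolony_id, records, validate=validate)


class AncestorChain(NamedTuple):
    """An ordered ancestor chain [a_0, ..., a_n] and a truncation flag.

    ``truncated`` is set when the lineage does not extend back to the query
    start (the chain then begins at the root's birth).
    """

    cells: list[str]
    truncated: bool


def ancestors_of(
    forest: LineageForest, cell_id: str, t_start: float, t_end: float | None = None
) -> AncestorChain:
    """Ancestor chain of ``cell_id`` covering ``[t_start, t_end]``.

    The last entry is the queried cell or its ancestor alive at the window
    end; the first is the ancestor alive at ``t_start`` (or the root, with
    the ``truncated`` flag, if the lineage begins later).  Consecutive
    entries are parent -> child and their lifetimes tile the window.
    """
    cell = forest[cell_id]
    if t_end is None:
        t_end = cell.end_time
    if t_start > cell.end_time:
        raise DataError(f"t_start {t_start} after cell {cell_id!r} disappears")
    # step up until we find the ancestor alive at (or before) t_end
    cur = cell
    while cur.start_time >= t_end and cur.parent_id is not None:
        cur = forest[cur.parent_id]
    chain = [cur.cell_id]
    while forest[chain[0]].start_time > t_start:
        pid = forest[chain[0]].parent_id
        if pid is None:
            break
        chain.insert(0, pid)
    truncated = forest[chain[0]].start_time > t_start
    return AncestorChain(chain, truncated)


def descendants_of(forest: LineageForest, root_id: str, include_root: bool = True) -> list[str]:
    """All descendants of ``root_id`` (depth-first, deterministic order)."""
    out = [root_id] if include_root else []
    stack = list(reversed(forest.children_of(root_id)))
    while stack:
        cid = stack.pop()
        out.append(cid)
        stack.extend(reversed(forest.children_of(cid)))
    return out


def subtree_cells_at(forest: LineageForest, root_id: str, t: float) -> set[str]:
    """Cells alive at ``t`` descending from ``root_id`` (inclusive)."""
    lo, hi = forest.observation_window
    if not (lo <= t <= hi):
        raise DataError(f"t = {t} outside observation window [{lo}, {hi}]")
    return {cid for cid in descendants_of(forest, root_id) if forest[cid].alive_at(t)}


def _generation_map(forest: LineageForest, cell_id: str) -> dict[str, int]:
    """Map ancestor id -> number of generations from ``cell_id`` up to it."""
    out = {}
    cur: str | None = cell_id
    g = 0
    while cur is not None:
        out[cur] = g
        cur = forest[cur].parent_id
        g += 1
    return out


def generations_to_common_ancestor(forest: LineageForest, cell_a: str, cell_b: str) -> int:
    """Generations ``n`` to the closest common ancestor of two cells.

    For equal-depth pairs this is the number of divisions separating each
    cell from the shared ancestor (sisters 1, first cousins 2).  For
    asymmetric pairs the larger of the two counts is used, so that a
    parent–child pair has n = 1 (CR 0.5), consistent with pedigree usage.
    """
    if cell_a == cell_b:
        return 0
    up_a = _generation_map(forest, cell_a)
    cur: str | None = cell_b
    g_b = 0
    while cur is not None:
        if cur in up_a:
            return max(up_a[cur], g_b)
        cur = forest[cur].parent_id
        g_b += 1
    raise NoCommonAncestorError(f"{cell_a!r} and {cell_b!r} share no ancestor")


def coefficient_of_relationship(n: int) -> float:
    """Coefficient of relationship CR = 2**(-n) for generation count ``n``."""
    if n < 0:
        raise ValueError("generation count must be non-negative")
    return math.pow(2.0, -n)


def number_of_generations(
    forest: LineageForest, cell_id: str, window: tuple[float, float]
) -> int:
    """Division events along the cell's ancestor chain strictly inside ``window``."""
    t0, t1 = window
    chain = ancestors_of(forest, cell_id, t0, t1)
    count = 0
    for cid in chain.cells:
        d = forest[cid].division_time
        if d is not None and t0 < d < t1:
            count += 1
    return count
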