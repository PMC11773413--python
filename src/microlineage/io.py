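"""Interchange-format readers and writers.

A dataset is a directory of plain-text files:

* ``cells.csv`` — one row per cell: ``cell_id, microcolony_id, parent_id,
  birth_time_min, division_time_min, fate`` (empty parent/birth/division
  for roots / cells present at start / undivided cells);
* ``series.csv`` — long format: ``cell_id, time_min, area_um2`` and
  optionally ``x_um, y_um``;
* ``schedule.json`` — the period schedule and a schema version;
* ``ground_truth.csv`` (simulated data only) — ``cell_id,
  microcolony_id, q``.

An import guide for mapping tracking-software output (e.g. Schnitzcells
schnitz structures) onto this schema lives in the package documentation;
parsing vendor formats directly is out of scope.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .lineage import DataError, LineageForest, PeriodSchedule, build_forest
from .simulate import SimDataset

__all__ = ["SCHEMA_VERSION", "write_dataset", "read_dataset", "write_schedule", "read_schedule"]

SCHEMA_VERSION = 1


def write_schedule(schedule: PeriodSchedule, path: Path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "periods": {name: list(schedule.span(name)) for name in schedule.PERIODS},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_schedule(path: Path) -> PeriodSchedule:
    payload = json.loads(Path(path).read_text())
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise DataError(f"schedule schema version {version!r} != {SCHEMA_VERSION}")
    p = payload["periods"]
    return PeriodSchedule(
        high=tuple(p["high"]), low=tuple(p["low"]), recovery=tuple(p["recovery"])
    )


def write_dataset(dataset: SimDataset | list[LineageForest], out_dir: Path,
                  schedule: PeriodSchedule | None = None) -> None:
    """Write forests (+ schedule, + ground truth if present) to ``out_dir``."""
    if isinstance(dataset, SimDataset):
        forests = dataset.forests
        schedule = dataset.schedule
        truth = dataset.ground_truth
    else:
        forests = dataset
        truth = None
        if schedule is None:
            raise ValueError("schedule required when writing a bare forest list")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cell_rows = []
    series_frames = []
    for f in forests:
        for cid in sorted(f.cells):
            c = f[cid]
            cell_rows.append(
                {
                    "cell_id": c.cell_id,
                    "microcolony_id": c.microcolony_id,
                    "parent_id": c.parent_id if c.parent_id is not None else "",
                    "birth_time_min": c.birth_time,
                    "division_time_min": c.division_time,
                    "fate": c.fate,
                }
            )
            frame = pd.DataFrame(
                {
                    "cell_id": c.cell_id,
                    "time_min": c.area_series[:, 0],
                    "area_um2": c.area_series[:, 1],
                }
            )
            if c.centroid_series is not None:
                frame["x_um"] = c.centroid_series[:, 1]
                frame["y_um"] = c.centroid_series[:, 2]
            series_frames.append(frame)
    pd.DataFrame(cell_rows).to_csv(out / "cells.csv", index=False)
    pd.concat(series_frames, ignore_index=True).to_csv(out / "series.csv", index=False)
    write_schedule(schedule, out / "schedule.json")
    if truth is not None:
        truth.to_csv(out / "ground_truth.csv", index=False)


def read_dataset(path: Path) -> tuple[list[LineageForest], PeriodSchedule]:
    """Load and validate every microcolony forest from a dataset directory."""
    path = Path(path)
    for name in ("cells.csv", "series.csv", "schedule.json"):
        if not (path / name).exists():
            raise DataError(f"dataset is missing {name}")
    schedule = read_schedule(path / "schedule.json")
    cells = pd.read_csv(path / "cells.csv", dtype={"cell_id": str, "parent_id": str,
                                                   "microcolony_id": str})
    series = pd.read_csv(path / "series.csv", dtype={"cell_id": str})
    required = {"cell_id", "microcolony_id", "parent_id", "birth_time_min",
                "division_time_min", "fate"}
    missing = required - set(cells.columns)
    if missing:
        raise DataError(f"cells.csv missing columns: {sorted(missing)}")
    forests = []
    series_by_colony = dict(
        series.merge(cells[["cell_id", "microcolony_id"]], on="cell_id", how="left")
        .groupby("microcolony_id", sort=True)
        .__iter__()
    )
    for colony_id, group in cells.groupby("microcolony_id", sort=True):
        forests.append(
            build_forest(group, series_by_colony[colony_id], microcolony_id=str(colony_id))
        )
    return forests, schedule


def read_ground_truth(path: Path) -> pd.DataFrame:
    return pd.read_csv(Path(path) / "ground_truth.csv", dtype={"cell_id": str})
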