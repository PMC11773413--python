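# Importing tracking data

The package reads a directory with three plain-text files:

## `cells.csv`

One row per tracked cell:

| column              | type   | meaning                                            |
|---------------------|--------|----------------------------------------------------|
| `cell_id`           | str    | unique within the microcolony                      |
| `microcolony_id`    | str    | colony identifier                                  |
| `parent_id`         | str    | empty for roots                                    |
| `birth_time_min`    | float  | empty for cells present at observation start       |
| `division_time_min` | float  | empty for cells that never divided                 |
| `fate`              | str    | `divided`, `lysed`, or `censored`                  |

Constraints enforced at load time: a `divided` cell has exactly two
children whose `birth_time_min` equals its `division_time_min`;
parent links form a forest (no cycles, no orphans).

## `series.csv`

Long format, one row per cell per frame: `cell_id`, `time_min`,
`area_um2` (> 0, strictly increasing times per cell) and optionally
`x_um`, `y_um` centroids. The series must span the cell's observed
lifetime; times need not be on a regular grid (analysis snaps them to
per-period grids by nearest frame).

## `schedule.json`

```json
{"schema_version": 1,
 "periods": {"high": [0, 360], "low": [360, 4680], "recovery": [4680, 5280]}}
```

## Mapping Schnitzcells-style output

Tracking suites that produce per-cell "schnitz" structures map directly:

- the schnitz index → `cell_id`; `P` (parent index) → `parent_id`;
- the first/last frame numbers × the frame interval → `birth_time_min`
  / `division_time_min` (birth empty for cells in the first frame;
  division empty when `D`/`E` daughter indices are absent);
- daughters present → `fate = divided`; otherwise `censored`, or
  `lysed` if your pipeline flags lysis;
- per-frame segmented areas (pixel counts × μm²/pixel) → `area_um2`;
  centroid columns (pixels × μm/pixel) → `x_um`, `y_um`.

Export those fields to the two CSVs with any MATLAB/Python script;
parsing vendor `.mat` files directly is deliberately out of scope.
Validate the result with:

```sh
microlineage validate path/to/dataset
```

which reports structural problems with the offending cell named.
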