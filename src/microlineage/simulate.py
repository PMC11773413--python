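"""Generative model of the nutrient-shift time-lapse experiment.

Each microcolony starts from one rod-shaped cell and is propagated through
a high-nutrient period (exponential area growth, median generation time
~120 min), a low-nutrient period of one or three days (strongly slowed,
highly variable growth), and a 10-h recovery period after nutrient
resupply.  Cells divide by an adder rule (divide after adding a roughly
constant area increment) with slightly asymmetric splits.

A one-dimensional heritable latent state q in [0, 1] carries the
"suppress-then-maintain" propensity: high-q lineages suppress growth
immediately after the downshift and hold a feeble constant rate
(~1.5e-4 min^-1), low-q lineages start the low-nutrient period faster but
decay over the days, and after resupply q sets both the probability of
regrowing at all and the lag time to the first division — so high-q
starters become the hyper-regrowers.  q is inherited as
``q_child = clip(lambda * q_parent + (1 - lambda) * mu + noise)``.

Daughters are placed along the mother's axis with angular noise and local
overlap relaxation, so close relatives end up as spatial neighbours; the
stored centroid of a cell is its final relaxed position (a static
approximation adequate for single-snapshot spatial analyses).

A ``mutant`` preset mimics a beta-oxidation-deficient strain: low-nutrient
rates are scaled down and the regrowth probability collapses to near zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lineage import CellRecord, LineageForest, PeriodSchedule

__all__ = ["SimConfig", "SimDataset", "simulate_colony", "simulate_experiment", "place_daughters"]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the synthetic experiment.

    Defaults reproduce the study conditions: 40 microcolonies, a 6-h
    high-nutrient period, a 3-day low-nutrient period, a 10-h recovery,
    imaging every 10 min (high/recovery) or 20 min (low).
    """

    n_colonies: int = 40
    low_days: int = 3                 # 3-day or 1-day low-nutrient variant
    high_len: float = 360.0           # min
    day_len: float = 1440.0           # min
    recovery_len: float = 600.0       # min
    frame_high: float = 10.0          # imaging interval, min
    frame_low: float = 20.0
    frame_recovery: float = 10.0

    # high-nutrient growth: median generation time ln(2)/r = 120 min
    r_high_median: float = LN2 / 120.0
    r_high_sigma: float = 0.12        # lognormal sd of the per-cell rate multiplier
    r_recovery_median: float = LN2 / 140.0
    r_recovery_sigma: float = 0.10

    # adder division rule
    adder_mean: float = 2.2           # mean added area per cycle, um^2
    adder_cv: float = 0.15
    init_area_sigma: float = 0.12     # lognormal sd of the founder's birth size
    asym: float = 0.05                # division asymmetry: split fraction 0.5 +/- U(0, asym)
    root_phase: float | None = None   # founder cell-cycle phase in [0,1); None = random

    # heritable latent state q: AR(1)-style inheritance toward q_mu with
    # Gaussian noise plus rare large upward innovations (a stochastic switch
    # into the suppress-then-maintain state), so high-q lineages arise
    # within colonies and cluster in subtrees
    heritability: float = 0.9         # lambda
    q_mu: float = 0.4
    q_sigma: float = 0.04             # per-generation inheritance noise
    q_jump_prob: float = 0.04         # per-division chance of an upward innovation
    q_jump_mean: float = 0.45
    q_jump_sd: float = 0.10
    q_beta_init: tuple[float, float] = (2.5, 4.0)  # founder q distribution
    q_init_value: float | None = None  # fixed founder q (overrides the Beta draw)

    # low-nutrient rates (min^-1): linear in q at day 1 and at the last day,
    # interpolated across days; high q = suppress early, maintain late
    r_low_day1_lo: float = 8.0e-4     # q = 0, day 1
    r_low_day1_hi: float = 1.5e-4     # q = 1, day 1
    r_low_day3_lo: float = 0.7e-4     # q = 0, last day
    r_low_day3_hi: float = 1.5e-4     # q = 1, last day
    r_low_sigma: float = 0.35
    lysis_rate_per_hour: float = 0.0015

    # recovery: regrowth probability and lag time as functions of q
    regrow_intercept: float = 0.15
    regrow_slope: float = 1.0
    regrow_day_bonus: float = 0.20    # added per day the low period is shorter than 3
    tau_min: float = 120.0            # min
    tau_scale: float = 780.0
    tau_pow: float = 1.15
    tau_sigma: float = 0.20
    division_growth_factor: float = 2.0   # area fold-change of a starter at its first division
    nondivider_rate: float = 2.0e-5

    # spatial model
    spatial: bool = True
    aspect: float = 4.0               # rod length : width
    angle_sd: float = 0.25            # rad
    spacing_factor: float = 0.8
    relax_iters: int = 8
    relax_radius: float = 5.0         # um

    # mutant preset (suppressed low-nutrient growth, near-zero regrowth)
    mutant: bool = False
    mutant_rate_scale: float = 0.4
    mutant_regrow_scale: float = 0.02

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_colonies < 0 or self.low_days < 1:
            raise ValueError("n_colonies must be >= 0 and low_days >= 1")
        if not (0.0 <= self.heritability <= 1.0):
            raise ValueError("heritability must lie in [0, 1]")

    @property
    def schedule(self) -> PeriodSchedule:
        t_low = self.high_len
        t_rec = t_low + self.low_days * self.day_len
        return PeriodSchedule(
            high=(0.0, t_low), low=(t_low, t_rec), recovery=(t_rec, t_rec + self.recovery_len)
        )

    def regrow_probability(self, q: float) -> float:
        p = self.regrow_intercept + self.regrow_slope * q
        p += self.regrow_day_bonus * max(0, 3 - self.low_days)
        if self.mutant:
            p *= self.mutant_regrow_scale
        return float(np.clip(p, 0.0, 1.0))

    def low_rate(self, q: float, day_index: int) -> float:
        frac = day_index / (self.low_days - 1) if self.low_days > 1 else 0.0
        r1 = self.r_low_day1_lo + (self.r_low_day1_hi - self.r_low_day1_lo) * q
        r3 = self.r_low_day3_lo + (self.r_low_day3_hi - self.r_low_day3_lo) * q
        r = (1.0 - frac) * r1 + frac * r3
        if self.mutant:
            r *= self.mutant_rate_scale
        return r


@dataclass
class SimDataset:
    """A simulated experiment: forests, schedule, per-cell ground truth."""

    forests: list[LineageForest]
    schedule: PeriodSchedule
    ground_truth: pd.DataFrame  # cell_id, microcolony_id, q
    config: SimConfig


# ---------------------------------------------------------------------------
# growth simulation (per-cell event walk)


class _SimCell:
    __slots__ = (
        "cell_id", "parent_id", "birth_time", "birth_area", "q",
        "division_time", "fate", "segments", "end_time", "end_area", "div_area",
    )

    def __init__(self, cell_id, parent_id, birth_time, birth_area, q):
        self.cell_id = cell_id
        self.parent_id = parent_id
        self.birth_time = birth_time  # None for the founder
        self.birth_area = birth_area
        self.q = q
        self.division_time = None
        self.fate = "censored"
        self.segments: list[tuple[float, float, float]] = []  # (t, area, rate)
        self.end_time = None
        self.end_area = None
        self.div_area = None

    @property
    def start_time(self) -> float:
        return 0.0 if self.birth_time is None else self.birth_time

    def area_at(self, t: np.ndarray) -> np.ndarray:
        starts = np.array([s[0] for s in self.segments])
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(starts) - 1)
        a = np.array([s[1] for s in self.segments])[idx]
        r = np.array([s[2] for s in self.segments])[idx]
        return a * np.exp(r * (np.asarray(t) - starts[idx]))


def _clip_q(x: float) -> float:
    return float(min(1.0, max(0.0, x)))


def _grow_colony(cfg: SimConfig, rng: np.random.Generator, colony_id: str) -> list[_SimCell]:
    sched = cfg.schedule
    t_low0, t_low1 = sched.low
    rec0, rec1 = sched.recovery
    day_bounds = [t_low0 + d * cfg.day_len for d in range(cfg.low_days)] + [t_low1]
    hazard = cfg.lysis_rate_per_hour / 60.0

    # founder: mid-cycle at observation start
    if cfg.q_init_value is not None:
        q0 = float(cfg.q_init_value)
    else:
        q0 = float(rng.beta(*cfg.q_beta_init))
    b0 = cfg.adder_mean * math.exp(cfg.init_area_sigma * rng.standard_normal())
    phase = cfg.root_phase if cfg.root_phase is not None else float(rng.random())
    delta0 = cfg.adder_mean * math.exp(cfg.adder_cv * rng.standard_normal())
    root = _SimCell(f"{colony_id}_0000", None, None, b0, q0)
    root_area0 = b0 + phase * delta0

    cells: list[_SimCell] = []
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"{colony_id}_{counter[0]:04d}"

    # (cell, current area at start, adder target area)
    queue: list[tuple[_SimCell, float, float]] = [(root, root_area0, b0 + delta0)]

    while queue:
        cell, area, target = queue.pop(0)
        cells.append(cell)
        t = cell.start_time
        q = cell.q
        # per-cell rate multipliers, drawn lazily per period entered
        mult: dict[str, float] = {}

        def multiplier(period: str, sigma: float) -> float:
            if period not in mult:
                mult[period] = math.exp(sigma * rng.standard_normal())
            return mult[period]

        def rate_at(tt: float) -> float:
            if tt < t_low0:
                return cfg.r_high_median * multiplier("high", cfg.r_high_sigma)
            if tt < rec0:
                day = min(int((tt - t_low0) // cfg.day_len), cfg.low_days - 1)
                return cfg.low_rate(q, day) * multiplier("low", cfg.r_low_sigma)
            return cfg.r_recovery_median * multiplier("recovery", cfg.r_recovery_sigma)

        bounds = [b for b in ([t_low0] + day_bounds[1:] + [rec1]) if b > t + 1e-12]
        divided = False
        lysed = False
        while bounds:
            seg_end = bounds.pop(0)
            in_low = t_low0 - 1e-9 <= t < rec0 - 1e-9
            entering_recovery = abs(t - rec0) < 1e-9 and cell.start_time < rec0 - 1e-9
            if entering_recovery:
                # starter cell: regrowth decision and explicit lag time
                p_regrow = cfg.regrow_probability(q)
                u = rng.random()
                tau = cfg.tau_min + cfg.tau_scale * (1.0 - q) ** cfg.tau_pow * math.exp(
                    cfg.tau_sigma * rng.standard_normal()
                )
                if u < p_regrow and tau < cfg.recovery_len:
                    r_eff = math.log(cfg.division_growth_factor) / tau
                    cell.segments.append((t, area, r_eff))
                    t_div = rec0 + tau
                    cell.division_time = t_div
                    cell.fate = "divided"
                    cell.end_time = t_div
                    cell.end_area = area * cfg.division_growth_factor
                    divided = True
                else:
                    cell.segments.append((t, area, cfg.nondivider_rate))
                    cell.end_time = rec1
                    cell.end_area = area * math.exp(cfg.nondivider_rate * (rec1 - t))
                    cell.fate = "censored"
                break
            r = rate_at(t + 1e-9)
            cell.segments.append((t, area, r))
            t_div = math.inf
            if r > 0 and area < target:
                t_div = t + math.log(target / area) / r
            t_lys = math.inf
            if in_low and hazard > 0:
                t_lys = t + rng.exponential(1.0 / hazard)
            t_next = min(t_div, t_lys, seg_end)
            if t_div <= min(t_lys, seg_end):
                cell.division_time = t_div
                cell.fate = "divided"
                cell.end_time = t_div
                cell.end_area = target
                divided = True
                break
            if t_lys < seg_end:
                cell.fate = "lysed"
                cell.end_time = t_lys
                cell.end_area = area * math.exp(r * (t_lys - t))
                lysed = True
                break
            area = area * math.exp(r * (seg_end - t))
            t = seg_end
        if not divided and not lysed and cell.end_time is None:
            cell.fate = "censored"
            cell.end_time = rec1
            cell.end_area = area
        cell.div_area = cell.end_area
        if divided and cell.division_time < rec1 - 1e-9:
            f = 0.5 + rng.uniform(-cfg.asym, cfg.asym)
            a_div = cell.end_area
            lam = cfg.heritability
            for frac in (f, 1.0 - f):
                eps = cfg.q_sigma * rng.standard_normal()
                if cfg.q_jump_prob > 0 and rng.random() < cfg.q_jump_prob:
                    eps += cfg.q_jump_mean + cfg.q_jump_sd * rng.standard_normal()
                qc = _clip_q(lam * q + (1.0 - lam) * cfg.q_mu + eps)
                child = _SimCell(new_id(), cell.cell_id, cell.division_time, frac * a_div, qc)
                delta = cfg.adder_mean * math.exp(cfg.adder_cv * rng.standard_normal())
                queue.append((child, frac * a_div, frac * a_div + delta))
        elif divided:
            # division exactly at the observation end: treat as censored
            cell.fate = "censored"
            cell.division_time = None
    return cells


# ---------------------------------------------------------------------------
# spatial layout


def place_daughters(
    positions: dict[str, np.ndarray],
    orientations: dict[str, float],
    widths: dict[str, float],
    parent_id: str,
    daughter_ids: tuple[str, str],
    daughter_widths: tuple[float, float],
    rng: np.random.Generator,
    cfg: SimConfig | None = None,
) -> None:
    """Replace a parent by its two daughters and relax local overlaps.

    Daughters are placed symmetrically about the parent centroid along the
    parent's axis (with angular noise), so their midpoint coincides with
    the parent position before relaxation; a bounded number of pairwise
    repulsion iterations then pushes overlapping local cells apart.
    Mutates ``positions``/``orientations``/``widths`` in place.
    """
    cfg = cfg or SimConfig()
    p = positions.pop(parent_id)
    theta = orientations.pop(parent_id) + rng.normal(0.0, cfg.angle_sd)
    w_par = widths.pop(parent_id)
    u = np.array([math.cos(theta), math.sin(theta)])
    offset = cfg.aspect * w_par / 4.0
    d1, d2 = daughter_ids
    positions[d1] = p + offset * u
    positions[d2] = p - offset * u
    for d, w in zip(daughter_ids, daughter_widths):
        orientations[d] = theta + rng.normal(0.0, 0.5 * cfg.angle_sd)
        widths[d] = w
    # local relaxation
    local = [cid for cid, x in positions.items() if np.linalg.norm(x - p) <= cfg.relax_radius]
    if len(local) < 2:
        return
    X = np.array([positions[c] for c in local])
    W = np.array([widths[c] for c in local])
    target = cfg.spacing_factor * (W[:, None] + W[None, :])
    for _ in range(cfg.relax_iters):
        diff = X[:, None, :] - X[None, :, :]
        dist = np.linalg.norm(diff, axis=2)
        np.fill_diagonal(dist, np.inf)
        overlap = np.clip(target - dist, 0.0, None)
        if not np.any(overlap > 1e-9):
            break
        with np.errstate(invalid="ignore", divide="ignore"):
            push = np.where(dist[..., None] > 1e-9, diff / dist[..., None], 0.0)
        X = X + 0.5 * np.sum(push * overlap[..., None], axis=1)
    for c, x in zip(local, X):
        positions[c] = x


def _compact(X: np.ndarray, W: np.ndarray, cfg: SimConfig,
             shrink_steps: int = 40) -> np.ndarray:
    """Shrink a layout toward its centroid while resolving overlaps.

    Push-only sequential placement leaves a microcolony looser than a real
    monolayer; alternating a small centripetal contraction with pairwise
    repulsion converges to a jammed packing at the configured spacing, so
    that direct neighbours fall within the boundary-gap adjacency rule.
    """
    if len(X) < 2:
        return X
    target = cfg.spacing_factor * (W[:, None] + W[None, :])
    for _ in range(shrink_steps):
        center = X.mean(axis=0)
        X = center + (X - center) * 0.96
        for _ in range(cfg.relax_iters):
            diff = X[:, None, :] - X[None, :, :]
            dist = np.linalg.norm(diff, axis=2)
            np.fill_diagonal(dist, np.inf)
            overlap = np.clip(target - dist, 0.0, None)
            if not np.any(overlap > 1e-9):
                break
            with np.errstate(invalid="ignore", divide="ignore"):
                push = np.where(dist[..., None] > 1e-9, diff / dist[..., None], 0.0)
            X = X + 0.5 * np.sum(push * overlap[..., None], axis=1)
    return X


def _layout_colony(
    cfg: SimConfig, rng: np.random.Generator, cells: list[_SimCell]
) -> dict[str, np.ndarray]:
    """Final per-cell centroids; the layout is frozen at the low-nutrient end.

    Divisions up to the recovery onset are placed sequentially with local
    relaxation, the colony is then compacted to its packing distance (the
    reference snapshot for all spatial analyses), and cells born during
    recovery inherit their parent's frozen position with a small jitter.
    """
    root = cells[0]
    rec0 = cfg.schedule.recovery[0]
    nominal_w = {
        c.cell_id: math.sqrt((c.birth_area + 0.5 * cfg.adder_mean) / cfg.aspect) for c in cells
    }
    positions: dict[str, np.ndarray] = {root.cell_id: np.zeros(2)}
    orientations = {root.cell_id: float(rng.uniform(0.0, 2.0 * math.pi))}
    widths = {root.cell_id: nominal_w[root.cell_id]}
    final: dict[str, np.ndarray] = {}

    children: dict[str, list[str]] = {}
    for c in cells:
        if c.parent_id is not None:
            children.setdefault(c.parent_id, []).append(c.cell_id)
    events = []
    for c in cells:
        if c.fate == "divided" and c.division_time < rec0:
            kids = sorted(children[c.cell_id])
            events.append((c.division_time, "div", c.cell_id, kids))
        elif c.fate == "lysed":
            events.append((c.end_time, "end", c.cell_id, None))
    for t, kind, cid, kids in sorted(events, key=lambda e: (e[0], e[2])):
        if kind == "div":
            final[cid] = positions[cid].copy()
            place_daughters(
                positions, orientations, widths, cid, (kids[0], kids[1]),
                (nominal_w[kids[0]], nominal_w[kids[1]]), rng, cfg,
            )
        else:
            final[cid] = positions.pop(cid)
            orientations.pop(cid)
            widths.pop(cid)
    ids = sorted(positions)
    X = _compact(np.array([positions[c] for c in ids]),
                 np.array([widths[c] for c in ids]), cfg)
    for cid, x in zip(ids, X):
        final[cid] = x
    # recovery-born cells: inherit the parent's frozen position
    for c in cells:
        if c.cell_id in final:
            continue
        parent_pos = final[c.parent_id]
        final[c.cell_id] = parent_pos + rng.normal(0.0, 0.1, size=2)
    return final


# ---------------------------------------------------------------------------
# assembly


def _imaging_grid(cfg: SimConfig) -> np.ndarray:
    sched = cfg.schedule
    g_high = np.arange(sched.high[0], sched.high[1], cfg.frame_high)
    g_low = np.arange(sched.low[0], sched.low[1], cfg.frame_low)
    g_rec = np.arange(sched.recovery[0], sched.recovery[1] + 1e-9, cfg.frame_recovery)
    return np.concatenate([g_high, g_low, g_rec])


def simulate_colony(
    cfg: SimConfig, rng: np.random.Generator, colony_id: str
) -> tuple[LineageForest, pd.DataFrame]:
    """Simulate one microcolony; returns the forest and its ground truth.

    The ground-truth table has one row per cell with its latent state q.
    A configuration that extinguishes every lineage before recovery still
    returns a valid (censor-truncated) forest.
    """
    cells = _grow_colony(cfg, rng, colony_id)
    grid = _imaging_grid(cfg)
    positions = _layout_colony(cfg, rng, cells) if cfg.spatial else None

    records = []
    for c in cells:
        lo = c.start_time
        if c.fate == "divided":
            mask = (grid >= lo - 1e-9) & (grid < c.division_time - 1e-9)
        else:
            mask = (grid >= lo - 1e-9) & (grid <= c.end_time + 1e-9)
        times = grid[mask]
        if len(times) == 0:
            # short-lived lysed branch between frames: keep one frame at its end
            times = np.array([c.end_time])
        areas = c.area_at(times)
        cent = None
        if positions is not None:
            x, y = positions[c.cell_id]
            cent = np.column_stack([times, np.full_like(times, x), np.full_like(times, y)])
        records.append(
            CellRecord(
                cell_id=c.cell_id,
                microcolony_id=colony_id,
                parent_id=c.parent_id,
                birth_time=c.birth_time,
                division_time=c.division_time,
                fate=c.fate,
                area_series=np.column_stack([times, areas]),
                centroid_series=cent,
            )
        )
    forest = LineageForest(colony_id, records, validate=True)
    truth = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "microcolony_id": colony_id,
            "q": [c.q for c in cells],
        }
    )
    return forest, truth


def simulate_experiment(cfg: SimConfig) -> SimDataset:
    """Simulate ``cfg.n_colonies`` independent microcolonies.

    Each colony gets its own RNG stream derived from the master seed, so
    the same seed reproduces the dataset bit for bit.
    """
    streams = np.random.SeedSequence(cfg.seed).spawn(max(cfg.n_colonies, 1))
    forests = []
    truths = []
    for i in range(cfg.n_colonies):
        rng = np.random.default_rng(streams[i])
        forest, truth = simulate_colony(cfg, rng, f"colony{i:03d}")
        forests.append(forest)
        truths.append(truth)
    truth = (
        pd.concat(truths, ignore_index=True)
        if truths
        else pd.DataFrame(columns=["cell_id", "microcolony_id", "q"])
    )
    return SimDataset(forests=forests, schedule=cfg.schedule, ground_truth=truth, config=cfg)
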