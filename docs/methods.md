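# Methods

This note records the models, conventions and numerical choices behind
the package, and what the synthetic-data tests do and do not establish
about real tracking data.

## Data model

A microcolony is a forest of strict binary trees over tracked cells.
Each cell is a branch from birth to division, carrying per-frame area
(μm²) and centroid (μm) series on a real-valued minute axis. Cells
present at observation start have no birth time; their first observed
frame stands in. A cell is alive at time t if it has started and, for
divided cells, t is strictly before the division time; lysed and
censored cells count as alive through their last observed frame. Lysed
cells terminate their branch: they contribute to subtree area until
lysis and to the lysis-fraction summary, and are excluded from
rate-CV statistics (the treatment of lysed branches in dispersion
statistics is a documented package default, since there is no single
established convention). Tracking artifacts — a divided cell without
exactly two children, non-monotone series, orphan parents — are
rejected at ingest with named errors, never repaired: repair belongs to
the tracking software.

## Rate estimation

All estimators assume exponential area growth within a cell,
s(t) = s₀·e^{rt}, which for *E. coli* is the standard single-cell
growth law; no alternative (linear, bilinear) model is offered. The
pipeline is:

1. **Frame grid.** Each nutrient period has its own analysis grid
   anchored at the period start with spacing Δt′. Observed series are
   snapped to the grid by nearest-frame selection with tolerance Δt′/2;
   areas are never interpolated, and a gap larger than the tolerance
   makes the frame (and any rate using it) undefined rather than zero.
   The low-nutrient Δt′ = 40 min grid is an exact downsampling of the
   20-min imaging grid (every second frame, phase-anchored at the
   period start).
2. **Instantaneous rate** r(t) = ln(s(t+Δt)/s(t))/Δt with natural
   logarithm (the exponential-growth derivation forces ln), Δt an
   integer multiple of Δt′. Log-ratios never straddle a period
   boundary: each period is processed independently with its own
   parameters.
3. **Moving mean** over Δf frames (odd), centered, with
   symmetric-greedy edge truncation: near series edges only the
   existing frames inside ±(Δf−1)/2 enter. The smoothed series is
   defined exactly where the raw series is.
4. **Window average.** The scalar rate over [t_start, t_end] is the
   arithmetic mean of the smoothed values at the frames actually
   included (both endpoints inclusive). An alternative convention
   divides the inclusive frame sum by the frame-index difference
   f_end − f_start, which differs by one frame in the denominator;
   the included-frame mean is self-consistent and exact on constant
   series, and is used throughout.

The subtree estimator applies the same pipeline to
S(t) = Σᵢ sᵢ(t), the summed area of live descendants of a root; S is
defined at a frame only if every live member has an area there, and a
missing member frame propagates as undefined. Because daughters'
birth areas sum to the mother's division area, S is continuous across
divisions.

The lineage estimator walks a starter cell's ancestor chain back
through the query window. Each frame's rate is the instantaneous rate
of whichever ancestor is alive then, with the log-ratio and moving mean
confined to that ancestor's own series — so the halving (or any
perturbation) of size at division is excluded by construction, a
contract verified by a dedicated invariance test. The scalar is the
mean of smoothed values over all window frames, which reproduces the
chained per-segment sums exactly under the included-frame convention.
Frames within Δt of an ancestor's division, where the forward ratio
would need the daughter's size, are undefined and excluded from the
mean.

Default parameters: Δt′/Δt/Δf = 10/30/3 min/min/frames in the
high-nutrient and recovery periods and 40/400/9 in the low-nutrient
period, reflecting the ~10× slower dynamics under starvation.

## Relatedness and cousin subtrees

The coefficient of relationship between two cells is CR = 2⁻ⁿ with n
the number of generations to their closest common ancestor (sisters
n = 1, first cousins n = 2). For pairs at unequal depths, n is the
larger of the two generation counts to the common ancestor, which
reduces to the usual definition for equal-depth pairs and gives
parent–child CR = 0.5; pairs in different trees have no common ancestor
and count as CR = 0.

Cousin-subtree comparisons hold relatedness fixed at CR = 0.25 while
growth is compared: for every cell whose two daughters both divided,
the live grandchildren at a reference time form the candidate roots,
one per side (the earliest-born, so that pairwise relatedness is
exactly 0.25), and the within-pair CV of r_subtree is computed over a
window of twice the period's median generation time (clamped to the
period). In the low-nutrient period the window starts at the
downshift; in the high-nutrient period it is right-aligned to end at
the downshift, so the reference time falls about two generations into
the period and qualifying sets exist at all. Qualifying high-nutrient
sets are rare in a ~3-generation period — a handful per 40 colonies —
so cousin CVs are compared on the pooled sets of a dataset, not per
colony.

## Regrowth quantification

Starters are the cells alive at the start of the recovery period.
τ is the starter's first division time minus the resupply time (absent
if it never divides in the window, with the caveat that a 10-h window
right-censors longer lags). p_recovery counts the cells alive at the
end of the recovery window that descend from the starter, and is 0 for
undivided starters (so 1 is unreachable by construction). The fixed
classification (non: 0; normal: 1–7; hyper: > 7) keeps results
comparable across datasets; a top-fraction mode re-derives the hyper
cutoff as the empirical (1−q) quantile with ties included above the
cut. Rank tests across classes use Kruskal–Wallis followed by
all-pairs Mann–Whitney with Holm correction as the post hoc procedure
(a substitute for the Steel–Dwass all-pairs test, which has no
maintained implementation in this stack; the substitution is recorded
in the output metadata). CVs use the sample standard deviation (n−1)
given small per-colony counts.

## Shuffle test

Subtrees are rooted at the cells alive at the low-nutrient onset; each
starter is assigned to its unique ancestor among them, and a subtree's
normalized p_recovery is total progeny over starter count. The
outlier cutoff is Q3 + 1.5·IQR of the pooled observed values
(linear-interpolation quantiles, the common "type 7" rule; a
degenerate IQR of 0 collapses the cutoff to Q3 and is flagged), and
outliers are strictly above the cutoff. Each of the (default 10,000)
trials permutes the (starter, progeny-count) units across starter
slots independently within every microcolony — the shuffling unit is
the starter with its progeny, not individual progeny cells — keeping
subtree sizes and colony totals fixed, then pools subtrees across
colonies and counts outliers against the cutoff held fixed from the
observed data (a per-trial recomputed mode exists for sensitivity
analysis). The empirical p-value is (b+1)/(n+1). Pooling after
per-colony shuffling mirrors the merged-colony presentation of the
reference analysis; the fixed-cutoff default matches its fixed
published fence.

## Triplet decomposition

Spatial information is a single snapshot at the end of the low-nutrient
period. Cell width is derived from area under a 4:1 length:width rod
model (w = √(area/aspect)); two cells are adjacent when their
center-to-center distance minus their half-width sum is within 3/4 of
their mean width — a proxy for boundary contact, since contours are
unavailable downstream of tracking. The closest relative of a focal
starter is the starter with minimal n (ties by distance), which is the
literal sister when both sisters are starters and is otherwise the
minimal consistent generalization; the equidistant cell is the
neighbour of the relative minimizing |d_ED − d_CR|, accepted within a
tolerance of 15% of d_CR (unspecified in the reference procedure;
exposed as a parameter and reported in outputs); the equally related
cell is the most distant starter with the same n as the closest
neighbour. Every non-constructible triplet is dropped with a
machine-readable reason. The genealogy contrast family
(δ_ED − δ_CR) is tested one-sided for median > 0; the spatial family
(δ_ER − δ_NB) two-sided against 0 (Wilcoxon signed-rank, zeros
dropped; an all-zero family reports p = 1).

## Synthetic experiment

The simulator generates the full experiment — 40 microcolonies by
default, high-nutrient 0–360 min, low-nutrient 1 or 3 days, 600 min of
recovery, imaging every 10 min (high/recovery) or 20 min (low) — from
one founder cell per colony.

**Growth and division.** Exponential area growth with per-cell
lognormal rate multipliers; division by an adder rule (divide after
adding Δ ≈ 2.2 μm², CV 0.15) with ±5% split asymmetry — the standard
division-control model for *E. coli*, and immaterial to the estimators
under test. High-nutrient rates give a median generation time of
~120 min; the founder starts at a uniformly random cell-cycle phase.

**Latent state.** Each cell carries q ∈ [0, 1], inherited as
q_child = clip(λ·q_parent + (1−λ)·μ + ε) with λ = 0.9, μ = 0.4 and
Gaussian ε (σ = 0.04) plus a rare large upward innovation
(probability 0.04 per division, magnitude ≈ +0.45): an AR(1) toward a
modest baseline with occasional stochastic switching into a
high-q state. The jump term is what plants entire high-q subtrees
*within* colonies; purely founder-level variation would be invisible
to a within-colony permutation test. q expresses as:

- *low-nutrient rates*: linear in q at day 1 (8.0→1.5 ×10⁻⁴ min⁻¹
  from q = 0 to 1) and at day 3 (0.7→1.5 ×10⁻⁴), interpolated across
  days, with lognormal cell-level noise (σ = 0.35). High-q lineages
  thus suppress growth immediately and hold a feeble constant
  ~1.5×10⁻⁴ min⁻¹, low-q lineages start fast and decay below them —
  the crossing pattern that distinguishes the regrower classes'
  histories, with the hyper-like plateau in the 1–2×10⁻⁴ min⁻¹ range.
- *regrowth*: a starter regrows with probability clip(0.15 + q)
  (plus 0.2 per day the starvation is shorter than 3 days), and if so
  divides first at τ = 120 + 780·(1−q)^1.15 min (lognormal noise
  σ = 0.2), its area having grown continuously to twice its
  resupply-time size; descendants then divide by the adder at a
  ~140-min median generation time. Non-regrowers hold a negligible
  rate (2×10⁻⁵ min⁻¹).

**Other ingredients.** A small constant lysis hazard in the
low-nutrient period (0.0015 h⁻¹); a mutant preset scaling low-nutrient
rates by 0.4 and regrowth probability by 0.02.

These parameters were calibrated once against the reference
experiment's population-level anchors — ~40% of starters regrowing
after 3 days and ~65% after 1 day, hyper-regrowers (p_recovery > 7)
≈ the top 10% of starters and accounting for ~50% of all recovery
progeny, a mutant regrowth fraction below 5%, ~800–1200 starters
across 40 colonies, median generation times of ~120 min (high) and
~1400–1700 min (low, versus ~1580 reported) — and then frozen; they
are not adjusted per analysis.

**Spatial layout.** Daughters are placed symmetrically about the
mother along her axis with angular noise, with local pairwise
repulsion after each division; at the low-nutrient end the colony is
compacted (alternating centripetal contraction and overlap
resolution) to a jammed packing at the configured spacing, which is
the snapshot all spatial analyses use. Stored centroids are static
per cell (its final position) — adequate for single-snapshot analyses,
but the package does not model cell motion, rod-shaped contact
geometry, or mechanical rearrangement; drop rates of spatial triplets
on real contour data will differ.

**What the simulator does not emulate.** Segmentation and tracking
errors (broken lineages, merged cells), imaging noise on areas,
continuous spatial drift, mechanistic metabolism (the mutant preset is
phenomenological), interactions between cells (the latent state is
cell-autonomous by design — which is exactly what makes the
genealogy-vs-space decomposition's expected answer known), and
realistic lag-time distributions beyond a lognormal modulated by the
latent state (no quantitative distribution is available to fit).
Passing tests therefore establish the correctness and calibration of
the *analysis machinery* under a plausible generative model of the
biology, not the biological conclusions themselves on any particular
real dataset.

## Numerical and procedural choices

- Determinism: every simulation and permutation consumes an explicit
  seed; colonies use independent spawned RNG streams, so datasets are
  bit-reproducible and colony i does not depend on how many colonies
  follow it.
- Undefined is never zero: missing frames, unusable windows and empty
  estimators yield NaN/absent values that propagate explicitly.
- Times are compared with absolute tolerances of 1e-9 min to absorb
  float accumulation on the minute axis.
- Test problem sizes (e.g. 200 six-colony replicates for null
  calibration, 20 forty-colony replicates for power, 100 small forests
  for oracle equivalence) are the package's chosen desk-scale
  defaults: large enough for the binomial error bands asserted in the
  tests, small enough to keep the whole suite in a few minutes.
- The compact-letter display for post hoc tests uses a greedy
  block-merging algorithm; letters are reported per class with groups
  sharing a letter not significantly different.

## Known limitations

- The generations-to-common-ancestor convention for unequal-depth
  pairs (max of the two counts) is one of several defensible choices;
  analyses in this package only compare equal-depth starters, where
  all conventions coincide.
- The cousin-set rule (one earliest-born root per side) is a
  documented default; reference criteria for set eligibility are not
  public.
- With a 10-h recovery window, τ and p_recovery are right-censored;
  starters that would divide later are classed as non-regrowers, as in
  the reference analysis, and censored lags are excluded from 1/τ
  correlations.
- The lysed-cell analysis is reduced to a per-colony lysis fraction;
  no lysis-versus-growth correlation analysis is provided.
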