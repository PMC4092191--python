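# Methods

`epirepair` models and analyses the repair of a segmentally ablated
tubule epithelium: collective migration of the surviving sheet into the
dead zone, followed — after a delay, and only for sufficiently long
injuries — by stretch-triggered proliferation in two bands flanking the
injury. This note documents the model, its assumptions and parameters,
the synthetic-data generators, and the numerical and design choices.

## The agent-based model

### Geometry

The epithelium is a cut-open tubule: point cells (positions in µm) on a
plane whose x axis runs along the nephron and whose y axis is the
circumference. The transverse direction is periodic with period
`rows × cell_spacing`; conserving the circumference is essential, because
an open sheet can cover new area by thinning transversely at constant
density, in which case gap closure produces no stretch signal at all.
Cells within `anchor_margin` (2 pitches) of either axial end are anchored
and never move — they stand in for mechanical continuity with the rest of
the nephron; without them the sheet would translate rigidly instead of
stretching. Cells are initialised on a square lattice at pitch
`cell_spacing = 6.7 µm` and a centred half-open axial interval of the
requested gap length is ablated (a 20.1 µm gap removes exactly three
columns — three cell diameters).

### Mechanics: junctional springs

Within the force cutoff `d_max = 1.25 s` (below the resting diagonal
√2·s, so forces act along the four axial/transverse contacts) a pair at
separation `d` interacts piecewise linearly: repulsion `k_rep (d_rep − d)`
below `d_rep = 0.9 s`, nothing in the comfort zone `[0.9 s, 1.05 s]`,
attraction `−k_att (d − d_att)` between `d_att = 1.05 s` and the cutoff.
Displacements are equal and opposite, so interactions conserve the centre
of mass; updates are synchronous; the resting lattice is exactly
force-free. Gains `k = 0.4` keep the synchronous update stable (per-pair
relative gain 0.8 < 1) while making the lattice stiff.

### Sensing: a wider neighbourhood

Stretch sensing, free-edge detection and daughter placement integrate
over a larger ball `d_sense = 1.7 s` containing the full 8-cell
neighbourhood (4 contacts at `s`, 4 diagonals at `√2 s`). Two radii are
needed: forces through a ball containing the diagonals cannot leave the
resting lattice force-free without a dead zone so wide that positions
wander freely, while a stretch metric confined to a sub-diagonal ball
censors exactly the strongly stretched links it should report. The value
1.7 s keeps the second lattice ring (at `2 s`) two microns outside the
ball so positional jitter cannot churn it in and out of the average.

The **stretch metric** of a cell is the mean distance to its sensed
neighbours; a cell with no sensed neighbour returns the `ISOLATED`
sentinel (infinity) and is excluded from division eligibility. For a
uniformly strained interior cell the metric is `1.207 s` at rest and
`1.33 s` at 20 % axial strain, saturating near `1.45 s` as stretched
diagonals leave the ball.

### Active migration: free-edge crawling

Epithelia respond to a free edge with an active migratory response; a
passive force-and-noise system has no sustained drive into the gap (it
relaxes to equilibrium, and in our measurements either stalls, retracts,
or closes without generating stretch). The model therefore gives cells an
explicit crawling term. Each cell's polarity is minus the resultant of
distance-tapered unit vectors toward its sensed neighbours (taper weight
`1 − d/d_sense`, so a neighbour drifting across the sensing boundary
cannot flip the polarity). Interior cells have near-zero resultant; cells
flanking a single-cell vacancy reach ~0.4 and crawl to close it (keeping
the front and the suture confluent); wound-edge cells reach ~0.65.

* cells above `polarity_threshold = 0.3` crawl `edge_speed = 0.3 µm` per
  step along their polarity;
* cells within `activation_depth = 120 µm` behind a leader cell (above
  `front_threshold = 0.55`) crawl with it, so the near-edge epithelium
  advances as a coherent block — the model analogue of the observation
  that epithelium adjacent to the injury migrates at very similar rates
  while the stretch maximum sits ~100 µm behind the edge.

Crawling starts without any explicit wound signal (the free edge itself
is the signal) and stops by contact inhibition when the sheets meet.
Anchored cells neither crawl nor recruit followers.

### Substrate adhesion

Passive (non-crawling) cells are tethered to the basement membrane: a
weak spring of gain `k_sub = 0.0015` per step pulls each cell toward its
adhesion reference, which itself creeps toward the cell with time
constant `tau_adh = 400` steps (plastic adhesion remodelling). Migrating
cells are exempt (adhesion release). The tether dissipates
migration-applied tension into the substrate over a finite decay length,
so migration-induced stretch is largest in a finite zone behind the
activated block rather than spreading uniformly to the anchors — this is
what localises the proliferation bands and gives the finite stretch zone
seen in symmetric cell-pair tracing.

### Stretch-gated proliferation

A cell whose stretch metric exceeds `d_div = 1.36 s` accumulates a
consecutive-step counter; the counter resets whenever the metric drops
below threshold or after a division. Once the counter *exceeds*
`delay_steps = 100` (≈ 4 h) the cell divides with probability
`p_div = 0.3` per step; the daughter is placed at the midpoint toward the
mother's most distant sensed neighbour, nudged 0.1 pitch transversely,
and both counters reset. Division requires a sensed partner (isolated
cells are ineligible), anchored cells never divide, and cells within
`div_margin = 5` pitches of an anchored cell are ineligible because
residual material deficit piling against the rigid anchored ends is a
finite-window boundary artifact, not tissue stretch.

`d_div = 1.36 s` implements the discrimination rule that motivates the
model: the sustained stretch-zone response of a short (~20 µm) ablation
— whose average linear stretch over the zone is < 5 % — stays below
threshold in every run, while 55–100 µm ablations (~13–21 % average
stretch) exceed it reliably. The delay additionally suppresses transient
stretch during edge passage, so proliferation begins hours after
migration onset, as observed.

### Calibration

The iteration-to-hours mapping is fixed by the observed closure kinetics:
with `edge_speed = 0.3 µm/step` a long-ablation edge advances
~0.30 µm/step initially, so `step_hours = 0.04` puts the initial edge
speed at ≈ 7.4 µm/h, the observed in vivo mean over the first two hours.
A default run of `n_steps = 1200` spans 48 h. `activation_depth = 120 µm`
is calibrated against the flanking proliferation-band geometry: it places
the sustained stretch zone so that the simulated median band separation
after a 50–60 µm ablation falls in the 230–300 µm range estimated for the
stretch-zone peak separation (measured median ≈ 260 µm over 20 seeds,
band peaks near ±130 µm). Divisions per long run (55–90 µm) number ~2–25
and the gap closes to < 10 % of its initial width well before the run
ends; the closure rate declines from its initial maximum as flank tension
builds, with a transient secondary rate peak after division bursts.

The default sheet is 10 × 80 cells (circumference 67 µm, axial extent
536 µm). Problem sizes throughout (20-seed ensembles, 1200-step runs)
keep a full acceptance recomputation around a minute on one CPU while
leaving the band statistics stable across master seeds.

## Morphometry

* `edge_rate_series` — bins an edge trace into fixed time windows
  (default 20 min) and differentiates the bin means with centred finite
  differences; rates are closure speeds (positive toward the injury on
  either side). The one-sided boundary stencil is first-order, so
  round-trip identity (rate → displacement → rate) holds to 1e-6 only at
  interior bins.
* `early_vs_late_rate_test` — Welch two-sample two-tailed t-test of
  per-replicate early-bin means against late-bin means. Degenerate
  zero-variance-equal-mean input returns (t = 0, p = 1).
* `peak_rate_regression` — unweighted OLS of peak closure rate on
  ablation length; the slope has units (µm/h)/µm = 1/h. Two points give
  the exact interpolating line; identical lengths are a degenerate
  design.
* `pair_stretch_profile` — pairs cells symmetric about the injury centre
  (greedy nearest depth match within 10 µm, without reuse), computes each
  pair's separation change = initial − final Euclidean separation at
  closure time (positive when the pair converged), excludes pairs closer
  than 50 µm initially, and reports binned means over [50,100), [100,150),
  [150,200), ≥200 µm.
* `stretch_zone_extent` — OLS of separation change on initial separation;
  the x-intercept (−B/A, defined only for negative slope) estimates the
  total length of epithelium experiencing stretch. Because pairs wholly
  outside the zone contribute a flat (zero-change) tail that biases a
  plain OLS intercept outward (~+5 % at the default geometry), the
  default fit iteratively refits on points below the current x-intercept
  until stable; this recovers a noiseless zone exactly and removes the
  structural bias (noisy median recovery +3.4 % over 100 default
  datasets, single-dataset scatter ~6 %). Plain OLS is available with
  `truncate=False`. A non-negative slope raises rather than extrapolates.
* `stretch_fraction` — 100 × ablation length / zone extent, the average
  linear stretch: 20/434 → 4.61 % (< 5 %), 90/434 → 20.7 %.
* `proliferation_bands` — fixed-width Gaussian kernel density (default
  bandwidth 20 µm ≈ 3 cell diameters) of event positions on a 0.5 µm grid
  anchored at the injury centre (so separations are exactly translation
  invariant); one density argmax per side of the centre; separation is
  defined only when both sides have events, otherwise the result is
  flagged single-band.
* `injured_vs_contralateral_test` — paired two-tailed t-test for
  within-animal comparisons, Welch otherwise.

## Synthetic data

Generators produce data with the statistical structure the analyses
assume and return their generating parameters for recovery scoring.
They are bit-reproducible from their seeds.

* `gen_edge_trace` — position `x(t) = r0·τ·(1 − e^(−t/τ))` plus i.i.d.
  Gaussian frame noise. Defaults: `r0 = 7.4 µm/h` (the observed initial
  closure rate), τ = 2 h for older larvae and 4 h for 2–3 dpf animals
  (rates persist longer in younger fish), 10-min frames over 6 h, 1 µm
  noise. Exponential decline is the minimal monotone form consistent with
  rates that are maximal at onset and decay over a few hours; the real
  kinetics were not fit to any functional form.
* `gen_pair_traces` — symmetric pairs with initial separations uniform on
  [50, 1.2·L_tot] µm converge by `Δ(d0) = max(0, m·(L_tot − d0))` with
  `m` set so a pair spanning the injury converges by twice the edge
  displacement (default: full closure). Linear decay with a hard zero at
  `L_tot = 434 µm` mirrors the regression construction that the zone
  estimate is based on. Default noise 5 µm per coordinate per frame, 60
  pairs.
* `gen_band_events` — two Gaussian bands at ±140 µm (SD 25 µm) plus a
  Poisson-uniform background over a ±500 µm window (off-target labelling).
* `gen_count_table` — paired Poisson counts per animal; baseline mean 5
  per tubule, tripled on the injured side under the "long" regime and
  unchanged under "short" and "control". The magnitudes are
  order-of-magnitude choices consistent with counts of labelled nuclei
  per tubule segment; only means and tests are compared downstream.

Noise defaults are order-of-magnitude choices (per-animal variability was
never tabulated); parameter-recovery tests quantify what the analyses can
recover *under these assumptions* — homogeneous Gaussian tracking error,
exact pair symmetry, stationary band positions. Passing them does not
certify performance on real imaging data, where tracking error is
heteroscedastic, pairs are imperfectly symmetric and closure times vary.

## What the simulation does and does not show

The model demonstrates sufficiency, not mechanism identification: a free
edge plus contact inhibition reproduces immediate collective migration
with declining rate; stretch gating with a delay reproduces late
proliferation confined to long injuries and organised in two flanking
bands. The model compresses the in vivo timescale (proliferation begins
~8–15 h post-ablation in simulation vs 36–48 h in vivo) and contains no
cell death, debris, luminal flow or obstruction dynamics, no 3-D tubular
or basement-membrane mechanics, and no epithelial–mesenchymal state (the
repair proceeds without such a transition). The anchored ends are an
artificial truncation; divisions are not scored within 5 pitches of them.
Daughter cells appear instantaneously at half the mother–partner
separation; cell size, shape and junction topology are not represented.

## Numerical choices

* Single seeded `numpy` PCG64 generator per run; cells updated
  synchronously in id (creation) order; results are bit-reproducible
  from the seed.
* Neighbour searches use KD-trees; transverse periodicity uses the
  minimum-image convention (implemented by embedding positions in a
  periodic box much wider than the sheet in x).
* The gap interval is half-open [lo, hi); all lengths are µm and times
  hours; x increases proximal → distal.
* Edge traces record the mean x of the three cells nearest the gap on
  each side, every step.
* Division draws use one uniform per cell per step; daughters are
  appended so parent ids are stable.
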