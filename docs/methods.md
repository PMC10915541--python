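# Methods

This note documents the models behind `whaletrack`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would otherwise have to
reverse-engineer.

## Track preprocessing

Argos fix tables arrive in the Wildlife Computers CSV dialect (DeployID,
Date as `HH:MM:SS dd-mmm-yyyy`, Quality ∈ {3,2,1,0,A,B,Z}, Latitude,
Longitude). Cleaning is deliberately conservative and deterministic:

* **Class filter.** Class Z carries no usable location and is dropped by
  default; the class set is configurable.
* **Duplicates.** Two fixes with one timestamp keep the better location
  class, ties keep the first occurrence.
* **Land filter.** Optional polygon containment test; no coastline is
  bundled — the mask is caller-supplied.
* **Speed filter.** The literature states only a ceiling (7 m s⁻¹ for fin
  whales). Many removal rules are consistent with a ceiling; we use a
  forward sweep that drops the *later* fix of any violating pair and
  re-checks from the last retained fix, iterated to convergence. It is
  order-stable, never removes the first fix, idempotent, and leaves no
  consecutive pair above the ceiling — all asserted by tests.
* **Truncation.** Fixes strictly after a per-animal cutoff instant are
  dropped (used when an animal definitively leaves a study area).
* **Deployment summary.** Duration is the *calendar-day* difference between
  last and first uplink dates (8 → 22 May counts 14 days); across-animal
  dispersion uses the population standard deviation (divisor *n*). These
  conventions reproduce the campaign log statistics exactly (mean 23.5 d,
  sd 11.3 d over 11 whales).

## Continuous-time CRW regularization

State per planar axis: (position x, velocity v) with
dv = −β·v·dt + σ·dW and dx = v·dt — an integrated Ornstein–Uhlenbeck
(correlated-random-walk) process. Its transition over a gap Δ is exactly
linear-Gaussian:

    F = [[1, (1−e^{−βΔ})/β], [0, e^{−βΔ}]]

with the standard IOU covariance, so irregular fixes cost nothing: the
Kalman filter runs over the union of observation and prediction epochs, and
the Rauch–Tung–Striebel smoother delivers positions and standard errors on
the regular grid t₀ + kΔt (default Δt = 3 h).

* **Observation model.** Isotropic Gaussian per Argos class with fixed,
  configurable sds (defaults 250/500/1500/5000/5000/10000 m for classes
  3/2/1/0/A/B). Per-class variances are not estimated: a few hundred fixes
  cannot identify six variances and two process parameters.
* **Estimation.** (β, σ) maximised on log scale with Nelder–Mead from
  method-of-moments starts (β₀ = 1/mean gap, σ₀ from empirical displacement
  speed). The x and y axes share parameters; animals are fitted
  independently. Non-convergence is reported with best-so-far values, never
  silently.
* **Projection.** A local transverse Mercator centred on the dataset
  centroid (Krüger series, sub-mm accurate at regional scale); all
  step/kernel computations are planar thereafter.
* **Time-step comparison.** The marginal likelihood of this continuous-time
  model does not depend on the prediction interval, so candidate steps are
  compared by snapping fixes to each candidate grid (precision-weighted
  averaging of fixes sharing a node), refitting, and reporting AICc
  (2k − 2lnL + 2k(k+1)/(n−k−1)) plus one-step-ahead residual RMS. Because
  the candidates see differently binned data, the residual column is the
  more comparable diagnostic; the function returns a ranked table and
  deliberately declares no winner.
* **Validation twin.** `simulate_crw_truth` draws tracks from the IOU
  process itself. This matters: the smoothing-benefit check ("smoothed RMSE
  < raw RMSE") is a property of a correctly implemented smoother *under its
  own model class*, and is evaluated at the observation epochs — comparing
  gap extrapolations against raw error at fix times would conflate
  interpolation uncertainty with smoothing quality. Under hourly fixes
  inside the duty windows with class-3 noise (β = 10⁻⁵ s⁻¹, σ = 0.002
  m s⁻³ᐟ², velocity sd ≈ 0.45 m s⁻¹) the smoother wins in 50/50 replicates.

## Behavioural HMM

Two states on the 3-h step series: step length ~ Gamma (moment
parameterisation: shape = (μ/σ)², scale = σ²/μ), turning angle ~ von Mises.
ARS is identified by *both* the smaller step mean and the smaller angular
concentration; if a fitted model separates on step length but the
short-step state is the more directed one, labelling raises an error rather
than guessing — a silent relabel would corrupt every downstream budget.

* Pooled fitting by default: one parameter set, animals as independent
  chains (log-likelihoods add).
* The initial state distribution is the stationary distribution of the
  transition matrix.
* Optimisation on unconstrained transforms: log (positive scalars), logit
  (transition off-diagonals), a (sin, cos) pair through atan2 (angle
  means). Restarts jitter starts around data quantiles (30%/70% step
  quantiles seed the two state means) because HMM likelihoods are
  multimodal.
* The forward recursion and Viterbi run in log space (no underflow at 10⁴
  intervals) and are JIT-compiled; emission log-densities use
  `scipy.special` primitives directly, cross-checked in tests against
  `scipy.stats` and against brute-force path enumeration (n ≤ 10, 10⁻¹⁰).
* Missing turning angles (first interval of a track, zero-length steps)
  contribute the step density only — the correct marginal.
* Viterbi ties break toward ARS; budgets report per-animal ARS fractions
  with across-animal mean and median.

At the study conditions (5000 steps, well-separated states) the fit
recovers transition entries to ±0.01, step means to a few percent, and
decoding accuracy ≈ 98%.

## Kernel home ranges and overlap

Bivariate-normal kernel density over the regularized positions, gridded at
10 × 10 km; because positions are temporally equidistant, mass = fraction
of tracked time. Bandwidth is the reference (*ad hoc*) rule
h = ½(s_x + s_y)·n^(−1/6) — the arithmetic-mean convention of the classic
home-range software. The grid covers the points with a 3h margin (snapped
to whole cells); masses are renormalised to sum to exactly 1.

Isopleths take cells in decreasing density order (ties broken row-major)
until the level is reached, so the region is minimal; area = member cells ×
cell area, which is honest about the 10-km granularity (a finer grid is one
argument away). Percent overlap is area(A_i ∩ A_j)/area(A_i) — asymmetric
by definition. Bhattacharyya affinity truncates each UD to its own
isopleth *without renormalising*, giving ceilings equal to the level (0.95
home, 0.50 core); self-affinity then equals the contained isopleth mass,
which the tests pin to within one cell mass of the level.

Pooled (e.g. per-year) UDs weight every regular position equally, so an
animal contributes in proportion to its tracking duration; the bandwidth is
computed on the pooled set.

## Chlorophyll-front feeding habitat

The habitat model is deterministic: krill aggregates along persistent
productivity fronts, so the score is centred on the horizontal gradient of
surface chlorophyll-a, with absolute chlorophyll and depth acting only as
exclusions.

* **Gradient.** Centred finite differences on the 1/24° grid with spacing
  in km (east–west spacing scaled by cos φ); any missing neighbour makes
  the output cell missing; edges are missing. A planar-spacing mode exists
  for synthetic/rotation tests.
* **Daily habitat.** ramp(|∇CHL|; g₀, g₁) · 1[CHL ∈ [chl_min, chl_max]] ·
  depth_factor, in [0, 1]; depth_factor is 0 below a minimum depth, a
  configurable multiplier α in an outer-shelf band, 1 otherwise.
* **Thresholds are configuration.** The published calibration of g₀, g₁,
  the chlorophyll window and the depth rules is not reproduced here;
  `example_params()` provides clearly-labelled illustrative placeholders
  and `calibrate_gradient_ramp` sets (g₀, g₁) from quantiles (default
  5th/95th) of gradients sampled at presence points.
* **Time integration.** Daily habitat is smoothed with a centred 3-day
  rolling mean, then per-cell frequency = share of valid days above 0.3,
  expressed in percent; cloud-masked days leave the denominator (MODIS gaps
  would otherwise deflate frequency). A time-mean mode is available behind
  a flag. Main habitat: frequency strictly above 30%.
* **Distances.** Great-circle distance from each position to the nearest
  main-habitat cell (0 inside a cell), with a fraction-within-d summary
  (default 1 km).

On synthetic drifting-front fields the main habitat concentrates along the
swept front band (100% of cells in the acceptance run, against a ≥ 90%
requirement).

## Conservation-zone overlap

Ranges are converted back to lon/lat and both geometries projected to a
Lambert azimuthal equal-area frame centred on the range, built on the
authalic sphere with authalic latitudes — equal-area to ellipsoidal
accuracy, so overlap percentages are trustworthy at the 0.01% formatting
precision. An independent geodesic polygon-area line integral serves as the
oracle (agreement < 0.1%, typically ~10⁻⁶ relative). Zone polygons are
user-supplied GeoJSON, validated (closed, non-self-intersecting, unique
names) and never bundled. The report is long-format (zone × year ×
{core, home}); missing levels produce explicit missing rows.

## Synthetic-data generator

The generator reproduces the *structure* of the field campaign: 11 whales
across three seasons with 8–48-day deployments (the real duration
spectrum), 3-h true resolution, transmissions only inside two daily duty
windows (6–11 and 16–22 UTC), class-dependent isotropic position noise with
a class mix skewed toward A/B (typical of dorsal-fin LIMPET tags; no
published mix exists), and daily 1/24° chlorophyll fields with a logistic
front of configurable width and drift. The movement defaults — ARS steps
2 ± 1.6 km with κ = 0.6, transit 12 ± 6 km with κ = 9, stay-probabilities
0.95/0.65 giving stationary ARS occupancy 0.875 — are one-time choices
matching a slow-swimming feeding whale and the reported ~87% foraging
budget.

What it does **not** emulate: real oceanographic dynamics (fronts are a
single drifting logistic edge; clouds are i.i.d. per-cell), tag failure and
battery models, correlated Argos error ellipses, or behavioural coupling
between movement and the chlorophyll field (synthetic whales do not steer
toward fronts). Consequently, passing tests demonstrate that each estimator
recovers what its own model class generates and that the plumbing is exact
— not that the ecological conclusions of any particular field dataset are
reproduced.

## Numerical choices and degenerate inputs

* Fixed seeds thread through every stochastic component
  (`numpy.random.default_rng`); pipeline reruns are byte-identical and every
  artefact embeds the seed and a configuration hash.
* Turning angles wrap to (−π, π] (a U-turn is +π); zero-length steps make
  adjacent angles missing rather than arbitrary.
* UD isopleth ties (equal-density cells) resolve in row-major order, making
  regions reproducible across platforms.
* The Kalman filter uses a diffuse-ish position prior (first fix, inflated
  variance) and the stationary velocity variance σ²/(2β).
* Degenerate inputs fail loudly with named errors: non-stochastic transition
  matrices, overlapping duty windows, zero point spread in `href`, grids
  not covering points with a 3h margin, misaligned habitat rasters,
  all-equal presence gradients, invalid or duplicate zone polygons.

## Problem sizes

Defaults used by the test suite and the acceptance script: 5000 steps for
HMM recovery, 50-point UDs for oracle comparisons (10⁻¹² agreement with a
brute-force double loop), 50 replicates for the smoothing-benefit count,
30-day chlorophyll stacks on the 1/24° grid, and a 3–11-animal fleet for
end-to-end runs. These sizes give stable statistics (recovery errors well
inside their tolerances) while keeping a full run to minutes on one core.

## Known limitations

Per-class Argos sds are assumed, not estimated; the SSM is fitted per
animal (no hierarchical sharing); the speed filter is one of several rules
consistent with a bare ceiling; AICc across time steps compares differently
binned data; isopleth areas are cell-count areas; the habitat thresholds
ship as placeholders pending calibration on real presence data; and the
published dataset-level results (mean ARS budget 87.5%, inter-annual range
overlaps, Pelagos overlap) require the archived tracking data and official
zone geometries, which are catalogued as external references rather than
recomputed.
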