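# Methods

## Ellipsoid volumetry

Caliper measurements give three orthogonal tumor dimensions. Surface
area uses the power-mean (Thomsen-type) approximation with exponent
p = 1.6, the constant as used in the study design this package
implements (Thomsen's own 1.6075 can be passed explicitly); volume is
exact. Both formulas assume the dimensions are **semi-axes**. Whether
raw caliper readings are semi-axes or full widths is a lab convention,
so ingestion takes `caliper_convention: semi_axes | full_widths`
(default `semi_axes`, which applies the formulas to the numbers as
recorded; `full_widths` halves each dimension first). Rows with fewer
than three dimensions are rejected rather than imputed. Negative or
non-finite dimensions and duplicate (mouse, day) rows are validation
errors that name the offending field.

Accuracy of the p = 1.6 approximation against adaptive quadrature of
the exact parametric surface integral is below 1.5% relative error for
aspect ratios up to 4:1 (the test suite and acceptance script measure
≈0.5% worst-case on that grid); tumors are rarely more eccentric.

## Growth curves

Per strain, all individual measurements (every mouse, every day) are
pooled and fitted by unpenalized least squares in a clamped B-spline
basis: `n_basis = 6` cubic (order 4) functions on
[first observed day, last observed day], interior knots equally
spaced. Six basis functions on a ~31-day range smooth heavily — that
is the point with two mice per group — while a cubic basis keeps the
second derivative (acceleration) continuous. Derivatives are exact
spline differentiation; no extrapolation outside the fitted domain is
ever allowed. Per-day mean ± SE (sample SD/√n; 0 with a warning when
n = 1) is computed only for display and for the AUC simulation.

Design choices that were genuinely open:

* **Order.** Only the basis size is prescribed by the study design;
  cubic is the functional-data default and is what the derivative
  analysis (velocity, acceleration) needs. Exposed in config.
* **No roughness penalty.** Smoothing comes entirely from basis
  truncation; a second-derivative penalty hook exists in principle but
  the default (and tested) path is plain least squares.
* **Pooled, not per-mouse, fits.** One curve per strain fitted to the
  combined data; per-mouse curves are out of scope.
* Unconstrained smoothing can produce slightly negative early
  velocities on flat early data; this is a known artifact of
  unpenalized spline fits, not a biological signal.

## Monte-Carlo AUC comparison

The comparison statistic is the area under the size-time curve over
days 30–41, the late window where strains separate. The sampling
distribution of "simulated paired observations" is per-day Gaussian:
each iteration draws value ~ Normal(per-day mean, per-day SE),
truncated at zero, at each sampling day — the observed measurement
days inside the window, with window endpoints added by linear
interpolation of mean and SE when no measurement falls exactly there.
Gaussian around the reported summaries is the minimal assumption given
that mean ± SE is exactly what such studies report per timepoint.
"Paired" means a shared iteration index: each iteration yields one AUC
per strain and one winner (largest AUC). Defaults: 10,000 iterations,
explicit seed required. Draws are generated as mean + SE·z with a
per-strain stream, so raising one strain's means under a fixed seed
never lowers its win proportion (common random numbers). Ties are
measure-zero under continuous draws; they are broken toward the lowest
strain index and counted in the report. A single sampling day is
allowed and degenerates to comparing the day's values, which equals
the AUC comparison of flat trajectories — this is the configuration
under which the closed-form two-strain check
P(win) = Φ(Δmean/√(SE₁²+SE₂²)) applies exactly.

AUC is computed on the simulated day-level observations directly;
refitting a spline per iteration is unnecessary for a rank comparison
and is off by default.

## Cohort statistics

Lines of best fit are closed-form OLS with R² = 1 − SSres/SStot
(defined as 0, with a warning, for zero-variance y). The two-sample
test defaults to the pooled-variance Student t (two-sided), with Welch
available by flag. Degenerate zero-variance cases are made explicit:
equal-mean constants give t = 0, p = 1; unequal-mean constants are an
error. The tested-vs-selected comparison unit is the per-mouse size at
each mouse's final measurement day — an interpretation, stated here
because the comparison protocol is otherwise underdetermined. Percent
comparisons report 100·(a−b)/b rounded to integer percent, with the
raw value retained.

## Apoptotic index

Nsr = Nsp/Nt per region; per section, the mean of the k = 3 largest
Nsr values (all regions, with a warning, if fewer than 3). Top-k
hot-spot averaging targets the focal pattern of thermal-ablation
damage: apoptosis concentrates where the energy was focused, so a
whole-section mean would dilute the effect. Regions with Nt = 0 are
excluded with a warning. The tiling helper lays identical rectangles
(default 500×500 µm — a size chosen to give tens of regions on a
typical few-mm section; configurable) from the origin, clipping and
flagging partial edge rectangles, which are excluded from top-k
selection by default because their counts are area-biased. The module
consumes count tables; pixel-level classification of scanned slides is
upstream vendor-software territory. With several sections per arm the
per-section indices are averaged; percent increase is computed between
arm-level indices against a designated control arm.

## Synthetic data

The generator emulates the cohort structure the analysis assumes:
three strains × 2 mice (or one strain × 48 in 6 staggered batches),
measured 2–3×/week from day 10 to day 41 post-injection.

* **Growth law.** Gompertz, V(t) = v_max·exp(−exp(−k·(t−lag))):
  sigmoidal with a slow early phase and acceleration after ~day 20,
  matching the observed phenomenology; logistic/exponential variants
  can be expressed by supplying custom parameters objects if needed.
* **Preset calibration.** Each strain preset is pinned by two anchors
  of the noiseless trajectory: V(day 10) = 0.05 cm³ — the conventional
  ~50 mm³ measurable-size threshold at which caliper monitoring
  starts — and the strain's day-41 mean volume (0.80 / 0.51 / 0.40 cm³
  for nsg / nsgs / nude). Growth rates k = 0.085 / 0.080 / 0.075 per
  day set the separation in between; the solved inflection days land
  near day 21–23. Under this calibration the strains stay strictly
  ordered nsg > nsgs > nude throughout days 30–41 and none plateaus
  (volumes still grow 33–39% over that window).
* **Heterogeneity and noise.** Mean-one log-normal random effects
  (default 15% CV) multiply each mouse's v_max and k; each mouse keeps
  a persistent ellipsoid shape, sampled as two log aspect ratios
  (SD 0.15) with the third balancing the product so the axis product —
  hence the volume — is preserved exactly; caliper noise is
  independent mean-one log-normal per dimension per day (default 10%
  CV). Because every multiplicative factor has mean one, the expected
  reconstructed volume equals the Gompertz mean, which the large-n
  test verifies.
* **Histology.** Per region, Nt ~ Poisson(cells_per_region, floored at
  1) and Nsp ~ Binomial(Nt, p_arm).

What the generator does **not** emulate: tumor shape change over time,
measurement dropout, treatment effects on growth, inter-mouse
correlation beyond the random effects, or spatial structure within
histology sections. Passing tests therefore demonstrate that the
pipeline recovers what this generative model plants — correct
formulas, calibrated Monte-Carlo machinery, correct ranking under
realistic noise — not that real tumors follow a Gompertz law.

## Numerical choices and problem sizes

Spline fits use `BSpline.design_matrix` + `lstsq` (rank-revealing);
fitting requires at least `n_basis` distinct days. The default
reporting grid is 0.5-day spacing (display only). The round-trip check
(noiseless cohort → geometry → spline) holds spline-approximation
error ≈1% of the true curve on days 12–40. Monte-Carlo checks use
30,000 iterations (symmetry), 100,000 (closed-form case), and 50
replicate cohorts × 10,000 iterations (ordering recovery); these sizes
put the Monte-Carlo standard error an order of magnitude below the
tolerances asserted while keeping the whole suite fast. Type-I-error
calibration uses 10,000 null pairs of n = 10 normals. All simulations
take explicit integer seeds through `numpy.random.default_rng`.

## Known limitations

* Pooled spline fits have no confidence bands; no mixed-effects or
  monotonicity-constrained variants.
* The AUC win proportion is descriptive, not a hypothesis test; no
  multiplicity control is applied anywhere (two planned comparisons).
* The zero-truncation of Gaussian draws slightly biases simulated
  values upward when SE is comparable to the mean (only relevant for
  near-zero sizes; the day 30–41 window is far from that regime).
* Caliper-convention ambiguity (semi-axes vs. full widths) cannot be
  resolved from size magnitudes alone; results scale by 4 (SA) or
  8 (V) between conventions.
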