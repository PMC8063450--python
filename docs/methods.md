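# Methods

`movebench` is a simulation benchmark for statistical methods that infer
local habitat selection and large-scale attraction/avoidance from animal
tracking data. It simulates landscapes and tracks from an explicit
individual-based movement model, fits four families of models to the
simulated tracks, and measures their statistical power and type-I error
rates. This note documents the models, the choices behind every tunable
default, and what the synthetic data do and do not represent.

## Habitat model

A landscape is a square raster (default 1000 × 1000 pixels) of habitat
values `hab ∈ [0, 1]`, built from iid Uniform(0, 1) pixel noise smoothed by a
Gaussian moving window with reflect padding:

* `hab_auto ∈ [0, 1]` sets the window standard deviation along y to
  `6 · hab_auto` px. The maximum patch correlation length (~12 px) is of the
  same order as observed tracking-step lengths (~6–17 px), so habitat varies
  detectably within each step's availability neighbourhood; much wider
  windows make the landscape locally flat at the scale any of the fitted
  models can see. `hab_auto = 0` applies no smoothing at all.
* `hab_anis ∈ [0, 1]` multiplies the x-direction window scale by
  `1 + 9 · hab_anis`, stretching patches along the x-axis.
* After smoothing, the field is rank-equalized back to an exact Uniform(0, 1)
  marginal. Convolution alone concentrates values near 0.5 (the more so the
  wider the window), which would make the realized habitat contrast — and
  with it every power result — an artefact of the window width rather than of
  `hab_auto`.
* `hab_smooth` shapes patch transitions: `sharp` applies a sigmoid contrast
  curve after equalization (values pushed towards 0/1, crisp boundaries),
  `medium` keeps the equalized field, `blurry` smooths twice before
  equalizing.
* `hab_type = categorical` thresholds the final field at 0.5 into {0, 1}
  (balanced classes, since the marginal is uniform). When parameters are
  randomized, `hab_type` is Bernoulli(0.5) and the other knobs are uniform
  over their ranges.

Moran's I with rook contiguity (optionally restricted to one axis) is the
autocorrelation diagnostic; expected I is monotone in `hab_auto` and the
x/y directional split quantifies anisotropy.

## Movement model

An animal occupies one pixel per 1-minute step and moves to one of its 8
neighbours Y with probability `F(Y) / Σ_Z F(Z)`, where

```
F(Y) = exp( ε_Y + σ_ω·hab(Y) − μ·‖Y − X_t‖ − σ_α·α_att(Y) − f·α_pers(Y) )
f    = σ_ran / (1 + σ_ran2 · mean_neighbour_hab)
```

* `ε_Y ~ N(0, σ_SD)`, drawn independently for each neighbour at each step —
  unexplained variation; `σ_SD ∈ [0, 2.5]`.
* `σ_ω ∈ [0, 1]` — habitat-selection strength.
* `μ = 1.8` — distance penalty separating rook from diagonal moves.
* `α_att` is the absolute angle (radians, in [0, π]) between the candidate
  step direction and the direction from the current pixel to a fixed
  attraction centre; `σ_α ∈ [0, 0.1]` produces a biased random walk.
  (Measuring the angle at the current pixel rather than at the candidate is
  the only reading consistent with a directional bias; the alternative is
  noted as ambiguous.)
* `α_pers` is the same angle against the previous realized step direction;
  `σ_ran ∈ [0, 2.5]` gives directional persistence (correlated random walk)
  and `σ_ran2 ∈ [0, 1]` weakens it where the local habitat (neighbour mean)
  is good — area-restricted search. The first step has no previous heading
  and drops the persistence term.

Trips run 5000 steps from a start inside the central 500 × 500 square, with
the attraction centre inside the central 850 × 850 square; the border is
assumed unreachable and a trip that does reach it aborts (study runners retry
with a deterministically derived attempt sub-seed; at these settings this is
rare). The inner loop is numba-compiled with all random draws taken from a
numpy Generator beforehand, so a pure-Python stepper reproduces it exactly.

Device-like tracking data are the path positions at
`round(linspace(0, n_steps, 300))` with iid `N(0, Error_spat)` noise added to
each coordinate (`Error_spat ∈ [0, 3]` px). Per-point step metrics: step
length `d_x`, turning angle `ta`, distance to the attraction centre
`attrac_dist`, and `attrac_ang`, the cosine of the angular deviation of the
realized step from the line previous-point → centre. Zero-length steps leave
angles undefined; `d_x` is floored at 1e-6 before logs and affected strata
are dropped from stratified designs.

## Availability designs

All families share one design-table schema (used flag, response `u`, weight
`w`, covariates `hab`, `attrac_dist`, `attrac_ang`, `log_dx`, `cos_ta`), so
coefficients are comparable like-for-like. Strata are the tracking points at
which both the current step and the previous heading are defined. Nominal
dummy levels are 8/80/230 per tracking point.

* **SLRM** — dummy points uniform inside the minimum convex polygon of the
  track (shapely convex hull; rejection sampling), generated once per trip.
* **SSM/iSSM** — per stratum, available steps anchored at the previous
  tracking point with lengths from a maximum-likelihood gamma fit and turning
  angles from a von Mises fit to the observed steps (scipy MLE).
* **ST-PPM** — per stratum, a regular √n × √n grid (n = 9/81/225, the nearest
  perfect squares to the nominal levels) of side `l` centred on the previous
  tracking point, independently rotated by Uniform(0, 2π); rectangle-rule
  weights `w = l²/(n+1)` shared by the used point, `u = 1/w` on used rows.

The grid extent is chosen per trip by fitting a habitat-only probe model
(8 dummies) at `l = 2.5, 5.0, 7.5, …` and stopping when the relative change
of the monitored likelihood is ≤ 1% or switches sign, returning the previous
extent (cap 50 with a warning). The monitored quantity is the habitat
model's log-likelihood **gain** over the intercept-only fit at the same
extent: the raw quadrature log-likelihood falls like `−2·log l` per stratum
as the grid dilutes — a pure intercept rescaling that carries no convergence
information — whereas the gain is scale-invariant and stabilises (or starts
fluctuating in sign) once the grid covers the locally available area.

## Model fitting

* **SLRM** (`plain`/`smooth`/`weighted`): binomial GLM of used vs dummy on
  the focal covariate (statsmodels). `smooth` adds a penalized tensor-product
  B-spline over the coordinates (≤ 36 basis functions; no thin-plate basis
  exists in the installed stack, and a tensor product is the equivalent 2-D
  smooth); `weighted` gives dummies prior weight 1000, the "infinitely
  weighted" logistic regression whose likelihood approaches an inhomogeneous
  Poisson process.
* **SSM/iSSM**: conditional (per-stratum multinomial) logistic regression,
  solved by a vectorised Newton iteration with segment reductions (the study
  needs thousands of fits; statsmodels' ConditionalLogit is the cross-check
  oracle in the tests). The iSSM selects by AIC (= 2k − 2lnL, ties to fewer
  parameters) among five candidates adding `log(d_x)`, `cos(ta)` and their
  interaction to the focal covariate.
* **ST-PPM**: the spatio-temporal point-process likelihood is approximated by
  `Σ w(u·logλ − λ)` and fitted as a weighted Poisson regression. Smooth
  terms `s(·)` are penalized B-splines (basis and curvature penalty from
  statsmodels' BSplines, df 8, columns centred for identifiability, covariate
  clipped to its [1%, 99%] range so the grid-centre rows with near-zero step
  length do not consume the basis); `te(·)` is the tensor product of two
  5-column marginals with a Kronecker-sum penalty. Smoothing parameters
  minimise GCV `n·D/(n − edf)²` over a log-spaced grid (coordinate-wise for
  two smooths, warm-started); `edf` is the trace of the influence matrix.
  Candidate AICs use the point-process likelihood with these edf, not the
  Poisson GLM deviance. IRLS runs to a 1e-10 relative deviance tolerance,
  max 100 iterations, with the linear predictor clipped at ±30.
* Significance is a two-sided Wald z-test on the focal coefficient in every
  family. Non-convergence (including separation, guarded by a |coef| < 30
  check on unpenalized terms) flags the fit and excludes the record.

## Evaluation

A fit becomes the binary outcome `effect = 1{p < 0.05}` (strict). Rates are
aggregated hierarchically — block means per landscape, then across blocks —
with 95% percentile bootstrap intervals over 1000 block-mean resamples. The
multi-trip analysis tests whether the mean of five per-trip coefficients
differs from zero (one-sample t, df 4; all-equal-nonzero counts as
significant by convention, all-zero as not).

The meta-analysis regresses `effect` on habitat/movement/method predictors:
L1-penalized logistic regression (scikit-learn, predictors standardized,
10-fold CV) pre-selects predictors, then a binomial GEE with exchangeable
working correlation clustered on the landscape id (statsmodels, robust SEs)
tests them at the Bonferroni level α/m, m = number of candidates entering
the LASSO. The CV penalty follows the one-standard-error rule — the
strongest penalty within one SE of the minimum CV log-loss — because the
plain CV-minimum systematically retains several pure-noise predictors,
defeating the purpose of pre-selection.

## Study scales and seeding

Every random stream derives from `SeedSequence(master, spawn_key=(landscape,
trip, stage[, attempt]))`, so results are bit-identical regardless of worker
count or execution order (joblib parallelism over landscapes). The full
published-scale design (400 landscapes × 10 trips × 6 families × 3 dummy
levels) is configurable but far beyond a desktop; the shipped presets are a
40 × 10 desk study and a ~100-null/100-effect single-panel study, and the
acceptance script uses 400 null trips (iSSM), 100 null trips (ST-PPM) and
120 effect trips per habitat type — sizes chosen so the whole recomputation
runs in minutes on one CPU while keeping Monte-Carlo error a few percentage
points.

## What the synthetic data do not show

The generator emulates pixel-scale foraging with selection, persistence,
attraction and device noise. It does not include behavioural-state
switching, irregular sampling, habitat-dependent measurement error, home-
range revisitation memory, or real GIS layers; passing tests show method
behaviour under this generative model only. One caveat deserves emphasis:
under this kernel the detectable habitat-selection signal is substantially
stronger on categorical (binary) landscapes than on continuous ones — binary
rasters present O(σ_ω) per-step contrasts at patch boundaries while any
smooth field offers only O(σ_ω·0.3/σ_window), and binary covariates yield
smaller conditional-logit standard errors. Published comparisons based on a
different (unrecoverable) landscape recipe report the opposite ordering, so
absolute power levels here should be read as properties of this generator,
not of field data; the type-I error results, the method rankings within a
habitat type, and the covariate sign structure are the robust quantities.

## Known limitations

* GLMM variants, Brownian-bridge availability and non-rectangular quadrature
  are out of scope by design.
* The ST-PPM smoothing-parameter search uses a coarse 5-point grid per
  smooth; fully nested REML optimisation would be slower and was not needed
  for stable selection behaviour.
* `attrac_ang` is undefined for SLRMs (no temporal order) and the model
  rejects that combination explicitly.
* GeoTIFF output is not implemented; rasters are exchanged as ESRI ASCII
  grids with JSON sidecars.
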