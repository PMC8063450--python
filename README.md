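# movebench

A simulation benchmark for statistical methods that infer **local habitat
selection** and **large-scale attraction/avoidance** from animal tracking
data. The package simulates landscapes and GPS-like tracks from an explicit
individual-based movement model, fits four families of models to the tracks,
and measures their statistical power and type-I error rates — the kind of
evidence needed to decide which method to trust on real telemetry data.

Audience: movement ecologists and biostatisticians comparing step-selection
and point-process workflows, and methodologists who need a controlled
generative test-bed.

## The models being compared

Tracking points are "used" locations; every method augments them with dummy
points quantifying availability, then tests a focal covariate (habitat value
`hab`, distance to an attraction centre `attrac_dist`, or the directional
measure `attrac_ang`):

| family | availability | fit |
|---|---|---|
| `SLRM`, `SLRM_s`, `SLRM_w` | uniform dummies in the track's minimum convex polygon | binomial GLM (`_s`: + penalized 2-D spatial spline; `_w`: dummy weight 1000) |
| `SSM` | gamma step lengths × von Mises turning angles per stratum | conditional logistic regression |
| `iSSM` | as SSM | conditional logit + AIC selection over movement terms `log(d_x)`, `cos(ta)`, interaction |
| `STPPM` | rotated quadrature grids, rectangle-rule weights, data-driven extent | weighted Poisson regression of the point-process likelihood Σ wᵢ(uᵢ log λᵢ − λᵢ), penalized smooths `s(·)`, `te(·)`, PPM-likelihood AIC |

Tracks come from a stepping-stone kernel: at each 1-minute step the animal
moves to one of its 8 neighbouring pixels with probability ∝
`exp(ε + σ_ω·hab − μ‖Δ‖ − σ_α·α_att − f(σ_ran, σ_ran2)·α_pers)`,
then 5000 steps are thinned to 300 tracking points with Gaussian position
error — so the fitted data carry exactly the spatio-temporal and angular
autocorrelation that trips up naive spatial regressions. See
`docs/methods.md` for the full model and every default.

## Worked example

`examples/03_fit_all_models.py` simulates one trip with a true habitat
effect (σ_ω = 0.8) on a 1000 × 1000 landscape and fits all six models at 80
dummy points:

```
family    estimate      se         p  selected formula
SLRM         0.999   0.219  4.79e-06  hab
SLRM_s       0.604   0.241  1.23e-02  hab
SLRM_w       1.001   0.217  4.11e-06  hab
SSM          0.764   0.243  1.70e-03  hab
iSSM         0.764   0.243  1.70e-03  hab
STPPM        0.639   0.213  2.70e-03  hab + s(log_dx)
```

Every family recovers a positive habitat coefficient on this effect trip;
the benchmark's point is what happens on *null* trips, where the SLRMs —
blind to autocorrelation — keep "detecting" effects far above the 5% nominal
rate while iSSM and ST-PPM stay calibrated (run
`tests/test_acceptance.py` or the acceptance script to see those rates).
The other examples cover landscape generation and diagnostics (`01`), track
simulation (`02`), a miniature end-to-end power study (`04`) and the
LASSO + GEE meta-analysis (`05`).

## Layout

```
src/movebench/     habitat.py, movement.py  — synthetic-data generators
                   availability.py          — the three dummy-point schemes
                   inference.py             — the six model fits
                   evaluation.py            — rates, bootstrap CIs, LASSO+GEE
                   runner.py                — study orchestration, seeding, presets
examples/          one short narrative script per capability
tests/             pytest suite incl. end-to-end statistical checks
docs/methods.md    models, assumptions, defaults, limitations
```
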