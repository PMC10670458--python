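# Methods

## Model

Each (sample, drug) series is modelled with the four-parameter logistic
curve on a log10 molar concentration axis,

    f(x) = rmin + (rmax − rmin) / (1 + 10^(h·(x50 − x))),    x = log10 c,

where `rmin`/`rmax` are the lower/upper asymptotes in percent inhibition,
`h` the hill slope and `x50 = log10 IC50` the midpoint (traditional IC50).
Responses are always converted to percent inhibition first, so an active
drug produces a *rising* curve and the hill slope is constrained positive;
a data set that genuinely prefers a negative slope is reported as
non-convergent rather than silently flipped. The fit is ordinary
(unweighted) least squares on the per-concentration **mean** responses —
SEM is descriptive only (plots), never used as weights.

## Fitting procedure

1. **Initial guess**: asymptotes at the observed extreme means, slope 1,
   midpoint at the tested concentration whose mean is nearest the half-way
   response (ties broken toward the lower concentration — deterministic).
   Requires ≥ 4 distinct concentrations with defined means.
2. **Stage 1** — unconstrained Levenberg–Marquardt least squares
   (`scipy.optimize.curve_fit`) from that guess.
3. **Stage 2** — bounded trust-region refinement (`lmfit`, method
   `least_squares`) seeded by stage 1 and clipped into the bounds:
   `rmin ∈ [−10, 60]`, `rmax ∈ [−10, 120]`, `h ∈ (0, 20]`, `x50` within the
   tested range ± 3 log units. The asymptote bounds tolerate routine assay
   overshoot while rejecting absurd plateaus; all are configurable
   (`FitBounds`). The ordering constraint `rmax ≥ rmin` is enforced by a
   post-fit check (a violating fit is flagged) rather than inside the
   optimiser, since box bounds cannot couple two parameters.

A fit is **converged** only if both stages end with finite parameters, the
stage-2 SSE does not exceed the stage-1 SSE, and `rmax ≥ rmin`. Degenerate
inputs — flat response (range < 1e-9 % inhibition), fewer than four distinct
concentrations, optimiser breakdown — never raise; they return a flagged
result with a reason string so one pathological series cannot take down a
batch. Tolerances default to `xtol = ftol = 1e-12` with at most 10,000
function evaluations; on noiseless data from the model class this recovers
the generating parameters to ≈ 1e-13.

Standard errors of the estimates come from the stage-2 covariance estimate
and appear in `summary()`; they are asymptotic and indicative at n = 10
points, not exact.

## Replicates and outliers

Means are taken over non-missing wells; blank cells are allowed and
skipped, and a concentration whose wells are all missing is dropped with a
warning. SEM is defined only with ≥ 3 replicate columns. Optional outlier
screening uses an iterative **one-sided-max Grubbs test** per
concentration (default α = 0.05): the largest replicate is tested against
the rest, removed if extreme, and the test repeats on the survivors — one
removal per pass, never below three surviving wells. One-sided-max is the
right direction for contamination that inflates apparent inhibition;
symmetric two-sided screening was deliberately not implemented. The classic
Grubbs *masking* effect applies: two comparably extreme wells can shield
each other (covered by a test); with only 3–4 replicates no test can do
much better, which is why screening is opt-in.

## Metrics

All fitted-curve areas use the closed-form antiderivative
`∫ f dx = rmin·x + (rmax − rmin)·ln(1 + 10^(h(x − x50)))/(h·ln 10)`,
evaluated in overflow-safe form, so no score depends on a quadrature grid.
The test suite checks every area against an independent adaptive-quadrature
oracle to 1e-6.

* **Interpolated (absolute) IC50** — closed-form 50 % crossing
  `log10 c = x50 − (1/h)·log10((rmax − 50)/(50 − rmin))`; undefined when 50
  is outside the open interval (rmin, rmax).
* **AUC** — exact integral of `max(piecewise-linear interpolant of the mean
  responses − baseline, 0)` over the tested log10 range, splitting segments
  at the baseline crossing; baseline default 10 % inhibition. The trapezoid
  runs on the *raw means*, matching the spreadsheet/Prism convention the
  score is usually compared against; a fitted-curve AUC would be the
  closed-form integral and is trivially obtained from `logistic_area`.
* **DSS1–3** — with `A` the closed-form area of the fitted curve above
  threshold `t` (default 10) from its first crossing `x1` to the top of the
  tested range `x_max`:
  `DSS1 = 100·A/((100 − t)(x_max − x_min))`,
  `DSS2 = DSS1/log10(rmax)`,
  `DSS3 = DSS2·(x_max − x1)/(x_max − x_min)`.
  These are the published drug-sensitivity-score normalisations; since
  printed reference values for this assay design are not available, all
  three variants are validated against the quadrature oracle instead.
* **xepto50** — let `x0` be the interpolated-IC50 log-concentration and `C`
  the window width (default 2.0 log10 units, i.e. one hundred-fold span —
  wide enough to capture plateau behaviour, narrow enough to stay near a
  realistic tested range):

      score = ∫_{x0}^{x0+C} (min(f, 100) − 50) dx / ((100 − 50)·C) ∈ [0, 1].

  Implemented in midpoint-relative coordinates `u = x − x50`, in which `x0`
  is a pure function of (rmin, rmax, h); the score therefore never touches
  `x50` and position invariance holds to the last bit, not merely to a
  tolerance. Capping the integrand at 100 keeps the score inside [0, 1]
  even when the fitted plateau overshoots 100 (the bounds allow up to 120)
  while leaving it strictly increasing in `rmax` on (50, 100] and in `h`.
  Edge cases: the score is 0 when the curve never reaches 50 % inhibition
  (`rmax ≤ 50`); in the degenerate case `rmin ≥ 50` (curve above 50
  everywhere, crossing undefined) the window is anchored at the midpoint
  `x50`. The score is reported on [0, 1], not as a percentage.
  A note on the steep-slope limit: starting the window at the 50 % crossing
  puts exactly half of the sigmoid transition inside it, so the score
  approaches 1 with a deficit of `log10(2)/C · (100/h)/100` — about 3e-3 at
  h = 100, C = 2 — rather than reaching it.

## Quality scores

From residuals `r = observed − fitted` on the n mean responses with p = 4
parameters: `R² = 1 − SSE/SST`; adjusted R² with (n−1)/(n−p−1);
`Sy.x = sqrt(SSE/(n−p))`; `RMSE = sqrt(SSE/n)`; Shapiro–Wilk p on the
residuals (undefined below n = 5 or for identical residuals); explained
variance `1 − Var(r)/Var(observed)`; max |r|; `RMAE = sqrt(mean |r|)` —
the acronym is used inconsistently in the field, so plain MAE is emitted as
its own column; `MAPE` excludes exactly-zero observations rather than
erroring (0 % inhibition at low doses is routine). Undefined quantities are
reported as missing with a reason, never as NaN propagation or zero.

## Synthetic data

The generator emulates the target assay design: 10 concentrations
log-spaced 5 pM–10 µM, 3 replicate wells, 72 h viability readout expressed
in any response convention. Signal is the 4PL curve in percent inhibition;
noise is homoscedastic Gaussian, default σ = 2 % inhibition (a typical
luminescent-viability well-to-well scatter; no heteroscedastic option yet);
outlier wells (default rate 0) add a fixed +40 % inhibition shift.
Default documentation parameters are (0, 100, 1, −7.5). Draws are ordered
so that disabling noise or outliers leaves the other draws bit-identical.
What the generator does **not** emulate: plate-position (edge) effects,
drift over time, correlated replicate errors, biphasic responses, and
heteroscedastic noise near the asymptotes. Passing tests therefore
demonstrate correctness of the estimator and scores under the stated noise
model, not robustness to every artefact of real plates.

## Validation scale

Exact-recovery validation runs a 36-point grid of noiseless parameter
quadruples with hill slopes up to 3: steeper curves sampled at 10 points
degenerate toward step data in which slope and midpoint are no longer
jointly identifiable to tight tolerance, so the grid deliberately stays in
the identifiable regime. Statistical recovery uses 200 seeded series at
σ = 2 % (observed mean |Δlog10 IC50| ≈ 0.016–0.017); oracle agreement uses
100 randomised convergent parameter sets; the Shapiro–Wilk wiring is
calibrated on 1,000 seeded normal samples of n = 10.

## Known limitations

Five-parameter (asymmetric) and biphasic models are out of scope, as are
robust losses, synergy scoring and plate-map deconvolution. Fitting on
means discards replicate-level information (a pooled-replicate fit would
change Sy.x and the Shapiro–Wilk input). DSS2/DSS3 normalisation constants
follow the published DSS formulas; other implementations in circulation
differ in small ways, so cross-tool DSS comparisons should be made with the
formulas above in hand.
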