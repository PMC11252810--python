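# Methods

This note documents the statistical model, the estimation and inference
algorithms, the synthetic data-generating process used for testing, and the
design decisions taken where more than one reasonable choice existed.

## Outcome model and estimand

Annual emissions of a pollutant in unit *i* (a country's regulated or
unregulated sectoral aggregate) and year *t* are modelled on the natural log
scale as

    log y_it = τ_it D_it + x_it' β + μ + a_i + g_t + λ_i' F_t + ε_it

with treatment indicator `D_it = 1{i treated, t ≥ t₀}` (default adoption year
t₀ = 2005), covariates `x_it`, two-way additive intercepts, `r` latent common
factors `F_t` with unit loadings `λ_i`, and idiosyncratic noise. The estimand
is the average treatment effect on the treated per post-adoption year,

    ATT_t = (1/N_tr) Σ_{i∈T} τ_it,   τ_it = log y_it(1) − log ŷ_it(0),

and its unweighted mean across treated units and post years. Because the
outcome is in logs, effects are multiplicative on levels; headline percent
numbers use `100·(exp(τ)−1)` and the log-point convention (`100·τ`) is always
reported alongside, since the two differ materially for large effects.

## Estimation

**Step 1 (controls).** On control units only, `β`, the intercepts and the
rank-`r` component are fit by alternating least squares. Each iteration
alternates two *exact* blocks: given the low-rank component `L`, the
covariate coefficients and both intercept margins are solved jointly in
closed form (the intercepts are profiled out by double demeaning — valid
because the panel is balanced); given `(β, intercepts)`, `L` is the best
rank-`r` approximation of the residual matrix, computed from the Gram
eigenvectors of its smaller side. Solving the covariate/intercept block
jointly rather than coordinate-wise matters in practice: with nearly
collinear covariates (log GDP and its square) coordinate-wise updates can
crawl for thousands of iterations, while the joint block typically converges
in well under fifty.

Convergence is declared when the relative change in the sum of squared
residuals falls below 1e-8 (cap 2,000 iterations; exceeding it raises an
error carrying diagnostics). An absolute guard (`Δobj < 1e-16·‖Y‖²`) handles
near-perfect fits whose relative change only chatters in float noise.
Initialization is deterministic (zero low-rank start, equivalent to starting
from the two-way-within OLS), so fits are reproducible without a seed. At
`r = 0` the problem is solved in a single closed-form step and is exactly the
two-way fixed-effects (within) estimator.

Factors are normalized as `F'F/T = I` with mutually orthogonal loadings.
The normalization is a reporting convention only: imputed counterfactuals
and effects are invariant to factor rotation (tested).

**Step 2 (treated loadings).** For each treated unit, an intercept and
loadings are chosen by OLS of the covariate- and time-effect-adjusted outcome
on the estimated factor paths, using pretreatment years only. This forces the
mean pretreatment gap to zero by construction; the per-unit pretreatment RMSE
is reported as a fit diagnostic.

**Step 3 (imputation).** The counterfactual `ŷ_it(0)` combines `x'β̂`, the
intercepts and `λ̂_i'F̂_t` for every treated unit-year. Level-scale
counterfactuals are plain exponentials of the log imputation, with no
retransformation (smearing) correction; the omission is noted in report
output. Under log-normal errors this understates the conditional mean of
levels by ≈ σ²/2; with the residual scales seen here the bias is well under
one percent and does not accumulate differentially between observed and
counterfactual paths.

**Factor-count selection.** `r` is selected over candidates 0–5 (the search
range is configurable) by leave-one-pretreatment-period-out cross-validation:
for each candidate the control model is fit once on all years, then each
pretreatment year of the treated units is held out in turn, loadings are
re-estimated on the remaining pretreatment years and the held-out year is
predicted. The candidate with the smallest mean squared prediction error
wins; exact ties break toward smaller `r`. Requires at least three
pretreatment periods.

## Inference

**Parametric bootstrap** (default 1,000 replications at study scale, fewer in
tests). Per replication:

* control outcomes are simulated as fitted values plus resampled control
  residuals;
* treated outcomes are the imputed counterfactual plus a resampled
  *prediction-error* series, where the pool of prediction errors is built by
  treating each control unit in turn as pseudo-treated (refit on the
  remaining controls, project, impute) and recording its observed-minus-
  imputed series;
* the estimator is re-run with `r` held fixed. Simulated treated units carry
  no effect, so each replication's ATT path is a draw of pure estimation
  error; bands add its empirical quantiles to the point estimate.

Micro-choices, both exposed and recorded in the run manifest:

* residuals are resampled in whole unit blocks by default, preserving serial
  correlation within a unit (`resample="iid"` for cell-wise);
* in-sample control residuals are inflated by the usual degrees-of-freedom
  factor `sqrt(n/(n−k))`, with `k` counting covariate, intercept and factor
  parameters, because the fitted low-rank component absorbs noise and leaves
  in-sample residuals under-dispersed (the prediction-error pool is genuinely
  out-of-sample and is left unscaled);
* interval quantiles use the empirical (inverted-CDF) definition, which
  degenerates cleanly to min/max at two draws.

Replications whose refit fails to converge are dropped and counted, not
redrawn, keeping the draw stream reproducible; more than 10% failures abort
with diagnostics. In simulation at the preset's conditions the 95% interval
for the mean effect covers the truth in about 90% of trials — the slight
undercoverage is characteristic of schemes that condition on the point
estimates of the factors.

**Robustness re-runs.** `leave_one_out` re-estimates the model once per
omitted treated (optionally control) unit. `in_time_placebo` truncates the
data to years strictly before the true adoption, shifts the adoption year
earlier (≥3 pre-placebo years required) and re-runs the full estimation;
under a well-specified model the placebo ATT is centred on zero.

## Downstream accounting

* Cumulative physical reductions per post year: `Σ_{i∈T} (ŷ_it(0) − y_it)` in
  tons; totals are exact sums of the per-year terms.
* Share of economy-wide emissions: cumulative reduction divided by an
  *externally supplied* economy-wide series summed over the same window —
  the panel itself covers only the two-unit aggregation, so the denominator
  is a separate input.
* LCP bounding: `Reductions_t = E_t/(1 − ATT_t) − E_t` from 2008 onward
  (configurable), with `ATT_t` the proportional level-scale effect
  `exp(ATT_t^log) − 1`; with the log-point convention flag the raw log ATT is
  used instead, as a sensitivity. Negative values are tons avoided by the
  plants themselves; the formula is undefined at `ATT_t ≥ 1` and errors.
* Monetization: tons × configured per-ton damage cost per pollutant;
  `bounded = joint − LCP-attributed`. Cost values, currency and price-year
  are pure configuration — the package ships no damage-cost numbers and does
  no inflation arithmetic.

## Synthetic data generator

The generator simulates the outcome model forward and is the test bed for
the whole chain. The default preset mirrors the study design the estimator
targets: 25 treated + 25 control units (one regulated and one unregulated
aggregate per country), years 1990–2021, adoption 2005, two common factors.
Specific choices, each a field of `DgpSpec`:

* **Covariates**: per-unit mean-centred log-GDP random walks (start sd 0.6,
  drift 0.02, step sd 0.03 — growth-rate magnitudes typical of annual
  national accounts) plus the square, with β = (0.5, −0.2).
* **Factors**: i.i.d. normal innovations with sd 0.2 by default (random-walk
  factors available), loadings i.i.d. standard normal — conventional choices
  for interactive-fixed-effects simulation, giving factor components that
  dominate the noise (sd 0.05) so that rank selection is well-posed.
* **Intercepts**: unit levels centred at log-scale 12.2 (≈ 2×10⁵ tons/year,
  a national-aggregate order of magnitude).
* **Effects**: the τ profile is specified per post year on the log scale;
  the preset default declines linearly to −0.5 by the final year, and tests
  mostly use a flat −0.40. Treated minus counterfactual log outcomes equal τ
  exactly by construction.
* An optional confounding knob correlates loadings with the covariate level
  (off by default).

What the generator does **not** emulate: inventory reporting revisions,
sectoral reallocation between regulated and unregulated aggregates, serially
correlated or heteroskedastic idiosyncratic noise, anticipation effects, and
treatment spillovers to controls. Passing tests therefore demonstrate that
the estimator recovers effects when its model is correctly specified and
identifies rank/placebo behaviour under clean conditions — not that those
assumptions hold in any particular real inventory panel.

Auxiliary series for the accounting layer are likewise synthetic stand-ins:
the LCP series takes a fixed fraction (default 40%) of treated observed
emissions from 2008 on, and the economy-wide denominator is the sum over all
panel units.

## Problem sizes used in the checks

The statistical checks run at the preset scale (50 units × 32 years):
effect recovery and rank selection over 50 generated panels each, bootstrap
coverage over 50 trials × 200 replications, placebo nullity over 50 panels.
The acceptance script runs one full pipeline at the same scale with 1,000
bootstrap replications.

## Known limitations

* Single adoption year only; no staggered-adoption generality.
* Balanced panels only — there is no missing-data handling by design, since
  no principled imputation rule exists for this setting.
* The bounding correction inherits the aggregate ATT; it cannot disentangle
  plant-level policy overlap.
* Percentile (rather than bias-corrected) bootstrap intervals; mild
  undercoverage at moderate panel sizes, as quantified above.
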