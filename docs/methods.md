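# Methods

## Scoring model

Member stress `Sf = A + wP·E + pS·iS + eT` is a deterministic integer
composite of six weighted factors. The weights are fixed constants of
the model — they encode interview-derived judgements, not fitted
parameters — and the package makes no attempt to re-derive them from
data. Two readings of the printed formulas are ambiguous on their face
and are resolved here by the published worked examples:

* In `Sf`, multiplication binds tighter than addition
  (`A + (wP·E) + (pS·iS) + eT`). This is the only reading that
  reproduces all 29 rows of the published factor grid.
* Family stress is grouped as `TS = Sf·(|nD − nW| + 1) + nE`. The
  ungrouped linear reading fails every row of the published household
  grid; the grouped form with the absolute value reproduces all 31 rows,
  including the household with more workers than dependents
  (`Sf = 41, nW = 5, nD = 1 → 205`). The absolute value means a surplus
  of earners is treated as the same stress multiplier as an equal
  deficit; a balanced household (`nW = nD`) collapses the multiplier
  to 1, so `TS = Sf + nE`, and the degenerate all-zero composition is
  accepted (TS = Sf), not an error.
* For the income-status weights the package follows the factor-grid
  header (poor = 3, average = 2, rich = 1); the running-text description
  of that factor repeats the physical-status labels verbatim and cannot
  be reconciled with the grid's scores.

Area stress `OES = Σ TS / pA · 100` is linear in total family stress and
inversely proportional to population. `Sf` and `TS` are exact integers;
`OES` and all summary percentages are reported rounded half-up to two
decimals, and the decade summary is the arithmetic mean of the per-year
rounded percentages (again rounded half-up) — the convention that
reproduces the published per-year column and its 2.18% decade headline.

Only the minimum-stress area column is treated as exactly reproducible.
The published average/maximum representative family-stress values
(328.43 and 1003) are carried as constants and the pipeline emits those
columns, but the corresponding published percentages differ from
`nF·TS/pA·100` by about 0.1 and their exact computation is unknown, so
no test asserts them. Likewise the published 72.71% "average member
stress" matches neither stress grid's mean and is not reproduced.

## Forecasting

`fit_linear_trend` is ordinary least squares of annual count on calendar
year (via statsmodels); `forecast_linear` extrapolates the line and
reports normal-theory prediction intervals for a new observation (95% by
default). On a noise-free arithmetic series the extrapolation is exact
to numerical tolerance.

`fit_forecast_svr` is an epsilon-SVR (scikit-learn) on windows of the
previous `lag` annual counts, standardised in both features and target,
forecasting iteratively: each one-step prediction is appended to the
history and becomes the newest lag. Defaults — linear kernel, `lag = 1`,
`C = 1000`, `epsilon = 1e-3` in standardised units — are the smallest
configuration that tracks a noise-free linear series to within 1% over a
ten-year horizon. Both forecasters are deterministic for fixed inputs
and hyperparameters; no hyperparameter search is performed, and yearly
data makes seasonal structure vacuous, so none is modelled.

The decade forecast that drives the area-stress tables in the
reproduction pipeline is the published series itself (15,493 … 20,330,
summing to 179,561), shipped in `psem.datasets`: the original forecasts
were produced by a tool whose lag configuration is unpublished, so the
package's forecasters are validated by property tests (exactness on
lines, slope recovery on synthetic series) rather than by matching those
numbers. The published hold-out RMSE values are likewise not
reproducible — the observed 2011–2020 year-wise counts were never
printed — so the RMSE routine is checked against a brute-force oracle
instead.

## Evaluation

The forecast comparison is a Welch (unequal-variance) two-sample
*t*-test computed from summary statistics: `t = (m₁ − m₂)/√(se₁² + se₂²)`
with the Welch–Satterthwaite degrees of freedom **floored to an
integer** before the p-value and the 95% confidence interval are read
off the t distribution. Flooring is the convention of classical
reporting tools and is the only one consistent with the published df of
17 for two samples of ten (fractional df 17.98; a pooled-variance test
would give 18). With both sample SDs zero and equal means the statistic
is defined as 0 with p = 1; zero pooled SE with unequal means is an
error. In the plain-text report, means/SDs/SEs/CI bounds are rounded to
integers, t to two decimals and p to three, matching the published
presentation.

RMSE is `√(Σ(Pᵢ − Oᵢ)²/n)` over year-aligned series; mismatched years
are a validation error.

## Synthetic registry generator

The real registry (217,067 patients, 1998–2020) is not deposited. The
generator emulates its gross structure so every pipeline stage is
testable offline:

* **Incidence**: `round(intercept + slope·t + N(0, noise_sd))` clipped
  at zero. Defaults — intercept 2,800 patients at 1998, slope 590
  patients/year, noise SD 400 — give roughly 214k patients over the 23
  years, matching the registry's magnitude and its approximately linear
  upward trend.
* **Families**: factor labels drawn independently per factor, uniform
  over each label set by default (no empirical frequencies exist to
  fit); composition counts uniform over nW 0–3, nD 0–8, nE 0–2, a
  plausible household range for the setting.
* **Population**: geometric growth from 16,637,186 (the 2021 projection)
  at 2.76%/year, the growth rate implied by the published 2021→2030
  projections.

Each generator draws from an independent child stream of the single
seed, so outputs are reproducible and mutually independent. What the
generator does **not** emulate: correlations between factors (e.g.
income vs treatment funding), within-family correlation over time,
registry artefacts such as the 2,815 removed duplicates, or any
year-to-year structure beyond the linear trend. Tests passing on
synthetic data therefore demonstrate correctness of the computations
under the model's assumptions, not fidelity of the model to real
registries.

## Problem sizes and numerical choices

Tests run at the worked-example scale (tens of rows, decade horizons)
plus: exhaustive enumeration of all 1,800 factor encodings; 200
replicates for slope recovery (each replicate's estimate within 3
standard errors of the configured slope in at least 97% of cases); 2,000
replicates for null CI coverage (95% interval excluding zero in
5% ± 1.5%); chi-square goodness of fit at n = 10,000 with α = 0.01. The
whole suite completes in a few seconds on one CPU.

Rounding everywhere is decimal half-up (ties away from zero), matching
the published two-decimal percentages. Forecast values are clipped at
zero (counts cannot be negative). The linear-trend fit requires at least
three years; the SVR requires training length > lag + 2 so the lag
matrix retains at least two rows beyond the window.
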