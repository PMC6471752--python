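# Methods

This note documents the statistical procedures implemented in `airmort`,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not establish.

## Exposure aggregation

Station-level daily concentrations are combined by station-year centering:
for day `t` in year `y`, with `m_{s,y}` the station's annual mean,

    z_t = mean over reporting stations of (x_{s,t} − m_{s,y})
        + mean over ALL network stations of m_{·,y}.

Centering removes each station's level before averaging, so days on which a
high- or low-level station is silent are not biased; the added-back
constant restores the network's natural level. Two open points were
resolved as follows.

* **Added-back average.** The constant averages the annual means of *every*
  in-network station for that pollutant-year, not only the stations
  reporting that day. A same-day-reporters average would re-introduce the
  composition artifact the centering removes; a network-wide constant keeps
  day-to-day variation in `z` driven solely by centred values.
* **Partial years.** A station-year partially covered by the operation
  window uses the mean of its available days as the observed annual mean —
  the simplest unbiased choice.

Annual means for station-years with no data are imputed from the same
year's observed means at other stations: inverse-distance-weighted (power
2) when coordinates are available, the plain cross-station mean otherwise.
The imputer is a pluggable strategy; thin-plate spline interpolation was
deliberately not reimplemented, because the downstream inference depends
only on having a reasonable station-year level, not on the interpolant's
smoothness class.

Completeness is accounted per station as (days with a value) / (days in the
operation window), and road-side stations are excluded before aggregation
because they do not represent population exposure.

## Core model

Daily counts for one (cause, age-group) are modelled as quasi-Poisson with
log link:

    log E[Y_t] = α + s(t) + DOW + SARS + FLU + PH + afterPH
                 + s(DBT_{t−k}) + s(RH_{t−j}).

* **Splines.** Smooth terms are *unpenalised natural cubic regression
  splines* (truncated-power construction, knots at equally spaced quantiles,
  linear beyond the boundary knots). The basis dimension `df` plays the
  role of the smoothing parameter and is selected on the qAIC grid together
  with the meteorology lags, which reproduces a penalised smoother's
  selection surface without REML machinery. `df = 2` nests a straight
  line. Bases are reproducible bit-identically from their stored knots.
* **Calendar terms.** Day-of-week enters as six contrasts against a Sunday
  reference (the reference is arbitrary but must be fixed for
  reproducibility). `afterPH` is 1 exactly on the day after a holiday, so
  consecutive holidays are both `PH`-days and the second is additionally an
  `afterPH`-day. Epidemic indicators are closed date intervals supplied in
  configuration; the shipped defaults (2003-03-01..2003-07-31 and
  2009-06-01..2009-12-31) are labelled assumptions. Indicators that never
  fire inside the study window are dropped (they would be all-zero
  columns).
* **Fitting.** Coefficients are the Poisson MLE, computed by IRLS
  (statsmodels GLM; relative-change tolerance 1e−8, at most 100
  iterations; non-convergence is flagged, not raised). The Pearson
  dispersion `φ = X²/(n−p)` scales the covariance; quasi-Poisson point
  estimates are therefore *identical* to the Poisson fit and standard
  errors are `√φ` times larger, which the tests assert against an
  independent numerical maximiser of the Poisson likelihood.
* **Selection.** `qAIC = −2 logLik/ĉ + 2p`. A single `ĉ` is estimated from
  the *richest* grid candidate and held fixed for all candidates — qAIC
  differences are meaningless if each model rescales its own likelihood.
  Ties break toward fewer parameters, then the lexicographically smallest
  candidate key. Meteorology lags {1,2,3} are the default grid; lag 0 is
  accepted as a grid option but not a default.
* **Diagnostics.** ACF and PACF of the Pearson residuals (valid rows in
  date order), with ±1.96/√n white-noise bounds. Pearson (not deviance)
  residuals, matching the dispersion estimator.

## Effect models

* **Single-day lag.** One linear term `x_{t−k}` added to the chosen core
  design and refitted. Missing exposure days (e.g. a day no station
  reported) mask rows; they are never interpolated.
* **Two-pollutant.** Both pollutants at the same single-day lag — the
  symmetric choice, flagged as an assumption since published analyses often
  leave this unstated. A warning is emitted when the lagged series
  correlate beyond |r| = 0.9 (particulate pairs routinely do), because the
  joint estimates then become unstable; an exactly collinear pair is an
  error.
* **Distributed lag.** Lagged exposures `x_{t−0..L}` (default `L = 30`,
  one month: long enough to expose mortality displacement) are projected
  on the Almon basis `C[l,j] = (l/L)^j`, `j = 0..d` (degree 3 by default;
  the basis includes the constant column, so degree 3 means four free
  coefficients). Dividing the lag by `L` before powering is purely
  numerical conditioning — raw `l³` reaches 27 000 and degrades the
  cross-product — and does not change the fitted subspace, as the
  saturated-basis equivalence test verifies. Per-lag coefficients are
  `β = Cη` with `var(β_l) = C_l Σ_η C_lᵀ`; cumulative effects over 0..M use
  the summed functional `u = 1ᵀC_{0..M}`.
* **Excess risk.** `ER = (exp(Δβ) − 1)·100` with Wald 95% bounds
  `exp(Δ(β ± 1.96·se))`, on the log-rate scale throughout. Increments are
  fixed per pollutant (CO 0.1 mg/m³, others 10 μg/m³). The
  concentration-response is assumed log-linear; no nonlinear shapes are
  offered.

## Synthetic data generator

The generator mirrors the analysis model term for term, so every
coefficient is recoverable by a correctly specified fit.

| parameter | default | rationale |
|---|---|---|
| exposure mean / CV / lag-1 ρ | 29.4 μg/m³ / 0.44 / 0.7 | PM10-like marginal moments; log-AR(1) keeps the series positive, persistent and spike-capable |
| baseline counts | 43.5/day (all-age non-accidental); 15.4 and 11.2 for cardiovascular scenarios | realistic daily magnitudes for a ~5-million population |
| DBT / RH | 27.8 ± ~1 °C / ~81% | narrow tropical ranges |
| trend | long-period + annual sinusoid, amplitude 0.05 | smooth, spline-capturable, weak (no true seasons) |
| overdispersion ω | 1.2 | mild extra-Poisson variation typical of daily death counts |
| station offsets / noise | ±6 μg/m³ / sd 4 | free parameters (no published anchor); moderate heterogeneity |
| missingness | 5% (up to 30% in tests) | independent station-day deletion |

Counts are negative binomial parameterised to variance `ω·μ` — exactly the
quasi-Poisson variance assumption, so the Pearson dispersion of a correct
fit estimates `ω` (asserted at ω = 3). ω = 1 degenerates to Poisson. The
first `L` days are emitted but flagged as burn-in, since they lack full
lagged-exposure history.

The harvesting curve places positive coefficients on lags 0–5 and a smooth
negative band over mid lags, with the negative mass equal to
`rebound × positive mass`: `rebound = 1` is exact mortality displacement
(zero net 30-day effect), `rebound > 1` a net-protective 30-day total.
Harvesting is emulated at the lag-coefficient level; there is no
mechanistic frailty-pool simulation, no spatial correlation between
stations beyond the shared population series, and no transboundary haze
episodes. Passing tests therefore demonstrate correctness of the
*estimation machinery* under a known process, not epidemiological findings
about any real population.

All randomness flows from one root seed through named CRC32-keyed
SeedSequence streams; identical configurations give bit-identical datasets
across processes.

## Verification experiments and problem sizes

The replicate experiments (in `airmort.experiments`, shared by the test
suite and `scripts/acceptance.py`) use problem sizes chosen to balance
Monte-Carlo resolution against desk-scale runtimes: 200 replicates of
1500 days for bias/coverage and type-I error (≈15 deaths/day), 100
replicates of 4748 days (13 years) at elderly-cardiovascular magnitudes
(11.2/day) for the harvesting sign pattern, 50 replicates for selection
consistency, and one 3000-day dataset for degree-2/3/4 sensitivity. The
recovery experiment draws its truth from the degree-3 polynomial family so
the DLM is correctly specified and unbiasedness is the test; the
harvesting experiment's truth is *not* polynomial, so it additionally
exercises the approximation.

A known power limitation, documented rather than hidden: with the
harvesting rebound capped at 1.5 and the acute 0–5 effect at a realistic
~1.2%, the true 0–30 cumulative effect is only ≈ −0.4%, below one standard
error of its estimator even at full study length; the measured sign-pattern
rate is accordingly ~0.6–0.7, and the estimator is verified unbiased
(replicate means match truth for both windows).

## Numerical notes and degenerate inputs

* Rank deficiency is detected before fitting (pivoted QR) and reported with
  the offending column names; constant exposures and exactly collinear
  pollutant pairs are rejected.
* Constant spline inputs and insufficient distinct values are errors;
  duplicate quantile knots are collapsed.
* Zero-count days are valid responses (the log link constrains the mean,
  not the data); an all-zero series still fits an intercept at −∞ and will
  flag non-convergence rather than crash.
* Missing values propagate through design assembly to a row-validity mask;
  alignment is always by calendar date, so input row order is irrelevant.
* Excess-risk CIs are computed on the log-rate scale and exponentiated,
  guaranteeing `ci_low ≤ ER ≤ ci_high`.
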