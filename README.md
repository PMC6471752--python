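# airmort

Daily time-series analysis of air-pollutant effects on mortality, built for
settings like an equatorial city-state where exposure is monitored by a
multi-station network and outcomes are daily death counts by cause and age
group. The package provides, as one tested pipeline:

* **APHEA-style exposure aggregation** — station-year centering with
  annual-mean imputation, turning many incomplete station records into one
  population-level daily series per pollutant;
* **quasi-Poisson core models** — log-linear regressions of daily counts on
  a long-term-trend spline, day-of-week/holiday/epidemic indicators and
  smooth lagged meteorology, with spline dimensions and meteorology lags
  selected by qAIC;
* **effect models** — single-day-lag and two-pollutant models, and Almon
  polynomial distributed-lag models (DLMs) over lags 0–30, reported as
  excess risks with 95% confidence intervals;
* **a synthetic-data generator** — a fully known data-generating process at
  realistic magnitudes, so every stage is verifiable against ground truth,
  including mortality-displacement ("harvesting") lag shapes.

## The model

For daily death counts `Y_t` the core model is

    log E[Y_t] = α + s(t) + β₁·DOW + β₂·SARS + β₃·FLU + β₄·PH + β₅·afterPH
                 + s(DBT_{t−k}) + s(RH_{t−j})

with `s(·)` natural cubic regression splines, `PH`/`afterPH` public-holiday
indicators and `SARS`/`FLU` epidemic-period indicators. Counts are treated
as quasi-Poisson: variance `φ·μ`, coefficients equal to the Poisson MLE,
standard errors scaled by `√φ` (Pearson dispersion). Candidate models are
scored by `qAIC = −2·logLik/ĉ + 2p` with a common `ĉ`.

A pollutant enters either as a single-day-lag term `x_{t−k}` or through the
Almon-constrained DLM: per-lag coefficients `β_l = Σ_j η_j (l/L)^j`
(degree 3 by default, degrees 2/4 as sensitivity), giving cumulative
effects `Σ_{l≤M} β_l` over windows 0–5, 0–15 and 0–30 days. Effects are
reported as excess risk

    ER = (RR − 1) × 100%,   RR = exp(Δ·β)

per conventional increment Δ (0.1 mg/m³ for CO, 10 μg/m³ for the other
pollutants), with Wald intervals mapped through the same transform.

## Worked example

Simulate three thousand days with a smooth true lag curve whose cumulative
0–5-day excess risk is exactly 1% per 10 μg/m³, aggregate the five noisy
stations, select a core model and estimate the effects:

```python
import numpy as np
import airmort as am

curve = am.scale_lag_curve(
    am.polynomial_lag_curve(30, (1.0, -2.2, 1.6, -0.4)), (0, 5),
    np.log(1.01) / 10.0,
)
config = am.ScenarioConfig(n_days=3000, seed=42, true_lag_coefs=tuple(curve))
ds = am.simulate_dataset(config)

agg = am.aphea_center_aggregate(ds.stations)
holidays = [d.date() for d in ds.calendar.index[ds.calendar["holiday"] == 1]]
cal = am.calendar_covariates(ds.dates, holidays)
sel = am.select_core_model(
    ds.mortality["deaths"], cal, ds.meteo,
    {"trend_df": [6, 8], "dbt_df": [3], "dbt_lag": [1, 2, 3],
     "rh_df": [3], "rh_lag": [1]},
)
est, _ = am.single_lag_model(sel.chosen_design, agg.values, 3, 10.0,
                             pollutant="PM10")
dlm = am.fit_dlm(sel.chosen_design, agg.values, am.DLMSpec(30, 3), 10.0,
                 pollutant="PM10")
```

This prints (via the obvious `print` statements):

```
aggregated PM10: mean 29.8 ug/m3, 3000 days
core model: {'trend_df': 6, 'dbt_df': 3, 'dbt_lag': 3, 'rh_df': 3, 'rh_lag': 1}, dispersion c_hat = 1.25
single-day lag 3: ER 0.520% (95% CI 0.100, 0.941)
cumulative lags 0-5 : ER  1.297% (0.740, 1.856)
cumulative lags 0-15: ER  1.761% (0.924, 2.605)
cumulative lags 0-30: ER  2.032% (0.758, 3.321)
true cumulative 0-5 ER: 1.000%
```

The cumulative 0–5 interval covers the generating truth of 1%; the
dispersion estimate recovers the generator's variance inflation (1.2); the
single-day lag-3 estimate is smaller than the 0–5 cumulative effect, as a
one-day slice of a distributed response should be.

The same analysis runs from the shell on delimited files via the `airmort`
CLI (`simulate`, `aggregate`, `select-core`, `effects`, `run-all`,
`report`); `airmort run-all --config run.yaml` executes the whole pipeline
and writes every table plus a manifest.

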