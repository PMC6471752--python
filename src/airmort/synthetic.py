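"""Synthetic daily time-series data with a fully known data-generating process.

Every downstream stage of the pipeline (station aggregation, core-model
fitting, distributed-lag estimation) can be exercised against ground truth
generated here.  The generator emulates a tropical city-state setting:
multi-station particulate series with station-specific level offsets and
missingness, a weak seasonal/long-term trend in mortality, day-of-week and
holiday effects, smooth temperature/humidity confounders, and overdispersed
daily death counts at realistic magnitudes (tens of deaths per day).

The mortality model mirrors the analysis model exactly: on the log scale the
expected count is a baseline plus trend, calendar, meteorology and a
distributed-lag exposure term, and counts are drawn with variance equal to
``overdispersion × mean`` so that quasi-Poisson dispersion is a recoverable
quantity.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregate import StationSeries

__all__ = [
    "ScenarioConfig",
    "SyntheticDataset",
    "simulate_exposure",
    "simulate_meteorology",
    "simulate_calendar",
    "simulate_mortality",
    "simulate_dataset",
    "harvesting_curve",
    "polynomial_lag_curve",
    "scale_lag_curve",
    "write_dataset",
]

# Singapore-like defaults (daily PM10: mean ~29 ug/m3, SD ~13; DBT ~27.8 C;
# RH ~81%; all-age non-accidental deaths ~43.5/day).
_DEFAULT_DOW = (0.0, 0.01, 0.005, 0.0, -0.005, -0.01, 0.015)


@dataclass
class ScenarioConfig:
    """Complete specification of one synthetic scenario.

    Parameters mirror, term by term, the right-hand side of the log-linear
    mortality model so that recovery of each generating coefficient is
    testable.

    Attributes
    ----------
    n_days:
        Number of calendar days simulated.  Must be at least ``max_lag + 30``
        so that lag construction has usable history beyond burn-in.
    start_date:
        First calendar day (ISO string or date-like).
    n_stations:
        Number of monitoring stations.
    station_offsets:
        Per-station additive level offset (same units as the pollutant,
        ug/m3).  Length must equal ``n_stations``; ``None`` spreads offsets
        symmetrically over +/- 6 ug/m3.
    station_noise_sd:
        SD of independent station-day measurement noise (ug/m3).
    missing_rate:
        Probability that a station-day record is absent, independently.
    exposure_mean, exposure_cv, exposure_rho:
        Marginal mean, coefficient of variation and lag-1 autocorrelation of
        the population-level exposure series, generated as a log-scale AR(1)
        (strictly positive, persistent, spike-capable).
    baseline_log_rate:
        Log of the expected daily death count at reference conditions.
    trend_amplitude, trend_period_days:
        The long-term trend is ``A sin(2 pi t / P) + (A/2) sin(2 pi t /
        365.25)`` — one long-period plus one annual sinusoid, smooth and
        capturable by a regression spline.
    dow_effects:
        Seven log-scale day-of-week terms, indexed Monday..Sunday.
    holiday_effect, after_holiday_effect:
        Log-scale terms for public holidays and the following day.
    temp_effect:
        Coefficient on the smooth (centred quadratic) function of dry-bulb
        temperature.
    meteo_lag:
        Lag (days) at which temperature acts on mortality.
    true_lag_coefs:
        Length ``L+1`` vector of log-rate change per exposure unit at lags
        ``0..L``.  A scalar-free empty default means "no pollutant effect".
    overdispersion:
        Variance inflation factor omega >= 1; counts have variance
        ``omega * mean`` (negative binomial; omega = 1 is exactly Poisson).
    holiday_every:
        A public holiday is placed every this-many days (roughly the
        Singapore frequency of ~11/year at the default 30).
    seed:
        Root seed for all randomness in the scenario.
    """

    n_days: int = 1500
    start_date: str = "2001-01-01"
    n_stations: int = 5
    station_offsets: tuple[float, ...] | None = None
    station_noise_sd: float = 4.0
    missing_rate: float = 0.05
    exposure_mean: float = 29.4
    exposure_cv: float = 0.44
    exposure_rho: float = 0.7
    baseline_log_rate: float = float(np.log(43.5))
    trend_amplitude: float = 0.05
    trend_period_days: float = 2000.0
    dow_effects: tuple[float, ...] = _DEFAULT_DOW
    holiday_effect: float = 0.02
    after_holiday_effect: float = 0.01
    temp_effect: float = 0.01
    meteo_lag: int = 1
    true_lag_coefs: tuple[float, ...] = (0.0,)
    overdispersion: float = 1.2
    holiday_every: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        L = self.max_lag
        if self.n_days <= 0 or self.n_stations <= 0:
            raise ValueError("n_days and n_stations must be positive")
        if self.n_days < L + 30:
            raise ValueError(f"n_days must be at least max_lag + 30 = {L + 30}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.overdispersion < 1.0:
            raise ValueError("overdispersion must be >= 1")
        if len(self.dow_effects) != 7:
            raise ValueError("dow_effects needs exactly 7 entries")
        if self.station_offsets is not None and len(self.station_offsets) != self.n_stations:
            raise ValueError("station_offsets length must equal n_stations")

    @property
    def max_lag(self) -> int:
        return len(self.true_lag_coefs) - 1

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")

    def resolved_offsets(self) -> np.ndarray:
        if self.station_offsets is not None:
            return np.asarray(self.station_offsets, dtype=float)
        if self.n_stations == 1:
            return np.zeros(1)
        return np.linspace(-6.0, 6.0, self.n_stations)

    def rng(self, stream: str) -> np.random.Generator:
        """Named sub-stream of the root seed (documented stream splitting).

        Uses a CRC32 of the stream name so the split is stable across
        processes (Python's builtin str hash is salted)."""
        key = zlib.crc32(stream.encode("utf-8"))
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


@dataclass
class SyntheticDataset:
    """One realized scenario: stations, meteorology, calendar, counts, truth."""

    config: ScenarioConfig
    stations: list[StationSeries]
    population_exposure: pd.Series
    meteo: pd.DataFrame          # columns dbt_c, rh_pct
    calendar: pd.DataFrame       # columns holiday (0/1)
    mortality: pd.DataFrame      # columns date-indexed; one per (cause, age)
    burn_in: np.ndarray          # boolean mask, True on the first L days

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.population_exposure.index


def simulate_exposure(config: ScenarioConfig) -> tuple[list[StationSeries], pd.Series]:
    """Draw the population exposure series and per-station observed records.

    The population series is a log-scale AR(1): strictly positive,
    autocorrelated, with occasional high spikes from the lognormal tail.
    Station ``s`` observes ``population + offset_s + noise`` and each
    station-day is deleted independently with probability ``missing_rate``.
    """
    dates = config.dates
    rng = config.rng("exposure")
    n = config.n_days

    sigma_m = np.sqrt(np.log1p(config.exposure_cv**2))  # marginal log-sd
    rho = config.exposure_rho
    innov_sd = sigma_m * np.sqrt(1.0 - rho**2)
    mu_log = np.log(config.exposure_mean) - 0.5 * sigma_m**2

    z = np.empty(n)
    z[0] = mu_log + rng.normal(0.0, sigma_m)
    eps = rng.normal(0.0, innov_sd, size=n)
    for t in range(1, n):
        z[t] = mu_log + rho * (z[t - 1] - mu_log) + eps[t]
    population = pd.Series(np.exp(z), index=dates, name="exposure")

    offsets = config.resolved_offsets()
    st_rng = config.rng("stations")
    stations: list[StationSeries] = []
    for s in range(config.n_stations):
        vals = population.to_numpy() + offsets[s] + st_rng.normal(
            0.0, config.station_noise_sd, size=n
        )
        vals = np.clip(vals, 0.0, None)
        series = pd.Series(vals, index=dates)
        if config.missing_rate > 0:
            drop = st_rng.random(n) < config.missing_rate
            series = series[~drop]
        stations.append(
            StationSeries(
                station_id=f"S{s:02d}",
                pollutant="PM10",
                values=series,
                operation_window=(dates[0].date(), dates[-1].date()),
                roadside_flag=False,
            )
        )
    return stations, population


def simulate_meteorology(config: ScenarioConfig) -> pd.DataFrame:
    """Tropical meteorology: narrow-range DBT (~27.8 C) and RH (~81%)."""
    dates = config.dates
    rng = config.rng("meteo")
    t = np.arange(config.n_days)
    annual = np.sin(2 * np.pi * t / 365.25)
    dbt = 27.8 + 0.8 * annual + rng.normal(0.0, 0.6, size=config.n_days)
    rh = 81.4 - 3.0 * annual + rng.normal(0.0, 3.5, size=config.n_days)
    return pd.DataFrame(
        {"dbt_c": np.clip(dbt, 22.0, 32.0), "rh_pct": np.clip(rh, 55.0, 99.0)},
        index=dates,
    )


def simulate_calendar(config: ScenarioConfig) -> pd.DataFrame:
    """Deterministic public-holiday calendar (one holiday every k days)."""
    dates = config.dates
    holiday = np.zeros(config.n_days, dtype=int)
    holiday[:: config.holiday_every] = 1
    return pd.DataFrame({"holiday": holiday}, index=dates)


def _log_mean(
    config: ScenarioConfig,
    exposure: np.ndarray,
    meteo: pd.DataFrame,
    calendar: pd.DataFrame,
) -> np.ndarray:
    n = config.n_days
    t = np.arange(n)
    dates = config.dates
    L = config.max_lag

    trend = config.trend_amplitude * np.sin(2 * np.pi * t / config.trend_period_days)
    trend += 0.5 * config.trend_amplitude * np.sin(2 * np.pi * t / 365.25)

    dow = np.asarray(config.dow_effects)[dates.dayofweek]

    hol = calendar["holiday"].to_numpy().astype(float)
    after = np.roll(hol, 1)
    after[0] = 0.0
    holiday_term = config.holiday_effect * hol + config.after_holiday_effect * after

    dbt = meteo["dbt_c"].to_numpy()
    dbt_lagged = np.full(n, np.nan)
    k = config.meteo_lag
    if k == 0:
        dbt_lagged = dbt.copy()
    else:
        dbt_lagged[k:] = dbt[:-k]
    # smooth centred-quadratic temperature response; NaN history -> 0 (burn-in)
    temp_fn = ((dbt_lagged - 27.8) / 1.1) ** 2
    temp_term = config.temp_effect * np.nan_to_num(temp_fn, nan=0.0)

    coefs = np.asarray(config.true_lag_coefs)
    lag_term = np.zeros(n)
    for lag, beta in enumerate(coefs):
        if beta == 0.0:
            continue
        shifted = np.zeros(n)
        if lag == 0:
            shifted = exposure
        else:
            shifted[lag:] = exposure[:-lag]
        lag_term += beta * shifted

    return (
        config.baseline_log_rate + trend + dow + holiday_term + temp_term + lag_term
    )


def simulate_mortality(
    config: ScenarioConfig,
    exposure: pd.Series,
    meteo: pd.DataFrame,
    calendar: pd.DataFrame,
) -> tuple[pd.Series, np.ndarray]:
    """Draw daily death counts with variance ``overdispersion × mean``.

    Returns the count series (full length, including the first ``L`` burn-in
    days) and a boolean burn-in mask flagging those leading days, which lack
    complete lagged-exposure history.
    """
    if len(exposure) < config.n_days:
        raise ValueError("exposure series shorter than n_days")
    mu = np.exp(_log_mean(config, exposure.to_numpy()[: config.n_days], meteo, calendar))
    rng = config.rng("counts")
    omega = config.overdispersion
    if omega == 1.0:
        counts = rng.poisson(mu)
    else:
        # NB2 with size r = mu/(omega-1) gives Var = mu + mu^2/r = omega*mu
        r = mu / (omega - 1.0)
        counts = rng.negative_binomial(r, r / (r + mu))
    series = pd.Series(counts, index=config.dates, name="deaths")
    burn_in = np.zeros(config.n_days, dtype=bool)
    burn_in[: config.max_lag] = True
    return series, burn_in


def simulate_dataset(config: ScenarioConfig) -> SyntheticDataset:
    """Run the full generative model for one scenario."""
    stations, population = simulate_exposure(config)
    meteo = simulate_meteorology(config)
    calendar = simulate_calendar(config)
    counts, burn_in = simulate_mortality(config, population, meteo, calendar)
    mortality = pd.DataFrame({"deaths": counts})
    return SyntheticDataset(
        config=config,
        stations=stations,
        population_exposure=population,
        meteo=meteo,
        calendar=calendar,
        mortality=mortality,
        burn_in=burn_in,
    )


def harvesting_curve(L: int, acute_size: float, rebound_fraction: float) -> np.ndarray:
    """Lag-coefficient vector with a mortality-displacement (harvesting) shape.

    Positive over lags 0–5 (acute deaths advanced from a frail pool), then a
    smooth negative band over mid lags (the compensatory below-baseline
    period).  The positive coefficients sum to ``acute_size``; the negative
    band integrates to ``-rebound_fraction × acute_size``, so
    ``rebound_fraction = 1`` displaces deaths exactly (zero net cumulative
    effect over 0..L) and ``rebound_fraction > 1`` yields a net-negative
    30-day cumulative effect, the pattern reported for elderly cardiovascular
    deaths.
    """
    if L < 10:
        raise ValueError("harvesting_curve requires L >= 10")
    if not 0.0 <= rebound_fraction <= 1.5:
        raise ValueError("rebound_fraction must lie in [0, 1.5]")
    lags = np.arange(L + 1)
    pos = np.where(lags <= 5, np.cos(np.pi * lags / 12.0), 0.0)
    pos = pos / pos.sum() * acute_size
    neg = np.where(lags >= 6, np.sin(np.pi * (lags - 6) / (L - 6)), 0.0)
    neg[lags > 6] = np.maximum(neg[lags > 6], 0.0)
    if rebound_fraction > 0 and neg.sum() > 0:
        neg = neg / neg.sum() * (rebound_fraction * acute_size)
    else:
        neg = np.zeros_like(neg)
    return pos - neg


def polynomial_lag_curve(L: int, coefs: tuple[float, ...]) -> np.ndarray:
    """Evaluate a polynomial in (l / L) at lags 0..L — a smooth lag curve
    that a polynomial distributed-lag model of the same degree can represent
    exactly."""
    lags = np.arange(L + 1) / max(L, 1)
    return np.polynomial.polynomial.polyval(lags, np.asarray(coefs, dtype=float))


def scale_lag_curve(curve: np.ndarray, window: tuple[int, int], target_sum: float) -> np.ndarray:
    """Rescale a lag curve so its coefficients over ``window`` (inclusive)
    sum to ``target_sum``."""
    lo, hi = window
    s = curve[lo : hi + 1].sum()
    if s == 0:
        raise ValueError("curve sums to zero over the target window")
    return curve * (target_sum / s)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the delimited formats the ingestion layer reads,
    plus a truth file (config echo and realized series) for test harnesses."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = []
    for st in ds.stations:
        for date, value in st.values.items():
            rows.append((st.station_id, date.date().isoformat(), value))
    stations_df = pd.DataFrame(rows, columns=["station_id", "date", "value"])
    paths["stations"] = outdir / "stations_pm10.csv"
    stations_df.to_csv(paths["stations"], index=False)

    meta = pd.DataFrame(
        {
            "station_id": [st.station_id for st in ds.stations],
            "x": np.arange(len(ds.stations), dtype=float),
            "y": np.zeros(len(ds.stations)),
            "roadside": [int(st.roadside_flag) for st in ds.stations],
            "first_date": [st.operation_window[0].isoformat() for st in ds.stations],
            "last_date": [st.operation_window[1].isoformat() for st in ds.stations],
        }
    )
    paths["meta"] = outdir / "station_meta.csv"
    meta.to_csv(paths["meta"], index=False)

    meteo = ds.meteo.copy()
    meteo.insert(0, "date", [d.date().isoformat() for d in meteo.index])
    paths["meteo"] = outdir / "meteo.csv"
    meteo.to_csv(paths["meteo"], index=False)

    cal = ds.calendar.copy()
    cal.insert(0, "date", [d.date().isoformat() for d in cal.index])
    paths["calendar"] = outdir / "calendar.csv"
    cal.to_csv(paths["calendar"], index=False)

    mort = pd.DataFrame(
        {
            "date": [d.date().isoformat() for d in ds.mortality.index],
            "cause": "non_accidental",
            "age_group": "all",
            "deaths": ds.mortality["deaths"].to_numpy(),
            "burn_in": ds.burn_in.astype(int),
        }
    )
    paths["mortality"] = outdir / "mortality.csv"
    mort.to_csv(paths["mortality"], index=False)

    truth = dataclasses.asdict(ds.config)
    truth["realized_exposure"] = ds.population_exposure.round(6).tolist()
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(truth, indent=1, default=str))
    return paths
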