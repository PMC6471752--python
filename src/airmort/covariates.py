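"""Design-matrix construction for the core mortality model.

The core model explains daily death counts by long-term/seasonal trend,
day-of-week, public-holiday and epidemic-period indicators, and smooth
functions of lagged dry-bulb temperature and relative humidity:

    log E[Y_t] = a + s(t) + DOW + SARS + FLU + PH + afterPH + s(DBT_{t-k}) + s(RH_{t-j})

Smooth terms are natural cubic regression splines with knots at equally
spaced quantiles; the basis dimension (df) plays the role of the smoothing
parameter and is selected on a qAIC grid by the fitting layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date as Date

import numpy as np
import pandas as pd

__all__ = [
    "CalendarCovariates",
    "SplineBasis",
    "CoreDesign",
    "calendar_covariates",
    "ns_basis",
    "lagged",
    "build_core_design",
]


@dataclass
class CalendarCovariates:
    """Date-indexed calendar indicators: DOW category, PH, afterPH, SARS, FLU."""

    frame: pd.DataFrame

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.frame.index


@dataclass
class SplineBasis:
    """A natural cubic regression spline basis reproducible from its knots.

    Columns are the non-constant basis functions (dimension = df), linear
    outside the boundary knots.  Evaluating the stored knots on the training
    data reproduces ``basis_matrix`` bit-identically.
    """

    name: str
    df: int
    knots: np.ndarray
    basis_matrix: np.ndarray = field(repr=False)

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        return _ns_design(np.asarray(x, dtype=float), self.knots)

    @property
    def column_names(self) -> list[str]:
        return [f"{self.name}_ns{j+1}" for j in range(self.df)]


def _ns_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline design (truncated-power construction).

    With K knots the natural-spline space has dimension K; dropping the
    constant leaves K-1 columns: x itself plus K-2 curvature terms that are
    linear beyond the boundary knots.
    """
    K = len(knots)
    xi = knots

    def d(k: int, v: np.ndarray) -> np.ndarray:
        num = np.clip(v - xi[k], 0.0, None) ** 3 - np.clip(v - xi[K - 1], 0.0, None) ** 3
        return num / (xi[K - 1] - xi[k])

    cols = [x]
    dK2 = d(K - 2, x)
    for k in range(K - 2):
        cols.append(d(k, x) - dK2)
    out = np.column_stack(cols)
    # NaN inputs propagate to every column so row masking sees them
    out[np.isnan(x)] = np.nan
    return out


def ns_basis(x: pd.Series | np.ndarray, df: int, name: str = "x") -> SplineBasis:
    """Natural cubic regression spline basis with df columns.

    Knots sit at ``df+1`` equally spaced quantiles of the observed (non-NaN)
    values, including the extremes as boundary knots.  ``df == 2`` nests a
    straight line; larger df adds curvature terms.
    """
    values = np.asarray(x, dtype=float)
    obs = values[~np.isnan(values)]
    if df < 2:
        raise ValueError("df must be >= 2")
    if len(np.unique(obs)) < df + 1:
        raise ValueError("too few distinct values for requested df")
    knots = np.quantile(obs, np.linspace(0.0, 1.0, df + 1))
    knots = np.unique(knots)
    if len(knots) < 3:
        raise ValueError("degenerate input: quantile knots collapse")
    return SplineBasis(name=name, df=len(knots) - 1, knots=knots,
                       basis_matrix=_ns_design(values, knots))


def lagged(series: pd.Series, k: int) -> pd.Series:
    """Shift so the value at date t is the series value at t-k (no leads)."""
    if k < 0:
        raise ValueError("negative lags (leads) are not supported")
    if k > len(series):
        raise ValueError("lag exceeds series length")
    return series.shift(k)


@dataclass
class CoreDesign:
    """Response + named-block design matrix for one (cause, age-group).

    ``rows_valid`` masks out any day with a missing covariate (leading lag
    history, missing exposure, burn-in).  ``blocks`` maps block names to the
    design-column names they own.
    """

    response: pd.Series
    matrix: pd.DataFrame
    rows_valid: np.ndarray
    blocks: dict[str, list[str]]
    spline_bases: dict[str, SplineBasis] = field(default_factory=dict)

    @property
    def y(self) -> np.ndarray:
        return self.response.to_numpy()[self.rows_valid]

    @property
    def X(self) -> pd.DataFrame:
        return self.matrix.loc[self.rows_valid]

    def with_columns(self, extra: pd.DataFrame, block: str) -> "CoreDesign":
        """Return a new design with extra columns appended as a named block;
        rows with missing entries in the new columns are masked out."""
        extra = extra.reindex(self.matrix.index)
        matrix = pd.concat([self.matrix, extra], axis=1)
        if matrix.columns.duplicated().any():
            raise ValueError("duplicate column names in design")
        valid = self.rows_valid & ~extra.isna().any(axis=1).to_numpy()
        blocks = {**self.blocks, block: list(extra.columns)}
        return CoreDesign(self.response, matrix, valid, blocks, self.spline_bases)


def calendar_covariates(
    dates: pd.DatetimeIndex,
    holidays: list[Date] | None = None,
    sars_window: tuple[Date, Date] | None = None,
    flu_window: tuple[Date, Date] | None = None,
) -> CalendarCovariates:
    """Day-of-week category plus PH/afterPH/SARS/FLU indicators.

    ``afterPH`` is 1 exactly on (holiday + 1 day); consecutive holidays make
    a day both PH and afterPH.  Epidemic windows are closed date intervals.
    Duplicate holiday dates are deduplicated with a warning.
    """
    frame = pd.DataFrame(index=dates)
    frame["dow"] = dates.dayofweek  # 0 = Monday ... 6 = Sunday
    holidays = holidays or []
    if len(holidays) != len(set(holidays)):
        warnings.warn("duplicate holiday dates deduplicated", stacklevel=2)
        holidays = sorted(set(holidays))
    hset = {pd.Timestamp(h) for h in holidays}
    frame["PH"] = [int(d in hset) for d in dates]
    after = {h + pd.Timedelta(days=1) for h in hset}
    frame["afterPH"] = [int(d in after) for d in dates]
    for name, window in (("SARS", sars_window), ("FLU", flu_window)):
        if window is None:
            frame[name] = 0
        else:
            lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
            frame[name] = ((dates >= lo) & (dates <= hi)).astype(int)
    return CalendarCovariates(frame)


def _dow_contrasts(dow: np.ndarray) -> pd.DataFrame:
    """Six Monday..Saturday indicators against a Sunday reference."""
    cols = {}
    names = ["mon", "tue", "wed", "thu", "fri", "sat"]
    for code, name in enumerate(names):
        cols[f"dow_{name}"] = (dow == code).astype(float)
    return pd.DataFrame(cols)


def build_core_design(
    mortality: pd.Series,
    calendar: CalendarCovariates,
    meteo: pd.DataFrame | None,
    *,
    trend_df: int,
    dbt_df: int | None = None,
    dbt_lag: int = 1,
    rh_df: int | None = None,
    rh_lag: int = 1,
    include_dow: bool = True,
    include_calendar: bool = True,
    extra_invalid: np.ndarray | None = None,
) -> CoreDesign:
    """Assemble the core design matrix on the mortality date index.

    Blocks: intercept, trend spline (on the day index), DOW contrasts
    (Sunday reference), PH/afterPH/SARS/FLU, and optional DBT/RH splines at
    the chosen lags.  Rows with any missing entry — including the first
    ``max(lag)`` days — are masked out, not dropped, so calendar alignment
    is preserved.
    """
    dates = mortality.index
    if not calendar.frame.index.equals(dates):
        calendar = CalendarCovariates(calendar.frame.reindex(dates))
    pieces: list[pd.DataFrame] = []
    blocks: dict[str, list[str]] = {}
    bases: dict[str, SplineBasis] = {}

    intercept = pd.DataFrame({"intercept": np.ones(len(dates))}, index=dates)
    pieces.append(intercept)
    blocks["intercept"] = ["intercept"]

    t = np.arange(len(dates), dtype=float)
    trend = ns_basis(t, trend_df, name="trend")
    bases["trend"] = trend
    trend_frame = pd.DataFrame(trend.basis_matrix, index=dates, columns=trend.column_names)
    pieces.append(trend_frame)
    blocks["trend"] = trend.column_names

    if include_dow:
        dow = _dow_contrasts(calendar.frame["dow"].to_numpy())
        dow.index = dates
        pieces.append(dow)
        blocks["dow"] = list(dow.columns)

    if include_calendar:
        cal = calendar.frame[["PH", "afterPH", "SARS", "FLU"]].astype(float)
        # indicators that never fire (e.g. epidemic windows outside the
        # study period) carry no information and would be collinear zeros
        cal = cal.loc[:, cal.sum() > 0]
        if len(cal.columns):
            pieces.append(cal)
            blocks["calendar"] = list(cal.columns)

    if meteo is not None:
        for var, col, df_, lag_ in (
            ("dbt", "dbt_c", dbt_df, dbt_lag),
            ("rh", "rh_pct", rh_df, rh_lag),
        ):
            if df_ is None:
                continue
            series = lagged(meteo[col].reindex(dates), lag_)
            basis = ns_basis(series.to_numpy(), df_, name=f"{var}_lag{lag_}")
            bases[var] = basis
            frame = pd.DataFrame(basis.basis_matrix, index=dates, columns=basis.column_names)
            pieces.append(frame)
            blocks[var] = basis.column_names

    matrix = pd.concat(pieces, axis=1)
    valid = ~matrix.isna().any(axis=1).to_numpy() & mortality.notna().to_numpy()
    if extra_invalid is not None:
        valid &= ~np.asarray(extra_invalid, dtype=bool)
    if valid.sum() <= matrix.shape[1]:
        raise ValueError("fewer valid rows than design columns")
    return CoreDesign(mortality, matrix, valid, blocks, bases)
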