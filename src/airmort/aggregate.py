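"""Station-level ingestion and APHEA-style exposure aggregation.

A city's pollutant exposure is monitored by a network of stations that open,
close and miss days independently.  Averaging raw station values day by day
lets the network composition drive spurious day-to-day variation: a
high-level station dropping out lowers the network mean even if true air
quality is unchanged.  The APHEA remedy is *centering*: subtract each
station's annual mean from its daily values, average the centred values
across the stations reporting that day, and add back the network-average
annual mean so the series keeps its natural level.

Annual means for station-years with no observed data (site relocation or
closure) are imputed from the other stations, by inverse-distance weighting
when coordinates are available and by the cross-station same-year mean
otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date as Date
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StationSeries",
    "AnnualMeanTable",
    "AggregatedExposure",
    "completeness",
    "observed_annual_means",
    "impute_annual_means",
    "aphea_center_aggregate",
    "read_station_file",
    "write_aggregated",
]

POLLUTANTS = ("PM10", "PM2.5", "CO", "NO2", "O3", "SO2")


@dataclass
class StationSeries:
    """One monitoring station's daily concentration record.

    ``values`` is a date-indexed series containing only the days with a
    measurement; gaps are absent rows.  ``operation_window`` is the station's
    (first, last) day of operation; values must fall within it.  Units are
    mg/m3 for CO and ug/m3 for all other pollutants.
    """

    station_id: str
    pollutant: str
    values: pd.Series
    operation_window: tuple[Date, Date]
    roadside_flag: bool = False

    def __post_init__(self) -> None:
        if self.pollutant not in POLLUTANTS:
            raise ValueError(f"unknown pollutant {self.pollutant!r}")
        first, last = self.operation_window
        if first > last:
            raise ValueError("operation_window start after end")
        if len(self.values):
            v = self.values
            if (v.dropna() < 0).any():
                raise ValueError("negative concentrations")
            idx = pd.DatetimeIndex(v.index)
            if idx.min().date() < first or idx.max().date() > last:
                raise ValueError("values fall outside operation_window")


@dataclass
class AnnualMeanTable:
    """Mean concentration per (station, year) with provenance.

    ``table`` maps (station_id, year) -> mean; ``provenance`` maps the same
    keys to ``"observed"`` or ``"imputed"``.
    """

    table: dict[tuple[str, int], float]
    provenance: dict[tuple[str, int], str]

    def mean(self, station_id: str, year: int) -> float:
        return self.table[(station_id, year)]

    def network_mean(self, year: int) -> float:
        """Average annual mean over all stations in the network for a year."""
        vals = [v for (s, y), v in self.table.items() if y == year]
        if not vals:
            raise KeyError(f"no annual means for year {year}")
        return float(np.mean(vals))


@dataclass
class AggregatedExposure:
    """Population-level daily series for one pollutant.

    A day's value is absent (NaN) exactly when no station reported
    (``n_stations_used == 0``).
    """

    pollutant: str
    values: pd.Series
    n_stations_used: pd.Series


def completeness(station: StationSeries) -> float:
    """Fraction of operating days on which the station recorded a value."""
    first, last = station.operation_window
    n_days = (last - first).days + 1
    if n_days <= 0:
        raise ValueError("empty operation window")
    n_obs = int(station.values.notna().sum())
    return n_obs / n_days


def observed_annual_means(stations: list[StationSeries]) -> AnnualMeanTable:
    """Arithmetic mean of each station-year's observed daily values.

    Years inside a station's operation window with no observed days get no
    entry (candidates for imputation).  Partially covered years use the mean
    of the available days.
    """
    table: dict[tuple[str, int], float] = {}
    prov: dict[tuple[str, int], str] = {}
    for st in stations:
        vals = st.values.dropna()
        if not len(vals):
            continue
        years = pd.DatetimeIndex(vals.index).year
        for year, grp in vals.groupby(years):
            table[(st.station_id, int(year))] = float(grp.mean())
            prov[(st.station_id, int(year))] = "observed"
    return AnnualMeanTable(table, prov)


def impute_annual_means(
    stations: list[StationSeries],
    station_coords: dict[str, tuple[float, float]] | None = None,
    *,
    power: float = 2.0,
) -> AnnualMeanTable:
    """Annual means for every (station, year) overlapping the study period.

    Observed means come from the data; missing station-years are imputed
    from the same year's observed means at other stations — an
    inverse-distance-weighted mean when coordinates are supplied, the plain
    cross-station mean otherwise.  Provenance records which path produced
    each entry.
    """
    out = observed_annual_means(stations)
    years = sorted({y for (_, y) in out.table})
    # also cover years inside each operation window even if fully missing
    for st in stations:
        first, last = st.operation_window
        years = sorted(set(years) | set(range(first.year, last.year + 1)))

    for st in stations:
        first, last = st.operation_window
        for year in range(first.year, last.year + 1):
            key = (st.station_id, year)
            if key in out.table:
                continue
            donors = {
                s: v for (s, y), v in out.table.items()
                if y == year and out.provenance[(s, y)] == "observed"
            }
            if not donors:
                raise ValueError(
                    f"cannot impute {key}: no station observed in year {year}"
                )
            if station_coords is not None and st.station_id in station_coords:
                x0, y0 = station_coords[st.station_id]
                w, v = [], []
                for s, mean in donors.items():
                    if s not in station_coords:
                        continue
                    xs, ys = station_coords[s]
                    d = np.hypot(xs - x0, ys - y0)
                    if d == 0:
                        w, v = [1.0], [mean]
                        break
                    w.append(d**-power)
                    v.append(mean)
                if w:
                    imputed = float(np.average(v, weights=w))
                else:
                    imputed = float(np.mean(list(donors.values())))
            else:
                imputed = float(np.mean(list(donors.values())))
            out.table[key] = imputed
            out.provenance[key] = "imputed"
    return out


def aphea_center_aggregate(
    stations: list[StationSeries],
    annual_means: AnnualMeanTable | None = None,
    station_coords: dict[str, tuple[float, float]] | None = None,
) -> AggregatedExposure:
    """Centred cross-station aggregation to one population-level series.

    For day ``t`` in year ``y`` with reporting stations ``s``:

        z_t = mean_s( x_{s,t} - m_{s,y} ) + mean over ALL network stations of m_{.,y}

    The added-back constant averages the annual means of every in-network
    station for that year (not only same-day reporters) so that day-to-day
    variation in ``z`` reflects only the centred values.  Road-side stations
    must already have been excluded by the caller.
    """
    if not stations:
        raise ValueError("no stations supplied")
    pollutant = stations[0].pollutant
    if any(st.pollutant != pollutant for st in stations):
        raise ValueError("stations mix pollutants")
    if any(st.roadside_flag for st in stations):
        raise ValueError("road-side stations must be excluded before aggregation")
    if annual_means is None:
        annual_means = impute_annual_means(stations, station_coords)

    wide = pd.DataFrame({st.station_id: st.values for st in stations})
    full_index = pd.date_range(wide.index.min(), wide.index.max(), freq="D")
    wide = wide.reindex(full_index)

    years = full_index.year
    centred = pd.DataFrame(index=full_index, columns=wide.columns, dtype=float)
    for st in stations:
        m = np.array([
            annual_means.table.get((st.station_id, y), np.nan) for y in years
        ])
        centred[st.station_id] = wide[st.station_id].to_numpy() - m

    n_used = centred.notna().sum(axis=1)
    mean_centred = centred.mean(axis=1)  # NaN when no station reports
    addback = np.array([annual_means.network_mean(int(y)) for y in years])
    z = mean_centred + addback
    z[n_used == 0] = np.nan
    return AggregatedExposure(
        pollutant=pollutant,
        values=z.rename("value"),
        n_stations_used=n_used.rename("n_stations_used"),
    )


def read_station_file(
    path: str | Path,
    pollutant: str,
    meta_path: str | Path | None = None,
    *,
    drop_roadside: bool = True,
) -> list[StationSeries]:
    """Read one delimited station file (columns station_id, date, value).

    The optional metadata file (station_id, x, y, roadside, first_date,
    last_date) supplies operation windows and road-side flags; without it the
    window is each station's observed span.  Road-side stations are dropped
    by default, with a warning naming them.
    """
    df = pd.read_csv(path, parse_dates=["date"])
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path).set_index("station_id")
    out: list[StationSeries] = []
    for sid, grp in df.groupby("station_id"):
        series = grp.set_index("date")["value"].sort_index()
        roadside = False
        if meta is not None and sid in meta.index:
            row = meta.loc[sid]
            window = (
                pd.Timestamp(row["first_date"]).date(),
                pd.Timestamp(row["last_date"]).date(),
            )
            roadside = bool(row.get("roadside", 0))
        else:
            window = (series.index.min().date(), series.index.max().date())
        if roadside and drop_roadside:
            warnings.warn(f"excluding road-side station {sid}", stacklevel=2)
            continue
        out.append(
            StationSeries(
                station_id=str(sid),
                pollutant=pollutant,
                values=series,
                operation_window=window,
                roadside_flag=roadside,
            )
        )
    return out


def station_coords_from_meta(meta_path: str | Path) -> dict[str, tuple[float, float]]:
    meta = pd.read_csv(meta_path)
    if not {"x", "y"}.issubset(meta.columns):
        return {}
    return {
        str(r.station_id): (float(r.x), float(r.y)) for r in meta.itertuples()
    }


def write_aggregated(agg: AggregatedExposure, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "date": [d.date().isoformat() for d in agg.values.index],
            "value": agg.values.to_numpy(),
            "n_stations_used": agg.n_stations_used.to_numpy(),
        }
    )
    out.to_csv(path, index=False)
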