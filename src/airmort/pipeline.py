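"""End-to-end orchestration: aggregate → core-model selection → effect
models → tables and plots, driven by one structured configuration.

Every numeric output is a delimited table with a fixed column order, and a
manifest records the configuration digest, seed and produced files so a run
is auditable and exactly repeatable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from datetime import date as Date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregate import (
    aphea_center_aggregate,
    impute_annual_means,
    read_station_file,
    station_coords_from_meta,
    write_aggregated,
)
from .covariates import calendar_covariates, build_core_design
from .effects import (
    DEFAULT_INCREMENTS,
    DLMSpec,
    cumulative_er,
    fit_dlm,
    lag_response_curve,
    single_lag_model,
    two_pollutant_model,
)
from .glm import residual_acf_pacf, select_core_model

log = logging.getLogger("airmort")

# Epidemic-control windows; the study years are known (2003 SARS, 2009
# H1N1) but the exact dates are an assumption of this package's shipped
# configuration.
DEFAULT_SARS_WINDOW = (Date(2003, 3, 1), Date(2003, 7, 31))
DEFAULT_FLU_WINDOW = (Date(2009, 6, 1), Date(2009, 12, 31))


@dataclass
class RunConfig:
    """Structured configuration of one full pipeline run."""

    station_files: dict[str, str]        # pollutant -> delimited station file
    meta_file: str | None
    meteo_file: str
    mortality_file: str
    calendar_file: str
    outcomes: list[tuple[str, str]]      # (cause, age_group)
    pollutants: list[str] = dc_field(default_factory=lambda: ["PM10"])
    single_lags: tuple[int, ...] = (0, 1, 2, 3)
    dlm_max_lag: int = 30
    dlm_degrees: tuple[int, ...] = (2, 3, 4)
    dlm_windows: tuple[int, ...] = (5, 15, 30)
    grid: dict = dc_field(default_factory=dict)
    increments: dict = dc_field(default_factory=lambda: dict(DEFAULT_INCREMENTS))
    sars_window: tuple[Date, Date] | None = DEFAULT_SARS_WINDOW
    flu_window: tuple[Date, Date] | None = DEFAULT_FLU_WINDOW
    imputer: str = "idw"
    seed: int = 0
    outdir: str = "airmort_results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        outcomes = [tuple(o) for o in raw.pop("outcomes")]
        for key in ("sars_window", "flu_window"):
            if raw.get(key):
                raw[key] = tuple(pd.Timestamp(d).date() for d in raw[key])
        for key in ("single_lags", "dlm_degrees", "dlm_windows"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(outcomes=outcomes, **raw)

    def digest(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in self.__dict__.items()}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_mortality(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    need = {"date", "cause", "age_group", "deaths"}
    if not need.issubset(df.columns):
        raise ValueError(f"mortality file must have columns {sorted(need)}")
    return df


def _aggregate_all(config: RunConfig, outdir: Path) -> dict[str, pd.Series]:
    coords = station_coords_from_meta(config.meta_file) if (
        config.meta_file and config.imputer == "idw"
    ) else None
    exposures: dict[str, pd.Series] = {}
    for pollutant in config.pollutants:
        stations = read_station_file(
            config.station_files[pollutant], pollutant, config.meta_file
        )
        means = impute_annual_means(stations, coords)
        agg = aphea_center_aggregate(stations, means)
        path = outdir / f"aggregated_{pollutant.lower().replace('.', '')}.csv"
        write_aggregated(agg, path)
        exposures[pollutant] = agg.values
        log.info("aggregated %s over %d stations -> %s", pollutant, len(stations), path)
    return exposures


def run_pipeline(config: RunConfig) -> dict:
    """Run aggregation, core-model selection and every effect model; write
    all tables plus a manifest.  Failures in one (pollutant, outcome) cell
    are logged and recorded; completed outputs are preserved."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "outputs": [],
        "errors": [],
    }

    def emit(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.6f")
        manifest["outputs"].append(name)

    exposures = _aggregate_all(config, outdir)
    manifest["outputs"] += [
        f"aggregated_{p.lower().replace('.', '')}.csv" for p in config.pollutants
    ]

    mort = _load_mortality(config.mortality_file)
    meteo = pd.read_csv(config.meteo_file, parse_dates=["date"]).set_index("date")
    cal_df = pd.read_csv(config.calendar_file, parse_dates=["date"]).set_index("date")

    for cause, age in config.outcomes:
        tag = f"{cause}_{age}".replace(" ", "").replace("<", "lt").replace(">=", "ge")
        sub = mort[(mort["cause"] == cause) & (mort["age_group"] == age)]
        if sub.empty:
            manifest["errors"].append(f"no mortality rows for {cause}:{age}")
            continue
        y = sub.set_index("date")["deaths"].sort_index()
        dates = y.index
        holidays = [
            d.date() for d in cal_df.index[cal_df["holiday"] == 1] if d in dates
        ]
        calendar = calendar_covariates(
            dates, holidays, config.sars_window, config.flu_window
        )
        try:
            sel = select_core_model(y, calendar, meteo.reindex(dates), config.grid)
        except Exception as exc:  # noqa: BLE001 - stage isolation
            log.error("core-model selection failed for %s:%s: %s", cause, age, exc)
            manifest["errors"].append(f"select {cause}:{age}: {exc}")
            continue
        emit(sel.grid, f"core_grid_{tag}.csv")
        emit(
            sel.chosen_fit.summary_frame().reset_index(names="term"),
            f"core_fit_{tag}.csv",
        )
        emit(residual_acf_pacf(sel.chosen_fit, 30), f"core_acf_pacf_{tag}.csv")

        single_rows, significant = [], []
        for pollutant in config.pollutants:
            delta = config.increments[pollutant]
            any_sig = False
            for k in config.single_lags:
                try:
                    est, _ = single_lag_model(
                        sel.chosen_design, exposures[pollutant], k, delta,
                        pollutant=pollutant, outcome=f"{cause}:{age}",
                    )
                except Exception as exc:  # noqa: BLE001
                    manifest["errors"].append(
                        f"single {pollutant} lag{k} {cause}:{age}: {exc}"
                    )
                    continue
                single_rows.append(est.row())
                any_sig = any_sig or est.significant
            if any_sig:
                significant.append(pollutant)
        emit(pd.DataFrame(single_rows), f"single_lag_{tag}.csv")

        two_rows = []
        for a in significant:
            for b in config.pollutants:
                if b == a:
                    continue
                for k in config.single_lags:
                    try:
                        est, _ = two_pollutant_model(
                            sel.chosen_design, exposures[a], exposures[b], k,
                            config.increments[a], pollutant_a=a, pollutant_b=b,
                            outcome=f"{cause}:{age}",
                        )
                        two_rows.append(est.row())
                    except Exception as exc:  # noqa: BLE001
                        manifest["errors"].append(
                            f"two-pollutant {a}+{b} lag{k} {cause}:{age}: {exc}"
                        )
        if two_rows:
            emit(pd.DataFrame(two_rows), f"two_pollutant_{tag}.csv")

        cum_rows, curve_rows = [], []
        for pollutant in config.pollutants:
            delta = config.increments[pollutant]
            for degree in config.dlm_degrees:
                spec = DLMSpec(max_lag=config.dlm_max_lag, degree=degree)
                try:
                    dlm = fit_dlm(
                        sel.chosen_design, exposures[pollutant], spec, delta,
                        pollutant=pollutant, outcome=f"{cause}:{age}",
                    )
                except Exception as exc:  # noqa: BLE001
                    manifest["errors"].append(
                        f"dlm {pollutant} d{degree} {cause}:{age}: {exc}"
                    )
                    continue
                for m in config.dlm_windows:
                    row = cumulative_er(dlm, min(m, spec.max_lag)).row()
                    row["degree"] = degree
                    cum_rows.append(row)
                for est in lag_response_curve(dlm):
                    row = est.row()
                    row["degree"] = degree
                    curve_rows.append(row)
        emit(pd.DataFrame(cum_rows), f"dlm_cumulative_{tag}.csv")
        emit(pd.DataFrame(curve_rows), f"dlm_curve_{tag}.csv")

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def make_report(outdir: str | Path) -> list[Path]:
    """Cumulative and per-lag excess-risk charts from a results bundle.

    One cumulative-ER chart and one per-lag chart per (pollutant, outcome),
    built from the ``dlm_*`` tables written by :func:`run_pipeline`, with
    the 95% band shaded.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    curve_files = sorted(outdir.glob("dlm_curve_*.csv"))
    if not curve_files:
        raise FileNotFoundError("no DLM results found in bundle")
    written: list[Path] = []
    for curve_file in curve_files:
        tag = curve_file.stem.removeprefix("dlm_curve_")
        curves = pd.read_csv(curve_file)
        cums = pd.read_csv(outdir / f"dlm_cumulative_{tag}.csv")
        for pollutant, grp in curves.groupby("pollutant"):
            sub = grp[grp["degree"] == 3] if (grp["degree"] == 3).any() else grp
            lags = sub["lag"].str.extract(r"(\d+)$")[0].astype(int)

            fig, ax = plt.subplots(figsize=(6, 4))
            ax.fill_between(lags, sub["ci_low"], sub["ci_high"], alpha=0.25)
            ax.plot(lags, sub["er_percent"])
            ax.axhline(0.0, color="k", lw=0.7)
            ax.set_xlabel("lag (days)")
            ax.set_ylabel("per-lag excess risk (%)")
            ax.set_title(f"{pollutant} — {tag}")
            path = outdir / f"curve_{tag}_{pollutant}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)

            csub = cums[cums["pollutant"] == pollutant]
            csub = csub[csub["degree"] == 3] if (csub["degree"] == 3).any() else csub
            ends = csub["lag"].str.extract(r"(\d+)$")[0].astype(int)
            fig, ax = plt.subplots(figsize=(6, 4))
            ax.errorbar(
                ends, csub["er_percent"],
                yerr=[csub["er_percent"] - csub["ci_low"],
                      csub["ci_high"] - csub["er_percent"]],
                fmt="o", capsize=4,
            )
            ax.axhline(0.0, color="k", lw=0.7)
            ax.set_xlabel("cumulative window end (days)")
            ax.set_ylabel("cumulative excess risk (%)")
            ax.set_title(f"{pollutant} — {tag}")
            path = outdir / f"cumulative_{tag}_{pollutant}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)
    return written
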