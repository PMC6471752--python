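"""Pollutant effect models and excess-risk transformation.

Effects are estimated by adding pollutant terms to a previously selected
core design and refitting the quasi-Poisson model:

* single-day lag models add the concentration from exactly ``k`` days
  before the outcome day as one linear term;
* two-pollutant models add both pollutants at the same lag, to check
  robustness of one pollutant's effect to adjustment for the other;
* distributed lag models (DLMs) regress on exposures over lags 0..L with
  the lag coefficients constrained to a low-degree polynomial of lag (the
  Almon constraint): beta_l = sum_j eta_j (l/L)^j, so only d+1 free
  parameters describe the whole 31-day lag-response curve.

A log-rate coefficient beta is reported as excess risk ER = (RR - 1) x 100%
with RR = exp(delta * beta) per a conventional increment delta (0.1 mg/m3
for CO, 10 ug/m3 for other pollutants), with Wald 95% intervals mapped
through the same transformation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import CoreDesign, lagged
from .glm import GLMFit, fit_quasipoisson

__all__ = [
    "DEFAULT_INCREMENTS",
    "EffectEstimate",
    "DLMSpec",
    "DLMFit",
    "excess_risk",
    "single_lag_model",
    "two_pollutant_model",
    "dlm_basis",
    "lag_matrix",
    "fit_dlm",
    "cumulative_er",
    "lag_response_curve",
]

# conventional reporting increments: 0.1 mg/m3 for CO, 10 ug/m3 otherwise
DEFAULT_INCREMENTS = {
    "PM10": 10.0, "PM2.5": 10.0, "NO2": 10.0, "O3": 10.0, "SO2": 10.0, "CO": 0.1,
}


@dataclass
class EffectEstimate:
    """One excess-risk estimate with its 95% confidence interval."""

    pollutant: str
    outcome: str
    lag_spec: str
    delta: float
    beta_per_unit: float
    se_per_unit: float
    er_percent: float
    ci_low_percent: float
    ci_high_percent: float

    @property
    def significant(self) -> bool:
        return self.ci_low_percent > 0 or self.ci_high_percent < 0

    def row(self) -> dict:
        return {
            "pollutant": self.pollutant,
            "outcome": self.outcome,
            "lag": self.lag_spec,
            "er_percent": self.er_percent,
            "ci_low": self.ci_low_percent,
            "ci_high": self.ci_high_percent,
            "significant": int(self.significant),
        }


def excess_risk(
    beta_per_unit: float,
    se_per_unit: float,
    delta: float,
    *,
    pollutant: str = "",
    outcome: str = "",
    lag_spec: str = "",
) -> EffectEstimate:
    """(RR - 1) x 100% per increment delta, with Wald 95% CI.

    ER = (exp(delta * beta) - 1) * 100; the CI maps beta +/- 1.96 se through
    the same exponential, so it is symmetric on the log-rate scale.
    """
    if se_per_unit < 0:
        raise ValueError("standard error must be non-negative")
    er = (np.exp(delta * beta_per_unit) - 1.0) * 100.0
    lo = (np.exp(delta * (beta_per_unit - 1.96 * se_per_unit)) - 1.0) * 100.0
    hi = (np.exp(delta * (beta_per_unit + 1.96 * se_per_unit)) - 1.0) * 100.0
    return EffectEstimate(
        pollutant=pollutant,
        outcome=outcome,
        lag_spec=lag_spec,
        delta=delta,
        beta_per_unit=float(beta_per_unit),
        se_per_unit=float(se_per_unit),
        er_percent=float(er),
        ci_low_percent=float(min(lo, hi)),
        ci_high_percent=float(max(lo, hi)),
    )


def single_lag_model(
    core_design: CoreDesign,
    exposure: pd.Series,
    lag: int,
    delta: float,
    *,
    pollutant: str = "pollutant",
    outcome: str = "",
) -> tuple[EffectEstimate, GLMFit]:
    """Refit the core design plus one linear exposure term at lag ``k``.

    Days without the lagged exposure value (leading history or missing
    monitoring days) are masked, never interpolated.
    """
    if lag < 0:
        raise ValueError("lag must be non-negative")
    x = lagged(exposure.reindex(core_design.matrix.index), lag)
    name = f"{pollutant}_lag{lag}"
    design = core_design.with_columns(x.to_frame(name), block="pollutant")
    if np.nanstd(x.to_numpy()[design.rows_valid]) == 0:
        raise ValueError("exposure constant over valid rows")
    fit = fit_quasipoisson(design)
    est = excess_risk(
        fit.params[name], fit.bse[name], delta,
        pollutant=pollutant, outcome=outcome, lag_spec=f"lag {lag}",
    )
    return est, fit


def two_pollutant_model(
    core_design: CoreDesign,
    exposure_a: pd.Series,
    exposure_b: pd.Series,
    lag: int,
    delta_a: float,
    *,
    pollutant_a: str = "a",
    pollutant_b: str = "b",
    outcome: str = "",
    collinearity_r: float = 0.9,
) -> tuple[EffectEstimate, GLMFit]:
    """Effect of pollutant ``a`` adjusted for ``b``, both at lag ``k``.

    Highly correlated co-pollutants make joint estimates unstable; a
    warning is emitted when |r| of the two lagged series exceeds
    ``collinearity_r``, and an exactly collinear pair raises.
    """
    idx = core_design.matrix.index
    xa = lagged(exposure_a.reindex(idx), lag)
    xb = lagged(exposure_b.reindex(idx), lag)
    both = pd.DataFrame({
        f"{pollutant_a}_lag{lag}": xa,
        f"{pollutant_b}_lag{lag}": xb,
    })
    ok = both.notna().all(axis=1).to_numpy() & core_design.rows_valid
    r = np.corrcoef(xa.to_numpy()[ok], xb.to_numpy()[ok])[0, 1]
    if abs(r) > collinearity_r:
        warnings.warn(
            f"lagged {pollutant_a}/{pollutant_b} correlation r={r:.3f} exceeds "
            f"{collinearity_r}; estimates may be unstable",
            stacklevel=2,
        )
    design = core_design.with_columns(both, block="pollutants")
    fit = fit_quasipoisson(design)
    name = f"{pollutant_a}_lag{lag}"
    est = excess_risk(
        fit.params[name], fit.bse[name], delta_a,
        pollutant=pollutant_a, outcome=outcome,
        lag_spec=f"lag {lag} adj {pollutant_b}",
    )
    return est, fit


@dataclass
class DLMSpec:
    """Polynomial distributed-lag specification.

    ``max_lag`` lags 0..L are modelled; the lag-coefficient curve is a
    polynomial of ``degree`` in (l / lag_scale).  Scaling the lag before
    powering (default: by L) keeps the basis well conditioned without
    changing the fitted subspace.
    """

    max_lag: int = 30
    degree: int = 3
    lag_scale: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.degree <= self.max_lag:
            raise ValueError("degree must lie in [0, max_lag]")
        if self.lag_scale is None:
            self.lag_scale = float(max(self.max_lag, 1))


def dlm_basis(spec: DLMSpec) -> np.ndarray:
    """(L+1) x (d+1) Almon basis, C[l, j] = (l / scale)^j (column 0 all ones)."""
    lags = np.arange(spec.max_lag + 1, dtype=float) / spec.lag_scale
    return np.column_stack([lags**j for j in range(spec.degree + 1)])


def lag_matrix(exposure: pd.Series, index: pd.Index, max_lag: int) -> pd.DataFrame:
    """n x (L+1) matrix of lagged exposure values aligned to ``index``."""
    cols = {f"xlag{l}": lagged(exposure.reindex(index), l) for l in range(max_lag + 1)}
    return pd.DataFrame(cols, index=index)


@dataclass
class DLMFit:
    """Polynomial-constrained distributed-lag fit.

    ``eta`` are the d+1 polynomial coefficients; per-lag coefficients are
    the deterministic transform beta = C eta, with var(beta_l) = C_l
    cov_eta C_l'.
    """

    spec: DLMSpec
    pollutant: str
    outcome: str
    delta: float
    eta: np.ndarray
    cov_eta: np.ndarray
    glm: GLMFit
    basis: np.ndarray = field(repr=False)
    n_obs_used: int = 0

    @property
    def lag_betas(self) -> np.ndarray:
        return self.basis @ self.eta

    @property
    def lag_beta_ses(self) -> np.ndarray:
        return np.sqrt(np.einsum("lj,jk,lk->l", self.basis, self.cov_eta, self.basis))


def fit_dlm(
    core_design: CoreDesign,
    exposure: pd.Series,
    spec: DLMSpec,
    delta: float,
    *,
    pollutant: str = "pollutant",
    outcome: str = "",
) -> DLMFit:
    """Fit the Almon-constrained DLM on top of a core design.

    The lagged exposure matrix X (lags 0..L) is projected onto the
    polynomial basis, W = X C, and the d+1 columns of W join the core
    design in one quasi-Poisson fit.  Days lacking full 0..L exposure
    history are masked out.
    """
    C = dlm_basis(spec)
    X = lag_matrix(exposure, core_design.matrix.index, spec.max_lag)
    n_missing_history = int(X.isna().any(axis=1).sum())
    if n_missing_history:
        warnings.warn(
            f"masking {n_missing_history} days without full {spec.max_lag}-day "
            "exposure history",
            stacklevel=2,
        )
    incomplete = X.isna().any(axis=1).to_numpy()[:, None]
    W = pd.DataFrame(
        np.where(incomplete, np.nan, np.nan_to_num(X.to_numpy()) @ C),
        index=X.index,
        columns=[f"{pollutant}_poly{j}" for j in range(spec.degree + 1)],
    )
    design = core_design.with_columns(W, block="dlm")
    fit = fit_quasipoisson(design)
    names = list(W.columns)
    eta = fit.params[names].to_numpy()
    cov_eta = fit.cov.loc[names, names].to_numpy()
    return DLMFit(
        spec=spec,
        pollutant=pollutant,
        outcome=outcome,
        delta=delta,
        eta=eta,
        cov_eta=cov_eta,
        glm=fit,
        basis=C,
        n_obs_used=fit.n_obs,
    )


def cumulative_er(dlm: DLMFit, window_end: int, delta: float | None = None) -> EffectEstimate:
    """Cumulative excess risk over lags 0..M.

    beta_cum = sum_{l<=M} beta_l = (1' C_{0..M}) eta; the variance follows
    from the same linear functional applied to cov_eta.
    """
    if not 0 <= window_end <= dlm.spec.max_lag:
        raise ValueError("window_end must lie in [0, max_lag]")
    delta = dlm.delta if delta is None else delta
    u = dlm.basis[: window_end + 1].sum(axis=0)
    beta = float(u @ dlm.eta)
    var = float(u @ dlm.cov_eta @ u)
    return excess_risk(
        beta, np.sqrt(max(var, 0.0)), delta,
        pollutant=dlm.pollutant, outcome=dlm.outcome,
        lag_spec=f"lags 0-{window_end}",
    )


def lag_response_curve(dlm: DLMFit, delta: float | None = None) -> list[EffectEstimate]:
    """Per-lag (non-cumulative) excess risks for lags 0..L."""
    delta = dlm.delta if delta is None else delta
    betas = dlm.lag_betas
    ses = dlm.lag_beta_ses
    return [
        excess_risk(
            betas[l], ses[l], delta,
            pollutant=dlm.pollutant, outcome=dlm.outcome, lag_spec=f"lag {l}",
        )
        for l in range(dlm.spec.max_lag + 1)
    ]
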