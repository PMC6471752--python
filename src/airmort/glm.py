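"""Quasi-Poisson core-model fitting, qAIC model selection and diagnostics.

Quasi-Poisson regression keeps the Poisson mean structure and log link but
lets the variance be phi * mu.  Point estimates are therefore exactly the
Poisson maximum-likelihood estimates; only the covariance is inflated, by
the Pearson dispersion phi = X^2 / (n - p).  Model comparison across a grid
of spline dimensions and meteorology lags uses qAIC = -2 logLik / c_hat +
2 p with a single c_hat fixed from the richest candidate, so the penalised
likelihoods are on a common scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from statsmodels.tsa.stattools import acf as _acf, pacf as _pacf

from .covariates import CalendarCovariates, CoreDesign, build_core_design

__all__ = [
    "GLMFit",
    "SelectionResult",
    "fit_quasipoisson",
    "qaic",
    "select_core_model",
    "residual_acf_pacf",
]


@dataclass
class GLMFit:
    """A quasi-Poisson fit: Poisson MLE coefficients with dispersion-scaled
    covariance."""

    params: pd.Series
    cov: pd.DataFrame            # phi * (X' W X)^-1
    dispersion: float            # Pearson phi
    poisson_loglik: float
    deviance: float
    n_obs: int
    n_params: int
    converged: bool
    iterations: int
    fitted_mu: np.ndarray = field(repr=False)
    pearson_resid: np.ndarray = field(repr=False)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def summary_frame(self) -> pd.DataFrame:
        se = self.bse
        z = self.params / se
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": se,
                "z": z,
                "ci_low": self.params - 1.96 * se,
                "ci_high": self.params + 1.96 * se,
            }
        )


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # name the offending columns via pivoted QR
        _, r, piv = scipy.linalg.qr(mat, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(mat.shape) * np.finfo(float).eps
        bad = [X.columns[j] for j in piv[diag < tol]] or list(X.columns[rank:])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def fit_quasipoisson(design: CoreDesign, *, tol: float = 1e-8, maxiter: int = 100) -> GLMFit:
    """Fit the quasi-Poisson log-linear model on a design's valid rows.

    Coefficients maximise the Poisson log-likelihood (IRLS, relative
    coefficient change below ``tol``, at most ``maxiter`` iterations);
    non-convergence is flagged, not raised.  The covariance is the inverse
    Fisher information scaled by the Pearson dispersion.
    """
    y = design.y
    X = design.X
    if len(y) < X.shape[1] + 1:
        raise ValueError("too few valid rows for the number of parameters")
    if (y < 0).any():
        raise ValueError("negative counts")
    _check_rank(X)

    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(method="IRLS", tol=tol, maxiter=maxiter)
    n, p = len(y), X.shape[1]
    mu = res.fittedvalues
    pearson = (y - mu) / np.sqrt(mu)
    phi = float(res.pearson_chi2 / (n - p))
    cov_unscaled = res.cov_params() / res.scale  # (X'WX)^-1, scale-free
    return GLMFit(
        params=pd.Series(res.params, index=X.columns),
        cov=pd.DataFrame(phi * cov_unscaled, index=X.columns, columns=X.columns),
        dispersion=phi,
        poisson_loglik=float(res.llf),
        deviance=float(res.deviance),
        n_obs=n,
        n_params=p,
        converged=bool(res.converged),
        iterations=int(getattr(res, "fit_history", {}).get("iteration", 0) or maxiter),
        fitted_mu=np.asarray(mu),
        pearson_resid=np.asarray(pearson),
    )


def qaic(fit: GLMFit, c_hat: float) -> float:
    """Quasi-AIC: -2 logLik / c_hat + 2 p.  Reduces to AIC at c_hat = 1."""
    if c_hat <= 0:
        raise ValueError("c_hat must be positive")
    return -2.0 * fit.poisson_loglik / c_hat + 2.0 * fit.n_params


@dataclass
class SelectionResult:
    """Ranked qAIC grid and the chosen core-model candidate."""

    grid: pd.DataFrame              # one row per candidate with qAIC
    chosen: dict                    # candidate key -> value mapping
    chosen_fit: GLMFit
    chosen_design: CoreDesign
    c_hat: float


def _candidate_key(c: dict) -> tuple:
    return tuple(sorted(c.items()))


def select_core_model(
    mortality: pd.Series,
    calendar: CalendarCovariates,
    meteo: pd.DataFrame,
    grid: dict[str, list] | None = None,
    *,
    extra_invalid: np.ndarray | None = None,
) -> SelectionResult:
    """Fit every candidate on the (trend_df, dbt_df, dbt_lag, rh_df, rh_lag)
    grid and pick the qAIC minimiser.

    The dispersion c_hat used in every qAIC is estimated once, from the
    candidate with the most parameters, and held fixed so candidates are
    scored on a common scale.  Ties break toward fewer parameters, then the
    lexicographically smallest candidate key.
    """
    grid = grid or {}
    trend_dfs = grid.get("trend_df", [6, 8, 10])
    dbt_dfs = grid.get("dbt_df", [3, 4, 5])
    dbt_lags = grid.get("dbt_lag", [1, 2, 3])
    rh_dfs = grid.get("rh_df", [3])
    rh_lags = grid.get("rh_lag", [1])

    candidates = [
        {"trend_df": a, "dbt_df": b, "dbt_lag": c, "rh_df": d, "rh_lag": e}
        for a, b, c, d, e in itertools.product(trend_dfs, dbt_dfs, dbt_lags, rh_dfs, rh_lags)
    ]
    if not candidates:
        raise ValueError("empty candidate grid")

    fits: list[tuple[dict, GLMFit, CoreDesign] | None] = []
    for cand in candidates:
        try:
            design = build_core_design(
                mortality, calendar, meteo, extra_invalid=extra_invalid, **cand
            )
            fit = fit_quasipoisson(design)
            fits.append((cand, fit, design) if fit.converged else None)
        except ValueError:
            fits.append(None)
    ok = [f for f in fits if f is not None]
    if not ok:
        raise RuntimeError("no grid candidate converged")

    richest = max(ok, key=lambda f: f[1].n_params)
    c_hat = richest[1].dispersion

    rows = []
    for cand, fit, _ in ok:
        rows.append({**cand, "n_params": fit.n_params, "qaic": qaic(fit, c_hat)})
    table = pd.DataFrame(rows).sort_values(
        ["qaic", "n_params"], kind="mergesort"
    ).reset_index(drop=True)

    best_q = table["qaic"].min()
    contenders = [
        (cand, fit, design)
        for cand, fit, design in ok
        if qaic(fit, c_hat) == best_q
    ]
    contenders.sort(key=lambda f: (f[1].n_params, _candidate_key(f[0])))
    chosen, chosen_fit, chosen_design = contenders[0]
    return SelectionResult(table, chosen, chosen_fit, chosen_design, c_hat)


def residual_acf_pacf(fit: GLMFit, max_lag: int) -> pd.DataFrame:
    """Sample ACF and (Durbin–Levinson) PACF of the Pearson residuals.

    Residuals are taken over the fit's valid rows in date order.  The
    returned table carries the +/- 1.96 / sqrt(n) white-noise reference
    bound.
    """
    if max_lag <= 0:
        raise ValueError("max_lag must be positive")
    resid = fit.pearson_resid
    if max_lag >= len(resid) / 4:
        raise ValueError("max_lag too large for the residual length")
    a = _acf(resid, nlags=max_lag, fft=True)
    p = _pacf(resid, nlags=max_lag, method="ldb")
    bound = 1.96 / np.sqrt(len(resid))
    return pd.DataFrame(
        {"lag": np.arange(max_lag + 1), "acf": a, "pacf": p, "bound": bound}
    )
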