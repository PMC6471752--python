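"""Quasi-Poisson fitting against closed forms and an independent optimizer."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import gammaln

from airmort.covariates import CoreDesign, build_core_design, calendar_covariates
from airmort.glm import fit_quasipoisson, qaic, residual_acf_pacf, select_core_model
from airmort.synthetic import ScenarioConfig, simulate_dataset

from conftest import make_counts_design


def design_from(X: pd.DataFrame, y: pd.Series) -> CoreDesign:
    idx = pd.date_range("2005-01-01", periods=len(y), freq="D")
    X = X.set_axis(idx)
    y = y.set_axis(idx)
    return CoreDesign(y, X, np.ones(len(y), dtype=bool), {"all": list(X.columns)})


def poisson_negloglik(beta, X, y):
    eta = X @ beta
    return -(y @ eta - np.exp(eta).sum() - gammaln(y + 1).sum())


def test_intercept_only_closed_form(rng):
    y = pd.Series(rng.poisson(7.0, size=200))
    X = pd.DataFrame({"intercept": np.ones(200)})
    fit = fit_quasipoisson(design_from(X, y))
    assert fit.params["intercept"] == pytest.approx(np.log(y.mean()), abs=1e-10)


def test_recovers_simulated_coefficients(rng):
    X, y, beta = make_counts_design(rng, n=3000)
    fit = fit_quasipoisson(design_from(X, y))
    assert fit.converged
    for name, b in zip(X.columns, beta):
        assert abs(fit.params[name] - b) < 3 * fit.bse[name]
    assert abs(fit.dispersion - 1.0) < 0.1


def test_agrees_with_generic_optimizer(rng):
    """IRLS coefficients match an independent numerical maximizer of the
    Poisson log-likelihood to 1e-6."""
    X, y, _ = make_counts_design(rng, n=1000)
    fit = fit_quasipoisson(design_from(X, y))
    res = minimize(
        poisson_negloglik, np.zeros(X.shape[1]),
        args=(X.to_numpy(), y.to_numpy().astype(float)),
        method="BFGS", options={"gtol": 1e-10},
    )
    assert np.allclose(fit.params.to_numpy(), res.x, atol=1e-6)
    assert fit.poisson_loglik == pytest.approx(-res.fun, abs=1e-6)


def test_quasi_scaling_of_standard_errors(rng):
    """Quasi-Poisson SEs are sqrt(phi) times the unscaled Poisson SEs, and
    the covariance is symmetric PSD."""
    X, y, _ = make_counts_design(rng, n=800)
    y = pd.Series(y.to_numpy() * rng.poisson(1, size=len(y)).clip(0, 2))  # roughen
    fit = fit_quasipoisson(design_from(X, y))
    cov = fit.cov.to_numpy()
    assert np.allclose(cov, cov.T)
    assert (np.linalg.eigvalsh(cov) > -1e-12).all()
    poisson_se = np.sqrt(np.diag(cov / fit.dispersion))
    assert np.allclose(fit.bse.to_numpy() / poisson_se, np.sqrt(fit.dispersion))


def test_row_order_and_rescaling_invariance(rng):
    X, y, _ = make_counts_design(rng, n=600)
    base = fit_quasipoisson(design_from(X, y))

    perm = rng.permutation(600)
    shuffled = fit_quasipoisson(design_from(
        X.iloc[perm].reset_index(drop=True), y.iloc[perm].reset_index(drop=True)
    ))
    assert np.allclose(base.params, shuffled.params, atol=1e-8)

    X2 = X.copy()
    X2["x1"] = 10.0 * X["x1"] + 3.0  # affine rescale of one covariate
    rescaled = fit_quasipoisson(design_from(X2, y))
    assert rescaled.params["x1"] == pytest.approx(base.params["x1"] / 10.0, abs=1e-8)
    mu_a = np.exp(X.to_numpy() @ base.params.to_numpy())
    mu_b = np.exp(X2.to_numpy() @ rescaled.params.to_numpy())
    assert np.allclose(mu_a, mu_b, atol=1e-8)


def test_rank_deficiency_names_columns(rng):
    X, y, _ = make_counts_design(rng, n=200)
    X["dup"] = X["x1"]
    with pytest.raises(ValueError, match="dup|x1"):
        fit_quasipoisson(design_from(X, y))


def test_negative_counts_rejected(rng):
    X, _, _ = make_counts_design(rng, n=50)
    y = pd.Series(np.full(50, -1))
    with pytest.raises(ValueError):
        fit_quasipoisson(design_from(X, y))


class TestQaic:
    def test_reduces_to_aic(self, rng):
        X, y, _ = make_counts_design(rng, n=300)
        fit = fit_quasipoisson(design_from(X, y))
        assert qaic(fit, 1.0) == pytest.approx(
            -2 * fit.poisson_loglik + 2 * fit.n_params
        )

    def test_dispersion_halves_likelihood_term(self, rng):
        X, y, _ = make_counts_design(rng, n=300)
        fit = fit_quasipoisson(design_from(X, y))
        assert qaic(fit, 2.0) - 2 * fit.n_params == pytest.approx(
            (qaic(fit, 1.0) - 2 * fit.n_params) / 2
        )

    def test_penalty_arithmetic(self, rng):
        X, y, _ = make_counts_design(rng, n=300)
        small = fit_quasipoisson(design_from(X[["intercept", "x1"]], y))
        big = fit_quasipoisson(design_from(X, y))
        # force identical likelihoods to isolate the penalty
        big.poisson_loglik = small.poisson_loglik
        assert qaic(big, 1.3) - qaic(small, 1.3) == pytest.approx(
            2 * (big.n_params - small.n_params)
        )

    def test_invalid_dispersion(self, rng):
        X, y, _ = make_counts_design(rng, n=100)
        fit = fit_quasipoisson(design_from(X, y))
        with pytest.raises(ValueError):
            qaic(fit, 0.0)


class TestSelection:
    def test_single_candidate_grid(self):
        ds = simulate_dataset(ScenarioConfig(n_days=400, seed=13,
                                             true_lag_coefs=(0.0,)))
        cal = calendar_covariates(ds.dates)
        grid = {"trend_df": [4], "dbt_df": [3], "dbt_lag": [1],
                "rh_df": [3], "rh_lag": [1]}
        sel = select_core_model(ds.mortality["deaths"], cal, ds.meteo, grid)
        assert sel.chosen == {"trend_df": 4, "dbt_df": 3, "dbt_lag": 1,
                              "rh_df": 3, "rh_lag": 1}
        assert len(sel.grid) == 1
        assert sel.grid["qaic"].idxmin() == 0

    def test_chosen_attains_minimum(self):
        ds = simulate_dataset(ScenarioConfig(n_days=500, seed=14,
                                             true_lag_coefs=(0.0,)))
        cal = calendar_covariates(ds.dates)
        grid = {"trend_df": [4, 6], "dbt_df": [3], "dbt_lag": [1, 2],
                "rh_df": [3], "rh_lag": [1]}
        sel = select_core_model(ds.mortality["deaths"], cal, ds.meteo, grid)
        chosen_row = sel.grid.iloc[0]
        assert chosen_row["qaic"] == sel.grid["qaic"].min()
        assert all(chosen_row[k] == v for k, v in sel.chosen.items())

    def test_empty_grid_rejected(self):
        ds = simulate_dataset(ScenarioConfig(n_days=200, seed=15,
                                             true_lag_coefs=(0.0,)))
        cal = calendar_covariates(ds.dates)
        with pytest.raises(ValueError):
            select_core_model(ds.mortality["deaths"], cal, ds.meteo,
                              {"trend_df": []})


class TestDiagnostics:
    def test_acf_lag0_is_one(self, small_design):
        fit = fit_quasipoisson(small_design)
        table = residual_acf_pacf(fit, 20)
        assert table["acf"].iloc[0] == pytest.approx(1.0)
        assert table["pacf"].iloc[0] == pytest.approx(1.0)
        assert table["bound"].iloc[0] == pytest.approx(1.96 / np.sqrt(fit.n_obs))
        assert table["bound"].nunique() == 1

    def test_well_specified_fit_is_white(self, small_design):
        fit = fit_quasipoisson(small_design)
        table = residual_acf_pacf(fit, 30)
        outside = (table["acf"].iloc[1:].abs() > table["bound"].iloc[1:]).mean()
        assert outside < 0.2

    def test_missing_trend_leaves_autocorrelation(self):
        """Dropping the trend from a strongly trending series shows up as a
        large lag-1 residual ACF."""
        config = ScenarioConfig(n_days=800, seed=19, trend_amplitude=0.5,
                                trend_period_days=800.0, true_lag_coefs=(0.0,))
        ds = simulate_dataset(config)
        cal = calendar_covariates(ds.dates)
        design = build_core_design(
            ds.mortality["deaths"], cal, None, trend_df=2,
            include_dow=False, include_calendar=False,
        )
        # degrade trend to intercept-only by zeroing the spline columns
        flat = design.matrix.copy()
        flat[design.blocks["trend"]] = 0.0
        bad = CoreDesign(design.response, flat[["intercept"]],
                         design.rows_valid, {"intercept": ["intercept"]})
        fit = fit_quasipoisson(bad)
        table = residual_acf_pacf(fit, 5)
        assert table["acf"].iloc[1] > 0.3

    def test_bad_max_lag(self, small_design):
        fit = fit_quasipoisson(small_design)
        with pytest.raises(ValueError):
            residual_acf_pacf(fit, 0)
        with pytest.raises(ValueError):
            residual_acf_pacf(fit, fit.n_obs)
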