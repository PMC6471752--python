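"""Excess-risk transformation, single-lag/two-pollutant models, Almon DLM."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import airmort as am
from airmort.covariates import calendar_covariates, build_core_design
from airmort.effects import (
    DLMSpec,
    cumulative_er,
    dlm_basis,
    excess_risk,
    fit_dlm,
    lag_matrix,
    lag_response_curve,
    single_lag_model,
    two_pollutant_model,
)
from airmort.glm import fit_quasipoisson
from airmort.synthetic import ScenarioConfig, simulate_dataset


@pytest.fixture(scope="module")
def effect_setup():
    """Dataset with a known lag-0 effect plus its correctly specified core
    design (module-scoped: several model variants reuse it)."""
    config = ScenarioConfig(n_days=900, seed=23, true_lag_coefs=(2e-4,))
    ds = simulate_dataset(config)
    holidays = [d.date() for d in ds.calendar.index[ds.calendar["holiday"] == 1]]
    cal = calendar_covariates(ds.dates, holidays)
    design = build_core_design(
        ds.mortality["deaths"], cal, ds.meteo,
        trend_df=4, dbt_df=3, dbt_lag=1, rh_df=3, rh_lag=1,
    )
    return ds, design


class TestExcessRisk:
    def test_null_effect(self):
        est = excess_risk(0.0, 0.01, 10.0)
        assert est.er_percent == 0.0
        # symmetric about zero on the log scale
        assert np.log1p(est.ci_high_percent / 100) == pytest.approx(
            -np.log1p(est.ci_low_percent / 100)
        )

    def test_doubling_closed_form(self):
        est = excess_risk(np.log(2) / 10, 0.0, 10.0)
        assert est.er_percent == pytest.approx(100.0)
        assert est.ci_low_percent == pytest.approx(100.0)
        assert est.ci_high_percent == pytest.approx(100.0)

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            excess_risk(0.0, -1.0, 10.0)

    @settings(max_examples=50, deadline=None)
    @given(
        beta=st.floats(-0.01, 0.01),
        se=st.floats(0.0, 0.005),
        delta=st.sampled_from([0.1, 10.0]),
    )
    def test_transformation_identities(self, beta, se, delta):
        est = excess_risk(beta, se, delta)
        assert est.er_percent == pytest.approx((np.exp(delta * beta) - 1) * 100)
        assert est.ci_low_percent <= est.er_percent <= est.ci_high_percent


class TestDlmBasis:
    def test_degree_zero_is_moving_sum(self):
        C = dlm_basis(DLMSpec(max_lag=4, degree=0))
        assert C.shape == (5, 1)
        assert (C == 1.0).all()

    def test_enumerated_rows(self):
        C = dlm_basis(DLMSpec(max_lag=3, degree=2, lag_scale=1.0))
        expected = np.array([[1, 0, 0], [1, 1, 1], [1, 2, 4], [1, 3, 9]], dtype=float)
        assert np.array_equal(C, expected)

    def test_saturated_is_invertible(self):
        C = dlm_basis(DLMSpec(max_lag=4, degree=4))
        assert C.shape == (5, 5)
        assert np.linalg.matrix_rank(C) == 5

    def test_degree_exceeding_lag_rejected(self):
        with pytest.raises(ValueError):
            DLMSpec(max_lag=3, degree=4)


class TestSingleLag:
    def test_orthogonal_pollutant_preserves_core(self, effect_setup, rng):
        """A noise 'pollutant' uncorrelated with mortality leaves every core
        coefficient within one SE of the core-only fit."""
        ds, design = effect_setup
        core_fit = fit_quasipoisson(design)
        noise = pd.Series(rng.normal(30, 5, size=len(ds.dates)), index=ds.dates)
        est, joint = single_lag_model(design, noise, 0, 10.0, pollutant="X")
        for name in core_fit.params.index:
            assert abs(joint.params[name] - core_fit.params[name]) <= core_fit.bse[name]

    def test_masks_missing_exposure_days(self, effect_setup):
        ds, design = effect_setup
        exposure = ds.population_exposure.copy()
        exposure.iloc[100:103] = np.nan
        _, fit = single_lag_model(design, exposure, 0, 10.0)
        base_n = fit_quasipoisson(design).n_obs
        assert fit.n_obs == base_n - 3

    def test_constant_exposure_rejected(self, effect_setup):
        ds, design = effect_setup
        flat = pd.Series(10.0, index=ds.dates)
        with pytest.raises(ValueError):
            single_lag_model(design, flat, 0, 10.0)

    def test_negative_lag_rejected(self, effect_setup):
        ds, design = effect_setup
        with pytest.raises(ValueError):
            single_lag_model(design, ds.population_exposure, -1, 10.0)

    def test_recovers_true_lag0_effect(self, effect_setup):
        ds, design = effect_setup
        est, _ = single_lag_model(design, ds.population_exposure, 0, 10.0,
                                  pollutant="PM10")
        true_er = (np.exp(10 * 2e-4) - 1) * 100
        assert est.ci_low_percent < true_er < est.ci_high_percent


class TestTwoPollutant:
    def test_identical_pair_rejected(self, effect_setup):
        ds, design = effect_setup
        x = ds.population_exposure
        with pytest.raises(ValueError):
            two_pollutant_model(design, x, x, 0, 10.0)

    def test_independent_copollutant_harmless(self, effect_setup, rng):
        ds, design = effect_setup
        x = ds.population_exposure
        single, _ = single_lag_model(design, x, 0, 10.0, pollutant="PM10")
        noise = pd.Series(rng.normal(25, 7, size=len(ds.dates)), index=ds.dates)
        adj, _ = two_pollutant_model(design, x, noise, 0, 10.0,
                                     pollutant_a="PM10", pollutant_b="X")
        assert abs(adj.beta_per_unit - single.beta_per_unit) <= single.se_per_unit

    def test_collinear_copollutant_inflates_se_and_warns(self, effect_setup, rng):
        ds, design = effect_setup
        x = ds.population_exposure
        twin = x + pd.Series(rng.normal(0, 0.25 * x.std(), size=len(x)),
                             index=x.index)
        assert np.corrcoef(x, twin)[0, 1] > 0.9
        single, _ = single_lag_model(design, x, 0, 10.0, pollutant="PM10")
        with pytest.warns(UserWarning, match="correlation"):
            adj, _ = two_pollutant_model(design, x, twin, 0, 10.0,
                                         pollutant_a="PM10", pollutant_b="PM2.5")
        assert adj.se_per_unit > single.se_per_unit


class TestDlm:
    def test_saturated_equals_unconstrained(self, effect_setup):
        """Degree = L: the Almon map is invertible, so per-lag coefficients
        match entering the three lags separately."""
        ds, design = effect_setup
        dlm = fit_dlm(design, ds.population_exposure, DLMSpec(2, 2), 10.0)
        X = lag_matrix(ds.population_exposure, design.matrix.index, 2)
        free = fit_quasipoisson(design.with_columns(X, block="lags"))
        free_betas = free.params[["xlag0", "xlag1", "xlag2"]].to_numpy()
        assert np.allclose(dlm.lag_betas, free_betas, atol=1e-6)
        # covariance agrees through the same change of basis
        C = dlm.basis
        cov_free = free.cov.loc[["xlag0", "xlag1", "xlag2"],
                                ["xlag0", "xlag1", "xlag2"]].to_numpy()
        assert np.allclose(C @ dlm.cov_eta @ C.T, cov_free, atol=1e-6)

    def test_cumulative_window0_equals_lag0(self, effect_setup):
        ds, design = effect_setup
        dlm = fit_dlm(design, ds.population_exposure, DLMSpec(10, 3), 10.0)
        c0 = cumulative_er(dlm, 0)
        lag0 = lag_response_curve(dlm)[0]
        assert c0.er_percent == pytest.approx(lag0.er_percent)
        assert c0.ci_low_percent == pytest.approx(lag0.ci_low_percent)

    def test_degree0_closed_form(self, effect_setup):
        ds, design = effect_setup
        dlm = fit_dlm(design, ds.population_exposure, DLMSpec(10, 0), 10.0)
        M = 6
        est = cumulative_er(dlm, M)
        beta_cum = (M + 1) * dlm.eta[0]
        var_cum = (M + 1) ** 2 * dlm.cov_eta[0, 0]
        assert est.beta_per_unit == pytest.approx(beta_cum)
        assert est.se_per_unit == pytest.approx(np.sqrt(var_cum))

    def test_per_lag_sum_equals_full_cumulative(self, effect_setup):
        ds, design = effect_setup
        dlm = fit_dlm(design, ds.population_exposure, DLMSpec(15, 3), 10.0)
        total = cumulative_er(dlm, 15)
        assert dlm.lag_betas.sum() == pytest.approx(total.beta_per_unit, abs=1e-10)

    def test_curve_sign_changes_bounded_by_degree(self, effect_setup):
        ds, design = effect_setup
        dlm = fit_dlm(design, ds.population_exposure, DLMSpec(30, 3), 10.0)
        ers = np.array([e.er_percent for e in lag_response_curve(dlm)])
        signs = np.sign(ers[np.abs(ers) > 1e-12])
        assert (np.diff(signs) != 0).sum() <= 3

    def test_window_bounds_checked(self, effect_setup):
        ds, design = effect_setup
        dlm = fit_dlm(design, ds.population_exposure, DLMSpec(10, 2), 10.0)
        with pytest.raises(ValueError):
            cumulative_er(dlm, 11)

    def test_history_masking_warns(self, effect_setup):
        ds, design = effect_setup
        with pytest.warns(UserWarning, match="history"):
            dlm = fit_dlm(design, ds.population_exposure, DLMSpec(30, 3), 10.0,
                          pollutant="PM10")
        base_valid = design.rows_valid.sum()
        # first 30 days lack full history; one already masked by dbt lag
        assert dlm.glm.n_obs == base_valid - 29

    def test_monotone_truth_orders_lags(self):
        """A decaying true lag curve yields fitted lag-0 ER above lag-20 ER."""
        curve = am.scale_lag_curve(
            am.polynomial_lag_curve(30, (1.0, -2.2, 1.6, -0.4)), (0, 5),
            np.log(1.015) / 10,
        )
        config = ScenarioConfig(n_days=2500, seed=29, true_lag_coefs=tuple(curve))
        ds = simulate_dataset(config)
        cal = calendar_covariates(ds.dates)
        design = build_core_design(ds.mortality["deaths"], cal, ds.meteo,
                                   trend_df=6, dbt_df=3, dbt_lag=1,
                                   rh_df=3, rh_lag=1)
        dlm = fit_dlm(design, ds.population_exposure, DLMSpec(30, 3), 10.0)
        ers = [e.er_percent for e in lag_response_curve(dlm)]
        assert ers[0] > ers[20]
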