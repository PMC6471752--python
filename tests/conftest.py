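import warnings

import numpy as np
import pandas as pd
import pytest

from airmort.covariates import build_core_design, calendar_covariates
from airmort.synthetic import ScenarioConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One 600-day scenario with a modest lag-0 pollutant effect."""
    config = ScenarioConfig(
        n_days=600, seed=11, true_lag_coefs=(2e-4,), missing_rate=0.1
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def small_design(small_dataset):
    ds = small_dataset
    holidays = [d.date() for d in ds.calendar.index[ds.calendar["holiday"] == 1]]
    calendar = calendar_covariates(ds.dates, holidays)
    return build_core_design(
        ds.mortality["deaths"], calendar, ds.meteo,
        trend_df=4, dbt_df=3, dbt_lag=1, rh_df=3, rh_lag=1,
    )


@pytest.fixture(autouse=True)
def _quiet_history_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="masking .* days")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_counts_design(rng, n=500, beta=(1.5, 0.3, -0.2)):
    """Poisson counts from a known intercept + two-covariate design."""
    X = pd.DataFrame(
        {
            "intercept": np.ones(n),
            "x1": rng.normal(size=n),
            "x2": rng.normal(size=n),
        }
    )
    mu = np.exp(X.to_numpy() @ np.asarray(beta))
    y = rng.poisson(mu)
    return X, pd.Series(y), np.asarray(beta)
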