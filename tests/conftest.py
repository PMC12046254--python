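import numpy as np
import pandas as pd
import pytest

from trendmed.synthetic import ScenarioTruth, default_scenario


@pytest.fixture(scope="session")
def tiny_truth() -> ScenarioTruth:
    """4-country scenario with the default noise levels."""
    return default_scenario(seed=11, n_high=2, n_middle=2)


@pytest.fixture(scope="session")
def quiet_truth() -> ScenarioTruth:
    """4-country scenario with every noise source switched off."""
    return default_scenario(
        seed=11, n_high=2, n_middle=2,
        sigma_search=0.0, sigma_mobility=0.0, sigma_outcome=0.0, sigma_deaths=0.0,
    )


@pytest.fixture
def weekly_index():
    def make(n: int, start: str = "2015-03-01") -> pd.DatetimeIndex:
        return pd.date_range(start, periods=n, freq="7D")

    return make


@pytest.fixture
def ar1_series(weekly_index):
    """AR(1) series factory: phi, n, seed -> pd.Series on a weekly index."""

    def make(phi: float = 0.8, n: int = 260, seed: int = 0, level: float = 50.0) -> pd.Series:
        rng = np.random.default_rng(seed)
        eps = rng.normal(0.0, 1.0, n)
        x = np.empty(n)
        x[0] = eps[0] / np.sqrt(1 - phi**2)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        return pd.Series(level + x, index=weekly_index(n))

    return make
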