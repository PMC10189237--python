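import numpy as np
import pytest

from fhdgm import EMConfig, SimulationSetting, fit_mle, simulate


@pytest.fixture(scope="session")
def reduced_setting_ii():
    return SimulationSetting.preset("II", n_stations=6, n_days=40)


@pytest.fixture(scope="session")
def fitted_reduced_ii(reduced_setting_ii):
    """One fitted reduced Setting II model shared across tests."""
    data, truth = simulate(reduced_setting_ii, 314)
    model = fit_mle(data, EMConfig())
    return data, truth, model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
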