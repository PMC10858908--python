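import numpy as np
import pytest

from chitosec.chemistry import enumerate_candidates
from chitosec.ri import windows_from_calibration
from chitosec.synthetic import DigestionScenario, synthetic_column_calibration

SEED = 42  # package-wide test seed


@pytest.fixture(scope="session")
def cal_model():
    return synthetic_column_calibration()


@pytest.fixture(scope="session")
def window_map(cal_model):
    return windows_from_calibration(cal_model, 2, 10)


@pytest.fixture(scope="session")
def candidates(cal_model):
    return enumerate_candidates(2, 10)


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced digestion (50 chains, 5 timepoints) shared across tests."""
    return DigestionScenario(n_chains=50, timepoints=(0.0, 15.0, 60.0, 150.0, 300.0),
                             seed=SEED)


@pytest.fixture(scope="session")
def small_states(small_scenario):
    return small_scenario.simulate()


def gaussian_trace(centers, areas, sigma=0.05, runtime=14.0, rate_hz=10.0, offset=0.0):
    """Sum of Gaussians on a uniform RI grid; closed-form areas are exact."""
    t = np.arange(0.0, runtime + 0.5 / (rate_hz * 60), 1.0 / (rate_hz * 60))
    s = np.full_like(t, float(offset))
    for c, a in zip(centers, areas):
        s += a / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - c) / sigma) ** 2)
    return t, s
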