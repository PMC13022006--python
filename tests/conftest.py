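import numpy as np
import pandas as pd
import pytest

from plumetroph import SyntheticScenario, final_ratio_matrix, initial_ratio_matrix


@pytest.fixture
def scenario():
    return SyntheticScenario(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ratio_final():
    return final_ratio_matrix()


@pytest.fixture
def ratio_initial():
    return initial_ratio_matrix()


@pytest.fixture
def two_layer_cast():
    """Two-layer density profile on a 1-m grid: sigma 22 above 20 m, 24 below."""
    z = np.arange(0.0, 41.0, 1.0)
    sig = np.where(z <= 20.0, 22.0, 24.0)
    return pd.DataFrame(
        {
            "depth": z,
            "temperature": np.full_like(z, 28.0),
            "salinity": np.where(z <= 20.0, 30.0, 36.0),
            "sigma_theta": sig,
        }
    )
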