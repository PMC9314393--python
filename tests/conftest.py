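import numpy as np
import pytest

from ntrace import CoupledIsotopeModel, FractionationSet, SynthConfig


@pytest.fixture(scope="session")
def synth_config():
    """Coarse synthetic world used across tests (seconds, not minutes)."""
    return SynthConfig(seed=11, resolution=8.0)


@pytest.fixture(scope="session")
def model(synth_config):
    return CoupledIsotopeModel.from_synthetic(synth_config)


@pytest.fixture(scope="session")
def simulation(model):
    return model.simulate({"frac_ex": 0.55, "temp_sens": 1.1,
                           "fert_ef_red": 0.3}, seed=0)


@pytest.fixture
def fractionation():
    return FractionationSet(frac_ex=0.55)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
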