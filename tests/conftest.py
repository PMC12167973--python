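import numpy as np
import pytest

from pcdrift.placefield import SpatialBinning
from pcdrift.synth import BehaviorConfig, gen_behavior


@pytest.fixture(scope="session")
def binning():
    return SpatialBinning(800.0, 80)


@pytest.fixture(scope="session")
def behavior_20laps():
    """A 20-lap default-config behavior trace shared across tests."""
    return gen_behavior(BehaviorConfig(n_laps=20), seed=11)


@pytest.fixture(scope="session")
def behavior_50laps():
    return gen_behavior(BehaviorConfig(n_laps=50), seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
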