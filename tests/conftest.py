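import warnings

import numpy as np
import pytest

from ccakit.correlator import MultiTauScheme, characterize_dark
from ccakit.detector import build_airyscan_layout
from ccakit.simulate import SimulationConfig, simulate_dark_trace


@pytest.fixture(scope="session")
def array():
    return build_airyscan_layout()


@pytest.fixture(scope="session")
def scheme():
    return MultiTauScheme()


def make_dark(channels, n_steps=250_000, seed=9_990):
    """Shared dark calibration for simulated analog traces."""
    cfg = SimulationConfig(n_steps=n_steps, channels=channels, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return characterize_dark(simulate_dark_trace(cfg), MultiTauScheme())


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (keeps tests order-independent)."""
    return np.random.default_rng(1234)
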