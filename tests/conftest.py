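import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from evflim import (
    BasisPair,
    InstrumentResponse,
    SimulationConfig,
    TimeAxis,
    default_analysis_axis,
    default_basis,
    default_irf,
)


@pytest.fixture(scope="session")
def axis() -> TimeAxis:
    """128 ps analysis bins tiling the 12.288 ns repetition period."""
    return default_analysis_axis()


@pytest.fixture(scope="session")
def irf() -> InstrumentResponse:
    return default_irf()


@pytest.fixture(scope="session")
def basis() -> BasisPair:
    return default_basis()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def small_ev_config() -> SimulationConfig:
    """Compact EV field for fast pipeline tests: bright vesicles, 128 px."""
    return SimulationConfig(
        fov_shape=(128, 128),
        n_evs=12,
        seed=5,
        photon_budget=(5000.0, 20000.0),
    )
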