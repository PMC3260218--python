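import numpy as np
import pytest

from crowdsim import ParameterSet, run_simulation
from crowdsim.engine import derive_run_seed


@pytest.fixture(scope="session")
def dilute_params():
    """A small dilute condition that runs in seconds."""
    return ParameterSet(
        c_r=0.05, c_i=0.0, box_nm=(30.0, 30.0, 30.0),
        duration_us=0.5, record_us=0.05, seed=11,
    )


@pytest.fixture(scope="session")
def dilute_run(dilute_params):
    return run_simulation(dilute_params, seed=derive_run_seed(11, 0))


@pytest.fixture(scope="session")
def long_mixed_run():
    """Mixed reactants + crowders over many record points (slow chemistry
    so the run is cheap); used by conservation/invariant tests."""
    params = ParameterSet(
        c_r=0.04, c_i=0.04, box_nm=(40.0, 40.0, 40.0),
        m_ns=50.0, duration_us=5.0, record_us=0.03125, seed=23,
    )
    return run_simulation(params, seed=derive_run_seed(23, 0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
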