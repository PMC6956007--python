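import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fnspike as fs

# numba-backed paths can be slow on first call (JIT); keep hypothesis quiet
# about per-example timing and derandomized for reproducible CI runs.
settings.register_profile(
    "fnspike",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fnspike")


@pytest.fixture(scope="session")
def default_grid():
    return fs.TimeGrid(tf=30.0, dt=0.01)


@pytest.fixture(scope="session")
def tiny_dataset():
    """8 baseline-condition trials at the nominal parameters."""
    sc = fs.Scenario(nit=8, repetitions=2, seed=1234)
    return fs.generate_dataset(fs.NOMINAL_PARAMS, sc, np.random.default_rng(1234))
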