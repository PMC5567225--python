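import numpy as np
import pytest
from hypothesis import settings

from tfdtt import (
    BathDiscretization,
    build_exciton_system,
    build_thermal_hamiltonian,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def dimer_system():
    """Two-site aggregate with 100 cm^-1 gap and 100 cm^-1 coupling."""
    return build_exciton_system([0.0, 100.0], [[0.0, 100.0], [100.0, 0.0]])


@pytest.fixture
def single_mode_bath():
    """One 180 cm^-1 mode with g = 50 cm^-1 (attached to site 1 only)."""
    return BathDiscretization(
        frequencies=np.array([180.0]), couplings=np.array([50.0]), spacing=1.0
    )


@pytest.fixture
def dimer_baths(single_mode_bath):
    """Per-site baths: the mode couples to site 1, site 2 is bare."""
    return [single_mode_bath, None]


@pytest.fixture
def dimer_thermal_300(dimer_system, dimer_baths):
    return build_thermal_hamiltonian(dimer_system, dimer_baths, 300.0)


@pytest.fixture
def random_tt():
    """Factory for random complex TTs with given mode dims and ranks."""
    from tfdtt import TensorTrain

    def _make(rng, dims, ranks):
        full = [1, *ranks, 1]
        cores = [
            (rng.standard_normal((full[k], n, full[k + 1]))
             + 1j * rng.standard_normal((full[k], n, full[k + 1])))
            for k, n in enumerate(dims)
        ]
        return TensorTrain(cores)

    return _make
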