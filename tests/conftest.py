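import numpy as np
import pytest

from rhangio import CapillaryState, SimDomain, UnitSystem, default_parameters


@pytest.fixture(scope="session")
def units():
    return UnitSystem()


@pytest.fixture(scope="session")
def params(units):
    return default_parameters(units)


@pytest.fixture
def small_domain_2d():
    """A 21x21 grid spanning 0.2 sau (160 um) with h = 0.01 sau."""
    return SimDomain(dim=2, extent=(0.2, 0.2), h=0.01)


@pytest.fixture
def blob_state(small_domain_2d, params):
    """Sharp circular vessel blob in the domain center."""
    X, Y = small_domain_2d.meshgrid()
    c0 = np.where((X - 0.1) ** 2 + (Y - 0.1) ** 2 < 0.05**2, 1.0, -1.0)
    return CapillaryState.from_field(c0, params, small_domain_2d)
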