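import numpy as np
import pytest

from poremech.fvk import MembraneSpec, get_profile


@pytest.fixture(scope="session")
def profile():
    """Warm the exact-model profile cache once per session."""
    return get_profile(0.485)


@pytest.fixture()
def pmc_spec():
    """Membrane parameters typical of the cholesterol-containing bilayer."""
    return MembraneSpec(E=513e6, sigma=5.2e-3, h=6.7e-9, R=600e-9, nu=0.485)


@pytest.fixture()
def pmc_minus_spec():
    return MembraneSpec(E=21.4e6, sigma=2.0e-3, h=6.0e-9, R=400e-9, nu=0.485)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
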