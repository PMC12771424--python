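import numpy as np
import pytest

from hexakin import KineticScheme


@pytest.fixture
def moss_scheme() -> KineticScheme:
    """Moss-globin rates (O2/CO association and dissociation) with distal-His
    rebinding disabled, so relaxations are exactly single-exponential."""
    return KineticScheme(
        k_h_on=0.0,
        k_h_off=2.0,
        k_prime_o2=148.0,
        k_o2_off=5.2,
        k_prime_co=0.58,
        k_co_off=0.001,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
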