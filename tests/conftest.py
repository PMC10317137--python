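import numpy as np
import pytest

from mcscale import UnitCell, generate_hkl


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def cubic_cell():
    return UnitCell(20.0, 20.0, 20.0)


@pytest.fixture
def small_miller(cubic_cell):
    """A modest reflection set (cubic 20 A cell, d_min 4 A)."""
    return generate_hkl(cubic_cell, 4.0)


def random_components(rng, n_refl, m, scale=10.0):
    """Random complex component structure factors, shape (m, n_refl)."""
    return scale * (rng.normal(size=(m, n_refl)) + 1j * rng.normal(size=(m, n_refl)))
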