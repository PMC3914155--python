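import numpy as np
import pytest

from vcsd.conductors import InfiniteHomogeneousConductor, default_cortex_profile
from vcsd.forward import assemble_leadfield
from vcsd.geometry import build_lattice_array, centered_grid


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_array():
    """2x2x2 lattice at 100 um pitch, top sites at 300 um depth."""
    return build_lattice_array((2, 2, 2), 100.0, origin=(-50.0, -50.0, 300.0))


@pytest.fixture(scope="session")
def small_grid(small_array):
    """3x3x4 grid at 50 um pitch centered on the small array (36 nodes)."""
    return centered_grid(small_array, (3, 3, 4), 50.0, offset=(25.0, 25.0, 25.0))


@pytest.fixture(scope="session")
def small_leadfield(small_array, small_grid):
    return assemble_leadfield(small_array, small_grid,
                              InfiniteHomogeneousConductor(0.3))


@pytest.fixture(scope="session")
def cortex_profile():
    return default_cortex_profile()
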