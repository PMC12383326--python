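import numpy as np
import pytest
from hypothesis import settings

import specsave as ss
from specsave import fixtures as fx
from specsave.spectral import fit_pipeline

settings.register_profile("deterministic", derandomize=True, max_examples=25)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def grid():
    return ss.DEFAULT_GRID


@pytest.fixture(scope="session")
def cmf(grid):
    return ss.load_cmf(grid=grid)


@pytest.fixture(scope="session")
def d65(grid):
    return ss.load_d65(grid=grid)


@pytest.fixture(scope="session")
def white(cmf, d65):
    return d65.white_point(cmf)


@pytest.fixture(scope="session")
def color_set(grid, cmf, d65):
    """Color-consistent 24-patch reflectance set + exact 8-bit chart colors."""
    return fx.generate_color_consistent_set(seed=3, cmf=cmf, illuminant=d65)


@pytest.fixture(scope="session")
def bundle(color_set, grid, cmf, d65):
    spectra, rgb = color_set
    return fit_pipeline(rgb, spectra, grid, cmf, d65, n_components=6)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
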