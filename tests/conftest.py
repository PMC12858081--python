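import numpy as np
import pytest

from gliotan import DomainGrid, ModelParameters, build_tissue_map


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture
def small_grid():
    return DomainGrid(21, 21)


@pytest.fixture
def tiny_grid():
    return DomainGrid(9, 9)


@pytest.fixture
def white_tissue(small_grid):
    return build_tissue_map("uniform_white", small_grid)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
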