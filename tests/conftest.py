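import numpy as np
import pytest

from cellstack3d import PSFModel, generate_cell_image


@pytest.fixture(scope="session")
def psf():
    return PSFModel()


@pytest.fixture(scope="session")
def cell_image():
    return generate_cell_image(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
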