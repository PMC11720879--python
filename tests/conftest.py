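import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_grid():
    from sparsepat.acoustics import Grid2D

    return Grid2D()


@pytest.fixture(scope="session")
def medium():
    from sparsepat.acoustics import Medium

    return Medium()


@pytest.fixture(scope="session")
def disc_phantom():
    """Centred disc absorber, a standard smooth test object."""
    r, c = np.mgrid[0:128, 0:128]
    return ((r - 64) ** 2 + (c - 64) ** 2 <= 12**2).astype(np.float64)
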