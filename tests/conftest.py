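import numpy as np
import pytest

from mpuscad.phantom import PhantomConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """One fully generated 24^3 phantom patient shared across tests."""
    cfg = PhantomConfig(grid_shape=(24, 24, 24), voxel_size_mm=2.5, seed=11,
                        n_swe_planes=6)
    return generate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
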