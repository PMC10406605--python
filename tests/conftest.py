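import numpy as np
import pytest
from hypothesis import settings

import resptemp as rt

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_world():
    """The default study conditions: 20x40 grid, 48 months, 44 towers, 0.5 ppm noise."""
    return rt.generate_world(rt.WorldConfig())


@pytest.fixture(scope="session")
def noiseless_world():
    """Same geometry with zero observation noise, for exact-recovery checks."""
    return rt.generate_world(rt.WorldConfig(noise_ppm=0.0))


@pytest.fixture(scope="session")
def clean_world():
    """Noise-free world with homogeneous baselines: exact Arrhenius everywhere."""
    return rt.generate_world(
        rt.WorldConfig(noise_ppm=0.0, re_ref_sigma=0.0, t_cell_sigma=0.0)
    )


@pytest.fixture()
def small_world():
    return rt.generate_world(rt.small_world_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
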