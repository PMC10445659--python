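import numpy as np
import pytest

from astromorph.synthetic import SceneParams, render_flatmount


@pytest.fixture(scope="session")
def small_scene():
    """A noiseless 6-cell scene rendered once and shared across tests."""
    params = SceneParams(
        shape=(4, 512, 512),
        n_cells=6,
        n_vessel_branches=3,
        noise_sigma=0.0,
        seed=3,
    )
    stack, truth = render_flatmount(params)
    return params, stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
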