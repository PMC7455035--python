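import numpy as np
import pytest

import capiflow as cf


@pytest.fixture(scope="session")
def noise_free_stack():
    """Small noise-free stack with a high stall fraction for scoring tests."""
    cfg = cf.SimulationConfig(seed=3, stall_fraction=0.3, n_vessels=20,
                              noise_model=None)
    stack, truth = cf.simulate_stack(cfg)
    return stack, truth


@pytest.fixture(scope="session")
def default_stack():
    """Stack at default SNR (photon + read noise)."""
    cfg = cf.SimulationConfig(seed=3, stall_fraction=0.3, n_vessels=20)
    stack, truth = cf.simulate_stack(cfg)
    return stack, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_tube_stack(polys_radii, shape, noise_model=None, seed=0,
                    background=20.0, lumen=80.0):
    """Rasterize analytic tubes into a constant-intensity stack."""
    vol = np.full(shape, background)
    for poly, r in polys_radii:
        vox, _ = cf.rasterize_tube(poly, r, shape)
        vol[vox[:, 0], vox[:, 1], vox[:, 2]] = lumen
    if noise_model is not None:
        vol = noise_model.apply(vol, np.random.default_rng(seed))
    return cf.AngiogramStack(data=vol, voxel_size=(1.0, 1.0, 1.0),
                             frame_interval=1.0)
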