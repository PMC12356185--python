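import pytest
from hypothesis import settings

import grasslue as gl

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def scene_cfg():
    """Small noise-free single-year scene shared across tests."""
    return gl.SceneConfig(grid_width=32, grid_height=32, years=(2020, 2020), seed=11)


@pytest.fixture(scope="session")
def pipeline(scene_cfg):
    """Reflectance, climate and uGPP cube for the shared scene."""
    refl = gl.gen_reflectance(scene_cfg)
    clim = gl.gen_climate_cube(scene_cfg, coarse_factor=4)
    cube = gl.compute_ugpp_cube(refl, clim)
    return refl, clim, cube
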