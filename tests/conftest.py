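import numpy as np
import pytest

from dda2d import (BackgroundMedium, SourceSpec, build_grid, default_config,
                   rasterize_phantom)
from dda2d import config as cfgmod

OMEGA = 2.0 * np.pi * 1.3e9


@pytest.fixture(scope="session")
def background():
    """Default lossy background: eps 21.99, sigma 1.0 S/m at 1.3 GHz."""
    return BackgroundMedium(eps_r=21.99, sigma=1.0, omega=OMEGA)


@pytest.fixture(scope="session")
def base_config():
    return default_config()


@pytest.fixture
def scene_factory(base_config):
    """Build (grid, medium, alpha) for the default phantom at a given n_side."""

    def make(n_side, extent=0.40, scheme=None):
        cfg = base_config
        if scheme is not None:
            cfg = cfg.model_copy(update={
                "polarizability": cfg.polarizability.model_copy(
                    update={"scheme": scheme})})
        grid = build_grid(n_side, extent)
        medium = rasterize_phantom(grid, cfgmod.build_phantom(cfg),
                                   cfgmod.omega(cfg))
        alpha = cfgmod.build_alpha(cfg, medium)
        return grid, medium, alpha

    return make


@pytest.fixture
def source():
    return SourceSpec(I0=1.0, omega=OMEGA, position=(0.076, 0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)
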