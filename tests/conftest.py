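import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from memfis.geometry import Grid
from memfis.params import ModelParams
from memfis.scft import scft_converge
from memfis.topology import seed_topology


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def planar_grid_coarse():
    return Grid("planar1d", (120,), (0.1,), ("no-flux",))


@pytest.fixture(scope="session")
def converged_bilayer(params, planar_grid_coarse):
    """A converged planar bilayer (canonical lipid content, coarse grid)."""
    seed = seed_topology("planar_bilayer", planar_grid_coarse,
                         params.with_mu(11.6))
    return scft_converge(seed, params, planar_grid_coarse, lipid_mass=1.35,
                         tol=1e-7, max_iter=6000, mixing=0.02, warmup=100)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240117)
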