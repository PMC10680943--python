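import numpy as np
import pytest

from heatdyn import (
    EnsembleSpec, SolenoidSpec, make_ensemble, make_solenoid_pair,
)
from heatdyn.structures import Residue, Structure


@pytest.fixture(scope="session")
def solenoid_pair():
    """Default 15-repeat compact/extended solenoid pair with its planted
    deformation vector."""
    return make_solenoid_pair(SolenoidSpec())


@pytest.fixture(scope="session")
def planted_ensemble(solenoid_pair):
    """500-frame ensemble with dominant variance 10x the orthogonal noise
    along the planted deformation direction."""
    compact, _, planted = solenoid_pair
    return make_ensemble(
        compact, planted,
        EnsembleSpec(n_frames=500, mode_amplitude=10.0, noise_amplitude=1.0,
                     seed=42))


@pytest.fixture
def path3():
    """Three collinear beads at 3.8 A spacing (path graph P3)."""
    return Structure([Residue("A", i + 1, "GLY") for i in range(3)],
                     [[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])


@pytest.fixture
def path4():
    """Four collinear beads at 3.8 A spacing (path graph P4)."""
    return Structure([Residue("A", i + 1, "GLY") for i in range(4)],
                     [[i * 3.8, 0, 0] for i in range(4)])


def make_cloud(n=20, seed=0, scale=8.0):
    """Random 3-D bead cloud (helper, not a fixture, for parametrisation)."""
    rng = np.random.default_rng(seed)
    coords = rng.normal(scale=scale, size=(n, 3))
    return Structure([Residue("A", i + 1, "GLY") for i in range(n)], coords)
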