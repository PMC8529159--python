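import numpy as np
import pytest

from ifnsig import defaults
from ifnsig.params import (CellGeometry, PStatParams, ReceptorSurface,
                           affinities_from_solution)


@pytest.fixture(scope="session")
def geom450():
    """Cell with 450 um^2 of membrane (the reference geometry)."""
    return CellGeometry.from_area(450.0)


@pytest.fixture(scope="session")
def surf2000(geom450):
    """Balanced receptor surface: 1000 copies of each subunit on 450 um^2."""
    return ReceptorSurface.from_copies(1000.0, 1000.0, geom450.area)


@pytest.fixture(scope="session")
def pstat_params():
    """ST equivalent to 0.7 nM in the reference cell; Kp = 900 copies."""
    return PStatParams(485.0, 900.0)


@pytest.fixture(scope="session")
def ligands():
    return defaults.IFN_ALPHA2, defaults.IFN_BETA


def random_affinity(rng):
    """Log-uniform valid affinity set (detailed balance built in)."""
    K1 = 10 ** rng.uniform(-8, -5)
    X = 10 ** rng.uniform(-4, 0)
    return affinities_from_solution(K1, K1 * X)


def random_surface(rng):
    return ReceptorSurface(10 ** rng.uniform(-1, 1), 10 ** rng.uniform(-1, 1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
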