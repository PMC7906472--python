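import numpy as np
import pytest

from cgmem import (CGSite, CGSystem, ContactParams, MembraneSlab,
                   make_cys_toy, make_helix_fixture)


@pytest.fixture
def membrane_helix():
    """20-residue helix straddling the membrane midplane."""
    return make_helix_fixture(20, z_offset=0.0)


@pytest.fixture
def surface_helix():
    """Helix entirely in the aqueous phase (z = 100 A)."""
    return make_helix_fixture(20, z_offset=100.0)


@pytest.fixture
def varied_helix():
    """Longer helix with a mixed sequence, spanning the slab boundary."""
    seq = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL"
    return make_helix_fixture(30, z_offset=10.0, sequence=seq)


@pytest.fixture
def random_params():
    return ContactParams.random_symmetric(np.random.default_rng(11))


@pytest.fixture
def slab():
    return MembraneSlab()


@pytest.fixture
def cys_pair():
    """Two cysteines at the 3.8 A crystallographic bond distance."""
    return make_cys_toy([(0.0, 0.0, 0.0), (3.8, 0.0, 0.0)], spacer=5)


def pair_system(distance, sep=12, restype="A"):
    """Minimal two-residue chain with CB sites `distance` apart.

    Residues are `sep` apart in sequence so any eligibility rule applies.
    """
    sites = []
    for n, x in enumerate((0.0, distance)):
        idx = 1 + n * sep
        sites.append(CGSite("A", idx, restype, "CA", (x, 1.5, 0.0)))
        sites.append(CGSite("A", idx, restype, "CB", (x, 0.0, 0.0)))
    return CGSystem(sites)


@pytest.fixture
def two_residue_factory():
    return pair_system
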