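import numpy as np
import pytest

from structkit.fixtures import (
    ScaffoldSpec,
    make_dimer,
    make_hairpin,
    make_ideal_helix,
    make_ideal_strand,
    make_random_dimer,
    make_scaffold,
)
from structkit.structio import Structure


@pytest.fixture(scope="session")
def helix12():
    return make_ideal_helix(12)


@pytest.fixture(scope="session")
def strand8():
    return make_ideal_strand(8)


@pytest.fixture(scope="session")
def hairpin():
    return make_hairpin(6)


@pytest.fixture(scope="session")
def scaffold_spec():
    return ScaffoldSpec(D=10.0, theta=90.0, loop_len=6, seed=1)


@pytest.fixture(scope="session")
def scaffold(scaffold_spec):
    return make_scaffold(scaffold_spec)


@pytest.fixture(scope="session")
def dimer3():
    return make_dimer(n_contacts=3, contact_distance=3.0, seed=11)


@pytest.fixture(scope="session")
def random_dimer():
    return make_random_dimer(30, seed=5)


@pytest.fixture(scope="session")
def fixture_structures(helix12, strand8, hairpin, scaffold, dimer3):
    """The standard structure set used for round-trip and format tests."""
    return {
        "helix12": Structure("helix12", [helix12]),
        "strand8": Structure("strand8", [strand8]),
        "hairpin": Structure("hairpin", [hairpin]),
        "scaffold": Structure("scaffold", [scaffold]),
        "dimer3": dimer3,
    }


def random_rigid_transform(rng):
    """A uniformly random proper rotation + bounded translation."""
    from scipy.spatial.transform import Rotation

    from structkit.geometry import Transform

    q = rng.normal(size=4)
    R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
    t = rng.uniform(-20.0, 20.0, size=3)
    return Transform(R, t)


def max_coord_delta(s1, s2):
    """Largest per-atom coordinate difference between two structures."""
    deltas = []
    for c1, c2 in zip(s1.chains, s2.chains):
        for r1, r2 in zip(c1.residues, c2.residues):
            for a1, a2 in zip(r1.atoms, r2.atoms):
                deltas.append(float(np.linalg.norm(a1.coords - a2.coords)))
    return max(deltas)


def same_hierarchy(s1, s2):
    if [c.chain_id for c in s1.chains] != [c.chain_id for c in s2.chains]:
        return False
    for c1, c2 in zip(s1.chains, s2.chains):
        if [(r.id, r.res_name) for r in c1.residues] != [(r.id, r.res_name) for r in c2.residues]:
            return False
        for r1, r2 in zip(c1.residues, c2.residues):
            if [a.name for a in r1.atoms] != [a.name for a in r2.atoms]:
                return False
    return True
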