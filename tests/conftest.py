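import numpy as np
import pytest

from shellkit import icosa_lattice as il
from shellkit import synthetic_shells as ss


@pytest.fixture(scope="session")
def operators():
    return il.generate_point_group_operators("I")


@pytest.fixture(scope="session")
def lattice(operators):
    return il.build_subunit_lattice(operators)


@pytest.fixture(scope="session")
def default_spec():
    return ss.SyntheticSpec(seed=11)


@pytest.fixture(scope="session")
def reference_shell(lattice, default_spec):
    return ss.make_reference_shell(lattice, default_spec)


@pytest.fixture(scope="session")
def reference_subunit(lattice, default_spec):
    return ss.make_reference_subunit(lattice, default_spec)


def occupancy_oracle(lattice, present_sites):
    """Independent brute-force recount over all 62 groups.

    Walks every group of every class explicitly and accumulates the
    subunit-count histogram; shares nothing with the production tabulation
    beyond the lattice partition itself.
    """
    present = set(int(s) for s in present_sites)
    out = {}
    for name, table, n_groups in (
        ("dimer", lattice.dimer_of, 30),
        ("trimer", lattice.trimer_of, 20),
        ("pentamer", lattice.pentamer_of, 12),
    ):
        hist = {}
        for g in range(n_groups):
            members = [s for s in range(60) if table[s] == g]
            k = sum(1 for s in members if s in present)
            if k:
                hist[k] = hist.get(k, 0) + k
        out[name] = hist
    return out


@pytest.fixture(scope="session")
def oracle():
    return occupancy_oracle


def random_rotation(rng):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return il.rotation_about(axis, rng.uniform(0, 2 * np.pi))
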