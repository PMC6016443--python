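import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from memint.molecular_model import Atom, Frame, MoleculeKind, Topology
from memint.synthetic_systems import (
    BilayerSpec,
    build_system,
    write_default_chemistry_table,
)


@pytest.fixture(scope="session")
def default_system():
    """The standard 90 PE + 38 PG bilayer with 4 amide chains."""
    return build_system(BilayerSpec(seed=11))


@pytest.fixture(scope="session")
def small_spec():
    """A reduced bilayer for brute-force-oracle comparisons."""
    return BilayerSpec(n_pope=12, n_popg=6, polymer_chains=2, seed=5)


@pytest.fixture(scope="session")
def chemistry_csv(tmp_path_factory):
    path = tmp_path_factory.mktemp("chem") / "chemistry.csv"
    write_default_chemistry_table(path)
    return path


def make_point_topology(n, charge=0.0, epsilon=0.1, rmin_half=2.0):
    """n independent featureless particles (for RDF / density tests)."""
    return Topology(
        [
            Atom(i, "X", "X", i, MoleculeKind.OTHER, -1, None, charge, epsilon,
                 rmin_half, False, False)
            for i in range(n)
        ]
    )


def make_pair(q1, q2, eps1, eps2, rmin1, rmin2, separation, box=100.0):
    """Two-atom system at a given separation along x."""
    top = Topology(
        [
            Atom(0, "A", "A", 0, MoleculeKind.OTHER, -1, None, q1, eps1, rmin1,
                 False, False),
            Atom(1, "B", "B", 1, MoleculeKind.OTHER, -1, None, q2, eps2, rmin2,
                 False, False),
        ]
    )
    frame = Frame(
        np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]]), [box] * 3
    )
    return top, frame
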