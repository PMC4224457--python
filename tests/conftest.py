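"""Shared fixtures: packaged fingerprint targets, a 12-nt helix map, and the
default conformer database.  Everything is generated in memory; nothing is
downloaded."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from natrace import AtomRecord, Placement, density_from_atoms
from natrace.fingerprint import load_default_targets
from natrace.synthetic import HelixSpec, default_database, helix_map


@pytest.fixture(scope="session")
def targets():
    return load_default_targets()


@pytest.fixture(scope="session")
def sugar_target(targets):
    return targets["sugar"]


@pytest.fixture(scope="session")
def phosphate_target(targets):
    return targets["phosphate"]


@pytest.fixture(scope="session")
def helix12():
    """(grid, fragments, axis centre) for a clean 12-nt helix at 0.5 A."""
    return helix_map(HelixSpec(n_nt=12))


@pytest.fixture(scope="session")
def db():
    return default_database()


@pytest.fixture(scope="session")
def single_sugar_case(sugar_target):
    """A map containing one nucleotide at a known placement."""
    rot = Rotation.from_euler("zyz", [40, 55, 10], degrees=True).as_matrix()
    trans = np.array([10.2, 9.7, 10.4])
    pl = Placement(rotation=rot, translation=trans)
    atoms = [
        AtomRecord(name=k, element="P" if k == "P" else k[0], pos=pl.transform(v))
        for k, v in sugar_target.frame_atoms.items()
    ]
    grid = density_from_atoms(atoms, cell=(20.0, 20.0, 20.0), spacing=0.5)
    return grid, pl
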