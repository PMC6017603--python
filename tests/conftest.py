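import numpy as np
import pytest

from ensemblebind.io_formats import Atom, Structure, Trajectory
from ensemblebind.synthetic import helical_backbone, make_ligand


@pytest.fixture
def helix12() -> Structure:
    return helical_backbone(12)


@pytest.fixture
def ligand() -> Structure:
    return make_ligand()


@pytest.fixture
def peptide5() -> Structure:
    """A 5-residue backbone-only peptide with mixed residue names."""
    return helical_backbone(5, sequence=["ALA", "LEU", "SER", "PHE", "GLY"])


@pytest.fixture
def static_traj(helix12) -> Trajectory:
    """Three identical frames."""
    xyz = np.repeat(helix12.coords()[None], 3, axis=0)
    return Trajectory(topology=helix12, xyz=xyz, timestep_ps=10.0)


def make_atom(serial, name, element, resid, resname="ALA", chain="A", xyz=(0, 0, 0), hetero=False):
    return Atom(serial, name, element, resid, resname, chain, tuple(map(float, xyz)), hetero=hetero)


@pytest.fixture
def atom_factory():
    return make_atom
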