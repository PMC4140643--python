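"""Shared fixtures: a standard toy homodimer and its topologies."""

import numpy as np
import pytest

import bindscape as bs


@pytest.fixture(scope="session")
def toy():
    """Standard 2x20-bead toy homodimer with rho = 0.15."""
    return bs.make_toy_homodimer(
        bs.ToySpec(n_residues=20, n_inter=6, rho=0.15, seed=1))


@pytest.fixture(scope="session")
def toy_structure(toy):
    return toy.structure


@pytest.fixture(scope="session")
def toy_cmap(toy):
    return toy.cmap


@pytest.fixture(scope="session")
def top_flexible(toy):
    return bs.build_topology(toy.structure, toy.cmap, mode="flexible",
                             restraint=bs.Restraint())


@pytest.fixture(scope="session")
def top_rigid(toy):
    return bs.build_topology(toy.structure, toy.cmap, mode="rigid_chains",
                             restraint=bs.Restraint())


@pytest.fixture(scope="session")
def bond_dimer():
    """Two-bead single chain: a pure harmonic-bond test system."""
    chain = bs.Chain("A", np.array([1, 2]),
                     np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]]))
    structure = bs.DimerStructure(chains=(chain,))
    cmap = bs.build_contact_map(structure)
    return bs.build_topology(structure, cmap, mode="flexible")


TOY_PDB = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   3       3.800   3.800   0.000  1.00  0.00           C
TER
ATOM      4  CA  GLY B   1       0.000   0.000   6.000  1.00  0.00           C
ATOM      5  CA  GLY B   2       3.800   0.000   6.000  1.00  0.00           C
ATOM      6  CA  GLY B   3       3.800   3.800   6.000  1.00  0.00           C
TER
END
"""


@pytest.fixture
def toy_pdb_text():
    return TOY_PDB
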