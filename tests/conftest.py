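import textwrap

import numpy as np
import pytest

from bioxtal import FixtureSpec, generate_interface_fixture

TOY_PDB = textwrap.dedent(
    """\
    ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
    ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
    ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
    ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
    ATOM      5  N   SER A   2       0.000   3.800   0.000  1.00  0.00           N
    ATOM      6  CA  SER A   2       1.458   3.800   0.000  1.00  0.00           C
    ATOM      7  OG  SER A   2       2.100   4.500   1.100  1.00  0.00           O
    ATOM      8  N   LYS A   3       0.000   7.600   0.000  1.00  0.00           N
    ATOM      9  CA  LYS A   3       1.458   7.600   0.000  1.00  0.00           C
    TER      10      LYS A   3
    ATOM     11  N   GLY B   1       4.500   0.000   0.000  1.00  0.00           N
    ATOM     12  CA  GLY B   1       5.958   0.000   0.000  1.00  0.00           C
    ATOM     13  N   THR B   2       4.500   3.800   0.000  1.00  0.00           N
    ATOM     14  CA  THR B   2       5.958   3.800   0.000  1.00  0.00           C
    ATOM     15  N   GLU B   3       4.500   7.600   0.000  1.00  0.00           N
    ATOM     16  CA  GLU B   3       5.958   7.600   0.000  1.00  0.00           C
    TER      17      GLU B   3
    END
    """
)


@pytest.fixture
def toy_pdb(tmp_path):
    """Two-chain toy complex: chains A and B, three residues each."""
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


@pytest.fixture
def lattice_pair():
    """Deterministic 8x8 grid fixture with closed-form expected contacts."""
    return generate_interface_fixture(
        FixtureSpec(n_res_per_chain=8, inter_chain_gap=4.5, seed=11)
    )


def two_atom_residue_pair(distance):
    """Minimal InterfacePair: two single-atom residues a given distance apart."""
    from bioxtal import Atom, InterfacePair, Residue, Structure

    res_a = Residue("ALA", "A", "1", [Atom("CA", "C", np.array([0.0, 0.0, 0.0]))])
    res_b = Residue("GLY", "B", "1", [Atom("CA", "C", np.array([distance, 0.0, 0.0]))])
    structure = Structure(chains={"A": [res_a], "B": [res_b]})
    return InterfacePair(frozenset("A"), frozenset("B"), structure)
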