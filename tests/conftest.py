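import numpy as np
import pytest

from haloadapt.structure_io import AtomRecord, Residue, Structure, annotate


def single_atom_residue(name3: str, seq: int, chain: str, xyz,
                        atom_name: str = "CB", element: str = "C") -> Residue:
    return Residue(name=name3, seq=seq, chain_id=chain,
                   atoms=[AtomRecord(serial=seq, name=atom_name, element=element,
                                     coords=np.asarray(xyz, dtype=float))])


def carbon_structure(positions, chain: str = "A", start_seq: int = 1) -> Structure:
    """One single-carbon ALA residue per position; annotated."""
    residues = [single_atom_residue("ALA", start_seq + i, chain, p)
                for i, p in enumerate(positions)]
    return annotate(Structure(id="carbons", chains=[(chain, residues)]))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


TOY_PDB = """\
ATOM      1  N   ALA A   1      -1.460   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       0.730   1.330   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       0.600   2.560   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       0.000   0.000   1.530  1.00  0.00           C
ATOM      6  N   GLY A   2      -1.460   3.800   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   2       0.000   3.800   0.000  1.00  0.00           C
ATOM      8  C   GLY A   2       0.730   5.130   0.000  1.00  0.00           C
ATOM      9  O   GLY A   2       0.600   6.360   0.000  1.00  0.00           O
TER      10
END
"""
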