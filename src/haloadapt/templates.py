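"""Idealized heavy-atom residue templates.

Each template places a residue in a local frame: CA at the origin, backbone
in the z=0 plane, side chain growing along +z.  Aromatic rings (Phe/Tyr/His,
the six-membered ring of Trp) and the Arg guanidinium group lie in the x=0
plane, so their plane normal is the local x axis — convenient for planting
stacking geometries.  Bond lengths are approximately physical (1.5 Å C–C
steps, 1.39 Å aromatic bonds) but torsions are not: these templates exist to
satisfy distance/angle criteria of contact detectors and area computations,
not to be energetically plausible.
"""

from __future__ import annotations

import numpy as np

from haloadapt.structure_io import AtomRecord, Residue, Structure

_BACKBONE = [
    ("N", "N", (-1.46, 0.00, 0.00)),
    ("CA", "C", (0.00, 0.00, 0.00)),
    ("C", "C", (0.73, 1.33, 0.00)),
    ("O", "O", (0.60, 2.56, 0.00)),
]

# hexagon of radius 1.39 in the x=0 plane, attached to CB at (0,0,1.53);
# ring center at (0, 0, 4.31)
_RING6 = {
    "CG": (0.00, 0.00, 2.92),
    "CD1": (0.00, 1.20, 3.61),
    "CE1": (0.00, 1.20, 5.00),
    "CZ": (0.00, 0.00, 5.70),
    "CE2": (0.00, -1.20, 5.00),
    "CD2": (0.00, -1.20, 3.61),
}

_SIDE_CHAINS: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "GLY": [],
    "ALA": [("CB", "C", (0.00, 0.00, 1.53))],
    "VAL": [("CB", "C", (0.00, 0.00, 1.53)),
            ("CG1", "C", (0.00, 1.26, 2.40)),
            ("CG2", "C", (0.00, -1.26, 2.40))],
    "LEU": [("CB", "C", (0.00, 0.00, 1.53)),
            ("CG", "C", (0.00, 0.00, 3.06)),
            ("CD1", "C", (0.00, 1.26, 3.93)),
            ("CD2", "C", (0.00, -1.26, 3.93))],
    "ILE": [("CB", "C", (0.00, 0.00, 1.53)),
            ("CG1", "C", (0.00, 1.26, 2.40)),
            ("CG2", "C", (0.00, -1.26, 2.40)),
            ("CD1", "C", (0.00, 1.26, 3.93))],
    "PRO": [("CB", "C", (0.00, 0.00, 1.53)),
            ("CG", "C", (-0.80, 0.80, 2.30)),
            ("CD", "C", (-1.60, 0.40, 1.20))],
    "SER": [("CB", "C", (0.00, 0.00, 1.53)),
            ("OG", "O", (0.00, 0.00, 2.92))],
    "THR": [("CB", "C", (0.00, 0.00, 1.53)),
            ("OG1", "O", (0.00, 1.10, 2.30)),
            ("CG2", "C", (0.00, -1.20, 2.35))],
    "CYS": [("CB", "C", (0.00, 0.00, 1.53)),
            ("SG", "S", (0.00, 0.00, 3.34))],
    "MET": [("CB", "C", (0.00, 0.00, 1.53)),
            ("CG", "C", (0.00, 0.00, 3.06)),
            ("SD", "S", (0.00, 0.00, 4.40)),
            ("CE", "C", (0.00, 1.20, 5.40))],
    "ASN": [("CB", "C", (0.00, 0.00, 1.53)),
            ("CG", "C", (0.00, 0.00, 3.06)),
            ("OD1", "O", (0.00, 1.10, 3.70)),
            ("ND2", "N", (0.00, -1.15, 3.70))],
    "GLN": [("CB", "C", (0.00, 0.00, 1.53)),
            ("CG", "C", (0.00, 0.00, 3.06)),
            ("CD", "C", (0.00, 0.00, 4.59)),
            ("OE1", "O", (0.00, 1.10, 5.23)),
            ("NE2", "N", (0.00, -1.15, 5.23))],
    "ASP": [("CB", "C", (0.00, 0.00, 1.53)),
            ("CG", "C", (0.00, 0.00, 3.06)),
            ("OD1", "O", (0.00, 1.10, 3.70)),
            ("OD2", "O", (0.00, -1.10, 3.70))],
    "GLU": [("CB", "C", (0.00, 0.00, 1.53)),
            ("CG", "C", (0.00, 0.00, 3.06)),
            ("CD", "C", (0.00, 0.00, 4.59)),
            ("OE1", "O", (0.00, 1.10, 5.23)),
            ("OE2", "O", (0.00, -1.10, 5.23))],
    "LYS": [("CB", "C", (0.00, 0.00, 1.53)),
            ("CG", "C", (0.00, 0.00, 3.06)),
            ("CD", "C", (0.00, 0.00, 4.59)),
            ("CE", "C", (0.00, 0.00, 6.12)),
            ("NZ", "N", (0.00, 0.00, 7.65))],
    "ARG": [("CB", "C", (0.00, 0.00, 1.53)),
            ("CG", "C", (0.00, 0.00, 3.06)),
            ("CD", "C", (0.00, 0.00, 4.40)),
            ("NE", "N", (0.00, 0.00, 5.70)),
            ("CZ", "C", (0.00, 0.00, 7.00)),
            ("NH1", "N", (0.00, 1.15, 7.65)),
            ("NH2", "N", (0.00, -1.15, 7.65))],
    "PHE": [("CB", "C", (0.00, 0.00, 1.53))]
           + [(n, "C", c) for n, c in _RING6.items()],
    "TYR": [("CB", "C", (0.00, 0.00, 1.53))]
           + [(n, "C", c) for n, c in _RING6.items()]
           + [("OH", "O", (0.00, 0.00, 7.10))],
    # six-membered ring in the x=0 plane centered at (0, 0, 4.90); the
    # five-membered ring is an approximate stub sharing the CD2-CE2 edge
    "TRP": [("CB", "C", (0.00, 0.00, 1.53)),
            ("CG", "C", (0.00, 1.45, 2.50)),
            ("CD1", "C", (0.00, 2.70, 3.10)),
            ("NE1", "N", (0.00, 2.55, 4.45)),
            ("CD2", "C", (0.00, 0.00, 3.51)),
            ("CE2", "C", (0.00, 1.20, 4.21)),
            ("CZ2", "C", (0.00, 1.20, 5.60)),
            ("CH2", "C", (0.00, 0.00, 6.29)),
            ("CZ3", "C", (0.00, -1.20, 5.60)),
            ("CE3", "C", (0.00, -1.20, 4.21))],
    # regular pentagon of radius 1.16 in the x=0 plane centered at (0,0,3.6)
    "HIS": [("CB", "C", (0.00, 0.00, 1.53)),
            ("CG", "C", (0.00, 0.00, 2.44)),
            ("ND1", "N", (0.00, 1.10, 3.24)),
            ("CE1", "C", (0.00, 0.68, 4.54)),
            ("NE2", "N", (0.00, -0.68, 4.54)),
            ("CD2", "C", (0.00, -1.10, 3.24))],
}


def residue_template(name3: str) -> list[tuple[str, str, np.ndarray]]:
    """(atom_name, element, local_coords) list for a 3-letter residue code."""
    if name3 not in _SIDE_CHAINS:
        raise KeyError(f"no template for residue {name3!r}")
    out = []
    for aname, elem, xyz in _BACKBONE + _SIDE_CHAINS[name3]:
        out.append((aname, elem, np.asarray(xyz, dtype=float)))
    return out


def rotation_about(axis: str, degrees: float) -> np.ndarray:
    """Right-handed rotation matrix about a named axis ('x'|'y'|'z')."""
    t = np.radians(degrees)
    c, s = np.cos(t), np.sin(t)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)
    raise ValueError(f"unknown axis {axis!r}")


def make_residue(name3: str, seq: int, chain_id: str,
                 origin: np.ndarray,
                 rotation: np.ndarray | None = None) -> Residue:
    """Instantiate a template residue at `origin`, optionally rotated."""
    origin = np.asarray(origin, dtype=float)
    atoms = []
    for aname, elem, local in residue_template(name3):
        xyz = local if rotation is None else rotation @ local
        atoms.append(AtomRecord(serial=0, name=aname, element=elem,
                                coords=origin + xyz))
    return Residue(name=name3, seq=seq, chain_id=chain_id, atoms=atoms)


def build_peptide(sequence: str, chain_id: str = "A",
                  ca_spacing: float = 3.8,
                  structure_id: str = "peptide") -> Structure:
    """Straight-chain peptide: consecutive residues spaced along y.

    Used for reference-area computation (e.g. Gly-X-Gly tripeptides) and as a
    minimal multi-residue fixture.  Geometry is extended and non-physical.
    """
    from haloadapt.structure_io import ONE_TO_THREE
    residues = []
    for i, letter in enumerate(sequence):
        name3 = ONE_TO_THREE.get(letter)
        if name3 is None:
            raise KeyError(f"no template for residue letter {letter!r}")
        origin = np.array([0.0, i * ca_spacing, 0.0])
        residues.append(make_residue(name3, i + 1, chain_id, origin))
    return Structure(id=structure_id, chains=[(chain_id, residues)])
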