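"""PDB structure input/output and atom annotation.

Structures are read into a small chain → residue → atom hierarchy carrying
only what the downstream geometry needs: heavy-atom coordinates, van der
Waals radii and a binary hydrophobicity class per atom.  Parsing is delegated
to :mod:`gemmi`; on top of it we resolve alternate locations (highest
occupancy wins, ties broken by record order), drop hydrogens, keep only the
first MODEL and flag hetero groups (hemes, waters) as non-protein so that
composition statistics run over amino-acid residues only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import gemmi
import numpy as np

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: main-chain atom names; everything else on a standard residue is side chain
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


class PDBParseError(ValueError):
    """Raised when PDB content cannot be parsed into a structure."""


@dataclass
class ClassScheme:
    """Residue/atom classification used throughout the analysis.

    ``hydrophobic_residues`` drives the surface-composition bucket and the
    hydrophobic-contact detector; ``atom_rule`` assigns the binary
    hydrophobicity class used for interface decomposition and core detection
    (carbon and sulfur apolar, nitrogen and oxygen polar); ``radii_table``
    holds Bondi-style van der Waals radii in Å.
    """

    hydrophobic_residues: frozenset[str] = frozenset("AVLIMFWP")
    negative: frozenset[str] = frozenset("DE")
    positive: frozenset[str] = frozenset("KRH")
    aromatic: frozenset[str] = frozenset("FWYH")
    atom_rule: dict[str, str] = field(default_factory=lambda: {
        "C": "hydrophobic", "S": "hydrophobic",
        "N": "hydrophilic", "O": "hydrophilic",
        "other": "hydrophilic",
    })
    radii_table: dict[str, float] = field(default_factory=lambda: {
        "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "other": 1.80,
    })

    def radius(self, element: str) -> float:
        try:
            return self.radii_table.get(element, self.radii_table["other"])
        except KeyError:
            raise KeyError(f"element {element!r} not in radii table and no 'other' default")

    def atom_class(self, element: str) -> str:
        try:
            return self.atom_rule.get(element, self.atom_rule["other"])
        except KeyError:
            raise KeyError(f"element {element!r} not in atom rule and no 'other' default")


DEFAULT_SCHEME = ClassScheme()


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    radius: float | None = None
    hydro_class: str | None = None

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS


@dataclass
class Residue:
    name: str          # 3-letter code (or het code)
    seq: int           # author numbering
    chain_id: str
    atoms: list[AtomRecord]
    is_hetero: bool = False

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def side_chain_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.name not in BACKBONE_ATOMS]

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.chain_id, self.name, self.seq)


@dataclass
class Structure:
    id: str
    chains: list[tuple[str, list[Residue]]]

    def chain_ids(self) -> list[str]:
        return [cid for cid, _ in self.chains]

    def chain(self, chain_id: str) -> list[Residue]:
        for cid, residues in self.chains:
            if cid == chain_id:
                return residues
        raise KeyError(f"chain {chain_id!r} not in structure {self.id!r}")

    def residues(self, include_hetero: bool = False,
                 chain_ids: set[str] | None = None) -> Iterator[Residue]:
        for cid, residues in self.chains:
            if chain_ids is not None and cid not in chain_ids:
                continue
            for res in residues:
                if res.is_hetero and not include_hetero:
                    continue
                yield res

    def atoms(self, include_hetero: bool = False,
              chain_ids: set[str] | None = None) -> Iterator[tuple[Residue, AtomRecord]]:
        for res in self.residues(include_hetero, chain_ids):
            for atom in res.atoms:
                yield res, atom

    def n_atoms(self, include_hetero: bool = False) -> int:
        return sum(1 for _ in self.atoms(include_hetero))


@dataclass
class AtomTable:
    """Flat numpy view over a (sub)structure, aligned index-wise."""

    coords: np.ndarray           # (n, 3)
    radii: np.ndarray            # (n,)
    hydrophobic: np.ndarray      # (n,) bool
    residue_index: np.ndarray    # (n,) int, index into `residue_keys`
    residue_keys: list[tuple[str, str, int]]
    atom_names: list[str]

    def __len__(self) -> int:
        return len(self.radii)


def flatten(s: Structure, include_hetero: bool = False,
            chain_ids: set[str] | None = None) -> AtomTable:
    """Flatten the hierarchy into aligned numpy arrays for geometry kernels."""
    coords, radii, hydro, res_idx, keys, names = [], [], [], [], [], []
    key_to_idx: dict[tuple[str, str, int], int] = {}
    for res, atom in s.atoms(include_hetero, chain_ids):
        if atom.radius is None or atom.hydro_class is None:
            raise ValueError(
                f"atom {atom.name} of {res.key} is not annotated; call annotate() first")
        if res.key not in key_to_idx:
            key_to_idx[res.key] = len(keys)
            keys.append(res.key)
        coords.append(atom.coords)
        radii.append(atom.radius)
        hydro.append(atom.hydro_class == "hydrophobic")
        res_idx.append(key_to_idx[res.key])
        names.append(atom.name)
    if not coords:
        raise ValueError("no atoms selected")
    return AtomTable(
        coords=np.asarray(coords, dtype=float),
        radii=np.asarray(radii, dtype=float),
        hydrophobic=np.asarray(hydro, dtype=bool),
        residue_index=np.asarray(res_idx, dtype=int),
        residue_keys=keys,
        atom_names=names,
    )


def _select_altloc(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per atom name: highest occupancy, ties by record order."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    # preserve record order of the retained atoms
    retained = set(id(a) for a in best.values())
    return [a for a in res if id(a) in retained]


def parse_pdb(text: str, structure_id: str = "structure") -> Structure:
    """Parse PDB-format content into a heavy-atom :class:`Structure`.

    Only the first MODEL is kept; hydrogens (and deuterium) are dropped;
    alternate locations are resolved to the highest-occupancy conformer;
    HETATM groups are retained but flagged ``is_hetero``.
    """
    try:
        gst = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"malformed PDB content: {exc}") from exc
    if len(gst) == 0:
        raise PDBParseError("no MODEL found in PDB content")
    model = gst[0]
    chains: list[tuple[str, list[Residue]]] = []
    serial = 0
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            is_het = gres.het_flag == "H" or gres.name not in THREE_TO_ONE
            atoms: list[AtomRecord] = []
            for gatom in _select_altloc(gres):
                element = gatom.element.name.upper()
                if element in ("H", "D"):
                    continue
                serial += 1
                pos = gatom.pos
                coords = np.array([pos.x, pos.y, pos.z], dtype=float)
                if not np.all(np.isfinite(coords)):
                    raise PDBParseError(
                        f"non-finite coordinates for atom {gatom.name} "
                        f"in {gchain.name}/{gres.name}{gres.seqid.num}")
                atoms.append(AtomRecord(serial=serial, name=gatom.name,
                                        element=element, coords=coords))
            if atoms:
                residues.append(Residue(name=gres.name, seq=gres.seqid.num,
                                        chain_id=gchain.name, atoms=atoms,
                                        is_hetero=is_het))
        if residues:
            chains.append((gchain.name, residues))
    if not chains:
        raise PDBParseError("empty structure: no heavy atoms parsed")
    return Structure(id=structure_id, chains=chains)


def write_pdb(s: Structure, include_hetero: bool = True) -> str:
    """Serialize to PDB format (ATOM/HETATM/TER/END, wwPDB v3.3 columns)."""
    lines: list[str] = []
    serial = 0
    for cid, residues in s.chains:
        wrote_protein = False
        for res in residues:
            if res.is_hetero and not include_hetero:
                continue
            record = "HETATM" if res.is_hetero else "ATOM  "
            if not res.is_hetero:
                wrote_protein = True
            for atom in res.atoms:
                serial += 1
                name = atom.name
                # column 13-16 alignment: 1/2-char element names start col 14
                if len(name) < 4 and len(atom.element) == 1:
                    name = " " + name
                x, y, z = atom.coords
                lines.append(
                    f"{record}{serial:5d} {name:<4s} {res.name:<3s} {cid:>1s}"
                    f"{res.seq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}")
        if wrote_protein:
            serial += 1
            lines.append(f"TER   {serial:5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def extract_sequence(s: Structure, chain_id: str) -> str:
    """One-letter sequence of a chain; non-standard residues become 'X';
    hetero groups (hemes, waters) are excluded."""
    residues = s.chain(chain_id)
    return "".join(r.one_letter for r in residues if not r.is_hetero)


def annotate(s: Structure, scheme: ClassScheme = DEFAULT_SCHEME) -> Structure:
    """Assign van der Waals radius and hydrophobicity class to every atom.

    In-place and idempotent; returns the structure for chaining.
    """
    for _cid, residues in s.chains:
        for res in residues:
            for atom in res.atoms:
                atom.radius = scheme.radius(atom.element)
                atom.hydro_class = scheme.atom_class(atom.element)
    return s
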