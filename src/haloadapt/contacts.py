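"""Non-covalent contact detection between residues.

Detectors for the six interaction kinds that discriminate habitat-adapted
oligomers: hydrophobic contacts (apolar side chains closer than 5 Å),
heavy-atom hydrogen bonds, salt bridges, parallel and T-shaped aromatic
stacking (including the aromatic-arginine T geometry through the guanidinium
plane), and sulfur-aromatic interactions.  Each contact is reported once per
residue pair and kind, with the minimal qualifying distance; partner order
is canonicalized lexicographically.

Geometric criteria operate on heavy atoms only (crystal structures and
homology models rarely carry hydrogens), so the hydrogen-bond rule is a
distance-only criterion — coarser than donor-hydrogen-acceptor angle tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from haloadapt.structure_io import (
    BACKBONE_ATOMS,
    DEFAULT_SCHEME,
    ClassScheme,
    Residue,
    Structure,
)

KINDS = ("hydrophobic", "hbond", "salt_bridge", "stack_parallel", "stack_T", "s_aromatic")

HYDROPHOBIC_CUTOFF = 5.0
HBOND_MAX = 3.5
SALT_BRIDGE_MAX = 4.0
STACK_PARALLEL_MAX = 5.5
STACK_PARALLEL_ANGLE = 30.0
STACK_T_MAX = 7.0
STACK_T_ANGLE = (60.0, 90.0)
S_AROMATIC_MAX = 6.0

RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),  # six-membered ring
    "HIS": ("CG", "ND1", "CE1", "NE2", "CD2"),
}
GUANIDINIUM_ATOMS = ("NE", "CZ", "NH1", "NH2")

ACIDIC_SC_O = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_SC_N = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2")}

ResidueId = tuple[str, str, int]  # (chain_id, residue_name, residue_seq)


@dataclass(frozen=True)
class Contact:
    kind: str
    partner_1: ResidueId
    partner_2: ResidueId
    distance: float
    angle: float | None = None
    scope: str = "intra_chain"


def _scope_of(r1: ResidueId, r2: ResidueId) -> str:
    return "intra_chain" if r1[0] == r2[0] else "inter_chain"


def _make_contact(kind: str, r1: ResidueId, r2: ResidueId,
                  distance: float, angle: float | None = None) -> Contact:
    a, b = sorted((r1, r2))
    return Contact(kind=kind, partner_1=a, partner_2=b,
                   distance=float(distance), angle=angle, scope=_scope_of(a, b))


def _filter_scope(contacts: list[Contact], scope: str | None) -> list[Contact]:
    if scope in (None, "all"):
        return sorted(contacts, key=lambda c: (c.kind, c.partner_1, c.partner_2))
    return sorted((c for c in contacts if c.scope == scope),
                  key=lambda c: (c.kind, c.partner_1, c.partner_2))


def _residue_list(s: Structure) -> list[Residue]:
    return list(s.residues(include_hetero=False))


def _min_pair_distances(atoms_by_res: list[np.ndarray], cutoff: float) -> dict[tuple[int, int], float]:
    """Minimal inter-atom distance per residue pair, among pairs whose atoms
    come within `cutoff`; KD-tree accelerated."""
    if not atoms_by_res:
        return {}
    coords = np.vstack(atoms_by_res)
    owner = np.concatenate([np.full(len(a), i) for i, a in enumerate(atoms_by_res)])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    best: dict[tuple[int, int], float] = {}
    for i, j in pairs:
        ri, rj = int(owner[i]), int(owner[j])
        if ri == rj:
            continue
        key = (min(ri, rj), max(ri, rj))
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d < best.get(key, np.inf):
            best[key] = d
    return best


def hydrophobic_contacts(s: Structure, scheme: ClassScheme = DEFAULT_SCHEME,
                         cutoff: float = HYDROPHOBIC_CUTOFF,
                         scope: str | None = None) -> list[Contact]:
    """Residue pairs of the hydrophobic set whose side chains approach below
    `cutoff` (strict) between heavy atoms."""
    residues = [r for r in _residue_list(s)
                if r.one_letter in scheme.hydrophobic_residues]
    arrays, kept = [], []
    for r in residues:
        sc = r.side_chain_atoms()
        if sc:
            arrays.append(np.array([a.coords for a in sc]))
            kept.append(r)
    out = []
    for (i, j), d in _min_pair_distances(arrays, cutoff).items():
        if d < cutoff:
            out.append(_make_contact("hydrophobic", kept[i].key, kept[j].key, d))
    return _filter_scope(out, scope)


def hydrogen_bonds(s: Structure, d_max: float = HBOND_MAX,
                   scope: str | None = None) -> list[Contact]:
    """Heavy-atom N/O···N/O pairs from different residues within `d_max`.

    Backbone-backbone pairs of sequence-adjacent residues (the covalent
    peptide neighbourhood) are excluded.  One contact per residue pair, at
    the minimal qualifying distance.
    """
    entries = []  # (coords, residue_index, is_backbone)
    residues = _residue_list(s)
    coords, owner, backbone = [], [], []
    for idx, r in enumerate(residues):
        for a in r.atoms:
            if a.element in ("N", "O"):
                coords.append(a.coords)
                owner.append(idx)
                backbone.append(a.is_backbone)
    if not coords:
        return []
    coords = np.asarray(coords)
    owner = np.asarray(owner)
    backbone = np.asarray(backbone)
    tree = cKDTree(coords)
    best: dict[tuple[int, int], float] = {}
    for i, j in tree.query_pairs(d_max, output_type="ndarray"):
        ri, rj = int(owner[i]), int(owner[j])
        if ri == rj:
            continue
        r1, r2 = residues[ri], residues[rj]
        adjacent = (r1.chain_id == r2.chain_id and abs(r1.seq - r2.seq) == 1)
        if adjacent and backbone[i] and backbone[j]:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        key = (min(ri, rj), max(ri, rj))
        if d < best.get(key, np.inf):
            best[key] = d
    out = [_make_contact("hbond", residues[i].key, residues[j].key, d)
           for (i, j), d in best.items()]
    return _filter_scope(out, scope)


def salt_bridges(s: Structure, d_max: float = SALT_BRIDGE_MAX,
                 scope: str | None = None) -> list[Contact]:
    """Acidic side-chain oxygen to basic side-chain nitrogen within `d_max`."""
    residues = _residue_list(s)
    acids, bases = [], []
    for idx, r in enumerate(residues):
        if r.name in ACIDIC_SC_O:
            pts = [a.coords for n in ACIDIC_SC_O[r.name] if (a := r.atom(n))]
            if pts:
                acids.append((idx, np.asarray(pts)))
        if r.name in BASIC_SC_N:
            pts = [a.coords for n in BASIC_SC_N[r.name] if (a := r.atom(n))]
            if pts:
                bases.append((idx, np.asarray(pts)))
    out = []
    for ia, pa in acids:
        for ib, pb in bases:
            diff = pa[:, None, :] - pb[None, :, :]
            d = float(np.sqrt((diff ** 2).sum(axis=2).min()))
            if d <= d_max:
                out.append(_make_contact("salt_bridge", residues[ia].key,
                                         residues[ib].key, d))
    return _filter_scope(out, scope)


def _plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of a near-planar atom group (via SVD)."""
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid)
    return centroid, vt[2]


def _ring_groups(s: Structure, include_guanidinium: bool) -> list[tuple[ResidueId, str, np.ndarray, np.ndarray]]:
    """(residue key, group kind, centroid, normal) for aromatic rings and,
    optionally, arginine guanidinium planes.  Incomplete rings are skipped
    with a warning."""
    groups = []
    for r in _residue_list(s):
        specs = []
        if r.name in RING_ATOMS:
            specs.append(("aromatic", RING_ATOMS[r.name]))
        if include_guanidinium and r.name == "ARG":
            specs.append(("guanidinium", GUANIDINIUM_ATOMS))
        for kind, names in specs:
            atoms = [r.atom(n) for n in names]
            if any(a is None for a in atoms):
                warnings.warn(f"incomplete {kind} group in {r.key}; skipped")
                continue
            centroid, normal = _plane(np.array([a.coords for a in atoms]))
            groups.append((r.key, kind, centroid, normal))
    return groups


def interplanar_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Acute angle between two plane normals, degrees in [0, 90]."""
    c = abs(float(np.dot(n1, n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def aromatic_stacking(s: Structure, scope: str | None = None,
                      parallel_max: float = STACK_PARALLEL_MAX,
                      parallel_angle: float = STACK_PARALLEL_ANGLE,
                      t_max: float = STACK_T_MAX,
                      t_angle: tuple[float, float] = STACK_T_ANGLE) -> list[Contact]:
    """Parallel and T-shaped stacking between aromatic rings, plus the
    aromatic-arginine T geometry through the guanidinium plane.

    Parallel: centroid distance ≤ `parallel_max` and interplanar angle ≤
    `parallel_angle`.  T: centroid distance ≤ `t_max` and angle within
    `t_angle`.  Tryptophan uses its six-membered ring.
    """
    groups = _ring_groups(s, include_guanidinium=True)
    out = []
    seen: set[tuple] = set()
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            key_i, kind_i, c_i, n_i = groups[i]
            key_j, kind_j, c_j, n_j = groups[j]
            if key_i == key_j:
                continue
            if kind_i == "guanidinium" and kind_j == "guanidinium":
                continue
            d = float(np.linalg.norm(c_i - c_j))
            ang = interplanar_angle(n_i, n_j)
            mixed = "guanidinium" in (kind_i, kind_j)
            kind = None
            if not mixed and d <= parallel_max and ang <= parallel_angle:
                kind = "stack_parallel"
            elif d <= t_max and t_angle[0] <= ang <= t_angle[1]:
                kind = "stack_T"  # guanidinium planes classify as T only
            if kind is None:
                continue
            contact = _make_contact(kind, key_i, key_j, d, angle=ang)
            dedup = (contact.kind, contact.partner_1, contact.partner_2)
            if dedup not in seen:
                seen.add(dedup)
                out.append(contact)
    return _filter_scope(out, scope)


def s_aromatic(s: Structure, d_max: float = S_AROMATIC_MAX,
               scope: str | None = None) -> list[Contact]:
    """Met SD / Cys SG sulfur within `d_max` of an aromatic ring centroid."""
    rings = [(k, c) for k, kind, c, _n in _ring_groups(s, include_guanidinium=False)
             if kind == "aromatic"]
    sulfurs = []
    for r in _residue_list(s):
        name = {"MET": "SD", "CYS": "SG"}.get(r.name)
        if name and (a := r.atom(name)):
            sulfurs.append((r.key, a.coords))
    out = []
    for skey, spos in sulfurs:
        for rkey, centroid in rings:
            if skey == rkey:
                continue
            d = float(np.linalg.norm(spos - centroid))
            if d <= d_max:
                out.append(_make_contact("s_aromatic", skey, rkey, d))
    return _filter_scope(out, scope)


def all_contacts(s: Structure, scheme: ClassScheme = DEFAULT_SCHEME,
                 scope: str | None = None) -> list[Contact]:
    """All six detectors at default thresholds."""
    out = (hydrophobic_contacts(s, scheme, scope=scope)
           + hydrogen_bonds(s, scope=scope)
           + salt_bridges(s, scope=scope)
           + aromatic_stacking(s, scope=scope)
           + s_aromatic(s, scope=scope))
    return out


def count_summary(contacts: list[Contact], scope: str | None = None) -> dict[str, int]:
    """Integer count per contact kind, optionally filtered to one scope."""
    counts = {k: 0 for k in KINDS}
    for c in contacts:
        if scope in (None, "all") or c.scope == scope:
            counts[c.kind] += 1
    return counts
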