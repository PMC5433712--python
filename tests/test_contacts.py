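"""Contact detectors vs brute-force oracles, monotonicity, invariance."""

import numpy as np
import pytest

from haloadapt.contacts import (
    ACIDIC_SC_O,
    BASIC_SC_N,
    GUANIDINIUM_ATOMS,
    RING_ATOMS,
    all_contacts,
    aromatic_stacking,
    count_summary,
    hydrogen_bonds,
    hydrophobic_contacts,
    s_aromatic,
    salt_bridges,
)
from haloadapt.structure_io import BACKBONE_ATOMS, DEFAULT_SCHEME, Structure, annotate
from haloadapt.templates import make_residue, rotation_about
from haloadapt.synth import PLANT_GEOMETRY, ToyOligomerSpec, gen_toy_oligomer

RESIDUE_POOL = ["ALA", "LEU", "VAL", "PHE", "TYR", "TRP", "HIS", "MET", "CYS",
                "SER", "THR", "ASP", "GLU", "LYS", "ARG", "GLY", "ASN"]


def random_structure(rng, n_residues=14, box=18.0, chains=("A", "B")) -> Structure:
    per_chain = {c: [] for c in chains}
    for i in range(n_residues):
        cid = chains[i % len(chains)]
        name = RESIDUE_POOL[rng.integers(len(RESIDUE_POOL))]
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        origin = rng.uniform(0, box, size=3)
        per_chain[cid].append(make_residue(name, len(per_chain[cid]) + 1, cid, origin, q))
    return annotate(Structure(id="rand", chains=[(c, per_chain[c]) for c in chains]))


# ---------------------------------------------------------------------------
# brute-force oracles (no spatial indexing, straight from the definitions)

def oracle_hydrophobic(s, cutoff=5.0):
    found = set()
    residues = list(s.residues())
    for i, r1 in enumerate(residues):
        for r2 in residues[i + 1:]:
            if (r1.one_letter not in DEFAULT_SCHEME.hydrophobic_residues
                    or r2.one_letter not in DEFAULT_SCHEME.hydrophobic_residues):
                continue
            d = min((np.linalg.norm(a.coords - b.coords)
                     for a in r1.side_chain_atoms() for b in r2.side_chain_atoms()),
                    default=np.inf)
            if d < cutoff:
                found.add(tuple(sorted((r1.key, r2.key))))
    return found


def oracle_hbond(s, d_max=3.5):
    found = set()
    residues = list(s.residues())
    for i, r1 in enumerate(residues):
        for r2 in residues[i + 1:]:
            adjacent = r1.chain_id == r2.chain_id and abs(r1.seq - r2.seq) == 1
            hit = False
            for a in r1.atoms:
                for b in r2.atoms:
                    if a.element not in "NO" or b.element not in "NO":
                        continue
                    if adjacent and a.is_backbone and b.is_backbone:
                        continue
                    if np.linalg.norm(a.coords - b.coords) <= d_max:
                        hit = True
            if hit:
                found.add(tuple(sorted((r1.key, r2.key))))
    return found


def oracle_salt_bridge(s, d_max=4.0):
    found = set()
    residues = list(s.residues())
    for r1 in residues:
        for r2 in residues:
            if r1.name not in ACIDIC_SC_O or r2.name not in BASIC_SC_N:
                continue
            if r1.key == r2.key:
                continue
            for an in ACIDIC_SC_O[r1.name]:
                for bn in BASIC_SC_N[r2.name]:
                    a, b = r1.atom(an), r2.atom(bn)
                    if a and b and np.linalg.norm(a.coords - b.coords) <= d_max:
                        found.add(tuple(sorted((r1.key, r2.key))))
    return found


def _plane_of(res, names):
    pts = np.array([res.atom(n).coords for n in names])
    c = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - c)
    return c, vt[2]


def oracle_stacking(s):
    parallel, tee = set(), set()
    groups = []
    for r in s.residues():
        if r.name in RING_ATOMS and all(r.atom(n) for n in RING_ATOMS[r.name]):
            groups.append((r.key, "aromatic", *_plane_of(r, RING_ATOMS[r.name])))
        if r.name == "ARG" and all(r.atom(n) for n in GUANIDINIUM_ATOMS):
            groups.append((r.key, "guanidinium", *_plane_of(r, GUANIDINIUM_ATOMS)))
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            k1, t1, c1, n1 = groups[i]
            k2, t2, c2, n2 = groups[j]
            if k1 == k2 or (t1 == t2 == "guanidinium"):
                continue
            d = np.linalg.norm(c1 - c2)
            cosv = abs(np.dot(n1, n2))
            ang = np.degrees(np.arccos(np.clip(cosv, 0, 1)))
            pair = tuple(sorted((k1, k2)))
            if t1 == t2 == "aromatic" and d <= 5.5 and ang <= 30.0:
                parallel.add(pair)
            elif d <= 7.0 and 60.0 <= ang <= 90.0:
                tee.add(pair)
    return parallel, tee


def oracle_s_aromatic(s, d_max=6.0):
    found = set()
    residues = list(s.residues())
    for r1 in residues:
        sname = {"MET": "SD", "CYS": "SG"}.get(r1.name)
        if not sname or not r1.atom(sname):
            continue
        for r2 in residues:
            if r2.name not in RING_ATOMS or r1.key == r2.key:
                continue
            if not all(r2.atom(n) for n in RING_ATOMS[r2.name]):
                continue
            c, _ = _plane_of(r2, RING_ATOMS[r2.name])
            if np.linalg.norm(r1.atom(sname).coords - c) <= d_max:
                found.add(tuple(sorted((r1.key, r2.key))))
    return found


def pairs(contacts):
    return {(c.partner_1, c.partner_2) for c in contacts}


# ---------------------------------------------------------------------------

def test_detectors_match_bruteforce_on_random_structures(rng):
    for _ in range(30):
        s = random_structure(rng)
        assert pairs(hydrophobic_contacts(s)) == oracle_hydrophobic(s)
        assert pairs(hydrogen_bonds(s)) == oracle_hbond(s)
        assert pairs(salt_bridges(s)) == oracle_salt_bridge(s)
        par, tee = oracle_stacking(s)
        stacks = aromatic_stacking(s)
        assert pairs([c for c in stacks if c.kind == "stack_parallel"]) == par
        assert pairs([c for c in stacks if c.kind == "stack_T"]) == tee
        assert pairs(s_aromatic(s)) == oracle_s_aromatic(s)


def test_cutoff_monotonicity(rng):
    s = random_structure(rng, n_residues=20)
    for lo, hi in ((3.5, 5.0), (5.0, 7.0)):
        assert pairs(hydrophobic_contacts(s, cutoff=lo)) <= pairs(hydrophobic_contacts(s, cutoff=hi))
        assert pairs(hydrogen_bonds(s, d_max=lo)) <= pairs(hydrogen_bonds(s, d_max=hi))
        assert pairs(salt_bridges(s, d_max=lo)) <= pairs(salt_bridges(s, d_max=hi))
        assert pairs(s_aromatic(s, d_max=lo)) <= pairs(s_aromatic(s, d_max=hi))


def test_rigid_motion_invariance(rng):
    s = random_structure(rng, n_residues=16)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    shift = np.array([50.0, -20.0, 13.0])
    for _res, atom in s.atoms():
        atom.coords = q @ atom.coords + shift
    moved = s
    ref = random_structure(np.random.default_rng(20240917), n_residues=16)
    assert pairs(all_contacts(moved)) == pairs(all_contacts(ref))


def test_no_duplicate_contacts(rng):
    s = random_structure(rng, n_residues=20)
    found = all_contacts(s)
    triples = [(c.kind, c.partner_1, c.partner_2) for c in found]
    assert len(triples) == len(set(triples))
    for c in found:
        assert c.partner_1 <= c.partner_2
        assert c.distance > 0


def test_specific_geometries():
    # two Ala with CB atoms 6.2 A apart: beyond the hydrophobic cutoff
    a = make_residue("ALA", 1, "A", (0, 0, 0))
    b = make_residue("ALA", 2, "A", (6.2, 0, -1.53))  # CBs at 6.2... apart
    s = annotate(Structure(id="t", chains=[("A", [a, b])]))
    assert hydrophobic_contacts(s) == []

    # Ser OG 3.2 A from Asp OD1: one hydrogen bond
    ser = make_residue("SER", 1, "A", (0, 0, 0))
    og = ser.atom("OG").coords
    asp = make_residue("ASP", 5, "A", og + np.array([3.2, 1.1, -3.7]) - np.array([0, 1.1, 3.7]) + np.array([0, 1.1, 3.7]))
    # place so OD1 sits exactly 3.2 A from OG along x
    asp = make_residue("ASP", 5, "A", og + np.array([3.2, 0, 0]) - np.array([0, 1.1, 3.7]))
    s = annotate(Structure(id="t", chains=[("A", [ser, asp])]))
    hb = hydrogen_bonds(s)
    assert len(hb) == 1 and hb[0].distance == pytest.approx(3.2, abs=0.01)

    # backbone O-N of sequence-adjacent residues is excluded
    g1 = make_residue("GLY", 1, "A", (0, 0, 0))
    g2 = make_residue("GLY", 2, "A", (2.2, 2.56, 0))  # its N ~ near g1's O
    s = annotate(Structure(id="t", chains=[("A", [g1, g2])]))
    assert hydrogen_bonds(s) == []

    # salt bridge distances: 4.5 A is out, 3.1 A is in
    asp = make_residue("ASP", 1, "A", (0, 0, 0))
    od2 = asp.atom("OD2").coords
    lys_far = make_residue("LYS", 2, "A", od2 + np.array([4.5, 0, 0]) - np.array([0, 0, 7.65]))
    s = annotate(Structure(id="t", chains=[("A", [asp, lys_far])]))
    assert salt_bridges(s) == []
    arg = make_residue("ARG", 3, "A", od2 + np.array([3.1, 0, 0]) - np.array([0, 1.15, 7.65]))
    s = annotate(Structure(id="t", chains=[("A", [asp, arg])]))
    sb = salt_bridges(s)
    assert len(sb) == 1 and sb[0].distance == pytest.approx(3.1, abs=0.01)

    # coplanar Phe rings, centroids 4.0 A, angle 0: parallel stack
    f1 = make_residue("PHE", 1, "A", (0, 0, 0))
    f2 = make_residue("PHE", 2, "A", (4.0, 0, 0))
    s = annotate(Structure(id="t", chains=[("A", [f1, f2])]))
    st = aromatic_stacking(s)
    assert [c.kind for c in st] == ["stack_parallel"]
    assert st[0].angle == pytest.approx(0.0, abs=1e-6)

    # perpendicular rings 10 A apart: nothing
    f2 = make_residue("PHE", 2, "A", (10.0, 0, 0), rotation_about("z", 90))
    s = annotate(Structure(id="t", chains=[("A", [f1, f2])]))
    assert aromatic_stacking(s) == []

    # centroids 6 A, angle 80: T-stack
    f2 = make_residue("PHE", 2, "A", (6.0, 0, 0), rotation_about("z", 80))
    s = annotate(Structure(id="t", chains=[("A", [f1, f2])]))
    st = aromatic_stacking(s)
    assert [c.kind for c in st] == ["stack_T"]
    assert st[0].angle == pytest.approx(80.0, abs=1e-6)

    # Met SD near / far from a Phe centroid
    met = make_residue("MET", 1, "A", (0, 0, 0))
    sd = met.atom("SD").coords
    phe_near = make_residue("PHE", 2, "A", sd + np.array([5.2, 0, 0]) - np.array([0, 0, 4.31]))
    s = annotate(Structure(id="t", chains=[("A", [met, phe_near])]))
    sa = s_aromatic(s)
    assert len(sa) == 1 and sa[0].distance == pytest.approx(5.2, abs=0.01)
    phe_far = make_residue("PHE", 2, "A", sd + np.array([8.0, 0, 0]) - np.array([0, 0, 4.31]))
    s = annotate(Structure(id="t", chains=[("A", [met, phe_far])]))
    assert s_aromatic(s) == []


def test_planted_contacts_recovered_exactly():
    spec = ToyOligomerSpec(planted_interface={k: 2 for k in PLANT_GEOMETRY},
                           residues_per_subunit=20, seed=9)
    s, truth = gen_toy_oligomer(spec)
    annotate(s)
    found = all_contacts(s, scope="inter_chain")
    counts = count_summary(found)
    assert counts == {k: 2 for k in counts}
    planted = {(p["kind"], tuple(p["partner_1"]), tuple(p["partner_2"]))
               for p in truth["planted_contacts"]}
    got = {(c.kind, c.partner_1, c.partner_2) for c in found}
    assert got == planted


def test_count_summary_empty():
    assert all(v == 0 for v in count_summary([]).values())
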