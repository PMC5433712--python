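"""Hydrophobic-core detection vs connected-components oracle."""

import numpy as np
import pytest

from haloadapt.core import core_composition, detect_core
from haloadapt.sasa import compute_sasa
from haloadapt.structure_io import Structure, annotate
from haloadapt.synth import ToyOligomerSpec, gen_toy_oligomer
from haloadapt.templates import make_residue


def test_all_polar_structure_yields_empty_core():
    residues = [make_residue("SER", i + 1, "A", (0, 0, 4.0 * i)) for i in range(8)]
    s = annotate(Structure(id="polar", chains=[("A", residues)]))
    core = detect_core(s)
    # Ser CB carbons are apolar but cannot form a >=10-atom cluster here
    assert core.core_atoms == set()
    with pytest.raises(ValueError):
        core_composition(s, core)


def test_planted_core_recovered_with_decoys():
    spec = ToyOligomerSpec(planted_core_atoms=20, n_scattered_apolar=3,
                           residues_per_subunit=12, seed=4)
    s, truth = gen_toy_oligomer(spec)
    annotate(s)
    core = detect_core(s)
    assert core.core_atoms == {tuple(a) for a in truth["core_atoms"]}
    comp = core_composition(s, core)
    assert comp.by_residue_type == {"L": 100.0}
    assert comp.n_core_atoms == 20


def test_bridged_clusters_merge_by_single_linkage():
    # two 3-residue leucine blocks 8 A apart, bridged by one leucine between
    left = [make_residue("LEU", i + 1, "A", (4.0 * i, 0, 0)) for i in range(3)]
    right = [make_residue("LEU", i + 4, "A", (16.0 + 4.0 * i, 0, 0)) for i in range(3)]
    bridge = [make_residue("LEU", 7, "A", (12.0, 0, 0))]
    shell = []  # bury everything by disabling the burial filter instead
    s = annotate(Structure(id="b", chains=[("A", left + right + bridge + shell)]))
    merged = detect_core(s, burial_max_rel_sasa=10.0, min_cluster_size=4)
    assert len(merged.clusters) == 1
    # without the bridge the two blocks stay separate
    s2 = annotate(Structure(id="b2", chains=[("A", left + right)]))
    split = detect_core(s2, burial_max_rel_sasa=10.0, min_cluster_size=4)
    assert len(split.clusters) == 2


def oracle_components(coords, cutoff):
    """Brute-force connected components of the distance graph."""
    n = len(coords)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted((frozenset(g) for g in groups.values()), key=sorted)


def test_single_linkage_matches_bruteforce_components(rng):
    for _ in range(10):
        n = int(rng.integers(10, 40))
        pos = rng.uniform(0, 25, size=(n, 3))
        residues = [make_residue("LEU", i + 1, "A", p) for i, p in enumerate(pos)]
        s = annotate(Structure(id="cc", chains=[("A", residues)]))
        core = detect_core(s, burial_max_rel_sasa=10.0, min_cluster_size=1, link_cutoff=5.0)
        # oracle over the same candidate atoms (all leucine side-chain atoms)
        ids, coords = [], []
        for r in s.residues():
            for a in r.side_chain_atoms():
                ids.append((r.chain_id, r.name, r.seq, a.name))
                coords.append(a.coords)
        expected = {frozenset(ids[i] for i in comp)
                    for comp in oracle_components(np.asarray(coords), 5.0)}
        got = {frozenset(c) for c in core.clusters}
        assert got == expected


def test_cluster_count_monotone_in_link_cutoff(rng):
    pos = rng.uniform(0, 30, size=(25, 3))
    residues = [make_residue("VAL", i + 1, "A", p) for i, p in enumerate(pos)]
    s = annotate(Structure(id="m", chains=[("A", residues)]))
    counts = [len(detect_core(s, burial_max_rel_sasa=10.0, min_cluster_size=1,
                              link_cutoff=c).clusters) for c in (3.0, 5.0, 8.0, 15.0)]
    assert counts == sorted(counts, reverse=True)


def test_core_pdb_export_contains_exactly_core_atoms():
    from haloadapt.core import core_to_pdb
    from haloadapt.structure_io import parse_pdb

    s, truth = gen_toy_oligomer(ToyOligomerSpec(planted_core_atoms=20,
                                                residues_per_subunit=8, seed=6))
    annotate(s)
    core = detect_core(s)
    exported = parse_pdb(core_to_pdb(s, core))
    keys = {(r.chain_id, r.name, r.seq, a.name) for r, a in exported.atoms()}
    assert keys == core.core_atoms == {tuple(a) for a in truth["core_atoms"]}


def test_composition_invariant_under_rigid_motion():
    spec = ToyOligomerSpec(planted_core_atoms=20, residues_per_subunit=8, seed=2)
    s, _ = gen_toy_oligomer(spec)
    annotate(s)
    base = core_composition(s, detect_core(s)).by_residue_type
    shift = np.array([40.0, -7.0, 11.0])
    for _r, a in s.atoms():
        a.coords = a.coords + shift
    moved = core_composition(s, detect_core(s)).by_residue_type
    assert moved == base
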