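"""Hydrophobic-core detection and composition.

A core is a spatial cluster of buried apolar atoms.  Candidate atoms are
hydrophobic-class side-chain atoms belonging to residues whose relative SASA
(against Gly-X-Gly reference areas) does not exceed a burial threshold;
candidates are grouped by single-linkage clustering at a link cutoff, and
clusters below a minimum size are discarded.  Composition is reported as the
percent of core atoms contributed by each residue type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from haloadapt.sasa import DEFAULT_N_POINTS, DEFAULT_PROBE, SasaResult, compute_sasa, reference_areas
from haloadapt.structure_io import (
    BACKBONE_ATOMS,
    DEFAULT_SCHEME,
    ClassScheme,
    Structure,
    THREE_TO_ONE,
)

LINK_CUTOFF = 5.0
MIN_CLUSTER_SIZE = 10
BURIAL_MAX_REL_SASA = 0.25

AtomId = tuple[str, str, int, str]  # (chain, residue_name, residue_seq, atom_name)


@dataclass
class CoreAssignment:
    clusters: list[set[AtomId]]
    core_atoms: set[AtomId]
    params: dict = field(default_factory=dict)


def detect_core(s: Structure, scheme: ClassScheme = DEFAULT_SCHEME,
                link_cutoff: float = LINK_CUTOFF,
                min_cluster_size: int = MIN_CLUSTER_SIZE,
                burial_max_rel_sasa: float = BURIAL_MAX_REL_SASA,
                sasa: SasaResult | None = None,
                probe: float = DEFAULT_PROBE,
                n_points: int = DEFAULT_N_POINTS) -> CoreAssignment:
    """Single-linkage clusters of buried apolar side-chain atoms.

    `sasa` may be passed to reuse a precomputed result for the same structure
    (protein atoms, default probe settings); otherwise it is computed here.
    An absence of candidates yields an empty assignment, not an error.
    """
    if sasa is None:
        sasa = compute_sasa(s, probe=probe, n_points=n_points)
    ref = reference_areas(sasa.probe, sasa.n_points)
    buried_residues = set()
    for key, area in sasa.per_residue.items():
        refa = ref.get(key[1])
        if refa and area / refa <= burial_max_rel_sasa:
            buried_residues.add(key)

    ids: list[AtomId] = []
    coords = []
    for res in s.residues(include_hetero=False):
        if res.key not in buried_residues:
            continue
        for a in res.atoms:
            if a.name in BACKBONE_ATOMS:
                continue
            if a.hydro_class is None:
                raise ValueError("structure not annotated; call annotate() first")
            if a.hydro_class == "hydrophobic":
                ids.append((res.chain_id, res.name, res.seq, a.name))
                coords.append(a.coords)
    params = {"link_cutoff": link_cutoff, "min_cluster_size": min_cluster_size,
              "burial_max_rel_sasa": burial_max_rel_sasa,
              "probe": sasa.probe, "n_points": sasa.n_points}
    if not ids:
        return CoreAssignment(clusters=[], core_atoms=set(), params=params)

    coords = np.asarray(coords)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(link_cutoff, output_type="ndarray")
    n = len(ids)
    if len(pairs):
        graph = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        graph = coo_matrix((n, n))
    n_comp, labels = connected_components(graph, directed=False)
    clusters = []
    for comp in range(n_comp):
        members = {ids[i] for i in np.flatnonzero(labels == comp)}
        if len(members) >= min_cluster_size:
            clusters.append(members)
    clusters.sort(key=lambda c: (-len(c), sorted(c)[0]))
    core_atoms = set().union(*clusters) if clusters else set()
    return CoreAssignment(clusters=clusters, core_atoms=core_atoms, params=params)


@dataclass
class CoreComposition:
    by_residue_type: dict[str, float]  # 1-letter code -> percent of core atoms
    n_core_atoms: int


def core_composition(s: Structure, core: CoreAssignment) -> CoreComposition:
    """Percent of core atoms per residue type (1-letter codes)."""
    if not core.core_atoms:
        raise ValueError(
            "empty core: no buried apolar cluster passed the size threshold; "
            "consider raising burial_max_rel_sasa or lowering min_cluster_size")
    counts: dict[str, int] = {}
    for (_chain, name3, _seq, _atom) in core.core_atoms:
        letter = THREE_TO_ONE.get(name3, "X")
        counts[letter] = counts.get(letter, 0) + 1
    total = len(core.core_atoms)
    pct = {k: 100.0 * v / total for k, v in sorted(counts.items())}
    return CoreComposition(by_residue_type=pct, n_core_atoms=total)


def core_to_pdb(s: Structure, core: CoreAssignment) -> str:
    """PDB text containing only the core atoms (for visual inspection)."""
    from haloadapt.structure_io import write_pdb

    kept_chains = []
    for cid, residues in s.chains:
        new_res = []
        for res in residues:
            atoms = [a for a in res.atoms
                     if (res.chain_id, res.name, res.seq, a.name) in core.core_atoms]
            if atoms:
                from dataclasses import replace
                new_res.append(replace(res, atoms=atoms))
        if new_res:
            kept_chains.append((cid, new_res))
    return write_pdb(Structure(id=s.id + "_core", chains=kept_chains))
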