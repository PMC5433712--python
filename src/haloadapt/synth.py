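"""Synthetic labeled sequence families and toy oligomeric structures.

Every pipeline stage needs inputs with known ground truth.  Two generators
provide them:

* :func:`gen_sequence_family` draws two groups of protein sequences i.i.d.
  per position from group-specific residue distributions.  The default
  shifts emulate the composition signature reported for haloalkaliphilic
  octaheme nitrite reductases relative to their neutrophile homologues
  (fewer lysines; more glutamate, arginine, phenylalanine, tryptophan and
  valine), at the study design of 4 versus 22 sequences of ~550 residues.

* :func:`gen_toy_oligomer` builds multi-chain structures from idealized
  residue templates on a sparse lattice (far enough apart that nothing
  interacts by accident) and plants specific features with a safety margin:
  inter-chain contacts of each detectable kind, a hydrophobic interface
  patch, and a buried apolar core wrapped in a glycine shell.  The emitted
  ground truth lists every planted feature so detectors can be tested
  closed-loop.

All outputs are byte-deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from haloadapt.structure_io import ONE_TO_THREE, Residue, Structure, AtomRecord
from haloadapt.templates import make_residue, residue_template, rotation_about

# ---------------------------------------------------------------------------
# sequence families

#: background residue composition (fractions), a typical proteome-average
DEFAULT_BACKGROUND = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0138,
    "Q": 0.0393, "E": 0.0672, "G": 0.0708, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0663, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}

#: per-residue percentage-point shifts applied to group A (haONR-like):
#: -K, +E, +R, +F, +W, +V with the balance taken from the bulky apolar pool
#: (L, I) so the distribution stays normalized without rescaling.
DEFAULT_HA_SHIFTS = {
    "K": -3.25, "E": +1.61, "R": +1.71, "F": +0.66, "W": +0.34, "V": +0.69,
    "L": -1.00, "I": -0.76,
}


@dataclass
class SeqFamilySpec:
    n_a: int = 4
    n_b: int = 22
    length: int = 550
    background: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BACKGROUND))
    shifts: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HA_SHIFTS))
    group_a: str = "haONR"
    group_b: str = "nnONR"
    #: planted subfamily-specific positions: 1-based column -> (residue fixed
    #: across group A, residue fixed across group B); e.g. {52: ("E", "K")}
    #: emulates a conserved K->E habitat substitution at that position
    ssp_columns: dict[int, tuple[str, str]] = field(default_factory=dict)
    seed: int = 0


def _shifted_distribution(background: dict[str, float],
                          shifts: dict[str, float]) -> dict[str, float]:
    out = {}
    for aa, p in background.items():
        q = p + shifts.get(aa, 0.0) / 100.0
        if q < 0:
            raise ValueError(f"shift makes probability of {aa!r} negative ({q:.4f})")
        out[aa] = q
    total = sum(out.values())
    return {aa: q / total for aa, q in out.items()}


def gen_sequence_family(spec: SeqFamilySpec) -> tuple[str, dict[str, str], dict]:
    """Generate (FASTA text, id→group labels, ground truth)."""
    rng = np.random.default_rng(spec.seed)
    bg_total = sum(spec.background.values())
    p_b = {aa: v / bg_total for aa, v in spec.background.items()}
    p_a = _shifted_distribution(p_b, spec.shifts)
    letters = sorted(p_b)
    probs_a = np.array([p_a[aa] for aa in letters])
    probs_b = np.array([p_b[aa] for aa in letters])
    records = []
    labels = {}
    for group, n, probs in ((spec.group_a, spec.n_a, probs_a),
                            (spec.group_b, spec.n_b, probs_b)):
        for i in range(n):
            sid = f"{group}_{i + 1:02d}"
            idx = rng.choice(len(letters), size=spec.length, p=probs)
            seq = list("".join(letters[k] for k in idx))
            for col, (res_a, res_b) in spec.ssp_columns.items():
                if not (1 <= col <= spec.length):
                    raise ValueError(f"ssp column {col} outside sequence length {spec.length}")
                seq[col - 1] = res_a if group == spec.group_a else res_b
            records.append(f">{sid}\n{''.join(seq)}")
            labels[sid] = group
    fasta = "\n".join(records) + "\n"
    truth = {
        "group_a": spec.group_a, "group_b": spec.group_b,
        "n_a": spec.n_a, "n_b": spec.n_b, "length": spec.length,
        "distribution_a": {aa: p_a[aa] for aa in letters},
        "distribution_b": {aa: p_b[aa] for aa in letters},
        "shifts_pp": dict(spec.shifts),
        "ssp_columns": {str(c): list(v) for c, v in spec.ssp_columns.items()},
        "seed": spec.seed,
    }
    return fasta, labels, truth


# ---------------------------------------------------------------------------
# toy oligomers

#: geometry of each plantable inter-chain pair: residue on side A, residue on
#: side B, rotation applied to B's template, offset of B's origin from A's.
#: Offsets satisfy the kind's detection criterion with >= 0.3 A margin while
#: staying clear of every other detector's threshold.
PLANT_GEOMETRY: dict[str, tuple[str, str, np.ndarray | None, tuple[float, float, float]]] = {
    "hydrophobic": ("LEU", "LEU", None, (4.6, 0.0, 0.0)),
    "hbond": ("SER", "SER", None, (3.0, 0.0, 0.0)),
    "salt_bridge": ("ASP", "LYS", rotation_about("x", 180.0), (3.7, 1.1, 11.35)),
    "stack_parallel": ("TYR", "TYR", None, (4.0, -2.5, 0.0)),
    "stack_T": ("TYR", "TYR", rotation_about("z", 80.0), (6.0, -2.0, 0.0)),
    "s_aromatic": ("MET", "PHE", None, (5.7, 0.0, 0.09)),
}

LATTICE_SPACING = 14.0  # Å between residue origins; beyond every detector cutoff


@dataclass
class ToyOligomerSpec:
    n_subunits: int = 2
    residues_per_subunit: int = 20
    scaffold: str = "lattice"           # {lattice | helix}
    planted_interface: dict[str, int] = field(default_factory=dict)  # kind -> count
    planted_patch_pairs: int = 0        # facing LEU pairs (hydrophobic interface patch)
    planted_core_atoms: int = 0         # buried apolar cluster size (LEU side chains)
    n_scattered_apolar: int = 0         # exposed ALA decoys, far from everything
    subunit_gap: float = 50.0           # Å between consecutive chain blocks
    spacing: float = LATTICE_SPACING
    shell_radius: float = 9.0
    shell_count: int = 80
    filler_residues: tuple[str, ...] = ("GLY",)
    seed: int = 0


def _lattice_sites(n: int, spacing: float, origin: np.ndarray) -> list[np.ndarray]:
    """n sites on a cubic lattice block starting at `origin`."""
    side = int(np.ceil(n ** (1.0 / 3.0)))
    sites = []
    for i in range(n):
        ix, rem = divmod(i, side * side)
        iy, iz = divmod(rem, side)
        sites.append(origin + spacing * np.array([ix, iy, iz], dtype=float))
    return sites


def _helix_sites(n: int, origin: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Ideal alpha-helix CA trace: radius 2.3 Å, rise 1.5 Å, 100°/residue.
    Returns (site, rotation) with side chains pointing radially outward."""
    out = []
    for i in range(n):
        phi = np.radians(100.0 * i)
        site = origin + np.array([2.3 * np.cos(phi), 2.3 * np.sin(phi), 1.5 * i])
        # rotate +z (side-chain axis) to the outward radial direction
        rot = rotation_about("z", np.degrees(phi)) @ rotation_about("y", 90.0)
        out.append((site, rot))
    return out


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def gen_toy_oligomer(spec: ToyOligomerSpec) -> tuple[Structure, dict]:
    """Build a toy oligomer and its ground truth.

    Chains are labeled A, B, C, ...; planted inter-chain features always sit
    between chains A and B, in an interface slab well separated from both
    chain blocks.  The planted core (and its glycine shell) lives inside
    chain A's block.  Raises if the plants do not fit in the subunit size.
    """
    if spec.n_subunits < 1:
        raise ValueError("need at least one subunit")
    if spec.scaffold not in ("lattice", "helix"):
        raise ValueError(f"unknown scaffold {spec.scaffold!r}")
    for kind in spec.planted_interface:
        if kind not in PLANT_GEOMETRY:
            raise ValueError(f"unknown planted contact kind {kind!r}")

    rng = np.random.default_rng(spec.seed)
    chain_ids = [chr(ord("A") + i) for i in range(spec.n_subunits)]
    n_plant_pairs = sum(spec.planted_interface.values()) + spec.planted_patch_pairs
    core_leu = int(np.ceil(spec.planted_core_atoms / 4.0)) if spec.planted_core_atoms else 0
    needed_a = n_plant_pairs + core_leu + spec.n_scattered_apolar
    if needed_a > spec.residues_per_subunit:
        raise ValueError(
            f"planted features need {needed_a} residues in a subunit of "
            f"{spec.residues_per_subunit}; enlarge residues_per_subunit")
    if spec.n_subunits < 2 and n_plant_pairs:
        raise ValueError("inter-chain plants require at least two subunits")

    block_extent = spec.spacing * int(np.ceil(spec.residues_per_subunit ** (1 / 3))) + 10.0
    block_origins = [np.array([i * (block_extent + spec.subunit_gap), 0.0, 0.0])
                     for i in range(spec.n_subunits)]
    # interface slab midway between blocks A and B, displaced far in -y so the
    # planted pairs cannot touch either block
    if spec.n_subunits >= 2:
        x_slab = block_origins[0][0] + block_extent + 0.5 * spec.subunit_gap
    chains: dict[str, list[Residue]] = {cid: [] for cid in chain_ids}
    seq_counter = {cid: 0 for cid in chain_ids}

    def add_residue(cid: str, name3: str, origin, rotation=None) -> Residue:
        seq_counter[cid] += 1
        res = make_residue(name3, seq_counter[cid], cid, np.asarray(origin, float), rotation)
        chains[cid].append(res)
        return res

    truth: dict = {"planted_contacts": [], "patch_pairs": [], "core_atoms": [],
                   "scattered_apolar": [], "seed": spec.seed}

    # --- planted inter-chain contacts (chains A and B) ---------------------
    slab_y = -2.0 * spec.spacing
    slot = 0
    for kind, count in sorted(spec.planted_interface.items()):
        res_a, res_b, rot_b, offset = PLANT_GEOMETRY[kind]
        for _ in range(count):
            base = np.array([x_slab, slab_y - slot * spec.spacing, 0.0])
            ra = add_residue("A", res_a, base)
            rb = add_residue("B", res_b, base + np.asarray(offset), rot_b)
            truth["planted_contacts"].append(
                {"kind": kind, "partner_1": list(ra.key), "partner_2": list(rb.key)})
            slot += 1

    # --- hydrophobic interface patch: facing leucines ----------------------
    # side chains rotated to point along +x (chain A) and -x (chain B); the
    # nearest inter-chain atoms are all side-chain carbons, so the buried
    # area between them is hydrophobic-hydrophobic.
    rot_to_plus_x = rotation_about("y", 90.0)
    rot_to_minus_x = rotation_about("y", -90.0)
    for _ in range(spec.planted_patch_pairs):
        base = np.array([x_slab, slab_y - slot * spec.spacing, 0.0])
        ra = add_residue("A", "LEU", base, rot_to_plus_x)
        rb = add_residue("B", "LEU", base + np.array([2 * 3.93 + 4.2, 0.0, 0.0]),
                         rot_to_minus_x)
        truth["patch_pairs"].append([list(ra.key), list(rb.key)])
        slot += 1

    # --- planted buried core in chain A's block ----------------------------
    if core_leu:
        core_center = block_origins[0] + np.array([0.0, 0.0, 6.0 * spec.spacing])
        core_atoms_xyz = []
        side = int(np.ceil(core_leu ** (1.0 / 3.0)))
        for i in range(core_leu):
            ix, rem = divmod(i, side * side)
            iy, iz = divmod(rem, side)
            origin = core_center + 4.0 * np.array([ix, iy, iz], dtype=float)
            res = add_residue("A", "LEU", origin)
            for a in res.side_chain_atoms():
                truth["core_atoms"].append([res.chain_id, res.name, res.seq, a.name])
                core_atoms_xyz.append(a.coords)
        # glycine shell: occludes solvent, contributes no apolar side chains
        core_atoms_xyz = np.asarray(core_atoms_xyz)
        cluster_mid = core_atoms_xyz.mean(axis=0)
        r_shell = float(np.linalg.norm(core_atoms_xyz - cluster_mid, axis=1).max()) + 3.5
        n_shell = max(spec.shell_count, int(2.0 * r_shell ** 2))
        for v in _fibonacci_sphere(n_shell):
            add_residue("A", "GLY", cluster_mid + r_shell * v)

    # --- scattered exposed apolar decoys -----------------------------------
    for i in range(spec.n_scattered_apolar):
        origin = block_origins[0] + np.array(
            [0.0, 0.0, -4.0 * spec.spacing - i * spec.spacing])
        res = add_residue("A", "ALA", origin)
        truth["scattered_apolar"].append(list(res.key))

    # --- scaffold fillers ---------------------------------------------------
    for cid, origin in zip(chain_ids, block_origins):
        n_fill = spec.residues_per_subunit - seq_counter[cid]
        if n_fill <= 0:
            continue
        if spec.scaffold == "lattice":
            for site in _lattice_sites(n_fill, spec.spacing, origin):
                name3 = spec.filler_residues[int(rng.integers(len(spec.filler_residues)))]
                add_residue(cid, name3, site)
        else:
            for site, rot in _helix_sites(n_fill, origin):
                name3 = spec.filler_residues[int(rng.integers(len(spec.filler_residues)))]
                add_residue(cid, name3, site, rot)

    structure = Structure(id=f"toy_{spec.n_subunits}mer",
                          chains=[(cid, chains[cid]) for cid in chain_ids])
    serial = 0
    for _cid, residues in structure.chains:
        for res in residues:
            for a in res.atoms:
                serial += 1
                a.serial = serial
    truth["n_subunits"] = spec.n_subunits
    truth["chain_ids"] = chain_ids
    return structure, truth


def gen_scatter_structure(counts: dict[str, int], seed: int = 0,
                          spacing: float = 10.0,
                          probe: float = 1.4) -> tuple[Structure, dict]:
    """Far-separated one-atom residues with analytically known areas.

    Each residue is represented by a single CB carbon atom on a sparse grid
    (no two spheres overlap), so each residue's SASA is exactly the isolated
    sphere area 4π(r_C + probe)².  `counts` maps 1-letter residue types to
    how many such residues to emit.  Ground truth records the per-residue
    isolated-sphere areas.  A deliberately synthetic fixture for testing
    area-weighted surface composition.
    """
    rng = np.random.default_rng(seed)
    residues: list[Residue] = []
    area = 4.0 * np.pi * (1.70 + probe) ** 2
    truth = {"per_residue_area": {}, "sphere_area": area}
    i = 0
    order = [aa for aa, n in sorted(counts.items()) for _ in range(n)]
    rng.shuffle(order)
    for letter in order:
        name3 = ONE_TO_THREE[letter]
        side = 10
        ix, rem = divmod(i, side * side)
        iy, iz = divmod(rem, side)
        origin = spacing * np.array([ix, iy, iz], dtype=float)
        res = Residue(name=name3, seq=i + 1, chain_id="A",
                      atoms=[AtomRecord(serial=i + 1, name="CB", element="C",
                                        coords=origin)])
        residues.append(res)
        truth["per_residue_area"][f"A/{name3}/{i + 1}"] = area
        i += 1
    return Structure(id="scatter", chains=[("A", residues)]), truth
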