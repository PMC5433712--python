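"""Canonical synthetic study conditions.

The comparative design this package analyses contrasts a small group of
haloalkaliphile-derived proteins against a larger group of neutrophile
homologues.  This module pins the synthetic stand-in for that design in one
place so every driver (analysis scripts, tests, acceptance) runs the same
conditions:

* sequence family: 4 vs 22 sequences of 550 residues; group A shifted
  -K/+E/+R/+F/+W/+V against a proteome-average background (see
  :mod:`haloadapt.synth` for the exact percentage points), with four planted
  subfamily-specific columns emulating conserved habitat substitutions;

* toy oligomers: an "ha"-like dimer rich in planted interface hydrophobics,
  stacking and a hydrophobic patch, with acidic/arginine surface fillers,
  versus an "nn"-like dimer with a sparse, polar interface and lysine-rich
  surface fillers.  Both carry a 20-atom buried apolar core.

Everything here is synthetic and labelled as such; it emulates the structure
of the real comparison, not its absolute magnitudes.
"""

from __future__ import annotations

import json
from pathlib import Path

from haloadapt.structure_io import write_pdb
from haloadapt.synth import SeqFamilySpec, ToyOligomerSpec, gen_sequence_family, gen_toy_oligomer

GROUP_A = "haONR"
GROUP_B = "nnONR"

#: planted subfamily-specific columns: conserved residue per group
SSP_COLUMNS = {52: ("E", "K"), 155: ("A", "K"), 179: ("R", "K"), 284: ("S", "F")}


def sequence_spec(seed: int) -> SeqFamilySpec:
    return SeqFamilySpec(ssp_columns=dict(SSP_COLUMNS), seed=seed)


def ha_oligomer_spec(seed: int) -> ToyOligomerSpec:
    """Haloalkaliphile-like dimer: hydrophobic-rich interface, acidic surface."""
    return ToyOligomerSpec(
        n_subunits=2, residues_per_subunit=40,
        planted_interface={"hydrophobic": 4, "stack_parallel": 2, "stack_T": 2,
                           "s_aromatic": 2, "hbond": 3, "salt_bridge": 3},
        planted_patch_pairs=4, planted_core_atoms=20,
        filler_residues=("GLY", "ALA", "ASP", "GLU", "ARG", "SER", "VAL"),
        seed=seed)


def nn_oligomer_spec(seed: int) -> ToyOligomerSpec:
    """Neutrophile-like dimer: sparse polar interface, lysine-rich surface."""
    return ToyOligomerSpec(
        n_subunits=2, residues_per_subunit=40,
        planted_interface={"hydrophobic": 1, "hbond": 3, "salt_bridge": 1},
        planted_patch_pairs=1, planted_core_atoms=20,
        filler_residues=("GLY", "ALA", "LYS", "LYS", "SER", "THR", "LEU"),
        seed=seed)


def write_study_bundle(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Emit the full synthetic input bundle (FASTA, labels, MSA, PDBs,
    pipeline config, ground truth) and return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta, labels, seq_truth = gen_sequence_family(sequence_spec(seed))
    (out / "family.fasta").write_text(fasta)
    (out / "labels.tsv").write_text("".join(f"{k}\t{v}\n" for k, v in labels.items()))
    # equal-length i.i.d. sequences: the family doubles as a gap-free alignment
    (out / "family.afa").write_text(fasta)

    st_ha, truth_ha = gen_toy_oligomer(ha_oligomer_spec(seed + 1))
    st_nn, truth_nn = gen_toy_oligomer(nn_oligomer_spec(seed + 2))
    (out / "ha_oligomer.pdb").write_text(write_pdb(st_ha))
    (out / "nn_oligomer.pdb").write_text(write_pdb(st_nn))

    config = f"""\
output_dir: {out / 'pipeline_out'}
sequences: family.fasta
labels: labels.tsv
msa: family.afa
structures:
  ha_oligomer: ha_oligomer.pdb
  nn_oligomer: nn_oligomer.pdb
contacts:
  - {{name: dimer, side_a: [A], side_b: [B]}}
groups: [{GROUP_A}, {GROUP_B}]
seed: {seed}
"""
    (out / "config.yaml").write_text(config)
    truth = {"sequences": seq_truth, "ha_oligomer": truth_ha, "nn_oligomer": truth_nn}
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return {name: out / name for name in
            ("family.fasta", "labels.tsv", "family.afa", "ha_oligomer.pdb",
             "nn_oligomer.pdb", "config.yaml", "ground_truth.json")}
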