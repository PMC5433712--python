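# Methods

This note documents the models, geometric criteria, parameter choices and
known limitations of the `haloadapt` pipeline.

## Structures and atom classification

Structures are consumed as PDB files assumed to contain the biological
oligomer explicitly (no symmetry expansion; mmCIF is out of scope).  Parsing
keeps the first MODEL only, resolves alternate locations by highest
occupancy (ties by record order, for reproducibility), and drops hydrogens:
crystal structures and homology models of the proteins this pipeline
targets are heavy-atom, so every geometric criterion below is defined on
heavy atoms.  HETATM groups (hemes, waters) are retained but flagged
non-protein and excluded from all composition, surface and core statistics
by default, because those statistics are defined over amino-acid residues.

Atoms carry Bondi-style van der Waals radii (C 1.70, N 1.55, O 1.52,
S 1.80, other 1.80 Å) and a binary hydrophobicity class by element
(C, S apolar; N, O polar).  The binary rule is a deliberate simplification
of logP-style atomic hydrophobicity weightings; it is transparent,
parameter-free and sufficient for class-paired area decomposition.  The
residue-level "hydrophobic set" is {A, V, L, I, M, F, W, P} and is
configurable, since published surface-composition tables in this literature
rarely state the exact set behind their percentages.

## Solvent-accessible surface area

Shrake–Rupley with probe 1.4 Å (water) and 960 quadrature points per atom.
The point set is a deterministic golden-spiral lattice — no RNG, identical
results across runs.  Per-atom area is the unoccluded fraction of points on
the expanded sphere (radius r + probe) times 4π(r + probe)²; neighbour
search is KD-tree limited to atoms within rᵢ + rⱼ + 2·probe.  At 960 points
the single-sphere error against the analytic area is < 0.1% and random
small clusters agree with an independent Monte-Carlo estimate to well
within 2%.  Totals are exactly translation-invariant; under rotation they
agree only to quadrature accuracy (~0.1–1%), a property shared by every
fixed-orientation implementation of this algorithm.

Surface composition is area-weighted: the percent of total SASA contributed
by each residue class, with no exposure threshold (every residue contributes
its actual area).  Because adaptation claims are sometimes stated as counts
of exposed residues, a count-weighted variant is also emitted: residues with
relative SASA ≥ 5% are "exposed", where relative SASA divides the residue's
area by a per-type reference computed once from extended Gly-X-Gly
tripeptides built from the package's own templates.

## Interface decomposition

For a declared contact (two disjoint chain sets), each atom's buried area is
max(0, SASA(own side alone) − SASA(both sides together)).  S_buried is the
sum over both sides; each buried atom is classified by pairing its class
with that of the nearest opposite-side atom within 6.0 Å — apolar/apolar
burial accumulates into S_ll, polar/polar into S_hh, everything else
(including burial without a nearby partner) into S_mixed.  The three parts
sum to S_buried identically, which every run asserts.  Published tables in
this area report only the ll and hh parts, whose sum falls far short of the
total buried area; making the mixed remainder explicit resolves that
bookkeeping without changing either reported part.  Contact membership
(which chains form the dimer/trimer/hexamer contacts) is declared in
configuration, not auto-detected, because the oligomeric architecture is
known input.  S_total is the sum of the two sides' isolated SASAs.

## Contact criteria

All residue-pair detectors report one contact per (pair, kind) at the
minimal qualifying distance; partner order is canonicalized.  Defaults:

| kind | criterion | default |
|---|---|---|
| hydrophobic | min side-chain heavy-atom distance, both residues in hydrophobic set | < 5.0 Å |
| hydrogen bond | N/O···N/O heavy-atom distance, different residues; sequence-adjacent backbone–backbone pairs excluded | ≤ 3.5 Å |
| salt bridge | D/E side-chain O to K/R/H side-chain N | ≤ 4.0 Å |
| parallel stacking | ring-centroid distance and interplanar angle | ≤ 5.5 Å, ≤ 30° |
| T-stacking | centroid distance, angle (also aromatic–Arg via the guanidinium plane) | ≤ 7.0 Å, 60–90° |
| S-aromatic | Met SD / Cys SG to ring centroid | ≤ 6.0 Å |

Ring planes come from an SVD fit (tryptophan uses its six-membered ring);
incomplete rings are skipped with a warning.  The 5 Å hydrophobic cutoff is
the one criterion this literature states explicitly; the remaining
thresholds are standard values exposed in configuration.  Distance-only
hydrogen bonds are coarser than donor–H–acceptor angle tests — unavoidable
without hydrogens and acceptable for comparative counting.  Counting is per
residue pair, not per atom pair; inventories are reported for
intra-chain, inter-chain and combined scopes since published counts rarely
state which filter they used.

## Hydrophobic cores

Candidate atoms are apolar side-chain atoms of residues with relative SASA
≤ 0.25.  Single-linkage clustering at 5.0 Å; clusters under 10 atoms are
discarded; composition is the percent of core atoms per residue type.
Single linkage on buried apolar atoms is a transparent stand-in for
published core-detection tools whose algorithms and burial criteria are not
fully specified; all three parameters are configurable and recorded in the
output provenance.  Residues may appear in both surface and core statistics
— no exclusivity is enforced.

## Group statistics

Composition vectors are percents over standard residues (X excluded from
the denominator).  Group location is summarized as median and linear-
interpolation quartiles.  The two-sided Mann–Whitney U test is exact for
n₁+n₂ ≤ 30: the permutation distribution of the rank sum over all
C(n₁+n₂, n₁) labelings is computed by dynamic programming over doubled
mid-ranks (identical to full enumeration, polynomial cost); larger designs
fall back to the tie-corrected normal approximation.  The exact path is
verified against literal enumeration for all group sizes ≤ 5.  Decisions
use raw p < 0.05 per residue type with no multiple-testing correction —
deliberately matching how such comparisons are reported in this literature;
users scanning all 20 types should expect roughly one false positive per
scan under the null (measured type-I error at the 4-vs-22 design: ~5–6%).
Isoelectric points come from bisection of the Henderson–Hasselbalch net
charge (EMBOSS pKa set, tolerance 10⁻³ pH).  Signal peptides are not
trimmed before composition; sequences are analysed as given.

## Subfamily-specific positions

A column is subfamily-specific when both groups reach within-group consensus
frequency τ = 0.8 on different residues and the column's gap fraction is
≤ 0.2.  The continuous score freq_a + freq_b − 1 is emitted for every column
for ranking.  This deterministic rule is a simplification of
bootstrap-based specificity scoring; it is exact on the synthetic
closed-loop fixtures and qualitative on real alignments.

## Synthetic data

The generators define the study conditions everything is validated under:

- **Sequence families**: 4 vs 22 sequences of 550 residues (the comparative
  design and typical chain length of the protein family of interest), drawn
  i.i.d. per position from a proteome-average background; group A is shifted
  by −3.25 pp K, +1.61 E, +1.71 R, +0.66 F, +0.34 W, +0.69 V — percentage
  points chosen so the planted relative median shifts match the reported
  signature (−56% K, +24% E, +31% R, +17% F, +31% W) — balanced by −1.00 L
  and −0.76 I (the bulky-apolar pool the same literature reports shrinking)
  so the distribution stays normalized.  Four columns carry planted
  subfamily-specific substitutions.
- **Toy oligomers**: chains of idealized residue templates on a 14 Å lattice
  (beyond every detector cutoff, so nothing interacts by accident), with
  planted inter-chain pairs positioned to satisfy exactly one detector's
  criterion with ≥ 0.3 Å margin while staying clear of every other
  criterion; a hydrophobic interface patch of facing leucines; and a buried
  core of close-packed leucine side chains wrapped in a glycine shell
  (glycine contributes no apolar side-chain atoms, so the shell buries the
  core without joining it).

i.i.d. positions mean no covariation, no conserved motifs and no
phylogenetic structure; template side chains have non-physical torsions.
Passing closed-loop tests therefore demonstrates correctness of the
detectors and statistics under their stated criteria, not realism of any
energetic model.  Absolute areas and counts of the toy structures are not
comparable to real oligomers; only their engineered contrasts (ratios,
directions, planted counts) are meaningful.

## Problem sizes and numerics

Validation suites use: 1000 random dimers for interface conservation, 100
random structures for detector/oracle equivalence, 50 seeded toys for exact
core recovery, 1000 null and 500 shifted simulations for test calibration —
sizes at which every oracle is exhaustive and the whole suite runs in
minutes on one CPU.  The acceptance script uses the same designs (some at
reduced replicate counts and 240 SASA points where only conservation or
recovery, not area accuracy, is being measured).  Degenerate inputs are
errors with guidance (empty structures, zero total SASA, empty core at
composition time, a group with no members); an absence of core candidates
is an empty result, not an error.  Ties in every ranking/consensus step are
broken deterministically (record order, alphabetical).
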