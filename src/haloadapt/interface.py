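"""Inter-subunit interface buried-area decomposition.

For a named contact between two chain sets, the buried area of each atom is
the SASA it loses when its own side is joined with the opposite side
(side-alone minus complex).  Each buried atom is classified by pairing its
hydrophobicity class with that of the nearest opposite-side atom within a
partner radius: hydrophobic-hydrophobic burial accumulates into Sll,
hydrophilic-hydrophilic into Shh, and everything else (including burial with
no nearby partner, e.g. conformational occlusion) into Smixed, so that
Sll + Shh + Smixed = Sburied holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from haloadapt.sasa import DEFAULT_N_POINTS, DEFAULT_PROBE, sasa_from_table
from haloadapt.structure_io import Structure, flatten

PARTNER_RADIUS = 6.0  # Å, atom-to-atom classification radius


@dataclass(frozen=True)
class ContactDefinition:
    """A named inter-subunit contact: two disjoint chain sets."""

    name: str
    side_a: frozenset[str]
    side_b: frozenset[str]

    def __post_init__(self):
        a, b = frozenset(self.side_a), frozenset(self.side_b)
        object.__setattr__(self, "side_a", a)
        object.__setattr__(self, "side_b", b)
        if not a or not b:
            raise ValueError(f"contact {self.name!r}: both sides must be non-empty")
        if a & b:
            raise ValueError(f"contact {self.name!r}: sides overlap: {sorted(a & b)}")


@dataclass
class InterfaceDecomposition:
    name: str
    Sll: float
    Shh: float
    Smixed: float
    Sburied: float
    Stotal: float
    Sasa_complex: float


def buried_area(s: Structure, c: ContactDefinition,
                probe: float = DEFAULT_PROBE,
                n_points: int = DEFAULT_N_POINTS,
                partner_radius: float = PARTNER_RADIUS) -> InterfaceDecomposition:
    """Decompose the buried area of a declared contact.

    Raises if a declared chain is missing or a side has no atoms.
    """
    present = set(s.chain_ids())
    missing = (c.side_a | c.side_b) - present
    if missing:
        raise KeyError(f"contact {c.name!r}: chains not in structure: {sorted(missing)}")
    table_a = flatten(s, chain_ids=set(c.side_a))
    table_b = flatten(s, chain_ids=set(c.side_b))
    sasa_a = sasa_from_table(table_a, probe, n_points)
    sasa_b = sasa_from_table(table_b, probe, n_points)

    # complex = concatenation of the two sides, preserving per-side alignment
    coords = np.vstack([table_a.coords, table_b.coords])
    radii = np.concatenate([table_a.radii, table_b.radii])
    hydro = np.concatenate([table_a.hydrophobic, table_b.hydrophobic])
    n_a = len(table_a)
    from haloadapt.structure_io import AtomTable
    joint = AtomTable(coords=coords, radii=radii, hydrophobic=hydro,
                      residue_index=np.zeros(len(radii), dtype=int),
                      residue_keys=[("", "", 0)], atom_names=[])
    sasa_ab = sasa_from_table(joint, probe, n_points)

    alone = np.concatenate([sasa_a.per_atom, sasa_b.per_atom])
    delta = np.maximum(alone - sasa_ab.per_atom, 0.0)
    side = np.zeros(len(radii), dtype=bool)
    side[n_a:] = True

    # nearest opposite-side atom within partner_radius, per atom
    tree_a = cKDTree(table_a.coords)
    tree_b = cKDTree(table_b.coords)
    d_opp = np.empty(len(radii))
    dist_b, idx_b = tree_b.query(table_a.coords, k=1)
    dist_a, idx_a = tree_a.query(table_b.coords, k=1)
    d_opp[:n_a] = dist_b
    d_opp[n_a:] = dist_a
    partner_hydro = np.empty(len(radii), dtype=bool)
    partner_hydro[:n_a] = table_b.hydrophobic[idx_b]
    partner_hydro[n_a:] = table_a.hydrophobic[idx_a]

    has_partner = d_opp <= partner_radius
    ll = has_partner & hydro & partner_hydro
    hh = has_partner & ~hydro & ~partner_hydro
    Sll = float(delta[ll].sum())
    Shh = float(delta[hh].sum())
    Sburied = float(delta.sum())
    Smixed = Sburied - Sll - Shh
    return InterfaceDecomposition(
        name=c.name, Sll=Sll, Shh=Shh, Smixed=Smixed, Sburied=Sburied,
        Stotal=float(sasa_a.total + sasa_b.total),
        Sasa_complex=float(sasa_ab.total))


FIELDS = ["Sll", "Shh", "Smixed", "Sburied", "Stotal", "Sasa_complex"]


def contact_report(structures: dict[str, Structure],
                   defs: list[ContactDefinition],
                   probe: float = DEFAULT_PROBE,
                   n_points: int = DEFAULT_N_POINTS) -> pd.DataFrame:
    """One row per (contact, structure) with the six decomposition fields.

    When exactly two structures are given, ratio columns ``<field>_ratio``
    report first / second (in the given dict order) for each contact; zero
    denominators yield NaN.
    """
    if not defs:
        raise ValueError("no contact definitions given")
    rows = []
    for cdef in defs:
        for name, s in structures.items():
            dec = buried_area(s, cdef, probe=probe, n_points=n_points)
            rows.append({"contact": cdef.name, "structure": name,
                         **{f: getattr(dec, f) for f in FIELDS}})
    df = pd.DataFrame(rows)
    names = list(structures)
    if len(names) == 2:
        first, second = names
        for cdef in defs:
            sel = df["contact"] == cdef.name
            top = df[sel & (df["structure"] == first)].iloc[0]
            bot = df[sel & (df["structure"] == second)].iloc[0]
            for f in FIELDS:
                df.loc[sel, f + "_ratio"] = top[f] / bot[f] if bot[f] != 0 else np.nan
    return df
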