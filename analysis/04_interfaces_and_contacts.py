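"""Interface decomposition and contact inventories of the toy dimers.

Decomposes the declared A:B dimer interface of both structures into
hydrophobic-hydrophobic (Sll), hydrophilic-hydrophilic (Shh) and mixed
buried area, reports the ha/nn Sll ratio (the stronger hydrophobic
inter-subunit glue of the ha-like structure), and counts non-covalent
contacts per kind and scope.  Writes results/tables/
interface_decomposition.tsv and contact_counts.tsv.
"""

from pathlib import Path

import pandas as pd

from haloadapt.contacts import all_contacts, count_summary
from haloadapt.interface import ContactDefinition, contact_report
from haloadapt.structure_io import annotate, parse_pdb

ROOT = Path(__file__).resolve().parents[1]
SYN = ROOT / "results" / "synthetic"
TABLES = ROOT / "results" / "tables"


def main() -> None:
    structures = {
        name: annotate(parse_pdb((SYN / f"{name}.pdb").read_text(), structure_id=name))
        for name in ("ha_oligomer", "nn_oligomer")
    }
    dimer = ContactDefinition("dimer", frozenset("A"), frozenset("B"))
    df = contact_report(structures, [dimer])
    TABLES.mkdir(parents=True, exist_ok=True)
    df.to_csv(TABLES / "interface_decomposition.tsv", sep="\t", index=False,
              float_format="%.4g")
    print("dimer interface decomposition (Å²):")
    print(df[["structure", "Sll", "Shh", "Smixed", "Sburied"]].to_string(index=False))
    ratio = df["Sll_ratio"].dropna().iloc[0]
    print(f"Sll ratio ha/nn: {ratio:.2f} (hydrophobic interface glue is "
          f"{ratio:.1f}x larger in the ha-like dimer)")

    rows = []
    for name, s in structures.items():
        found = all_contacts(s)
        for scope in ("all", "inter_chain", "intra_chain"):
            rows.append({"structure": name, "scope": scope,
                         **count_summary(found, scope=scope)})
    counts = pd.DataFrame(rows)
    counts.to_csv(TABLES / "contact_counts.tsv", sep="\t", index=False)
    inter = counts[counts["scope"] == "inter_chain"].set_index("structure")
    print("\ninter-chain contact counts:")
    print(inter.drop(columns="scope").to_string())
    print(f"wrote {TABLES / 'interface_decomposition.tsv'} and contact_counts.tsv")


if __name__ == "__main__":
    main()
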