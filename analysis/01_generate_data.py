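"""Generate the synthetic study inputs.

Emits the labeled sequence family (4 haloalkaliphile-like vs 22
neutrophile-like sequences of 550 residues), the two toy dimer structures
with planted interface/core features, the gap-free alignment, the pipeline
config and the ground-truth record, under results/synthetic/.
"""

import sys
from pathlib import Path

from haloadapt.study import write_study_bundle

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main() -> None:
    paths = write_study_bundle(SEED, OUT)
    print(f"synthetic study bundle (seed={SEED}):")
    for name, path in paths.items():
        print(f"  {name}: {path}")


if __name__ == "__main__":
    main()
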