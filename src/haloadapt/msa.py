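"""Subfamily-specific positions (SSPs) in a multiple sequence alignment.

An SSP is an alignment column conserved within each of two labeled
subfamilies but with different consensus residues between them — the kind of
position that carries habitat-adaptation signal (e.g. a lysine in
neutrophile sequences replaced by glutamate across haloalkaliphiles).  The
detector is a deterministic threshold rule: a column is flagged when both
within-group consensus frequencies reach τ, the consensus residues differ,
and the column is not too gappy.  A continuous specificity score
(freq_a + freq_b − 1) is emitted for every column for ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

GAP_CHARS = {"-", "."}


@dataclass
class MSA:
    ids: list[str]
    matrix: np.ndarray  # (n_sequences, n_columns) of single characters

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def read_alignment(text: str) -> MSA:
    """Read an aligned FASTA; all records must have equal length."""
    records = list(SeqIO.parse(StringIO(text), "fasta"))
    if not records:
        raise ValueError("no records in alignment")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    matrix = np.array([list(str(r.seq).upper()) for r in records])
    return MSA(ids=[r.id for r in records], matrix=matrix)


def write_alignment(msa: MSA) -> str:
    out = []
    for sid, row in zip(msa.ids, msa.matrix):
        out.append(f">{sid}\n{''.join(row)}")
    return "\n".join(out) + "\n"


@dataclass
class SspColumn:
    column: int          # 1-based alignment column
    consensus_a: str
    consensus_b: str
    freq_a: float
    freq_b: float
    gap_fraction: float
    score: float         # freq_a + freq_b - 1, in [-1, 1]
    flagged: bool


def _consensus(column_chars: np.ndarray) -> tuple[str, float]:
    """Most frequent non-gap residue and its frequency over the group size.

    Ties are broken alphabetically for determinism.
    """
    n = len(column_chars)
    values, counts = np.unique(column_chars, return_counts=True)
    best_char, best_count = "-", 0
    for ch, ct in zip(values, counts):
        if ch in GAP_CHARS:
            continue
        if ct > best_count or (ct == best_count and ch < best_char):
            best_char, best_count = str(ch), int(ct)
    return best_char, best_count / n if n else 0.0


def ssp_detect(msa: MSA, labels: dict[str, str], tau: float = 0.8,
               gap_max: float = 0.2) -> list[SspColumn]:
    """Score every column; flag subfamily-specific ones.

    `labels` maps sequence id to one of exactly two group names.  Groups with
    fewer than 2 sequences trigger a warning but the analysis proceeds.
    """
    groups = sorted(set(labels.values()))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    ga, gb = groups
    idx_a = [i for i, sid in enumerate(msa.ids) if labels.get(sid) == ga]
    idx_b = [i for i, sid in enumerate(msa.ids) if labels.get(sid) == gb]
    unlabeled = [sid for sid in msa.ids if sid not in labels]
    if unlabeled:
        raise ValueError(f"unlabeled sequences in alignment: {unlabeled[:5]}")
    if min(len(idx_a), len(idx_b)) < 2:
        import warnings
        warnings.warn("a group has fewer than 2 sequences; SSP calls will be weak")
    out = []
    for col in range(msa.n_columns):
        chars = msa.matrix[:, col]
        gap_fraction = float(np.isin(chars, list(GAP_CHARS)).mean())
        ca, fa = _consensus(chars[idx_a])
        cb, fb = _consensus(chars[idx_b])
        flagged = (fa >= tau and fb >= tau and ca != cb and ca != "-" and cb != "-"
                   and gap_fraction <= gap_max)
        out.append(SspColumn(column=col + 1, consensus_a=ca, consensus_b=cb,
                             freq_a=fa, freq_b=fb, gap_fraction=gap_fraction,
                             score=fa + fb - 1.0, flagged=flagged))
    return out


def column_to_reference_positions(msa: MSA, reference_id: str) -> dict[int, int]:
    """Map 1-based alignment columns to 1-based residue numbers of a
    reference (ungapped) sequence; columns gapped in the reference are absent."""
    try:
        row = msa.matrix[msa.ids.index(reference_id)]
    except ValueError:
        raise KeyError(f"reference id {reference_id!r} not in alignment")
    mapping = {}
    pos = 0
    for col, ch in enumerate(row, start=1):
        if ch not in GAP_CHARS:
            pos += 1
            mapping[col] = pos
    return mapping


def ssp_table(columns: list[SspColumn], group_a: str = "a", group_b: str = "b") -> pd.DataFrame:
    rows = [{
        "column": c.column,
        f"consensus_{group_a}": c.consensus_a, f"freq_{group_a}": c.freq_a,
        f"consensus_{group_b}": c.consensus_b, f"freq_{group_b}": c.freq_b,
        "gap_fraction": c.gap_fraction, "score": c.score, "flagged": c.flagged,
    } for c in columns]
    return pd.DataFrame(rows)
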