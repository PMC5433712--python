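"""Amino-acid composition statistics and group comparison.

Composition vectors (percent per residue type), group medians and quartiles,
a two-sided Mann-Whitney U test that is exact for small samples (the study
design of interest compares 4 haloalkaliphile sequences against 22
neutrophile sequences, far too small for asymptotics alone), percent
differences as reported in comparative-adaptation work, and isoelectric
point by Henderson-Hasselbalch charge bisection.

The exact Mann-Whitney p-value is the permutation p over all C(n_a+n_b, n_a)
group labelings with mid-rank ties; it is computed from the exact null
distribution of the rank sum (dynamic programming over the doubled mid-ranks,
which are integers), which is identical to full enumeration.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
from scipy import stats

AA20 = "ACDEFGHIKLMNPQRSTVWY"

EXACT_TOTAL_MAX = 30  # use the exact permutation distribution up to this n_a+n_b

#: EMBOSS pKa set used for net-charge and pI computation
PKA_SIDE = {"C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1}
PKA_NTERM = 8.6
PKA_CTERM = 3.6


def aa_composition(seq: str) -> dict[str, float]:
    """Percent of each of the 20 standard residues; non-standard letters are
    excluded from the denominator."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    counts = {aa: 0 for aa in AA20}
    n = 0
    for ch in seq:
        if ch in counts:
            counts[ch] += 1
            n += 1
    if n == 0:
        raise ValueError("sequence contains no standard residues")
    return {aa: 100.0 * c / n for aa, c in counts.items()}


def _exact_rank_sum_distribution(ranks2: np.ndarray, k: int) -> np.ndarray:
    """Number of k-subsets of `ranks2` (integer doubled mid-ranks) achieving
    each possible doubled rank sum; index = sum, value = count."""
    max_sum = int(ranks2.sum())
    # ways[j, s] = number of j-subsets summing to s
    ways = np.zeros((k + 1, max_sum + 1), dtype=np.int64)
    ways[0, 0] = 1
    for r in ranks2:
        r = int(r)
        for j in range(k, 0, -1):
            ways[j, r:] += ways[j - 1, : max_sum + 1 - r]
    return ways[k]


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U, p) with U for the first
    sample (number of (x, y) pairs where x ranks above y, mid-rank ties).

    Exact permutation p for n_x + n_y <= 30; normal approximation with tie
    correction and continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    U = r1 - n1 * (n1 + 1) / 2.0
    if n1 + n2 <= EXACT_TOTAL_MAX:
        ranks2 = np.rint(2 * ranks).astype(np.int64)  # mid-ranks are half-integers
        dist = _exact_rank_sum_distribution(ranks2, n1)
        total = comb(n1 + n2, n1)
        # doubled U for every achievable doubled rank sum
        sums2 = np.flatnonzero(dist)
        u2 = sums2 - n1 * (n1 + 1)
        u2_obs = int(round(2 * U))
        center = n1 * n2  # doubled mean of U
        extreme = np.abs(u2 - center) >= abs(u2_obs - center)
        p = float(dist[sums2[extreme]].sum()) / total
    else:
        _, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(p)
    return float(U), min(p, 1.0)


def group_summary(values, labels) -> dict[str, tuple[float, float, float]]:
    """Median and quartiles (Me, Q1, Q3; linear interpolation) per group."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    out = {}
    for g in pd.unique(labels):
        v = values[labels == g]
        if v.size == 0:
            continue
        q1, me, q3 = np.percentile(v, [25, 50, 75])
        out[str(g)] = (float(me), float(q1), float(q3))
    return out


def percent_difference(value: float, baseline: float) -> float:
    """Signed percent change of `value` relative to `baseline`:
    100 x (value - baseline) / baseline."""
    if baseline == 0:
        raise ValueError("baseline must be non-zero")
    return 100.0 * (value - baseline) / baseline


def percent_decrease(value: float, baseline: float) -> float:
    """Decrease of `value` below `baseline` as a positive percent of baseline
    (the \"x% lower\" convention)."""
    return -percent_difference(value, baseline)


def compare_groups(sequences: dict[str, str], labels: dict[str, str],
                   group_a: str, group_b: str, alpha: float = 0.05) -> pd.DataFrame:
    """Per-residue-type group comparison of composition.

    One row per residue type with Me/Q1/Q3 for both groups, the Mann-Whitney
    U statistic and two-sided p (group A first), a significance flag at
    `alpha`, and the percent difference of group medians (A relative to B).
    No multiple-testing correction is applied across the 20 types; p-values
    are reported raw.
    """
    comp = {sid: aa_composition(seq) for sid, seq in sequences.items()}
    ids_a = [sid for sid in sequences if labels.get(sid) == group_a]
    ids_b = [sid for sid in sequences if labels.get(sid) == group_b]
    if not ids_a or not ids_b:
        raise ValueError(f"both groups need members: {group_a}={len(ids_a)}, {group_b}={len(ids_b)}")
    rows = []
    for aa in AA20:
        va = np.array([comp[sid][aa] for sid in ids_a])
        vb = np.array([comp[sid][aa] for sid in ids_b])
        U, p = mann_whitney(va, vb)
        q1a, mea, q3a = np.percentile(va, [25, 50, 75])
        q1b, meb, q3b = np.percentile(vb, [25, 50, 75])
        rows.append({
            "residue": aa,
            f"median_{group_a}": mea, f"q1_{group_a}": q1a, f"q3_{group_a}": q3a,
            f"median_{group_b}": meb, f"q1_{group_b}": q1b, f"q3_{group_b}": q3b,
            "U": U, "p": p, "significant": p < alpha,
            "median_pct_diff": percent_difference(mea, meb) if meb != 0 else np.nan,
        })
    return pd.DataFrame(rows)


def net_charge(seq: str, pH: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH (side chains + termini)."""
    seq = seq.upper()
    pos = 10.0 ** (PKA_NTERM - pH) / (1.0 + 10.0 ** (PKA_NTERM - pH))
    neg = 10.0 ** (pH - PKA_CTERM) / (1.0 + 10.0 ** (pH - PKA_CTERM))
    for ch in seq:
        pka = PKA_SIDE.get(ch)
        if pka is None:
            continue
        if ch in "KRH":
            pos += 10.0 ** (pka - pH) / (1.0 + 10.0 ** (pka - pH))
        else:
            neg += 10.0 ** (pH - pka) / (1.0 + 10.0 ** (pH - pka))
    return pos - neg


def isoelectric_point(seq: str, tol: float = 1e-3) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14]."""
    if not seq:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    if net_charge(seq, lo) < 0:
        return lo
    if net_charge(seq, hi) > 0:
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
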