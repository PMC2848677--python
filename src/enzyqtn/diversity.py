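"""Nucleotide diversity, maize/teosinte ratios and a selection screen.

Nucleotide diversity pi is the average number of nucleotide differences per
site between two sequences, computed over all unordered pairs with pairwise
deletion of sites where either sequence carries a gap or an ambiguous base
(amplicon alignments have ragged ends).  For a candidate locus sequenced in
a domesticated panel and in its wild ancestor, the ratio pi_maize /
pi_teosinte is placed in a reference distribution of ratios from random
genes ("percent tail"): a ratio far in the lower tail signals loss of
diversity beyond the genome-wide domestication bottleneck, i.e. selection.
A 2x2 chi-square test quantifies allele-frequency shifts of a focal site
between the two panels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

_VALID = frozenset(b"ACGT")


def _to_matrix(alignment) -> np.ndarray:
    rows = []
    for rec in alignment:
        s = str(getattr(rec, "seq", rec)).upper().encode()
        rows.append(np.frombuffer(s, dtype="S1"))
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    return np.vstack(rows)


@dataclass
class PiResult:
    pi: float
    n_seq: int
    length: int
    n_pairs_used: int
    n_pairs_skipped: int


def nucleotide_diversity(alignment, deletion: str = "pairwise") -> PiResult:
    """Average pairwise differences per site for one alignment.

    ``deletion``: "pairwise" drops, per pair, the sites where either
    sequence is not an unambiguous A/C/G/T; "complete" restricts all pairs
    to columns valid in every sequence.  Pairs with no comparable site are
    skipped (and counted).
    """
    m = _to_matrix(alignment)
    n, length = m.shape
    if n < 2:
        raise ValueError("need at least 2 sequences")
    valid = np.isin(m, np.frombuffer(b"ACGT", dtype="S1"))
    if deletion == "complete":
        cols = valid.all(axis=0)
        m = m[:, cols]
        valid = valid[:, cols]
    elif deletion != "pairwise":
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    vals, used, skipped = [], 0, 0
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            comp = int(both.sum())
            if comp == 0:
                skipped += 1
                continue
            diff = int(np.sum((m[i] != m[j]) & both))
            vals.append(diff / comp)
            used += 1
    if skipped:
        warnings.warn(f"{skipped} sequence pair(s) had no comparable sites")
    pi = float(np.mean(vals)) if vals else np.nan
    return PiResult(pi, n, length, used, skipped)


def pooled_pi(parts) -> float:
    """Sites-weighted average of per-amplicon pi values.

    ``parts``: iterable of (pi, n_sites) for each amplicon of a locus.
    """
    parts = [(p, w) for p, w in parts if np.isfinite(p)]
    total = sum(w for _, w in parts)
    if total == 0:
        return np.nan
    return sum(p * w for p, w in parts) / total


def diversity_ratio(pi1: float, pi2: float) -> float:
    """pi_panel1 / pi_panel2; NaN (undefined) when the denominator is 0."""
    if pi2 == 0 or not np.isfinite(pi2):
        warnings.warn("reference-panel pi is zero; ratio undefined")
        return np.nan
    return pi1 / pi2


def percent_tail(ratio: float, reference_ratios) -> float:
    """Percentile of ``ratio`` in the reference distribution.

    100 * #{reference <= ratio} / #reference, ties counted as <=.
    """
    ref = np.asarray(reference_ratios, dtype=float)
    ref = ref[np.isfinite(ref)]
    if len(ref) == 0:
        raise ValueError("empty reference distribution")
    return 100.0 * float(np.sum(ref <= ratio)) / len(ref)


@dataclass
class LocusDiversity:
    locus: str
    pi_panel1: float
    pi_panel2: float
    ratio: float
    percent_tail: float
    n_seq_panel1: int
    n_seq_panel2: int


def locus_diversity(locus: str, alignment_panel1, alignment_panel2,
                    reference_ratios, deletion: str = "pairwise") -> LocusDiversity:
    """Per-locus diversity contrast between two panels with tail placement."""
    r1 = nucleotide_diversity(alignment_panel1, deletion)
    r2 = nucleotide_diversity(alignment_panel2, deletion)
    ratio = diversity_ratio(r1.pi, r2.pi)
    tail = percent_tail(ratio, reference_ratios) if np.isfinite(ratio) else np.nan
    return LocusDiversity(locus, r1.pi, r2.pi, ratio, tail, r1.n_seq, r2.n_seq)


@dataclass
class FreqShiftResult:
    chi2: float
    p: float
    fisher_p: float
    min_expected: float
    sparse: bool


def allele_freq_shift(table) -> FreqShiftResult:
    """Pearson chi-square (df=1, no continuity correction) on a 2x2
    panel-by-allele count table; Fisher's exact P is always reported, and
    expected counts below 5 raise a warning recommending it."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of nonnegative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    if np.array_equal(t, np.zeros_like(t)):
        raise ValueError("empty table")
    chi2, p, _, expected = stats.chi2_contingency(t, correction=False)
    # identical frequencies give chi2 = 0, P = 1
    _, fisher_p = stats.fisher_exact(np.round(t).astype(int))
    min_exp = float(expected.min())
    sparse = min_exp < 5
    if sparse:
        warnings.warn("expected count < 5; prefer the exact test")
    return FreqShiftResult(float(chi2), float(p), float(fisher_p), min_exp, sparse)
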