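"""Pairwise linkage disequilibrium (r2) within a locus and its decay.

For fully inbred lines each sample contributes one haplotype, read directly
off the homozygous dosage, so the classical haplotype-count definition

    r2 = D^2 / (pA pa pB pb),   D = pAB - pA pB

applies without phasing and coincides with the squared Pearson correlation
of dosages.  INDELs are treated as biallelic presence/absence markers.
Distances come from 1-based positions within the gene.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix


def _r2_from_haplotypes(a: np.ndarray, b: np.ndarray) -> float | None:
    """r2 from two 0/1 haplotype vectors; None when either is monomorphic."""
    p_a = a.mean()
    p_b = b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return None
    p_ab = np.mean(a * b)
    d = p_ab - p_a * p_b
    return float(d * d / (p_a * (1 - p_a) * p_b * (1 - p_b)))


def pairwise_r2(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """All-pairs r2 for the markers of one locus.

    Heterozygous or missing calls are excluded pairwise (with a warning for
    heterozygotes, which an inbred panel should not contain); pairs where
    either marker is monomorphic on the shared samples are skipped and
    counted in ``.attrs['skipped_monomorphic']``.
    """
    d = genotypes.dosage.to_numpy(dtype=float)
    pos = genotypes.markers["position"].to_numpy()
    ids = list(genotypes.marker_ids)
    if np.any(d[np.isfinite(d)] == 1):
        warnings.warn("heterozygous calls present; excluded pairwise from r2")
    usable = np.isfinite(d) & (d != 1)
    hap = d / 2.0
    rows, skipped = [], 0
    m = len(ids)
    for i in range(m):
        for j in range(i + 1, m):
            ok = usable[:, i] & usable[:, j]
            if ok.sum() < 2:
                skipped += 1
                continue
            r2 = _r2_from_haplotypes(hap[ok, i], hap[ok, j])
            if r2 is None:
                skipped += 1
                continue
            rows.append((ids[i], ids[j], int(abs(pos[i] - pos[j])), r2, int(ok.sum())))
    out = pd.DataFrame(rows, columns=["marker_i", "marker_j", "distance", "r2", "n"])
    out.attrs["skipped_monomorphic"] = skipped
    return out


def ld_decay(pairs: pd.DataFrame, bin_width_bp: int) -> pd.DataFrame:
    """Mean r2 per half-open distance bin [k*w, (k+1)*w); empty bins absent."""
    if bin_width_bp <= 0:
        raise ValueError("bin width must be positive")
    df = pairs.copy()
    df["bin"] = df["distance"] // bin_width_bp
    g = df.groupby("bin")["r2"].agg(["mean", "count"])
    g.columns = ["mean_r2", "n_pairs"]
    g["bin_start"] = g.index * bin_width_bp
    g["bin_end"] = (g.index + 1) * bin_width_bp
    return g[["bin_start", "bin_end", "mean_r2", "n_pairs"]].reset_index(drop=True)
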