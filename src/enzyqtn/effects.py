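"""Genotype-class means and additive/dominance decomposition for one marker.

With class means m(hom1), m(het), m(hom2), the additive effect is
a = (m(hom1) - m(hom2)) / 2 and the dominance deviation is
d = m(het) - (m(hom1) + m(hom2)) / 2; d/a summarises the mode of action
(0 additive, +/-1 complete dominance).  By default hom1 is the homozygote
with the higher mean, giving a >= 0; pass ``allele_order`` to fix the
orientation instead (swapping it flips the sign of a and of d/a, not |d/a|).

Inbred and hybrid panels are pooled after z-scoring the activity within
each genetic background, so tester effects do not masquerade as marker
effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf


def standardize_within_background(y: pd.Series, background: pd.Series) -> pd.Series:
    """Z-score the trait separately within each background group."""
    df = pd.DataFrame({"y": y, "bg": background.loc[y.index]})
    out = df.groupby("bg")["y"].transform(lambda v: (v - v.mean()) / v.std(ddof=1))
    out.name = y.name
    return out


def class_means(y: pd.Series, marker: pd.Series) -> pd.DataFrame:
    """Mean and count of the trait per dosage class (0, 1, 2).

    Absent classes are reported with count 0 and NaN mean.
    """
    df = pd.DataFrame({"y": y, "x": marker.loc[y.index]}).dropna()
    g = df.groupby("x")["y"].agg(["mean", "count"])
    out = g.reindex([0.0, 1.0, 2.0])
    out["count"] = out["count"].fillna(0).astype(int)
    out.index = pd.Index(["hom_ref", "het", "hom_alt"], name="class")
    return out


@dataclass
class EffectDecomposition:
    mean_hom1: float
    mean_het: float
    mean_hom2: float
    n_hom1: int
    n_het: int
    n_hom2: int
    a: float
    d: float
    d_over_a: float
    p_a: float = np.nan
    p_d: float = np.nan


def additive_dominance(means, counts=None, allele_order: str | None = None) -> EffectDecomposition:
    """Additive effect and dominance deviation from three class means.

    ``means`` may be the DataFrame from :func:`class_means` or a sequence
    (hom_ref, het, hom_alt).  ``allele_order``: None (hom1 = higher-mean
    homozygote, the reporting convention), "ref_first" or "alt_first".
    """
    if isinstance(means, pd.DataFrame):
        m = means["mean"]
        c = means["count"]
        hom_ref, het, hom_alt = float(m["hom_ref"]), float(m["het"]), float(m["hom_alt"])
        n_ref, n_het, n_alt = int(c["hom_ref"]), int(c["het"]), int(c["hom_alt"])
    else:
        hom_ref, het, hom_alt = (float(v) for v in means)
        n_ref, n_het, n_alt = (int(v) for v in counts) if counts is not None else (0, 0, 0)
    if not (np.isfinite(hom_ref) and np.isfinite(hom_alt) and np.isfinite(het)):
        raise ValueError("a/d undefined: a genotype class is absent")
    if allele_order is None:
        order_ref_first = hom_ref >= hom_alt
    elif allele_order in ("ref_first", "alt_first"):
        order_ref_first = allele_order == "ref_first"
    else:
        raise ValueError("allele_order must be None, 'ref_first' or 'alt_first'")
    m1, m2 = (hom_ref, hom_alt) if order_ref_first else (hom_alt, hom_ref)
    n1, n2 = (n_ref, n_alt) if order_ref_first else (n_alt, n_ref)
    a = (m1 - m2) / 2.0
    d = het - (m1 + m2) / 2.0
    d_over_a = d / a if a != 0 else np.nan
    return EffectDecomposition(m1, het, m2, n1, n_het, n2, a, d, d_over_a)


def _letter_groups(means: pd.Series, pmat: pd.DataFrame, alpha: float) -> dict:
    """Compact-letter display: classes not significantly different share a
    letter; non-significant pairs are merged transitively."""
    labels = list(means.sort_values(ascending=False).index)
    parent = {l: l for l in labels}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i, li in enumerate(labels):
        for lj in labels[i + 1:]:
            if pmat.loc[li, lj] >= alpha:
                parent[find(lj)] = find(li)
    roots = []
    for l in labels:
        r = find(l)
        if r not in roots:
            roots.append(r)
    letters = {r: chr(ord("a") + k) for k, r in enumerate(roots)}
    return {l: letters[find(l)] for l in labels}


def test_effects(y: pd.Series, marker: pd.Series, background: pd.Series | None = None,
                 alpha: float = 0.01) -> dict:
    """Fixed-effects tests of the marker's additive and dominance contrasts.

    Fits y ~ C(class) (+ C(background)), tests the a and d contrasts of the
    class means with the pooled residual variance, and assigns significance
    letters to classes by pairwise t tests at ``alpha``.
    """
    df = pd.DataFrame({"y": y, "x": marker.loc[y.index]}).dropna()
    df["cls"] = df["x"].map({0.0: "hom_ref", 1.0: "het", 2.0: "hom_alt"})
    rhs = "C(cls)"
    if background is not None:
        df["bg"] = background.loc[df.index]
        rhs += " + C(bg)"
    fit = smf.ols(f"y ~ {rhs}", data=df).fit()
    mse = fit.mse_resid
    dfree = int(fit.df_resid)
    cm = df.groupby("cls")["y"].agg(["mean", "count"])
    present = list(cm.index)

    def contrast_p(weights: dict) -> float:
        est = sum(w * cm.loc[c, "mean"] for c, w in weights.items())
        var = mse * sum(w * w / cm.loc[c, "count"] for c, w in weights.items())
        t = est / np.sqrt(var)
        return float(2 * stats.t.sf(abs(t), dfree))

    p_a = p_d = np.nan
    if {"hom_ref", "hom_alt"} <= set(present):
        p_a = contrast_p({"hom_ref": 0.5, "hom_alt": -0.5})
        if "het" in present:
            p_d = contrast_p({"het": 1.0, "hom_ref": -0.5, "hom_alt": -0.5})

    pmat = pd.DataFrame(1.0, index=present, columns=present)
    for i, ci in enumerate(present):
        for cj in present[i + 1:]:
            diff = cm.loc[ci, "mean"] - cm.loc[cj, "mean"]
            se = np.sqrt(mse * (1.0 / cm.loc[ci, "count"] + 1.0 / cm.loc[cj, "count"]))
            p = float(2 * stats.t.sf(abs(diff / se), dfree))
            pmat.loc[ci, cj] = pmat.loc[cj, ci] = p
    letters = _letter_groups(cm["mean"], pmat, alpha)

    decomp = None
    if {"hom_ref", "het", "hom_alt"} <= set(present):
        decomp = additive_dominance(class_means(df["y"], df["x"]))
        decomp.p_a, decomp.p_d = p_a, p_d
    return {
        "class_means": cm,
        "p_a": p_a,
        "p_d": p_d,
        "letters": letters,
        "pairwise_p": pmat,
        "decomposition": decomp,
        "model": fit,
    }
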