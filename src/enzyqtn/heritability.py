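"""Genetic-effect ANOVA, broad-sense heritability and co-regulation summaries.

For a replicated panel of inbred lines the one-way (taxa) ANOVA partitions
activity variance between and within lines.  On a balanced design with r
replicates per line the expected mean squares give the variance components

    sigma2_G = max(0, (MS_G - MS_E) / r),   sigma2_E = MS_E,

and broad-sense heritability H2 = sigma2_G / (sigma2_G + sigma2_E).  The
positive correlation among the enzymes is summarised by the per-sample mean
of z-scored activities (the "Mean-STD" trait); subtracting that row mean
from each enzyme yields normalized enzyme-specific activities whose
heritability excludes the shared co-regulation component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .standardize import line_means, zscore_by_enzyme


@dataclass
class OneWayAnova:
    table: pd.DataFrame  # rows: between, within, total; cols: SS, df, MS, F, P
    ms_g: float
    ms_e: float
    f: float
    p: float
    degenerate: bool = False


def anova_one_way(values, groups) -> OneWayAnova:
    """One-way fixed-effects ANOVA of ``values`` on group labels."""
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "g": np.asarray(groups)})
    df = df.dropna()
    counts = df.groupby("g")["y"].count()
    if (counts == 0).any() or len(counts) < 2:
        raise ValueError("need >= 2 groups, each with >= 1 observation")
    n = len(df)
    k = len(counts)
    if n - k < 2:
        raise ValueError("need >= 2 residual degrees of freedom")
    grand = df["y"].mean()
    means = df.groupby("g")["y"].mean()
    ss_between = float((counts * (means - grand) ** 2).sum())
    ss_within = float(((df["y"] - means.loc[df["g"]].to_numpy()) ** 2).sum())
    df_b, df_w = k - 1, n - k
    ms_g, ms_e = ss_between / df_b, ss_within / df_w
    degenerate = False
    if ms_e == 0:
        degenerate = True
        f = np.inf if ms_g > 0 else 0.0
        p = 0.0 if ms_g > 0 else 1.0
    else:
        f = ms_g / ms_e
        p = float(stats.f.sf(f, df_b, df_w))
    table = pd.DataFrame(
        {
            "SS": [ss_between, ss_within, ss_between + ss_within],
            "df": [df_b, df_w, n - 1],
            "MS": [ms_g, ms_e, np.nan],
            "F": [f, np.nan, np.nan],
            "P": [p, np.nan, np.nan],
        },
        index=["between", "within", "total"],
    )
    return OneWayAnova(table, ms_g, ms_e, f, p, degenerate)


@dataclass
class HeritabilityResult:
    enzyme: str
    p_genetic: float
    ms_g: float
    ms_e: float
    sigma2_G_hat: float
    sigma2_E_hat: float
    h2: float
    degenerate: bool = False


def broad_sense_h2(ms_g: float, ms_e: float, r: float, enzyme: str = "") -> HeritabilityResult:
    """Variance components and H2 from one-way mean squares at r reps/line.

    Negative genetic-variance estimates are truncated to zero.  For
    unbalanced designs pass the harmonic-mean number of replicates.
    """
    if r < 2:
        raise ValueError("need r >= 2 replicates per line")
    degenerate = ms_e <= 0
    if degenerate:
        s2g = max(0.0, ms_g)
        h2 = 1.0 if s2g > 0 else np.nan
        return HeritabilityResult(enzyme, np.nan, ms_g, ms_e, s2g, max(ms_e, 0.0), h2, True)
    s2g = max(0.0, (ms_g - ms_e) / r)
    s2e = ms_e
    return HeritabilityResult(enzyme, np.nan, ms_g, ms_e, s2g, s2e, s2g / (s2g + s2e))


def heritability_from_matrix(matrix: pd.DataFrame, enzyme: str) -> HeritabilityResult:
    """One-way (line) ANOVA + H2 for one enzyme column of a (line, rep) matrix."""
    col = matrix[enzyme].dropna()
    lines = col.index.get_level_values("line")
    reps = col.groupby(lines).count()
    r = float(len(reps) / (1.0 / reps).sum())  # harmonic mean
    if reps.nunique() > 1:
        warnings.warn(f"{enzyme}: unbalanced replication, using harmonic-mean r={r:.3g}")
    a = anova_one_way(col.to_numpy(), lines.to_numpy())
    res = broad_sense_h2(a.ms_g, a.ms_e, r, enzyme)
    res.p_genetic = a.p
    res.degenerate = res.degenerate or a.degenerate
    return res


def mean_std_activity(matrix: pd.DataFrame) -> pd.Series:
    """Per-sample mean of the available z-scored enzyme activities."""
    out = matrix.mean(axis=1, skipna=True)
    out.name = "mean_std"
    out.attrs["n_enzymes"] = matrix.notna().sum(axis=1)
    return out


def normalize_enzyme_specific(matrix: pd.DataFrame) -> pd.DataFrame:
    """Residual activity after removing each sample's mean across enzymes.

    Output rows have mean 0 (over the enzymes observed in that row); this is
    the enzyme-specific variation not attributable to shared co-regulation.
    """
    out = matrix.sub(matrix.mean(axis=1, skipna=True), axis=0)
    out.attrs = dict(matrix.attrs)
    out.attrs["normalized"] = "enzyme_specific"
    return out


def heritability_report(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-enzyme genetic-effect P, raw H2 and normalized H2, plus the
    Mean-STD activity row — the standard summary for a replicated panel.

    ``matrix`` is the standardized (line, rep) x enzyme activity matrix; it
    is z-scored per enzyme internally so scales are comparable.
    """
    z = zscore_by_enzyme(matrix)
    specific = normalize_enzyme_specific(z)
    rows = []
    for enzyme in z.columns:
        raw = heritability_from_matrix(z, enzyme)
        norm = heritability_from_matrix(specific, enzyme)
        rows.append((enzyme, raw.p_genetic, raw.h2, norm.h2))
    mstd = heritability_from_matrix(mean_std_activity(z).to_frame("mean_std"), "mean_std")
    rows.append(("Mean-STD activity", mstd.p_genetic, mstd.h2, np.nan))
    return pd.DataFrame(rows, columns=["enzyme", "P_genetic", "H2_raw", "H2_norm"]).set_index("enzyme")


def correlation_matrix(line_mean_table: pd.DataFrame):
    """Pairwise Pearson correlations between enzyme columns.

    Returns (r, P, n) DataFrames; r has unit diagonal, P from the t
    transform of r.  Pairs are computed on complete observations
    (pairwise deletion) and need at least 3 of them.
    """
    cols = list(line_mean_table.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.nan, index=cols, columns=cols)
    n = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    for i in range(k):
        n.iloc[i, i] = line_mean_table[cols[i]].notna().sum()
        for j in range(i + 1, k):
            pair = line_mean_table[[cols[i], cols[j]]].dropna()
            if len(pair) < 3:
                raise ValueError(f"fewer than 3 paired observations for {cols[i]}-{cols[j]}")
            rr, pp = stats.pearsonr(pair[cols[i]], pair[cols[j]])
            r.iloc[i, j] = r.iloc[j, i] = rr
            p.iloc[i, j] = p.iloc[j, i] = pp
            n.iloc[i, j] = n.iloc[j, i] = len(pair)
    return r, p, n


def reproduce_published_heritability(long_table: pd.DataFrame):
    """Heritability and correlation summaries from a transcribed replicated
    activity panel.

    ``long_table`` holds one row per measurement with columns line, enzyme,
    rep, activity (already plate-standardized, e.g. a transcription of a
    published replicated panel).  Returns (heritability report, correlation
    r matrix) — the per-enzyme genetic-effect P, raw and normalized H2 plus
    the Mean-STD activity row, and the all-samples Pearson correlations.
    """
    need = {"line", "enzyme", "rep", "activity"}
    if not need <= set(long_table.columns):
        raise ValueError(f"table needs columns {sorted(need)}")
    matrix = long_table.pivot_table(index=["line", "rep"], columns="enzyme", values="activity")
    report = heritability_report(matrix)
    r, p, n = correlation_matrix(zscore_by_enzyme(matrix))
    return report, r


def correlation_report(matrix: pd.DataFrame):
    """Correlations over all samples' line x rep values (the published
    convention: every sample counts, e.g. 8 lines x 5 reps = 40)."""
    return correlation_matrix(matrix)


def anova_two_way(values, factor_a, factor_b, interaction: bool = True,
                  names=("A", "B"), covariate_b: bool = False) -> dict:
    """Fixed-effects two-way ANOVA (or ANCOVA when ``covariate_b``).

    Returns both sequential (type 1, A then B then A:B) and each-term-last
    (type 2) sums of squares.  When the design has empty cells the
    interaction term is dropped and flagged.
    """
    na, nb = names
    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       na: np.asarray(factor_a), nb: np.asarray(factor_b)}).dropna()
    b_term = nb if covariate_b else f"C({nb})"
    dropped = False
    if interaction and not covariate_b:
        cells = pd.crosstab(df[na], df[nb])
        if (cells == 0).any().any():
            warnings.warn("empty cells: interaction dropped")
            interaction, dropped = False, True
    rhs = f"C({na}) + {b_term}"
    if interaction:
        rhs += f" + C({na}):{b_term}"
    fit = smf.ols(f"y ~ {rhs}", data=df).fit()
    seq = anova_lm(fit, typ=1)
    marg = anova_lm(fit, typ=2)
    return {
        "sequential": seq,
        "each_term_last": marg,
        "model": fit,
        "interaction_dropped": dropped,
    }
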