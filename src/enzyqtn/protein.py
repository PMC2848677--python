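"""Two-factor model of total enzyme activity: causal SNP plus protein level.

Total activity can vary because the enzyme molecule differs (the amino-acid
substitution tagged by the candidate SNP) or because there is more or less
enzyme protein.  This module quantifies both routes: the correlation of
activity with immunoblot protein quantity, protein-normalized specific
activity, and a sequential ANOVA/ANCOVA of activity on the SNP genotype
(categorical) and protein quantity (continuous covariate).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .heritability import anova_two_way


def protein_activity_correlation(records: pd.DataFrame):
    """Pearson correlation of per-line mean activity and protein quantity.

    ``records`` needs columns line, activity, protein; replicate rows are
    averaged per line first.  Returns (r, P, n_lines).
    """
    per_line = records.groupby("line")[["activity", "protein"]].mean().dropna()
    if len(per_line) < 3:
        raise ValueError("need at least 3 lines")
    r, p = stats.pearsonr(per_line["activity"], per_line["protein"])
    return float(r), float(p), len(per_line)


def specific_activity(activity, protein_quantity):
    """Activity per unit protein; non-positive protein flagged as NaN."""
    act = np.asarray(activity, dtype=float)
    prot = np.asarray(protein_quantity, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(prot > 0, act / prot, np.nan)
    if isinstance(activity, pd.Series):
        return pd.Series(out, index=activity.index, name="specific_activity")
    return out if out.ndim else float(out)


def two_factor_anova(activity, marker, protein_quantity) -> dict:
    """Sequential ANOVA of activity ~ SNP genotype + protein covariate.

    The SNP enters first as a categorical factor (all observed dosage
    classes), protein second as a single-df continuous covariate; each-term-
    last SS are reported alongside.  Returns the dict from
    :func:`enzyqtn.heritability.anova_two_way` whose tables carry SS, F, P
    per term.
    """
    marker = pd.Series(marker).astype(float)
    return anova_two_way(
        activity,
        marker.map({0.0: "hom_ref", 1.0: "het", 2.0: "hom_alt"}),
        np.asarray(protein_quantity, dtype=float),
        interaction=False,
        names=("SNP", "protein"),
        covariate_b=True,
    )
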