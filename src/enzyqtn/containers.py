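"""Shared in-memory containers for genotype and ground-truth data."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

MARKER_COLUMNS = ["locus", "position", "alleles", "type"]


@dataclass
class GenotypeMatrix:
    """Samples x markers minor-allele dosage with marker metadata.

    ``dosage`` is a samples-by-markers DataFrame holding the minor-allele
    dosage (0, 1 or 2; NaN for missing calls).  Fully inbred panels carry no
    dosage-1 calls.  ``markers`` is indexed by marker id and carries at least
    ``locus``, 1-based ``position``, ``alleles`` and ``type`` (SNP/INDEL).
    """

    dosage: pd.DataFrame
    markers: pd.DataFrame
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing:
            raise ValueError(f"marker metadata lacks columns: {missing}")
        if not self.markers.index.equals(pd.Index(self.dosage.columns)):
            raise ValueError("marker metadata index must match dosage columns")

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosage.index

    @property
    def marker_ids(self) -> pd.Index:
        return self.dosage.columns

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def maf(self) -> pd.Series:
        """Minor-allele frequency per marker over non-missing calls.

        Each non-missing sample contributes one allele observation for an
        inbred (dosage/2 in {0, 1}); heterozygous calls contribute 1/2.
        """
        freq = self.dosage.mean(axis=0, skipna=True) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def is_inbred(self) -> bool:
        vals = self.dosage.to_numpy(dtype=float)
        return not np.any(vals[np.isfinite(vals)] == 1)

    def subset_samples(self, ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage.loc[ids], self.markers.copy(), dict(self.extras))

    def subset_markers(self, ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage[list(ids)], self.markers.loc[list(ids)], dict(self.extras))


def _as_enzyme_map(value, enzymes: list[str], name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        out = {e: float(value.get(e, 0.0)) for e in enzymes}
    else:
        out = {e: float(value) for e in enzymes}
    return out


@dataclass
class TruthRecord:
    """Ground truth behind a simulated activity panel.

    Per-enzyme genetic variance ``sigma2_G`` and residual variance
    ``sigma2_E`` (squared activity units), loadings ``coreg_lambda`` of the
    shared co-regulation factor, allele-substitution effects ``beta_causal``
    of the causal marker (per unit of dosage), the admixture matrix
    ``admixture_Q`` (lines x subpopulations, rows summing to 1), per-panel
    mutation parameters ``theta_panel`` and the master ``seed``.
    """

    sigma2_G: dict[str, float]
    sigma2_E: dict[str, float]
    coreg_lambda: dict[str, float]
    beta_causal: dict[str, float]
    admixture_Q: pd.DataFrame | None = None
    theta_panel: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for e, v in self.sigma2_G.items():
            if v < 0:
                raise ValueError(f"sigma2_G[{e}] must be >= 0")
        for e, v in self.sigma2_E.items():
            if v <= 0:
                raise ValueError(f"sigma2_E[{e}] must be > 0")
        if self.admixture_Q is not None:
            sums = self.admixture_Q.sum(axis=1).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-12):
                raise ValueError("admixture rows must sum to 1")

    @property
    def enzymes(self) -> list[str]:
        return list(self.sigma2_G)

    @classmethod
    def make(
        cls,
        enzymes,
        sigma2_G=1.0,
        sigma2_E=1.0,
        coreg_lambda=0.0,
        beta_causal=0.0,
        admixture_Q=None,
        theta_panel=None,
        seed=0,
    ) -> "TruthRecord":
        """Build a record broadcasting scalars over the enzyme list."""
        enzymes = list(enzymes)
        return cls(
            sigma2_G=_as_enzyme_map(sigma2_G, enzymes, "sigma2_G"),
            sigma2_E=_as_enzyme_map(sigma2_E, enzymes, "sigma2_E"),
            coreg_lambda=_as_enzyme_map(coreg_lambda, enzymes, "coreg_lambda"),
            beta_causal=_as_enzyme_map(beta_causal, enzymes, "beta_causal"),
            admixture_Q=admixture_Q,
            theta_panel=dict(theta_panel) if theta_panel else None,
            seed=int(seed),
        )

    def h2(self, enzyme: str) -> float:
        """Broad-sense heritability implied by the variance components.

        The shared co-regulation factor is a line-level (genetic) source of
        variance, so it counts toward the numerator.
        """
        g = self.sigma2_G[enzyme] + self.coreg_lambda[enzyme] ** 2
        return g / (g + self.sigma2_E[enzyme])
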