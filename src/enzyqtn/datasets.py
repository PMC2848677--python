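"""Small published reference tables bundled with the package."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str, **kwargs) -> pd.DataFrame:
    with resources.files("enzyqtn.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", comment="#", **kwargs)


def snp3593_class_means() -> pd.DataFrame:
    """Published genotype-class means (n, mean standardized IDH activity)
    at the focal idh SNP3593, indexed by genotype (AA/AT/TT)."""
    return _load("idh_snp3593_classes.tsv").set_index("genotype")


def ccm_locus_diversity() -> pd.DataFrame:
    """Published per-locus pi for 17 CCM loci in maize and teosinte panels,
    with maize/teosinte ratios and their percent tail among random genes."""
    return _load("ccm_locus_diversity.tsv").set_index("locus")
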