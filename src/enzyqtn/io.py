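"""Readers and writers for the pipeline's plain-text formats.

Activity tables and genotype matrices travel as tab-separated text,
alignments as FASTA (Biopython), ground truth as JSON.  Genotypes may also
be read from VCF (dosage derived from GT) when cyvcf2 is available.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

from .containers import GenotypeMatrix, TruthRecord


def write_activity_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_activity_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"line": "string", "plate": "string", "well": "string"})
    df["line"] = df["line"].astype(object).where(df["line"].notna(), None)
    return df


def write_genotypes(gm: GenotypeMatrix, prefix) -> None:
    """Dosage matrix to ``<prefix>.dosage.tsv`` and marker metadata sidecar
    to ``<prefix>.markers.tsv``."""
    prefix = str(prefix)
    gm.dosage.to_csv(prefix + ".dosage.tsv", sep="\t")
    gm.markers.to_csv(prefix + ".markers.tsv", sep="\t")


def read_genotypes(prefix) -> GenotypeMatrix:
    prefix = str(prefix)
    dosage = pd.read_csv(prefix + ".dosage.tsv", sep="\t", index_col=0)
    markers = pd.read_csv(prefix + ".markers.tsv", sep="\t", index_col=0)
    return GenotypeMatrix(dosage, markers)


def write_alignment(alignment, path) -> None:
    AlignIO.write(alignment, str(path), "fasta")


def read_alignment(path):
    return AlignIO.read(str(path), "fasta")


def read_reference_ratios(path) -> np.ndarray:
    """One-column plain-text reference distribution (e.g. random-gene
    diversity ratios); lines starting with '#' are ignored."""
    vals = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        vals.append(float(line))
    return np.asarray(vals)


def write_truth(truth: TruthRecord, path) -> None:
    payload = {
        "sigma2_G": truth.sigma2_G,
        "sigma2_E": truth.sigma2_E,
        "coreg_lambda": truth.coreg_lambda,
        "beta_causal": truth.beta_causal,
        "admixture_Q": None
        if truth.admixture_Q is None
        else {
            "index": list(truth.admixture_Q.index),
            "columns": list(truth.admixture_Q.columns),
            "values": truth.admixture_Q.to_numpy().tolist(),
        },
        "theta_panel": truth.theta_panel,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path) -> TruthRecord:
    payload = json.loads(Path(path).read_text())
    q = payload["admixture_Q"]
    if q is not None:
        q = pd.DataFrame(q["values"], index=q["index"], columns=q["columns"])
    return TruthRecord(
        sigma2_G=payload["sigma2_G"],
        sigma2_E=payload["sigma2_E"],
        coreg_lambda=payload["coreg_lambda"],
        beta_causal=payload["beta_causal"],
        admixture_Q=q,
        theta_panel=payload["theta_panel"],
        seed=payload["seed"],
    )


def read_vcf(path) -> GenotypeMatrix:
    """Genotypes from a VCF; minor-allele dosage derived from GT calls."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF input requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        alt = var.ALT[0] if var.ALT else "."
        dos = []
        for gt in var.genotypes:
            alleles = [a for a in gt[:-1] if a >= 0]
            dos.append(sum(1 for a in alleles if a > 0) * (2 / max(len(alleles), 1)) if alleles else np.nan)
        rows.append(dos)
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        vtype = "SNP" if len(var.REF) == 1 and len(alt) == 1 else "INDEL"
        meta.append((mid, var.CHROM, var.POS, f"{var.REF}/{alt}", vtype))
    meta_df = pd.DataFrame(meta, columns=["marker_id", "locus", "position", "alleles", "type"]).set_index("marker_id")
    dosage = pd.DataFrame(np.array(rows, dtype=float).T, index=pd.Index(samples, name="line"), columns=meta_df.index)
    # orient to the minor allele
    freq = dosage.mean(axis=0, skipna=True) / 2.0
    flip = freq > 0.5
    dosage.loc[:, flip] = 2.0 - dosage.loc[:, flip]
    return GenotypeMatrix(dosage, meta_df)
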