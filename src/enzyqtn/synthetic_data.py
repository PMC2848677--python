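"""Synthetic inputs with the statistical structure of a candidate-gene
enzyme-activity study in maize.

The generators emulate, with known ground truth: an admixed panel of fully
homozygous inbred lines typed at unlinked background SNPs
(Balding-Nichols subpopulation allele frequencies); a candidate gene whose
polymorphisms fall into a few major haplotypes containing one causal site;
replicated 96-well enzyme assay plates (40 experimental wells, 4 common
reference wells, 4 blanks per plate) for a set of co-regulated enzymes;
F1 testcross hybrids; and per-locus sequence panels with differing
mutation parameters for a maize-vs-teosinte style diversity contrast.

Every generator is deterministic in its seed: identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import GenotypeMatrix, TruthRecord

REFERENCE_LINE = "REF"
_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _rng(seed: int, stream: int) -> np.random.Generator:
    # one master seed; independent deterministic sub-streams per generator
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(int(stream),)))


def gen_population(
    n_lines: int,
    n_markers: int,
    k_subpops: int = 3,
    divergence: float = 0.2,
    seed: int = 0,
    ancestral_freq: float | None = None,
    admixture_alpha: float = 0.2,
    locus: str = "background",
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Admixed panel of inbred lines typed at unlinked biallelic markers.

    Subpopulation allele frequencies follow a Balding-Nichols draw around a
    common ancestral frequency: Beta(p(1-F)/F, (1-p)(1-F)/F) with
    F = ``divergence``, so Var(p_k) = F p(1-p).  Each line has a Dirichlet
    admixture vector; per marker, the line samples an ancestry according to
    its admixture and then a single allele from that subpopulation's
    frequency, doubled to a homozygous dosage (inbreds carry no dosage 1).

    Returns the genotype matrix and the lines-by-subpopulations admixture Q.
    """
    if n_lines < 2 or n_markers < 1:
        raise ValueError("need n_lines >= 2 and n_markers >= 1")
    if not (0.0 <= divergence < 1.0):
        raise ValueError(f"divergence must lie in [0, 1), got {divergence}")
    rng = _rng(seed, 1)

    if ancestral_freq is None:
        p_anc = rng.uniform(0.1, 0.9, size=n_markers)
    else:
        p_anc = np.full(n_markers, float(ancestral_freq))
    if divergence == 0.0:
        p_sub = np.tile(p_anc, (k_subpops, 1))
    else:
        a = p_anc * (1.0 - divergence) / divergence
        b = (1.0 - p_anc) * (1.0 - divergence) / divergence
        p_sub = rng.beta(a, b, size=(k_subpops, n_markers))

    q = rng.dirichlet(np.full(k_subpops, admixture_alpha), size=n_lines)
    # ancestry of each (line, marker), then one allele drawn and doubled
    cum = np.cumsum(q, axis=1)
    u = rng.random((n_lines, n_markers))
    ancestry = (u[:, :, None] > cum[:, None, :]).sum(axis=2)
    p_line = p_sub[ancestry, np.arange(n_markers)[None, :]]
    dosage = 2 * (rng.random((n_lines, n_markers)) < p_line).astype(np.int64)

    lines = [f"L{i:04d}" for i in range(n_lines)]
    marker_ids = [f"RND{j:04d}" for j in range(n_markers)]
    dos = pd.DataFrame(dosage, index=pd.Index(lines, name="line"), columns=marker_ids)
    markers = pd.DataFrame(
        {
            "locus": locus,
            "position": rng.integers(1, 300_000_000, size=n_markers),
            "alleles": "A/T",
            "type": "SNP",
        },
        index=pd.Index(marker_ids, name="marker_id"),
    )
    admixture = pd.DataFrame(
        q, index=dos.index, columns=[f"subpop{k+1}" for k in range(k_subpops)]
    )
    gm = GenotypeMatrix(dos, markers)
    gm.extras["subpop_freqs"] = pd.DataFrame(
        p_sub, index=admixture.columns, columns=marker_ids
    )
    gm.extras["ancestral_freq"] = pd.Series(p_anc, index=marker_ids)
    return gm, admixture


def gen_candidate_gene(
    n_lines: int,
    n_sites: int = 85,
    n_haplotypes: int = 3,
    causal_index: int | None = None,
    maf_floor: float = 0.1,
    hap_freqs=None,
    gene_length: int = 4800,
    recomb_rate: float = 0.03,
    locus: str = "idh",
    seed: int = 0,
) -> GenotypeMatrix:
    """Candidate-gene markers organised in a few major haplotypes.

    ``n_haplotypes`` founder haplotypes are built so every site is
    polymorphic among them; lines draw a haplotype at the given frequencies,
    with a small probability ``recomb_rate`` of carrying a single-crossover
    recombinant (the "several rare" haplotypes).  Sites whose realised MAF
    does not exceed ``maf_floor`` are dropped, except the causal site, which
    is always retained.  Positions are 1-based coordinates within the gene.

    The generated matrix records the causal marker id and per-line haplotype
    assignment in ``extras``.
    """
    if n_haplotypes < 1:
        raise ValueError("n_haplotypes must be >= 1")
    if causal_index is None:
        causal_index = n_sites // 2
    if not (0 <= causal_index < n_sites):
        raise ValueError("causal_index outside n_sites")
    rng = _rng(seed, 2)

    monomorphic = n_haplotypes == 1
    if monomorphic:
        warnings.warn("n_haplotypes=1: gene is monomorphic, r2/association undefined")
        haps = np.zeros((1, n_sites), dtype=np.int64)
    else:
        # each site: allele 1 on a random nonempty proper subset of haplotypes
        haps = np.zeros((n_haplotypes, n_sites), dtype=np.int64)
        for s in range(n_sites):
            size = rng.integers(1, n_haplotypes)
            carriers = rng.choice(n_haplotypes, size=size, replace=False)
            haps[carriers, s] = 1

    if hap_freqs is None:
        raw = rng.dirichlet(np.full(n_haplotypes, 5.0))
        hap_freqs = raw
    hap_freqs = np.asarray(hap_freqs, dtype=float)
    hap_freqs = hap_freqs / hap_freqs.sum()

    assignment = rng.choice(n_haplotypes, size=n_lines, p=hap_freqs)
    alleles = haps[assignment]
    hap_label = np.array([f"H{a+1}" for a in assignment], dtype=object)
    if not monomorphic:
        recomb = rng.random(n_lines) < recomb_rate
        for i in np.flatnonzero(recomb):
            h1, h2 = rng.choice(n_haplotypes, size=2, replace=False)
            cut = rng.integers(1, n_sites)
            alleles[i, :cut] = haps[h1, :cut]
            alleles[i, cut:] = haps[h2, cut:]
            hap_label[i] = f"H{h1+1}xH{h2+1}@{cut}"

    positions = np.sort(rng.choice(np.arange(1, gene_length + 1), size=n_sites, replace=False))
    marker_ids = [f"{locus.upper()}_SNP{p}" for p in positions]
    lines = [f"L{i:04d}" for i in range(n_lines)]
    dosage = pd.DataFrame(
        2 * alleles, index=pd.Index(lines, name="line"), columns=marker_ids
    )
    is_indel = rng.random(n_sites) < 0.2
    markers = pd.DataFrame(
        {
            "locus": locus,
            "position": positions,
            "alleles": np.where(is_indel, "-/T", "A/T"),
            "type": np.where(is_indel, "INDEL", "SNP"),
        },
        index=pd.Index(marker_ids, name="marker_id"),
    )
    gm = GenotypeMatrix(dosage, markers)

    causal_id = marker_ids[causal_index]
    if not monomorphic:
        maf = gm.maf()
        keep = maf.index[(maf > maf_floor) | (maf.index == causal_id)]
        gm = gm.subset_markers(keep)
    gm.extras.update(
        {
            "causal_marker": causal_id,
            "haplotype": pd.Series(hap_label, index=dosage.index, name="haplotype"),
            "monomorphic": monomorphic,
        }
    )
    return gm


def gen_activity(
    lines,
    enzymes,
    truth: TruthRecord,
    n_reps: int = 5,
    plate_capacity: int = 40,
    n_refs: int = 4,
    n_blanks: int = 4,
    causal_dosage: pd.Series | None = None,
    mu: float = 1.0,
    plate_sd: float = 0.1,
    blank_level: float = 0.2,
    blank_sd: float = 0.02,
    temperature: float = 25.0,
) -> pd.DataFrame:
    """Replicated plate-format assay measurements for a set of enzymes.

    Each (line, rep) sample's net activity on enzyme e is

        mu + g_ie + lambda_e * c_i + beta_e * x_i + plate + eps,

    with line genetic effect g ~ N(0, sigma2_G[e]), one shared standard-
    normal co-regulation factor c per line, causal dosage x (0/1/2) from
    ``causal_dosage``, a normal plate effect (sd ``plate_sd``) and residual
    eps ~ N(0, sigma2_E[e]).  Plates hold ``plate_capacity`` experimental
    wells plus ``n_refs`` wells of a common reference line and ``n_blanks``
    blanks whose net activity is the plate effect alone.  V_max is the net
    activity plus the well's V_blank baseline.

    Returns a tidy table with columns line, enzyme, plate, well, role, rep,
    temperature, Vmax, Vblank (blank rows carry no line).
    """
    lines = list(lines)
    enzymes = list(enzymes)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    unknown = [e for e in enzymes if e not in truth.sigma2_G]
    if unknown:
        raise ValueError(f"unknown enzyme name(s): {unknown}")
    rng = _rng(truth.seed, 3)

    if causal_dosage is None:
        x = pd.Series(0.0, index=lines)
    else:
        x = causal_dosage.reindex(lines).fillna(0.0).astype(float)

    all_lines = lines + [REFERENCE_LINE]
    coreg = pd.Series(rng.standard_normal(len(all_lines)), index=all_lines)
    rows = []
    for enzyme in enzymes:
        sg = np.sqrt(truth.sigma2_G[enzyme])
        se = np.sqrt(truth.sigma2_E[enzyme])
        lam = truth.coreg_lambda[enzyme]
        beta = truth.beta_causal[enzyme]
        g = pd.Series(rng.standard_normal(len(all_lines)) * sg, index=all_lines)
        samples = [(ln, r) for r in range(1, n_reps + 1) for ln in lines]
        plate_assign = [i // plate_capacity for i in range(len(samples))]
        n_plates = plate_assign[-1] + 1 if samples else 0
        plate_eff = rng.standard_normal(n_plates) * plate_sd
        for i, ((ln, rep), pl) in enumerate(zip(samples, plate_assign)):
            plate_id = f"{enzyme}-P{pl+1:03d}"
            well = f"W{(i % plate_capacity) + 1:02d}"
            act = (
                mu
                + g[ln]
                + lam * coreg[ln]
                + beta * x[ln]
                + plate_eff[pl]
                + (rng.standard_normal() * se if se > 0 else 0.0)
            )
            vb = blank_level + (rng.standard_normal() * blank_sd if blank_sd > 0 else 0.0)
            rows.append((ln, enzyme, plate_id, well, "sample", rep, temperature, act + vb, vb))
        for pl in range(n_plates):
            plate_id = f"{enzyme}-P{pl+1:03d}"
            for k in range(n_refs):
                act = (
                    mu
                    + g[REFERENCE_LINE]
                    + lam * coreg[REFERENCE_LINE]
                    + plate_eff[pl]
                    + (rng.standard_normal() * se if se > 0 else 0.0)
                )
                vb = blank_level + (rng.standard_normal() * blank_sd if blank_sd > 0 else 0.0)
                rows.append(
                    (REFERENCE_LINE, enzyme, plate_id, f"R{k+1:02d}", "ref", 1, temperature, act + vb, vb)
                )
            for k in range(n_blanks):
                act = plate_eff[pl] + (rng.standard_normal() * se * 0.1 if se > 0 else 0.0)
                vb = blank_level + (rng.standard_normal() * blank_sd if blank_sd > 0 else 0.0)
                rows.append(
                    (None, enzyme, plate_id, f"B{k+1:02d}", "blank", 1, temperature, act + vb, vb)
                )
    return pd.DataFrame(
        rows,
        columns=["line", "enzyme", "plate", "well", "role", "rep", "temperature", "Vmax", "Vblank"],
    )


def gen_alignments(
    n_seq_panel1: int,
    n_seq_panel2: int,
    length: int,
    theta1: float,
    theta2: float,
    seed: int = 0,
    locus: str = "locus",
) -> tuple[MultipleSeqAlignment, MultipleSeqAlignment]:
    """Two sequence panels for one locus with panel-specific diversity.

    Sites mutate independently: a site is polymorphic with probability
    min(1, 2*theta) and, at a polymorphic site, each sequence carries the
    alternative base with probability 1/2 -- so the expected per-site
    heterozygosity (hence expected pi) equals theta.  theta=0 yields
    identical sequences.
    """
    rng = _rng(seed, 4)
    out = []
    for panel, (n_seq, theta) in enumerate(
        [(n_seq_panel1, theta1), (n_seq_panel2, theta2)], start=1
    ):
        if theta < 0:
            raise ValueError("theta must be >= 0")
        ref_idx = rng.integers(0, 4, size=length)
        alt_idx = (ref_idx + rng.integers(1, 4, size=length)) % 4  # always != ref
        ref = _BASES[ref_idx]
        alt = _BASES[alt_idx]
        poly = rng.random(length) < min(1.0, 2.0 * theta)
        seqs = np.tile(ref, (n_seq, 1))
        if poly.any():
            carry = rng.random((n_seq, int(poly.sum()))) < 0.5
            cols = np.flatnonzero(poly)
            seqs[:, cols] = np.where(carry, alt[cols][None, :], ref[cols][None, :])
        records = [
            SeqRecord(
                Seq(seqs[i].tobytes().decode()),
                id=f"{locus}_p{panel}_s{i:03d}",
                description="",
            )
            for i in range(n_seq)
        ]
        out.append(MultipleSeqAlignment(records))
    return out[0], out[1]


def gen_hybrids(inbreds: GenotypeMatrix, testers) -> GenotypeMatrix:
    """F1 testcross hybrids of every non-tester inbred with each tester.

    F1 dosage at each marker is the mean of the two parental dosages, which
    for homozygous parents lands exactly on {0, 1, 2}.
    """
    testers = list(testers)
    missing = [t for t in testers if t not in inbreds.sample_ids]
    if missing:
        raise ValueError(f"tester(s) not in panel: {missing}")
    parents = [ln for ln in inbreds.sample_ids if ln not in testers]
    rows, names = [], []
    for t in testers:
        td = inbreds.dosage.loc[t]
        for p in parents:
            rows.append((inbreds.dosage.loc[p] + td) / 2.0)
            names.append(f"{p}x{t}")
    dosage = pd.DataFrame(rows, index=pd.Index(names, name="line"))
    gm = GenotypeMatrix(dosage, inbreds.markers.copy(), dict(inbreds.extras))
    gm.extras["testers"] = testers
    return gm


def gen_protein(
    activity_by_line: pd.Series,
    r_target: float = 0.72,
    seed: int = 0,
    mean: float = 1.0,
    cv: float = 0.3,
) -> pd.Series:
    """Immunoblot-style protein quantities correlated with activity.

    Protein z-scores are r*z_activity + sqrt(1-r^2)*noise, rescaled to a
    positive arbitrary-unit scale with the given mean and coefficient of
    variation (clipped just above zero).
    """
    if not (-1.0 <= r_target <= 1.0):
        raise ValueError("r_target must be in [-1, 1]")
    rng = _rng(seed, 5)
    z = (activity_by_line - activity_by_line.mean()) / activity_by_line.std(ddof=1)
    noise = rng.standard_normal(len(z))
    pz = r_target * z.to_numpy() + np.sqrt(1.0 - r_target**2) * noise
    protein = mean * (1.0 + cv * pz)
    return pd.Series(np.clip(protein, 1e-6, None), index=activity_by_line.index, name="protein")
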