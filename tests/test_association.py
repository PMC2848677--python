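"""Mixed-model association: reductions, recovery, calibration, oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from enzyqtn import synthetic_data as sd
from enzyqtn.containers import GenotypeMatrix
from enzyqtn.mlm import (
    assoc_scan,
    drop_last_column,
    empirical_null,
    fit_null_mlm,
    kinship_ibs,
    maf_filter,
    stepwise_extend,
)
from enzyqtn.mlm import test_marker as run_marker_test


def _gm(dosage: pd.DataFrame) -> GenotypeMatrix:
    markers = pd.DataFrame(
        {"locus": "x", "position": np.arange(1, dosage.shape[1] + 1),
         "alleles": "A/T", "type": "SNP"},
        index=pd.Index(dosage.columns, name="marker_id"),
    )
    return GenotypeMatrix(dosage, markers)


def _identity_k(ids):
    return pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)


# ---------------------------------------------------------------- MAF filter

def test_maf_filter_strict_boundary():
    lines = [f"L{i}" for i in range(10)]
    dos = pd.DataFrame({
        "at_boundary": [2] + [0] * 9,      # MAF exactly 0.10 -> dropped
        "monomorphic": [0] * 10,           # dropped
        "kept": [2] * 2 + [0] * 8,         # MAF 0.20 -> kept
    }, index=pd.Index(lines, name="line"))
    out = maf_filter(_gm(dos), 0.1)
    assert list(out.marker_ids) == ["kept"]


def test_maf_filter_inbred_count_arithmetic():
    lines = [f"L{i}" for i in range(100)]
    dos = pd.DataFrame({"m": [2] * 15 + [0] * 85}, index=pd.Index(lines, name="line"))
    gm = _gm(dos)
    assert gm.maf()["m"] == pytest.approx(0.15)
    assert list(maf_filter(gm, 0.1).marker_ids) == ["m"]


# ------------------------------------------------------------------- kinship

def test_kinship_ibs_hand_cases():
    lines = ["A", "B", "C"]
    dos = pd.DataFrame(
        [[0, 0, 0, 0], [2, 2, 2, 2], [0, 0, 2, 2]],
        index=pd.Index(lines, name="line"), columns=list("wxyz"),
    )
    k = kinship_ibs(_gm(dos))
    assert np.allclose(np.diag(k), 1.0)
    assert k.loc["A", "B"] == 0.0        # opposite homozygotes everywhere
    assert k.loc["A", "C"] == 0.5        # share half of markers
    assert np.allclose(k, k.T)


def test_kinship_identical_lines():
    dos = pd.DataFrame([[0, 2, 2]] * 2, index=pd.Index(["A", "B"], name="line"),
                       columns=list("xyz"))
    k = kinship_ibs(_gm(dos))
    assert k.loc["A", "B"] == 1.0


# ------------------------------------------------------------------ null fit

def test_reml_matches_closed_form_with_identity_k():
    """K = I, no covariates: total variance is not separable, but the REML
    total sigma2_g + sigma2_e must equal the sample variance of y."""
    rng = np.random.default_rng(1)
    ids = pd.Index([f"L{i}" for i in range(80)], name="line")
    y = pd.Series(rng.standard_normal(80) * 1.7, index=ids)
    fit = fit_null_mlm(y, None, _identity_k(ids))
    assert fit.sigma2_g + fit.sigma2_e == pytest.approx(y.var(ddof=1), rel=1e-3)


def test_reml_recovers_variance_components():
    """Median REML estimates within 15% of (sigma2_g, sigma2_e) = (2, 1)."""
    rng = np.random.default_rng(7)
    n = 200
    ids = pd.Index([f"L{i}" for i in range(n)], name="line")
    # structured kinship with substantial off-diagonal relatedness
    z = rng.integers(0, 2, size=(n, 400)) * 2.0
    k = kinship_ibs(_gm(pd.DataFrame(z, index=ids, columns=[f"m{j}" for j in range(400)])))
    kc = k.to_numpy()
    # center to a PSD covariance with unit-ish diagonal
    lam, u = np.linalg.eigh(kc)
    lam = np.clip(lam, 0, None)
    l = u @ np.diag(np.sqrt(lam))
    sg, se = [], []
    for _ in range(50):
        g = l @ rng.standard_normal(n) * np.sqrt(2.0)
        e = rng.standard_normal(n) * 1.0
        y = pd.Series(g + e, index=ids)
        fit = fit_null_mlm(y, None, k)
        sg.append(fit.sigma2_g)
        se.append(fit.sigma2_e)
    assert np.median(sg) == pytest.approx(2.0, rel=0.15)
    assert np.median(se) == pytest.approx(1.0, rel=0.15)


def test_sigma_g_zero_reduces_marker_test_to_ols():
    rng = np.random.default_rng(2)
    n = 60
    ids = pd.Index([f"L{i}" for i in range(n)], name="line")
    # a real (non-identity) kinship, but iid phenotype: sigma2_g -> 0
    gm, _ = sd.gen_population(n, 200, divergence=0.3, seed=5)
    k = kinship_ibs(gm)
    k.index = k.columns = ids
    y = pd.Series(rng.standard_normal(n), index=ids)
    fit = fit_null_mlm(y, None, k)
    assert fit.sigma2_g <= 0.05 * fit.sigma2_e
    x = pd.Series(rng.integers(0, 2, n) * 2.0, index=ids, name="m")
    res = run_marker_test(y, x, None, fit)
    ols = stats.linregress(x, y)
    assert res.p == pytest.approx(ols.pvalue, abs=2e-4)


def test_marker_test_equals_classical_regression_with_identity_k():
    rng = np.random.default_rng(3)
    n = 50
    ids = pd.Index([f"L{i}" for i in range(n)], name="line")
    y = pd.Series(rng.standard_normal(n), index=ids)
    x = pd.Series(rng.integers(0, 2, n) * 2.0, index=ids, name="m")
    fit = fit_null_mlm(y, None, _identity_k(ids))
    res = run_marker_test(y, x, None, fit)
    ols = stats.linregress(x, y)
    assert res.p == pytest.approx(ols.pvalue, abs=1e-8)
    assert res.r2_marker == pytest.approx(ols.rvalue**2, abs=1e-8)
    assert res.effect == pytest.approx(2 * ols.slope, abs=1e-8)


def test_collinear_marker_flagged():
    rng = np.random.default_rng(4)
    n = 30
    ids = pd.Index([f"L{i}" for i in range(n)], name="line")
    q = pd.DataFrame({"q1": rng.random(n)}, index=ids)
    y = pd.Series(rng.standard_normal(n), index=ids)
    fit = fit_null_mlm(y, q, _identity_k(ids))
    res = run_marker_test(y, pd.Series(q["q1"], name="m"), q, fit)
    assert res.collinear
    assert np.isnan(res.p)


def test_mlm_p_matches_permutation_oracle_unstructured():
    """n = 30, K = I: the MLM marker P equals a label-permutation P within
    Monte-Carlo error (the F test is exact under normality)."""
    rng = np.random.default_rng(5)
    n = 30
    ids = pd.Index([f"L{i}" for i in range(n)], name="line")
    y = pd.Series(rng.standard_normal(n), index=ids)
    x = pd.Series(rng.integers(0, 2, n) * 2.0, index=ids, name="m")
    fit = fit_null_mlm(y, None, _identity_k(ids))
    res = run_marker_test(y, x, None, fit)

    n_perm = 100_000
    yv = (y - y.mean()).to_numpy()
    xv = (x - x.mean()).to_numpy()
    obs = abs(xv @ yv)
    perms = np.empty(n_perm)
    yy = yv.copy()
    for b in range(n_perm):
        rng.shuffle(yy)
        perms[b] = abs(xv @ yy)
    p_perm = (1 + np.sum(perms >= obs - 1e-12)) / (n_perm + 1)
    se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
    assert res.p == pytest.approx(p_perm, abs=max(4 * se, 4e-3))


def test_marker_p_uniform_under_null():
    """No structure, marker orthogonal to y: P uniform over seeds."""
    n = 50
    ids = pd.Index([f"L{i}" for i in range(n)], name="line")
    k = _identity_k(ids)
    rng = np.random.default_rng(6)
    x = pd.Series(rng.integers(0, 2, n) * 2.0, index=ids, name="m")
    pvals = []
    for _ in range(400):
        y = pd.Series(rng.standard_normal(n), index=ids)
        fit = fit_null_mlm(y, None, k)
        pvals.append(run_marker_test(y, x, None, fit).p)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


# -------------------------------------------------------------- empirical null

def test_empirical_null_rank_arithmetic():
    rng = np.random.default_rng(8)
    n = 40
    ids = pd.Index([f"L{i}" for i in range(n)], name="line")
    dos = pd.DataFrame(
        rng.integers(0, 2, size=(n, 50)) * 2.0, index=ids,
        columns=[f"r{j}" for j in range(50)],
    )
    y = pd.Series(rng.standard_normal(n), index=ids)
    fit = fit_null_mlm(y, None, _identity_k(ids))
    nul = empirical_null(y, _gm(dos), None, fit, candidate_p=0.0)
    assert nul.candidate_quantile == pytest.approx(1 / (len(nul.null_p) + 1))
    # a candidate drawn from the null sits near the middle
    mid = empirical_null(y, _gm(dos), None, fit, candidate_p=np.median(nul.null_p))
    assert 0.3 < mid.candidate_quantile < 0.7


# ------------------------------------------------------------------ stepwise

def test_stepwise_excludes_perfect_ld_and_finds_second_signal():
    rng = np.random.default_rng(9)
    n = 120
    ids = pd.Index([f"L{i}" for i in range(n)], name="line")
    base = pd.Series(rng.integers(0, 2, n) * 2.0, index=ids, name="base")
    twin = pd.Series(base.to_numpy(), index=ids, name="twin")  # perfect LD
    indep = pd.Series(rng.integers(0, 2, n) * 2.0, index=ids, name="indep")
    y = pd.Series(0.5 * base + 0.8 * indep + rng.standard_normal(n), index=ids)
    fit = fit_null_mlm(y, None, _identity_k(ids))
    others = _gm(pd.concat([twin, indep], axis=1))
    res = stepwise_extend(y, base, others, None, fit, alpha=0.05)
    assert bool(res.loc["twin", "collinear"])
    assert not bool(res.loc["twin", "selected"])
    assert bool(res.loc["indep", "selected"])


def test_stepwise_empty_other_set():
    n = 20
    ids = pd.Index([f"L{i}" for i in range(n)], name="line")
    rng = np.random.default_rng(10)
    y = pd.Series(rng.standard_normal(n), index=ids)
    base = pd.Series(rng.integers(0, 2, n) * 2.0, index=ids, name="b")
    fit = fit_null_mlm(y, None, _identity_k(ids))
    empty = _gm(pd.DataFrame(index=ids))
    res = stepwise_extend(y, base, empty, None, fit)
    assert len(res) == 0


# ----------------------------------------------------- structured calibration

def test_structured_type_i_error_controlled_vs_naive():
    """Admixed panel (3 subpopulations, divergence 0.2): the mixed model
    with Q and K holds the 0.05-level type-I error in [0.03, 0.07] while a
    structure-naive regression exceeds 0.10."""
    gm, q = sd.gen_population(100, 553, k_subpops=3, divergence=0.2, seed=17)
    k = kinship_ibs(gm)
    gm = maf_filter(gm, 0.1)  # the scan convention: MAF > 0.1
    qq = drop_last_column(q)
    rng = np.random.default_rng(18)
    subpop_means = np.array([0.0, 1.0, 2.0])
    mlm_p, naive_p = [], []
    for rep in range(5):
        y = pd.Series(
            q.to_numpy() @ subpop_means + rng.standard_normal(gm.n_samples),
            index=gm.sample_ids,
        )
        fit = fit_null_mlm(y, qq, k)
        scan = assoc_scan(y, gm, qq, fit)
        mlm_p.extend(scan.loc[~scan["collinear"], "P"].tolist())
        yv = y.to_numpy()
        for mk in gm.marker_ids:
            naive_p.append(stats.linregress(gm.dosage[mk], yv).pvalue)
    mlm_rate = float(np.mean(np.asarray(mlm_p) < 0.05))
    naive_rate = float(np.mean(np.asarray(naive_p) < 0.05))
    assert 0.03 <= mlm_rate <= 0.07
    assert naive_rate > 0.10
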