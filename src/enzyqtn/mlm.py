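"""Candidate-gene association with a unified mixed linear model.

The phenotype of line i is modelled as

    y = X b + u + e,   u ~ N(0, sigma2_g K),   e ~ N(0, sigma2_e I),

where X holds an intercept, population-structure covariates Q and (for a
marker test) the marker dosage, and K is a genome-wide kinship matrix that
absorbs relatedness.  Variance components are estimated by REML through the
spectral decomposition of K, profiling the ratio delta = sigma2_e/sigma2_g
on a fixed log grid with golden-section refinement — a reproducible,
optimizer-free EMMA-style fit.  Following the "P3D" convention, the
components are estimated once on the null model and reused for every marker
test, which is then a generalized-least-squares F test under
V = sigma2_g K + sigma2_e I.

An empirical null built from unlinked random markers puts candidate-gene
P-values in perspective independently of how well K and Q control
stratification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix

DELTA_GRID = np.logspace(-5, 5, 61)
_GOLD = (np.sqrt(5.0) - 1.0) / 2.0


def maf_filter(genotypes: GenotypeMatrix, threshold: float = 0.1) -> GenotypeMatrix:
    """Keep markers with minor-allele frequency strictly above ``threshold``."""
    maf = genotypes.maf()
    keep = maf.index[maf > threshold]
    out = genotypes.subset_markers(keep)
    out.extras["maf_filter"] = {"threshold": threshold, "dropped": int(len(maf) - len(keep))}
    return out


def kinship_ibs(background: GenotypeMatrix) -> pd.DataFrame:
    """Identity-by-state kinship: mean allele sharing per pair, in [0, 1].

    Sharing at one marker is 1 - |d_i - d_j| / 2 for dosages d; identical
    lines score 1, opposite homozygotes 0.  Missing calls are ignored
    pairwise.  The result is symmetric with unit diagonal for complete data.
    """
    d = background.dosage.to_numpy(dtype=float)
    n = d.shape[0]
    obs = np.isfinite(d)
    d0 = np.where(obs, d, 0.0)
    k = np.empty((n, n))
    for i in range(n):
        both = obs[i] & obs
        diff = np.abs(d0[i][None, :] - d0) / 2.0
        share = np.where(both, 1.0 - diff, 0.0).sum(axis=1)
        cnt = both.sum(axis=1)
        k[i] = np.where(cnt > 0, share / np.maximum(cnt, 1), np.nan)
    return pd.DataFrame(k, index=background.sample_ids, columns=background.sample_ids)


@dataclass
class MixedModelFit:
    sigma2_g: float
    sigma2_e: float
    delta: float
    loglik_reml: float
    K: pd.DataFrame
    Q: pd.DataFrame | None
    sample_ids: pd.Index
    eigvals: np.ndarray = field(repr=False, default=None)
    eigvecs: np.ndarray = field(repr=False, default=None)

    def v_matrix(self, ids=None) -> np.ndarray:
        """V = sigma2_g K + sigma2_e I on the requested samples."""
        ids = self.sample_ids if ids is None else ids
        k = self.K.loc[ids, ids].to_numpy()
        return self.sigma2_g * k + self.sigma2_e * np.eye(len(ids))


def _design(n: int, Q: pd.DataFrame | None, ids: pd.Index) -> np.ndarray:
    x = [np.ones((n, 1))]
    if Q is not None and Q.shape[1] > 0:
        q = Q.loc[ids].to_numpy(dtype=float)
        x.append(q)
    return np.hstack(x)


def drop_last_column(Q: pd.DataFrame) -> pd.DataFrame:
    """Admixture proportions sum to 1; drop one column before use as fixed
    covariates so the design is not collinear with the intercept."""
    return Q.iloc[:, :-1]


def _reml_neg2(delta: float, lam: np.ndarray, yt: np.ndarray, xt: np.ndarray) -> tuple[float, float]:
    w = 1.0 / (lam + delta)
    sw = np.sqrt(w)
    xw = xt * sw[:, None]
    yw = yt * sw
    beta, *_ = np.linalg.lstsq(xw, yw, rcond=None)
    resid = yw - xw @ beta
    rss = float(resid @ resid)
    n, p = xt.shape
    s2 = rss / (n - p)
    sign, logdet_xvx = np.linalg.slogdet(xw.T @ xw)
    neg2 = (n - p) * np.log(s2) + float(np.sum(np.log(lam + delta))) + logdet_xvx
    return neg2, s2


def fit_null_mlm(y: pd.Series, Q: pd.DataFrame | None, K: pd.DataFrame,
                 grid: np.ndarray = DELTA_GRID, refine_tol: float = 1e-4) -> MixedModelFit:
    """REML fit of the covariates-only mixed model.

    Spectral trick: with K = U diag(lam) U', rotating y and X by U' makes V
    diagonal for any delta, so the REML criterion is a cheap 1-D function of
    delta evaluated on a fixed log grid and refined by golden-section search
    — fully reproducible across runs.
    """
    ids = y.dropna().index
    y = y.loc[ids]
    n = len(ids)
    x = _design(n, Q, ids)
    if n < x.shape[1] + 2:
        raise ValueError("too few samples for the fixed-effect design")
    k = K.loc[ids, ids].to_numpy(dtype=float)
    k = (k + k.T) / 2.0
    lam, u = np.linalg.eigh(k)
    if lam.min() < -1e-8:
        warnings.warn("kinship not PSD; clipping negative eigenvalues at 0")
    lam = np.clip(lam, 0.0, None)
    yt = u.T @ y.to_numpy(dtype=float)
    xt = u.T @ x

    vals = np.array([_reml_neg2(d, lam, yt, xt)[0] for d in grid])
    i = int(np.argmin(vals))
    lo = np.log(grid[max(i - 1, 0)])
    hi = np.log(grid[min(i + 1, len(grid) - 1)])
    # golden-section on log(delta) within the bracketing grid cells
    a, b = lo, hi
    c = b - _GOLD * (b - a)
    d_ = a + _GOLD * (b - a)
    fc = _reml_neg2(np.exp(c), lam, yt, xt)[0]
    fd = _reml_neg2(np.exp(d_), lam, yt, xt)[0]
    while b - a > refine_tol:
        if fc < fd:
            b, d_, fd = d_, c, fc
            c = b - _GOLD * (b - a)
            fc = _reml_neg2(np.exp(c), lam, yt, xt)[0]
        else:
            a, c, fc = c, d_, fd
            d_ = a + _GOLD * (b - a)
            fd = _reml_neg2(np.exp(d_), lam, yt, xt)[0]
    delta = float(np.exp((a + b) / 2.0))
    neg2, s2g = _reml_neg2(delta, lam, yt, xt)
    return MixedModelFit(
        sigma2_g=float(s2g),
        sigma2_e=float(delta * s2g),
        delta=delta,
        loglik_reml=-0.5 * neg2,
        K=K,
        Q=Q,
        sample_ids=ids,
        eigvals=lam,
        eigvecs=u,
    )


@dataclass
class AssociationResult:
    marker: str
    p: float
    effect: float
    r2_marker: float
    n: int
    beta: float = np.nan
    collinear: bool = False


def _decorrelate(fit: MixedModelFit, ids: pd.Index):
    v = fit.v_matrix(ids)
    l = np.linalg.cholesky(v)
    return l


def _whiten(l: np.ndarray, m: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular

    return solve_triangular(l, m, lower=True)


def test_marker(y: pd.Series, marker: pd.Series, Q: pd.DataFrame | None,
                fit: MixedModelFit, name: str | None = None) -> AssociationResult:
    """GLS F test of one marker under the P3D variance components.

    Samples with a missing call at this marker are dropped for this test
    only.  The reported effect is the fitted difference between the two
    homozygote classes (2 x the per-dosage slope); ``r2_marker`` is the
    fraction of whitened total SS (around the whitened intercept fit)
    explained by adding the marker.
    """
    name = name or (marker.name if marker.name else "marker")
    ids = fit.sample_ids.intersection(y.dropna().index).intersection(marker.dropna().index)
    yv = y.loc[ids].to_numpy(dtype=float)
    mv = marker.loc[ids].to_numpy(dtype=float)
    n = len(ids)
    x0 = _design(n, Q, ids)
    l = _decorrelate(fit, ids)
    yw = _whiten(l, yv)
    x0w = _whiten(l, x0)
    mw = _whiten(l, mv)

    # collinearity of the marker with the null design
    b0, *_ = np.linalg.lstsq(x0w, mw, rcond=None)
    m_resid = mw - x0w @ b0
    if np.linalg.norm(m_resid) <= 1e-8 * max(np.linalg.norm(mw), 1.0):
        return AssociationResult(name, np.nan, np.nan, np.nan, n, collinear=True)

    onew = _whiten(l, np.ones(n))
    b_int, *_ = np.linalg.lstsq(onew[:, None], yw, rcond=None)
    tss = float(np.sum((yw - onew * b_int[0]) ** 2))
    beta0, *_ = np.linalg.lstsq(x0w, yw, rcond=None)
    rss0 = float(np.sum((yw - x0w @ beta0) ** 2))
    x1w = np.hstack([x0w, mw[:, None]])
    beta1, *_ = np.linalg.lstsq(x1w, yw, rcond=None)
    rss1 = float(np.sum((yw - x1w @ beta1) ** 2))
    df2 = n - x1w.shape[1]
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom for the marker test")
    f = max(rss0 - rss1, 0.0) / (rss1 / df2) if rss1 > 0 else np.inf
    p = float(stats.f.sf(f, 1, df2))
    slope = float(beta1[-1])
    r2 = max(rss0 - rss1, 0.0) / tss if tss > 0 else np.nan
    return AssociationResult(name, p, 2.0 * slope, float(r2), n, beta=slope)


def assoc_scan(y: pd.Series, genotypes: GenotypeMatrix, Q: pd.DataFrame | None,
               fit: MixedModelFit) -> pd.DataFrame:
    """Test every marker in ``genotypes``; one row per marker."""
    rows = []
    for mk in genotypes.marker_ids:
        res = test_marker(y, genotypes.dosage[mk], Q, fit, name=mk)
        rows.append((res.marker, res.p, res.effect, res.r2_marker, res.n, res.collinear))
    return pd.DataFrame(
        rows, columns=["marker", "P", "effect", "R2", "n", "collinear"]
    ).set_index("marker")


@dataclass
class EmpiricalNull:
    null_p: np.ndarray  # sorted ascending
    neg_log10: np.ndarray  # sorted ascending
    candidate_p: float
    candidate_quantile: float
    ks_stat: float
    ks_p: float


def empirical_null(y: pd.Series, random_markers: GenotypeMatrix, Q: pd.DataFrame | None,
                   fit: MixedModelFit, candidate_p: float) -> EmpiricalNull:
    """Null P distribution from random unlinked markers.

    The candidate's quantile is (1 + #{null P <= candidate P}) / (m + 1), so
    a candidate smaller than all m null values scores 1/(m+1).  A KS test
    against Uniform(0,1) summarises how well structure is controlled.
    """
    scan = assoc_scan(y, random_markers, Q, fit)
    null_p = np.sort(scan.loc[~scan["collinear"], "P"].dropna().to_numpy())
    m = len(null_p)
    quant = (1 + int(np.sum(null_p <= candidate_p))) / (m + 1)
    ks = stats.kstest(null_p, "uniform")
    return EmpiricalNull(
        null_p=null_p,
        neg_log10=np.sort(-np.log10(null_p)),
        candidate_p=candidate_p,
        candidate_quantile=quant,
        ks_stat=float(ks.statistic),
        ks_p=float(ks.pvalue),
    )


def stepwise_extend(y: pd.Series, base_marker: pd.Series, other_markers: GenotypeMatrix,
                    Q: pd.DataFrame | None, fit: MixedModelFit,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Partial-F test of each extra marker on top of the base-marker model.

    Markers collinear with the base model (e.g. in perfect LD with the base
    marker) are flagged and never selected.  Returns a table with F, P and
    a ``selected`` flag for P < alpha.
    """
    rows = []
    for mk in other_markers.marker_ids:
        extra = other_markers.dosage[mk]
        ids = (
            fit.sample_ids.intersection(y.dropna().index)
            .intersection(base_marker.dropna().index)
            .intersection(extra.dropna().index)
        )
        n = len(ids)
        x_base = np.hstack([
            _design(n, Q, ids),
            base_marker.loc[ids].to_numpy(dtype=float)[:, None],
        ])
        l = _decorrelate(fit, ids)
        yw = _whiten(l, y.loc[ids].to_numpy(dtype=float))
        xbw = _whiten(l, x_base)
        ew = _whiten(l, extra.loc[ids].to_numpy(dtype=float))
        b0, *_ = np.linalg.lstsq(xbw, ew, rcond=None)
        if np.linalg.norm(ew - xbw @ b0) <= 1e-8 * max(np.linalg.norm(ew), 1.0):
            rows.append((mk, np.nan, np.nan, False, True))
            continue
        bb, *_ = np.linalg.lstsq(xbw, yw, rcond=None)
        rss0 = float(np.sum((yw - xbw @ bb) ** 2))
        x1 = np.hstack([xbw, ew[:, None]])
        b1, *_ = np.linalg.lstsq(x1, yw, rcond=None)
        rss1 = float(np.sum((yw - x1 @ b1) ** 2))
        df2 = n - x1.shape[1]
        f = max(rss0 - rss1, 0.0) / (rss1 / df2) if rss1 > 0 else np.inf
        p = float(stats.f.sf(f, 1, df2))
        rows.append((mk, f, p, bool(p < alpha), False))
    return pd.DataFrame(
        rows, columns=["marker", "F", "P", "selected", "collinear"]
    ).set_index("marker")
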