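"""Association mapping: SNP QC, line BLUPs, kinship, MLM scan, clumping.

The scan follows the standard single-marker mixed linear model

    y = mu + x alpha + u + e,   u ~ N(0, 2 K Vg),   e ~ N(0, I Ve)

with y the per-line trait BLUPs, K the VanRaden genomic relationship
matrix and (Vg, Ve) estimated once by REML on the marker-free null
model and reused for every marker (the population-parameters-
previously-determined approximation).  Significance is controlled by
Benjamini-Hochberg FDR and significant SNPs are clumped into QTL by
greedy LD grouping around the lowest-p peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._mixed import fit_variance_components
from .popsim import GenotypeMatrix

__all__ = [
    "filter_snps",
    "LineBLUPs",
    "compute_blups",
    "KinshipMatrix",
    "vanraden_kinship",
    "MLMAssociation",
    "MLMResults",
    "fit_null_mlm",
    "scan_markers",
    "bh_fdr",
    "ld_r2",
    "QTLCluster",
    "clump_loci",
    "PhaseSummary",
    "classify_phase",
]


# ---------------------------------------------------------------------------
# SNP quality control
# ---------------------------------------------------------------------------

def filter_snps(
    g: GenotypeMatrix, max_missing: float = 0.10, min_maf: float = 0.05
) -> GenotypeMatrix:
    """Missing-rate filter, modal imputation, then MAF filter (in that order).

    SNPs with a missing rate above ``max_missing`` are dropped first;
    surviving missing calls are set to the per-SNP modal genotype; SNPs
    whose post-imputation MAF falls below ``min_maf`` are then dropped.
    """
    keep = g.missing_rate() <= max_missing
    g2 = g.select(snp_keep=keep)
    d = g2.dosages.copy()
    if np.isnan(d).any():
        for j in np.flatnonzero(np.isnan(d).any(axis=0)):
            col = d[:, j]
            obs = col[~np.isnan(col)]
            vals, counts = np.unique(obs, return_counts=True)
            col[np.isnan(col)] = vals[np.argmax(counts)]
    g2 = GenotypeMatrix(d, g2.chrom, g2.pos, g2.snp_ids, g2.line_ids)
    keep2 = g2.maf() >= min_maf
    if not keep2.any():
        raise ValueError("all SNPs removed by QC filters")
    return g2.select(snp_keep=keep2)


# ---------------------------------------------------------------------------
# Line BLUPs from replicated observations
# ---------------------------------------------------------------------------

@dataclass
class LineBLUPs:
    """Per-line predicted trait values and aggregation variance components."""

    values: pd.Series  # index = line id
    sigma_g2: float
    sigma_r2: float
    sigma_e2: float
    grand_mean: float

    def __len__(self) -> int:
        return len(self.values)

    def to_array(self, line_order=None) -> np.ndarray:
        v = self.values if line_order is None else self.values.loc[line_order]
        return v.to_numpy(dtype=float)


def _balanced_blups(p: pd.DataFrame, value_col: str) -> LineBLUPs:
    # line and rep random; balanced ANOVA estimators coincide with REML
    wide = p.pivot(index="line", columns="rep", values=value_col)
    a, r = wide.shape
    mu = float(wide.to_numpy().mean())
    line_means = wide.mean(axis=1)
    rep_means = wide.mean(axis=0)
    resid = wide.to_numpy() - line_means.to_numpy()[:, None] \
        - rep_means.to_numpy()[None, :] + mu
    if a > 1 and r > 1:
        ms_line = r * line_means.sub(mu).pow(2).sum() / (a - 1)
        ms_rep = a * rep_means.sub(mu).pow(2).sum() / (r - 1)
        ms_e = (resid**2).sum() / ((a - 1) * (r - 1))
    elif r == 1:
        ms_line = line_means.sub(mu).pow(2).sum() / max(a - 1, 1)
        ms_rep = 0.0
        ms_e = 0.0
    else:  # a == 1
        ms_line = 0.0
        ms_rep = rep_means.sub(mu).pow(2).sum() / max(r - 1, 1)
        ms_e = 0.0
    sg2 = max((ms_line - ms_e) / r, 0.0)
    sr2 = max((ms_rep - ms_e) / a, 0.0)
    se2 = float(ms_e)
    if sg2 == 0.0:
        warnings.warn("zero between-line variance: all BLUPs equal the grand mean",
                      stacklevel=3)
        shrink = 0.0
    else:
        shrink = r * sg2 / (r * sg2 + se2) if (r * sg2 + se2) > 0 else 1.0
    blups = mu + shrink * (line_means - mu)
    return LineBLUPs(values=blups, sigma_g2=float(sg2), sigma_r2=float(sr2),
                     sigma_e2=se2, grand_mean=mu)


def _unbalanced_blups(p: pd.DataFrame, value_col: str) -> LineBLUPs:
    # dense REML over (sigma_g2, sigma_r2) with sigma_e2 profiled; intended
    # for modest n since it forms the full covariance
    from scipy.optimize import minimize

    y = p[value_col].to_numpy(dtype=float)
    lines = pd.Categorical(p["line"])
    reps = pd.Categorical(p["rep"])
    Zg = np.eye(len(lines.categories))[lines.codes]
    Zr = np.eye(len(reps.categories))[reps.codes]
    n = y.size
    X = np.ones((n, 1))
    GG = Zg @ Zg.T
    RR = Zr @ Zr.T

    def neg_remll(theta):
        g2, r2 = np.exp(theta)
        V = g2 * GG + r2 * RR + np.eye(n)
        try:
            Vi = np.linalg.inv(V)
        except np.linalg.LinAlgError:
            return np.inf
        XtVi = X.T @ Vi
        A = XtVi @ X
        beta = np.linalg.solve(A, XtVi @ y)
        r = y - X @ beta
        rss = float(r @ Vi @ r)
        sign, ld = np.linalg.slogdet(V)
        _, ldA = np.linalg.slogdet(A)
        return 0.5 * ((n - 1) * np.log(rss) + ld + ldA)

    res = minimize(neg_remll, x0=np.log([0.5, 0.5]), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    g2, r2 = np.exp(res.x)
    V = g2 * GG + r2 * RR + np.eye(n)
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    resid = y - X @ beta
    se2 = float(resid @ Vi @ resid) / (n - 1)
    sg2, sr2 = g2 * se2, r2 * se2
    mu = float(beta[0])
    u = sg2 * Zg.T @ (Vi / se2) @ resid
    blups = pd.Series(mu + u, index=lines.categories)
    return LineBLUPs(values=blups, sigma_g2=sg2, sigma_r2=sr2, sigma_e2=se2,
                     grand_mean=mu)


def compute_blups(p: pd.DataFrame, value_col: str = "value") -> LineBLUPs:
    """Line BLUPs from the model value = mu + line + rep + residual.

    ``line`` and ``rep`` are random effects; for balanced data the
    closed-form ANOVA estimators (exactly REML under balance) are used,
    otherwise a dense numerical REML.  BLUPs shrink line means toward
    the grand mean by r*sg2 / (r*sg2 + se2).
    """
    required = {"line", "rep", value_col}
    if not required.issubset(p.columns):
        raise ValueError(f"phenotype table must have columns {sorted(required)}")
    if p["line"].nunique() < 2:
        raise ValueError("need at least two lines")
    counts = p.groupby(["line", "rep"]).size()
    balanced = (
        (counts == 1).all()
        and len(counts) == p["line"].nunique() * p["rep"].nunique()
    )
    if balanced:
        return _balanced_blups(p, value_col)
    return _unbalanced_blups(p, value_col)


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

@dataclass
class KinshipMatrix:
    """VanRaden genomic relationship matrix and its scaling constant."""

    values: np.ndarray
    denom: float
    line_ids: np.ndarray = None

    def __post_init__(self):
        K = np.asarray(self.values, dtype=float)
        if K.shape[0] != K.shape[1] or not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("kinship must be a symmetric square matrix")
        self.values = (K + K.T) / 2.0


def vanraden_kinship(g: GenotypeMatrix) -> KinshipMatrix:
    """K = W W' / (2 sum p_j (1 - p_j)) with W frequency-centered dosages.

    Missing calls are mean-imputed for centering; monomorphic SNPs are
    excluded from both W and the denominator (with a warning).
    """
    d = g.dosages.copy()
    if np.isnan(d).any():
        means = np.nanmean(d, axis=0)
        idx = np.where(np.isnan(d))
        d[idx] = means[idx[1]]
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(
            f"excluding {int((~poly).sum())} monomorphic SNP(s) from kinship",
            stacklevel=2,
        )
    d = d[:, poly]
    p = p[poly]
    if d.shape[1] == 0:
        raise ValueError("no polymorphic SNPs for kinship")
    W = d - 2.0 * p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    return KinshipMatrix(values=(W @ W.T) / denom, denom=denom,
                         line_ids=g.line_ids)


# ---------------------------------------------------------------------------
# Mixed linear model scan
# ---------------------------------------------------------------------------

@dataclass
class MLMResults:
    """Null-model REML fit: variance components plus a spectral cache."""

    Vg: float
    Ve: float
    beta: np.ndarray  # fixed effects of the null model (intercept [+ PCs])
    X: np.ndarray
    eig: tuple  # (eigenvalues, eigenvectors) of 2K
    y: np.ndarray
    model: "MLMAssociation | None" = None

    @property
    def heritability(self) -> float:
        tot = self.Vg + self.Ve
        return self.Vg / tot if tot > 0 else float("nan")

    def summary(self) -> str:
        return (
            "Mixed linear model (null) REML fit\n"
            f"  n lines:            {self.y.size}\n"
            f"  Vg (genetic):       {self.Vg:.6g}\n"
            f"  Ve (residual):      {self.Ve:.6g}\n"
            f"  Vg / (Vg + Ve):     {self.heritability:.4f}\n"
            f"  intercept:          {self.beta[0]:.6g}"
        )

    def scan(self, g: GenotypeMatrix | None = None) -> pd.DataFrame:
        if g is None:
            if self.model is None:
                raise ValueError("no genotype matrix attached to this fit")
            g = self.model.genotypes
        return scan_markers(self, g, self.y)


class MLMAssociation:
    """Association-scan model: trait BLUPs against a genotype panel.

    Parameters
    ----------
    y : array or LineBLUPs
        Per-line trait values, ordered like ``genotypes.line_ids``.
    genotypes : GenotypeMatrix
        QC-filtered, imputed panel used both for the kinship matrix and
        the marker scan.
    kinship : KinshipMatrix, optional
        Precomputed VanRaden matrix; computed from ``genotypes`` if
        omitted.
    n_pcs : int
        Number of marker principal components as fixed covariates
        (0 by default: diverse inbred panels often need none).
    """

    def __init__(self, y, genotypes: GenotypeMatrix, kinship=None, n_pcs: int = 0):
        if isinstance(y, LineBLUPs):
            y = y.to_array(line_order=genotypes.line_ids)
        self.y = np.asarray(y, dtype=float).ravel()
        if self.y.size != genotypes.n_lines:
            raise ValueError("y length must equal the number of lines")
        self.genotypes = genotypes
        self.kinship = kinship or vanraden_kinship(genotypes)
        X = [np.ones((self.y.size, 1))]
        if n_pcs > 0:
            d = genotypes.dosages
            W = d - np.nanmean(d, axis=0)
            W = np.nan_to_num(W)
            _, _, Vt = np.linalg.svd(W, full_matrices=False)
            X.append(W @ Vt[:n_pcs].T)
        self.X = np.hstack(X)

    def fit(self) -> MLMResults:
        """REML of (Vg, Ve) under the marker-free null model."""
        res = fit_variance_components(self.y, self.X,
                                      G=2.0 * self.kinship.values)
        out = MLMResults(Vg=res["Vg"], Ve=res["Ve"], beta=res["beta"],
                         X=self.X, eig=res["eig"], y=self.y, model=self)
        return out


def fit_null_mlm(y, kinship: KinshipMatrix, X=None) -> MLMResults:
    """Functional form of :meth:`MLMAssociation.fit` without a marker panel."""
    y = np.asarray(y, dtype=float).ravel()
    if X is None:
        X = np.ones((y.size, 1))
    res = fit_variance_components(y, X, G=2.0 * kinship.values)
    return MLMResults(Vg=res["Vg"], Ve=res["Ve"], beta=res["beta"], X=X,
                      eig=res["eig"], y=y)


def scan_markers(
    fit: MLMResults, g: GenotypeMatrix, y=None, fdr_q: float = 0.05
) -> pd.DataFrame:
    """Per-marker GLS tests with variance components fixed from the null fit.

    Each SNP enters as a fixed effect in y = X b + x alpha + u + e with
    Var(u) + Var(e) = Vg * 2K + Ve * I evaluated at the null REML
    estimates; the two-sided t test on alpha gives the p-value.  The
    per-SNP R^2 column is from the ordinary (unweighted) regression of
    y on the SNP alone.  Monomorphic SNPs get p = 1 and a flag.
    """
    y = fit.y if y is None else np.asarray(y, dtype=float).ravel()
    s, U = fit.eig
    delta = fit.Ve / fit.Vg if fit.Vg > 0 else np.inf
    if np.isinf(delta):
        w = np.ones_like(s)
    else:
        w = 1.0 / (s + delta)
    ys = U.T @ y
    Xs = U.T @ fit.X
    d = g.dosages
    if np.isnan(d).any():
        means = np.nanmean(d, axis=0)
        idx = np.where(np.isnan(d))
        d = d.copy()
        d[idx] = means[idx[1]]
    Ms = U.T @ d  # rotated markers, n x m
    q = Xs.shape[1]
    n = y.size
    XtWX = (Xs.T * w) @ Xs
    XtWy = (Xs.T * w) @ ys
    XtWM = (Xs.T * w) @ Ms
    mWm = np.einsum("ij,ij->j", Ms * w[:, None], Ms)
    mWy = (Ms * w[:, None]).T @ ys
    yWy = float(np.sum(w * ys * ys))
    XtWX_inv = np.linalg.inv(XtWX)
    # per-SNP blockwise solve of [[XtWX, XtWm],[mWX, mWm]]
    AinvB = XtWX_inv @ XtWM  # q x m
    schur = mWm - np.einsum("ij,ij->j", XtWM, AinvB)
    resid_y = mWy - XtWM.T @ (XtWX_inv @ XtWy)
    poly = g.maf() > 0
    ok = poly & (schur > 1e-12)
    alpha = np.zeros(g.m_snps)
    se = np.full(g.m_snps, np.nan)
    pvals = np.ones(g.m_snps)
    alpha[ok] = resid_y[ok] / schur[ok]
    # residual variance of the marker model on the weighted scale
    beta0ty = float(XtWy @ (XtWX_inv @ XtWy))
    rss = yWy - beta0ty - alpha**2 * schur
    dfree = n - q - 1
    sigma2 = np.clip(rss, 1e-300, None) / dfree
    se[ok] = np.sqrt(sigma2[ok] / schur[ok])
    tstat = np.zeros(g.m_snps)
    tstat[ok] = alpha[ok] / se[ok]
    pvals[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), dfree)
    # plain GLM R^2 of y on the SNP alone
    dc = d - d.mean(axis=0)
    yc = y - y.mean()
    denom = np.einsum("ij,ij->j", dc, dc) * float(yc @ yc)
    r2 = np.zeros(g.m_snps)
    nz = denom > 0
    r2[nz] = (dc.T @ yc)[nz] ** 2 / denom[nz]
    sig, qvals = bh_fdr(pvals, q=fdr_q)
    return pd.DataFrame(
        {
            "snp": g.snp_ids,
            "chrom": g.chrom,
            "pos": g.pos,
            "maf": g.maf(),
            "effect": alpha,
            "se": se,
            "p": pvals,
            "q": qvals,
            "r2": r2,
            "significant": sig,
            "monomorphic": ~poly,
        }
    )


def bh_fdr(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up: (reject flags, q-values)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.array([], dtype=bool), np.array([])
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject, qvals


# ---------------------------------------------------------------------------
# LD, clumping, allelic phase
# ---------------------------------------------------------------------------

def _dosage_at(g: GenotypeMatrix, locus) -> np.ndarray:
    if isinstance(locus, (int, np.integer)):
        return g.dosages[:, int(locus)]
    j = np.flatnonzero(g.snp_ids == locus)
    if j.size != 1:
        raise KeyError(f"SNP {locus!r} not found (or not unique)")
    return g.dosages[:, j[0]]


def ld_r2(g: GenotypeMatrix, snp_i, snp_j) -> float:
    """Squared Pearson correlation of dosages (haplotype r^2 for inbreds)."""
    a = _dosage_at(g, snp_i)
    b = _dosage_at(g, snp_j)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("LD r^2 undefined for a monomorphic SNP")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class QTLCluster:
    """One clumped locus: the peak SNP and its LD-linked members."""

    peak: str
    chrom: str
    pos: int
    peak_p: float
    members: tuple
    member_r2: tuple


def clump_loci(
    assoc: pd.DataFrame, g: GenotypeMatrix, r2_threshold: float = 0.20
) -> list[QTLCluster]:
    """Greedy LD clumping of FDR-significant SNPs into QTL.

    Repeatedly takes the remaining SNP with the lowest p-value as a
    peak and absorbs remaining same-chromosome significant SNPs with
    r^2 above the threshold to that peak.  Clusters are returned in
    (chromosome, position) order of their peaks.
    """
    sig = assoc.loc[assoc["significant"]].copy()
    clusters = []
    remaining = sig.sort_values(["p", "chrom", "pos"]).reset_index(drop=True)
    while not remaining.empty:
        peak = remaining.iloc[0]
        same = remaining.iloc[1:]
        members, r2s = [], []
        drop = [remaining.index[0]]
        for idx, row in same.iterrows():
            if row["chrom"] != peak["chrom"]:
                continue
            r2 = ld_r2(g, row["snp"], peak["snp"])
            if r2 > r2_threshold:
                members.append(row["snp"])
                r2s.append(r2)
                drop.append(idx)
        clusters.append(
            QTLCluster(
                peak=str(peak["snp"]),
                chrom=str(peak["chrom"]),
                pos=int(peak["pos"]),
                peak_p=float(peak["p"]),
                members=tuple(members),
                member_r2=tuple(r2s),
            )
        )
        remaining = remaining.drop(index=drop)
    clusters.sort(key=lambda c: (c.chrom, c.pos))
    return clusters


@dataclass
class PhaseSummary:
    """Two-locus allelic phase counts over an inbred panel."""

    n_informative: int
    n_coupling: int
    n_repulsion: int
    n_favorable_favorable: int

    @property
    def coupling_fraction(self) -> float:
        return self.n_coupling / self.n_informative

    @property
    def repulsion_fraction(self) -> float:
        return self.n_repulsion / self.n_informative

    @property
    def favorable_fraction(self) -> float:
        return self.n_favorable_favorable / self.n_informative


def classify_phase(
    g: GenotypeMatrix, locus_a, locus_b, favorable_a: float, favorable_b: float
) -> PhaseSummary:
    """Coupling vs repulsion of two loci across inbred lines.

    ``favorable_a`` / ``favorable_b`` are the favorable homozygous
    dosage (0 or 2) at each locus.  A line is in coupling when its two
    alleles are both favorable or both unfavorable; lines missing or
    heterozygous at either locus are excluded (with a warning).
    """
    a = _dosage_at(g, locus_a)
    b = _dosage_at(g, locus_b)
    het = (a == 1) | (b == 1)
    if het.any():
        warnings.warn(f"excluding {int(het.sum())} heterozygous line(s)",
                      stacklevel=2)
    ok = ~(np.isnan(a) | np.isnan(b)) & ~het
    if not ok.any():
        raise ValueError("no informative lines at this locus pair")
    fa = a[ok] == favorable_a
    fb = b[ok] == favorable_b
    coupling = fa == fb
    return PhaseSummary(
        n_informative=int(ok.sum()),
        n_coupling=int(coupling.sum()),
        n_repulsion=int((~coupling).sum()),
        n_favorable_favorable=int((fa & fb).sum()),
    )
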