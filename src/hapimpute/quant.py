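"""Downstream uses of (imputed) genotypes: GRM, mixed-model GWAS, GBLUP.

The association scan follows the EMMAX/FaST-LMM recipe: variance
components of the null model ``y = Xb + g + e`` with ``g ~ N(0, sg2 K)``
are estimated once by REML via the eigendecomposition of the genomic
relationship matrix ``K``, and every SNP is then tested by generalized
least squares with the null variance ratio held fixed. Genomic prediction
is standard GBLUP: the held-out breeding values are the conditional means
given the training records under the fitted variance components.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GRMatrix",
    "compute_grm",
    "GWASResult",
    "lmm_gwas",
    "EBVReport",
    "gblup_cv",
    "gblup_predict",
    "Concordance",
    "concordance",
]


@dataclass
class GRMatrix:
    """Centered genomic relationship matrix with its animal order."""

    values: np.ndarray
    animal_ids: np.ndarray
    n_snps_used: int


def compute_grm(genotypes: GenotypeMatrix, scale: str = "vanraden") -> GRMatrix:
    """Centered GRM ``W W' / c`` with columns centered by twice the allele
    frequency.

    ``scale="vanraden"`` divides by ``2 * sum p_j q_j`` (mean diagonal ~ 1
    under HWE); ``scale="mean"`` divides by the SNP count, the plain
    centered convention. Missing dosages are mean-filled with a warning;
    monomorphic SNPs are dropped (count logged).
    """
    dos = genotypes.dosage.astype(float)
    miss = genotypes.dosage == MISSING
    if miss.any():
        warnings.warn("missing genotypes mean-filled for GRM", stacklevel=2)
        dos[miss] = np.nan
        col = np.nanmean(dos, axis=0)
        inds = np.where(np.isnan(dos))
        dos[inds] = np.take(col, inds[1])
    p = dos.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    n_drop = int((~poly).sum())
    if n_drop:
        logger.info("compute_grm: dropped %d monomorphic SNPs", n_drop)
    dos, p = dos[:, poly], p[poly]
    w = dos - 2.0 * p
    if scale == "vanraden":
        denom = 2.0 * np.sum(p * (1.0 - p))
    elif scale == "mean":
        denom = dos.shape[1]
    else:
        raise ValueError("scale must be 'vanraden' or 'mean'")
    values = w @ w.T / denom
    return GRMatrix(values=values, animal_ids=genotypes.animal_ids.copy(), n_snps_used=int(poly.sum()))


def _psd_eigh(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d, u = np.linalg.eigh((K + K.T) / 2.0)
    if d.min() < -1e-8:
        logger.info("non-PSD relationship matrix: clipping %d negative eigenvalues", int((d < 0).sum()))
    return np.clip(d, 0.0, None), u


def _reml_delta(d: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> float:
    """REML estimate of delta = se2/sg2 on the rotated model, by bounded
    scalar optimization over log10(delta)."""
    n, p = Xt.shape

    def neg_reml(log_delta: float) -> float:
        delta = 10.0**log_delta
        w = 1.0 / (d + delta)
        XtW = Xt * w[:, None]
        xtx = XtW.T @ Xt
        beta = np.linalg.solve(xtx, XtW.T @ yt)
        r = yt - Xt @ beta
        rss = float(np.sum(w * r * r))
        sg2 = rss / (n - p)
        ll = -0.5 * (
            (n - p) * np.log(2.0 * np.pi * sg2)
            + np.sum(np.log(d + delta))
            + np.linalg.slogdet(xtx)[1]
            + (n - p)
        )
        return -ll

    grid = np.linspace(-5.0, 5.0, 21)
    vals = [neg_reml(g) for g in grid]
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_reml, bounds=(lo, hi), method="bounded")
    return float(10.0**res.x)


def _fit_null(K: np.ndarray, y: np.ndarray, X: np.ndarray) -> dict:
    d, u = _psd_eigh(K)
    yt, Xt = u.T @ y, u.T @ X
    delta = _reml_delta(d, yt, Xt)
    w = 1.0 / (d + delta)
    XtW = Xt * w[:, None]
    beta = np.linalg.solve(XtW.T @ Xt, XtW.T @ yt)
    r = yt - Xt @ beta
    sg2 = float(np.sum(w * r * r) / (len(y) - X.shape[1]))
    se2 = sg2 * delta
    return {"d": d, "u": u, "delta": delta, "sigma2_g": sg2, "sigma2_e": se2, "beta0": beta}


@dataclass
class GWASResult:
    """Per-SNP effect sizes and Wald tests from the mixed-model scan."""

    table: pd.DataFrame          # columns: beta, se, stat, p, tested
    sigma2_g: float
    sigma2_e: float

    def to_tsv(self, path, marker_map=None) -> None:
        tab = self.table
        if marker_map is not None:
            tab = pd.concat(
                [marker_map.table[["chrom", "snp_id", "pos_bp"]].reset_index(drop=True), tab], axis=1
            )
        tab.to_csv(path, sep="\t", index=False)


def lmm_gwas(
    genotypes: GenotypeMatrix,
    y: np.ndarray,
    grm: GRMatrix | np.ndarray,
    covariates: np.ndarray | None = None,
    exact: bool = False,
) -> GWASResult:
    """Mixed-model association scan with the null variance ratio fixed.

    Each SNP is added to the null fixed effects (intercept + covariates)
    and tested by GLS under ``V = sg2 K + se2 I``; ``exact=True``
    re-estimates the variance ratio per SNP (slower, near-identical at
    these sizes). Zero-variance SNPs are flagged and not tested.
    """
    K = grm.values if isinstance(grm, GRMatrix) else np.asarray(grm)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if np.isnan(y).any():
        raise ValueError("phenotype must be complete")
    X0 = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])

    null = _fit_null(K, y, X0)
    d, u, delta = null["d"], null["u"], null["delta"]
    w = 1.0 / (d + delta)
    a = np.sqrt(w)

    dos = genotypes.dosage.astype(float)
    dos[genotypes.dosage == MISSING] = np.nan
    colmean = np.nanmean(dos, axis=0)
    inds = np.where(np.isnan(dos))
    dos[inds] = np.take(colmean, inds[1])

    yt = a * (u.T @ y)
    Xt = a[:, None] * (u.T @ X0)
    Gt = a[:, None] * (u.T @ dos)

    # residualize against null fixed effects (FWL)
    Q = np.linalg.solve(Xt.T @ Xt, Xt.T)
    yr = yt - Xt @ (Q @ yt)
    Gr = Gt - Xt @ (Q @ Gt)

    gg = np.einsum("ij,ij->j", Gr, Gr)
    tested = gg > 1e-12
    gy = Gr.T @ yr
    dof = n - X0.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(tested, gy / gg, np.nan)
        rss = float(yr @ yr) - np.where(tested, beta**2 * gg, 0.0)
        s2 = rss / dof
        se = np.sqrt(np.where(tested, s2 / np.where(tested, gg, 1.0), np.nan))
        tstat = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), df=dof)

    if exact:
        for j in np.flatnonzero(tested):
            Xj = np.column_stack([X0, dos[:, j]])
            fit = _fit_null(K, y, Xj)
            wj = 1.0 / (fit["d"] + fit["delta"])
            Xjt = (fit["u"].T @ Xj) * np.sqrt(wj)[:, None]
            yjt = (fit["u"].T @ y) * np.sqrt(wj)
            xtx = Xjt.T @ Xjt
            bj = np.linalg.solve(xtx, Xjt.T @ yjt)
            rj = yjt - Xjt @ bj
            s2j = float(rj @ rj) / (n - Xj.shape[1])
            cov = s2j * np.linalg.inv(xtx)
            beta[j] = bj[-1]
            se[j] = np.sqrt(cov[-1, -1])
            tstat[j] = beta[j] / se[j]
            pval[j] = 2.0 * stats.t.sf(abs(tstat[j]), df=n - Xj.shape[1])

    table = pd.DataFrame({"beta": beta, "se": se, "stat": tstat, "p": pval, "tested": tested})
    return GWASResult(table=table, sigma2_g=null["sigma2_g"], sigma2_e=null["sigma2_e"])


def gblup_predict(
    K: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    sigma2_g: float,
    sigma2_e: float,
) -> np.ndarray:
    """Conditional-mean GBLUP of held-out animals given training records.

    ``ghat_test = sg2 K[test, train] V^-1 (y_train - mu)`` with
    ``V = sg2 K[train, train] + se2 I`` and ``mu`` the GLS intercept.
    """
    Ktt = K[np.ix_(train_idx, train_idx)]
    V = sigma2_g * Ktt + sigma2_e * np.eye(len(train_idx))
    try:
        Vinv_y = np.linalg.solve(V, y[train_idx])
        ones = np.ones(len(train_idx))
        Vinv_1 = np.linalg.solve(V, ones)
    except np.linalg.LinAlgError:
        logger.info("singular training V: adding 1e-8 ridge")
        V = V + 1e-8 * np.eye(len(train_idx))
        Vinv_y = np.linalg.solve(V, y[train_idx])
        ones = np.ones(len(train_idx))
        Vinv_1 = np.linalg.solve(V, ones)
    mu = float(ones @ Vinv_y / (ones @ Vinv_1))
    resid = np.linalg.solve(V, y[train_idx] - mu)
    return sigma2_g * K[np.ix_(test_idx, train_idx)] @ resid


@dataclass
class EBVReport:
    """Cross-validated genomic prediction accuracy.

    ``r`` is the across-fold mean correlation of held-out EBV with
    phenotype; ``pa_pooled`` pools all held-out animals before
    correlating; ``r_h2_scaled`` divides ``r`` by the square root of the
    mean estimated heritability (an accuracy-style rescaling). All three
    are emitted because the field uses several conventions.
    """

    per_animal: pd.DataFrame     # columns: animal, fold, ebv, y
    r: float
    pa_pooled: float
    r_h2_scaled: float
    h2_hat: float

    def to_tsv(self, path) -> None:
        self.per_animal.to_csv(path, sep="\t", index=False)


def gblup_cv(
    grm: GRMatrix | np.ndarray,
    y: np.ndarray,
    k_folds: int = 5,
    seed: int = 0,
    animal_ids=None,
) -> EBVReport:
    """K-fold cross-validated GBLUP with per-fold REML variance components."""
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    K = grm.values if isinstance(grm, GRMatrix) else np.asarray(grm)
    if animal_ids is None:
        animal_ids = grm.animal_ids if isinstance(grm, GRMatrix) else np.arange(len(y)).astype(str)
    y = np.asarray(y, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k_folds)

    rows, fold_r, fold_h2 = [], [], []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx)
        X = np.ones((len(train_idx), 1))
        fit = _fit_null(K[np.ix_(train_idx, train_idx)], y[train_idx], X)
        sg2, se2 = fit["sigma2_g"], fit["sigma2_e"]
        ebv = gblup_predict(K, y, train_idx, test_idx, sg2, se2)
        if np.std(ebv) > 0 and np.std(y[test_idx]) > 0:
            fold_r.append(float(np.corrcoef(ebv, y[test_idx])[0, 1]))
        fold_h2.append(sg2 / (sg2 + se2) if sg2 + se2 > 0 else 0.0)
        for i, idx in enumerate(test_idx):
            rows.append({"animal": animal_ids[idx], "fold": f, "ebv": ebv[i], "y": y[idx]})

    per_animal = pd.DataFrame(rows)
    r = float(np.mean(fold_r)) if fold_r else np.nan
    pooled = (
        float(np.corrcoef(per_animal["ebv"], per_animal["y"])[0, 1])
        if per_animal["ebv"].std() > 0
        else np.nan
    )
    h2_hat = float(np.mean(fold_h2))
    r_scaled = r / np.sqrt(h2_hat) if h2_hat > 0 else np.nan
    return EBVReport(per_animal=per_animal, r=r, pa_pooled=pooled, r_h2_scaled=r_scaled, h2_hat=h2_hat)


@dataclass
class Concordance:
    """Agreement between two association scans over a shared SNP panel."""

    corr_p: float
    corr_beta: float
    outliers: pd.DataFrame


def concordance(
    result_real: GWASResult,
    result_imputed: GWASResult,
    maf: np.ndarray | None = None,
    log10_p: bool = False,
    outlier_sd: float = 3.0,
) -> Concordance:
    """Pearson correlation of p-values and effect sizes across SNPs, with
    effect-size outliers flagged at ``outlier_sd`` robust SDs (1.4826 MAD),
    annotated with MAF when given."""
    a, b = result_real.table, result_imputed.table
    if len(a) != len(b):
        warnings.warn("SNP panels differ in length; truncating to the shorter", stacklevel=2)
        k = min(len(a), len(b))
        a, b = a.iloc[:k], b.iloc[:k]
    ok = a["tested"].to_numpy() & b["tested"].to_numpy()
    pa, pb = a["p"].to_numpy()[ok], b["p"].to_numpy()[ok]
    if log10_p:
        pa, pb = -np.log10(pa), -np.log10(pb)
    ba, bb = a["beta"].to_numpy()[ok], b["beta"].to_numpy()[ok]

    corr_p = float(np.corrcoef(pa, pb)[0, 1])
    corr_beta = float(np.corrcoef(ba, bb)[0, 1])

    diff = ba - bb
    mad = np.median(np.abs(diff - np.median(diff)))
    robust_sd = 1.4826 * mad
    # MAD of 0 means most effects agree exactly: flag any strict deviation
    thresh = outlier_sd * robust_sd if robust_sd > 0 else 0.0
    snp_idx = np.flatnonzero(ok)
    dev = np.abs(diff - np.median(diff))
    out_sel = dev > thresh if thresh > 0 else dev > 0
    outliers = pd.DataFrame({
        "snp_index": snp_idx[out_sel],
        "beta_real": ba[out_sel],
        "beta_imputed": bb[out_sel],
    })
    if maf is not None:
        outliers["maf"] = np.asarray(maf)[snp_idx[out_sel]]
    return Concordance(corr_p=corr_p, corr_beta=corr_beta, outliers=outliers)
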