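"""Marker-wise quality control on dosage matrices.

Only the genotype-derivable filters are implemented: per-SNP call rate,
minor allele frequency, and a Hardy-Weinberg equilibrium chi-square test.
Array-intensity filters need raw cluster data and are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, GenotypeMatrix, MarkerMap

__all__ = ["QCReport", "filter_markers", "minor_allele_frequency", "hwe_chi2"]

FILTER_ORDER = ("call_rate", "maf", "hwe")


@dataclass
class QCReport:
    """Per-filter removal counts plus the surviving marker indices.

    A SNP failing several filters is attributed to the first one in the
    fixed order call_rate -> maf -> hwe.
    """

    n_input: int
    removed: dict[str, int]
    surviving: np.ndarray
    removed_by: pd.Series  # index = removed SNP rank, value = filter name

    def summary_frame(self) -> pd.DataFrame:
        rows = [{"filter": f, "n_removed": self.removed.get(f, 0)} for f in FILTER_ORDER]
        rows.append({"filter": "surviving", "n_removed": len(self.surviving)})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.summary_frame().to_csv(path, sep="\t", index=False)


def minor_allele_frequency(dosage: np.ndarray) -> np.ndarray:
    """Per-SNP minor allele frequency over non-missing genotypes.

    Dosage counts copies of the designated minor allele, but after masking
    or subsetting the empirical minor allele can flip, so the folded
    frequency min(p, 1-p) is returned. All-missing SNPs give NaN.
    """
    dos = np.array(dosage, dtype=float, copy=True)
    dos[np.asarray(dosage) == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(dos, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def hwe_chi2(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson 1-d.f. chi-square test of Hardy-Weinberg proportions per SNP.

    Returns (chi2, p_value); monomorphic SNPs get chi2 = 0, p = 1.
    """
    dos = np.asarray(dosage)
    obs = np.stack([(dos == g).sum(axis=0) for g in (0, 1, 2)]).astype(float)  # (3, m)
    n = obs.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * obs[2] + obs[1]) / (2 * n)
        exp = np.stack([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0).sum(axis=0)
    chi2 = np.where((p <= 0) | (p >= 1) | (n == 0), 0.0, chi2)
    pval = stats.chi2.sf(chi2, df=1)
    pval = np.where(chi2 == 0.0, 1.0, pval)
    return chi2, pval


def filter_markers(
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap | None = None,
    maf_min: float = 0.01,
    call_rate_min: float = 0.984,
    hwe_alpha: float = 1e-6,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove SNPs failing call rate, MAF, or HWE, in that order.

    A SNP fails call rate when the non-missing fraction is below
    ``call_rate_min``; MAF below ``maf_min`` (computed on non-missing
    genotypes); HWE when the 1-d.f. chi-square p-value drops below
    ``hwe_alpha``. Returns the filtered matrix and a :class:`QCReport`.
    If a marker map is given the filtered map can be obtained via
    ``marker_map.subset(report.surviving)``.
    """
    if genotypes.n_snps == 0:
        raise ValueError("empty genotype matrix")
    dos = genotypes.dosage
    n = genotypes.n_animals

    call_rate = (dos != MISSING).sum(axis=0) / n
    maf = minor_allele_frequency(dos)
    _, hwe_p = hwe_chi2(dos)

    fail_cr = call_rate < call_rate_min
    fail_maf = np.isnan(maf) | (maf < maf_min)
    fail_hwe = hwe_p < hwe_alpha

    removed_by = np.full(genotypes.n_snps, "", dtype=object)
    removed_by[fail_hwe] = "hwe"
    removed_by[fail_maf] = "maf"
    removed_by[fail_cr] = "call_rate"

    surviving = np.flatnonzero(removed_by == "")
    removed_counts = {f: int((removed_by == f).sum()) for f in FILTER_ORDER}
    if len(surviving) == 0:
        warnings.warn("all SNPs removed by QC", stacklevel=2)

    rem_idx = np.flatnonzero(removed_by != "")
    report = QCReport(
        n_input=genotypes.n_snps,
        removed=removed_counts,
        surviving=surviving,
        removed_by=pd.Series(removed_by[rem_idx], index=rem_idx),
    )
    return genotypes.subset_snps(surviving), report
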