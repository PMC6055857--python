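"""Imputation accuracy statistics.

Two animal-wise measures are scored over the masked slots only: the
percentage of correctly imputed discrete genotypes (% correct) and the
Pearson correlation between true and imputed genotypes after per-SNP
standardization, which corrects for allele frequency so that rare-allele
SNPs do not inflate apparent accuracy. A SNP-wise correlation, binned by
HighD MAF, exposes the dependence of accuracy on allele frequency, and a
genomic-relatedness summary characterizes how close each validation animal
is to the reference panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .qc import minor_allele_frequency

__all__ = [
    "MAF_BIN_EDGES",
    "maf_bin_labels",
    "percent_correct",
    "standardized_corr_animal",
    "snp_corr_by_maf",
    "relatedness_summary",
    "AccuracyReport",
    "evaluate",
]

# half-open MAF bins covering [0, 0.5)
MAF_BIN_EDGES = np.array([0.0, 0.025, 0.05, 0.075, 0.1, 0.2, 0.3, 0.4, 0.5])


def maf_bin_labels() -> list[str]:
    return [f"[{lo:g},{hi:g})" for lo, hi in zip(MAF_BIN_EDGES[:-1], MAF_BIN_EDGES[1:])]


def _check_shapes(true: GenotypeMatrix, imputed: GenotypeMatrix, masked: np.ndarray) -> None:
    if true.dosage.shape != imputed.dosage.shape or masked.shape != true.dosage.shape:
        raise ValueError("true, imputed and masked-slot arrays must share one shape")


def percent_correct(
    true: GenotypeMatrix,
    imputed: GenotypeMatrix,
    masked_slots: np.ndarray,
) -> pd.Series:
    """Per-animal percentage of masked slots imputed to the true genotype.

    Animals with zero masked slots are excluded with a warning.
    """
    _check_shapes(true, imputed, masked_slots)
    n_masked = masked_slots.sum(axis=1)
    agree = (true.dosage == imputed.dosage) & masked_slots
    with np.errstate(invalid="ignore"):
        pct = 100.0 * agree.sum(axis=1) / n_masked
    keep = n_masked > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} animals with no masked slots excluded", stacklevel=2)
    return pd.Series(pct[keep], index=true.animal_ids[keep], name="percent_correct")


def _standardize_params(true: GenotypeMatrix, masked_slots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP mean and SD of true genotypes over validation animals (rows
    with at least one masked slot)."""
    val_rows = masked_slots.any(axis=1)
    g = true.dosage[val_rows].astype(float)
    mu = g.mean(axis=0)
    sd = g.std(axis=0)
    return mu, sd


def standardized_corr_animal(
    true: GenotypeMatrix,
    imputed: GenotypeMatrix,
    masked_slots: np.ndarray,
    freqs_from: GenotypeMatrix | None = None,
) -> pd.Series:
    """Per-animal Pearson correlation of standardized true vs imputed
    genotypes across that animal's masked slots.

    Standardization is ``z = (g - mu_j) / sd_j`` with ``mu_j``, ``sd_j`` the
    empirical mean and SD of the *true* genotypes of the validation animals
    (``freqs_from`` overrides the matrix used). SNPs with zero true SD are
    excluded; animals with fewer than two usable slots are reported NaN and
    excluded from scenario means.
    """
    _check_shapes(true, imputed, masked_slots)
    mu, sd = _standardize_params(freqs_from if freqs_from is not None else true, masked_slots)
    usable_snp = sd > 0

    out = np.full(true.n_animals, np.nan)
    zt_all = np.where(usable_snp, (true.dosage - mu) / np.where(usable_snp, sd, 1.0), np.nan)
    zi_all = np.where(usable_snp, (imputed.dosage - mu) / np.where(usable_snp, sd, 1.0), np.nan)
    for i in range(true.n_animals):
        sel = masked_slots[i] & usable_snp
        if sel.sum() < 2:
            continue
        zt, zi = zt_all[i, sel], zi_all[i, sel]
        # z-scores are O(1); treat numerically-zero spread as undefined
        if zt.std() < 1e-12 or zi.std() < 1e-12:
            continue
        out[i] = np.corrcoef(zt, zi)[0, 1]
    has_mask = masked_slots.any(axis=1)
    return pd.Series(out[has_mask], index=true.animal_ids[has_mask], name="corr")


def snp_corr_by_maf(
    true: GenotypeMatrix,
    imputed: GenotypeMatrix,
    masked_slots: np.ndarray,
    highd_maf: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-SNP true/imputed correlation across validation animals, averaged
    within MAF bins.

    Per-SNP standardization is a linear map, so SNP-wise Pearson is computed
    on raw dosages. Bins use the MAF estimated in the full (HighD) data when
    ``highd_maf`` is not supplied. Empty bins are reported NaN.

    A SNP whose truth varies but whose imputation is constant (typically a
    rare allele whose carriers were all missed) is scored 0: a constant
    prediction carries no information about the varying truth. SNPs with
    constant truth are undefined and excluded.
    """
    _check_shapes(true, imputed, masked_slots)
    if highd_maf is None:
        highd_maf = minor_allele_frequency(true.dosage)
    m = true.n_snps
    snp_corr = np.full(m, np.nan)
    for j in range(m):
        sel = masked_slots[:, j]
        if sel.sum() < 2:
            continue
        t = true.dosage[sel, j].astype(float)
        im = imputed.dosage[sel, j].astype(float)
        if t.std() == 0:
            continue
        if im.std() == 0:
            snp_corr[j] = 0.0
            continue
        snp_corr[j] = np.corrcoef(t, im)[0, 1]

    bin_idx = np.digitize(highd_maf, MAF_BIN_EDGES[1:-1], right=False)
    rows = []
    for b, label in enumerate(maf_bin_labels()):
        sel = (bin_idx == b) & ~np.isnan(snp_corr)
        rows.append({
            "maf_bin": label,
            "n_snps": int(sel.sum()),
            "mean_corr": float(snp_corr[sel].mean()) if sel.any() else np.nan,
        })
    frame = pd.DataFrame(rows)
    frame.attrs["snp_corr"] = snp_corr
    return frame


def relatedness_summary(
    grm: np.ndarray,
    animal_ids,
    reference_ids,
    validation_ids,
) -> pd.DataFrame:
    """GRmean and GRmax of each validation animal against the reference set."""
    ref = set(reference_ids)
    val = set(validation_ids)
    if ref & val:
        raise ValueError("reference and validation sets overlap")
    lookup = {a: i for i, a in enumerate(animal_ids)}
    ref_idx = np.array([lookup[a] for a in reference_ids], dtype=np.intp)
    rows = []
    for a in validation_ids:
        r = grm[lookup[a], ref_idx]
        rows.append({"animal": a, "gr_mean": float(r.mean()), "gr_max": float(r.max())})
    return pd.DataFrame(rows)


@dataclass
class AccuracyReport:
    """Scenario-level accuracy: animal-wise statistics plus MAF-bin table."""

    per_animal: pd.DataFrame      # columns percent_correct, corr
    maf_bins: pd.DataFrame

    @property
    def mean_percent_correct(self) -> float:
        return float(self.per_animal["percent_correct"].mean())

    @property
    def sd_percent_correct(self) -> float:
        return float(self.per_animal["percent_correct"].std())

    @property
    def mean_corr(self) -> float:
        return float(self.per_animal["corr"].mean())

    @property
    def sd_corr(self) -> float:
        return float(self.per_animal["corr"].std())

    def summary_row(self) -> dict:
        return {
            "mean_percent_correct": self.mean_percent_correct,
            "sd_percent_correct": self.sd_percent_correct,
            "mean_corr": self.mean_corr,
            "sd_corr": self.sd_corr,
            "n_animals": len(self.per_animal),
        }


def evaluate(
    true: GenotypeMatrix,
    imputed: GenotypeMatrix,
    masked_slots: np.ndarray,
    highd_maf: np.ndarray | None = None,
) -> AccuracyReport:
    """Animal-wise % correct and corr plus the SNP-wise MAF-bin table."""
    pc = percent_correct(true, imputed, masked_slots)
    cr = standardized_corr_animal(true, imputed, masked_slots)
    per_animal = pd.concat([pc, cr], axis=1)
    bins = snp_corr_by_maf(true, imputed, masked_slots, highd_maf=highd_maf)
    return AccuracyReport(per_animal=per_animal, maf_bins=bins)
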