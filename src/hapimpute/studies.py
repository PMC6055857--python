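"""Pre-wired evaluation studies on the standard simulated population.

Each study fixes the cohort (one simulated population), re-draws
reference/validation membership over replicate seeds, runs the imputation
engine, and aggregates accuracy — the desk-scale analogue of the scenario
grids used to characterize imputation on real cohorts. Problem sizes
default to 300 genotyped animals x 3000 SNPs with 10 membership re-draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .accuracy import evaluate
from .containers import MISSING
from .engine import WindowSchedule, impute, phase_reference
from .masking import apply_mask, design_lowd
from .qc import minor_allele_frequency
from .scenarios import anova_relatedness, make_rel_scenario
from .simulate import Population, standard_population

__all__ = [
    "DensityStudy",
    "density_study",
    "relatedness_study",
    "reference_size_study",
    "pedigree_use_study",
]

DEFAULT_KS = (2, 4, 8, 16, 32, 64)


def _seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def _score(pop: Population, phased_ref, val_ids, k: int, pedigree, seed: int,
           schedule: WindowSchedule, highd_maf: np.ndarray):
    g = pop.genotypes
    gm = apply_mask(g, design_lowd(pop.marker_map, k), val_ids)
    masked = (gm.dosage == MISSING) & (g.dosage != MISSING)
    result = impute(gm, pedigree, phased_ref, schedule=schedule, seed=seed)
    return evaluate(g, result.genotypes, masked, highd_maf=highd_maf)


@dataclass
class DensityStudy:
    """Accuracy vs LowD density over membership re-draws."""

    table: pd.DataFrame        # seed, k, mean_percent_correct, mean_corr
    maf_bins: pd.DataFrame     # k, maf_bin, mean_corr (averaged over seeds)

    def mean_corr_by_k(self) -> pd.Series:
        return self.table.groupby("k")["mean_corr"].mean()

    def bin_mean(self, k: int, bin_label: str) -> float:
        sel = (self.maf_bins["k"] == k) & (self.maf_bins["maf_bin"] == bin_label)
        return float(self.maf_bins.loc[sel, "mean_corr"].iloc[0])


def density_study(
    seed: int = 0,
    n_seeds: int = 10,
    ks: tuple[int, ...] = DEFAULT_KS,
    n_ref: int = 200,
    n_val: int = 100,
    n_genotyped: int = 300,
    n_snps: int = 3000,
    population: Population | None = None,
) -> DensityStudy:
    """Fixed population; per replicate draw ``n_ref``/``n_val`` animals at
    random, phase the reference once, and impute at every masking level."""
    pop = population or standard_population(seed=seed, n_genotyped=n_genotyped, n_snps=n_snps)
    g = pop.genotypes
    highd_maf = minor_allele_frequency(g.dosage)
    schedule = WindowSchedule()
    rows, bin_rows = [], []
    for s in _seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        perm = rng.permutation(g.n_animals)
        ref_ids = g.animal_ids[perm[:n_ref]]
        val_ids = g.animal_ids[perm[n_ref: n_ref + n_val]]
        phased = phase_reference(g.subset_animals(ref_ids), schedule, seed=s)
        for k in ks:
            rep = _score(pop, phased, val_ids, k, None, s, schedule, highd_maf)
            rows.append({"seed": s, "k": k,
                         "mean_percent_correct": rep.mean_percent_correct,
                         "mean_corr": rep.mean_corr})
            for _, b in rep.maf_bins.iterrows():
                bin_rows.append({"seed": s, "k": k, "maf_bin": b["maf_bin"],
                                 "mean_corr": b["mean_corr"]})
    table = pd.DataFrame(rows)
    bins = (pd.DataFrame(bin_rows)
            .groupby(["k", "maf_bin"], as_index=False)["mean_corr"].mean())
    return DensityStudy(table=table, maf_bins=bins)


def relatedness_study(
    seed: int = 0,
    n_seeds: int = 10,
    keep_every_k: int = 8,
    n_genotyped: int = 300,
    n_snps: int = 3000,
    population: Population | None = None,
) -> pd.DataFrame:
    """REL (one sib per sire family in the reference) vs the size-matched
    random control, with a per-replicate two-group ANOVA on animal corr."""
    pop = population or standard_population(seed=seed, n_genotyped=n_genotyped, n_snps=n_snps)
    g = pop.genotypes
    highd_maf = minor_allele_frequency(g.dosage)
    schedule = WindowSchedule()
    rows = []
    for s in _seeds(seed, n_seeds):
        rel, rel_c = make_rel_scenario(pop.pedigree, seed=s, keep_every_k=keep_every_k)
        vals = {}
        means = {}
        for spec in (rel, rel_c):
            phased = phase_reference(g.subset_animals(spec.reference_ids), schedule, seed=s)
            rep = _score(pop, phased, spec.validation_ids, keep_every_k,
                         pop.pedigree, s, schedule, highd_maf)
            vals[spec.name] = rep.per_animal["corr"].dropna().to_numpy()
            means[spec.name] = rep.mean_corr
        f, p = anova_relatedness(vals["REL"], vals["REL-C"])
        rows.append({"seed": s, "corr_rel": means["REL"], "corr_relc": means["REL-C"],
                     "anova_f": f, "anova_p": p})
    return pd.DataFrame(rows)


def reference_size_study(
    seed: int = 0,
    n_seeds: int = 10,
    fractions: tuple[float, ...] = (0.9, 0.1),
    keep_every_k: int = 8,
    n_genotyped: int = 300,
    n_snps: int = 3000,
    population: Population | None = None,
) -> pd.DataFrame:
    """Mean corr for large vs small random reference fractions."""
    from .scenarios import make_random_scenario

    pop = population or standard_population(seed=seed, n_genotyped=n_genotyped, n_snps=n_snps)
    g = pop.genotypes
    highd_maf = minor_allele_frequency(g.dosage)
    schedule = WindowSchedule()
    rows = []
    for s in _seeds(seed, n_seeds):
        for frac in fractions:
            spec = make_random_scenario(g.animal_ids, frac, keep_every_k=keep_every_k, seed=s)
            phased = phase_reference(g.subset_animals(spec.reference_ids), schedule, seed=s)
            rep = _score(pop, phased, spec.validation_ids, keep_every_k, None, s,
                         schedule, highd_maf)
            rows.append({"seed": s, "ref_fraction": frac,
                         "mean_percent_correct": rep.mean_percent_correct,
                         "mean_corr": rep.mean_corr})
    return pd.DataFrame(rows)


def pedigree_use_study(
    seed: int = 0,
    n_seeds: int = 10,
    keep_every_k: int = 8,
    n_ref: int = 200,
    n_val: int = 100,
    n_genotyped: int = 300,
    n_snps: int = 3000,
    population: Population | None = None,
) -> pd.DataFrame:
    """Same membership imputed with and without the pedigree pass.

    With few genotyped parents the pedigree pass touches few slots, so the
    expected gap is small but non-negative.
    """
    pop = population or standard_population(seed=seed, n_genotyped=n_genotyped, n_snps=n_snps)
    g = pop.genotypes
    highd_maf = minor_allele_frequency(g.dosage)
    schedule = WindowSchedule()
    rows = []
    for s in _seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        perm = rng.permutation(g.n_animals)
        ref_ids = g.animal_ids[perm[:n_ref]]
        val_ids = g.animal_ids[perm[n_ref: n_ref + n_val]]
        phased = phase_reference(g.subset_animals(ref_ids), schedule, seed=s)
        rep_ped = _score(pop, phased, val_ids, keep_every_k, pop.pedigree, s, schedule, highd_maf)
        rep_nop = _score(pop, phased, val_ids, keep_every_k, None, s, schedule, highd_maf)
        rows.append({"seed": s, "corr_ped": rep_ped.mean_corr, "corr_noped": rep_nop.mean_corr,
                     "pct_ped": rep_ped.mean_percent_correct,
                     "pct_noped": rep_nop.mean_percent_correct})
    return pd.DataFrame(rows)
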