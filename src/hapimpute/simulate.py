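"""Synthetic pedigreed SNP populations.

The generator is the study-conditions stand-in for a real genotyped cohort:
a single autosome of ordered biallelic SNPs in LD, a shallow pedigree with
many sires/dams, a mix of paternal half-sibs, full-sibs and unrelated
animals, and an optional polygenic phenotype.

LD comes from a first-order copying chain on a latent uniform: haplotype h
carries u_j, equal to u_{j-1} with probability ``rho`` and redrawn
Uniform(0,1) otherwise, and the allele at marker ``j`` is the indicator
``u_j < p_j`` with ``p_j`` that marker's frequency drawn from ``maf_law``.
Copying the quantile rather than the realized allele keeps every marker's
marginal frequency exactly ``p_j`` (allele-level copying would smooth
frequencies toward their running mean and empty the low-MAF tail), while
adjacent-marker association still decays geometrically in distance, and —
as in real genomes — a rare marker's r^2 with a common neighbour is capped
by their frequency ratio, which is what makes rare alleles hard to impute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    UNKNOWN_PARENT,
    GenotypeMatrix,
    MarkerMap,
    Pedigree,
    PhasedMatrix,
)

__all__ = [
    "SimParams",
    "simulate_founder_haplotypes",
    "build_pedigree",
    "gene_drop",
    "genotypes_from_phase",
    "random_phase",
    "simulate_phenotype",
    "PhenotypeSim",
    "simulate_population",
    "standard_population",
]


def uniform_maf(low: float = 0.01, high: float = 0.5) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Default founder-MAF law: Uniform(low, high], matching a post-QC panel
    where MAF < 0.01 has been filtered out."""

    def law(rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.uniform(low, high, size=size)

    return law


@dataclass
class SimParams:
    """Founder-haplotype simulation parameters.

    ``ld_strength`` is the adjacent-marker copying probability rho in [0, 1);
    ``maf_law(rng, size)`` draws per-marker allele frequencies with support
    in (0, 0.5]; ``cM_per_Mb`` scales the uniform recombination map.
    """

    n_founders: int
    n_snps: int
    ld_strength: float = 0.9
    maf_law: Callable[[np.random.Generator, int], np.ndarray] = field(default_factory=uniform_maf)
    cM_per_Mb: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not (isinstance(self.n_founders, (int, np.integer)) and self.n_founders > 0):
            raise ValueError("n_founders must be a positive integer")
        if not (isinstance(self.n_snps, (int, np.integer)) and self.n_snps > 0):
            raise ValueError("n_snps must be a positive integer")
        rho = float(self.ld_strength)
        if not np.isfinite(rho) or not (0.0 <= rho < 1.0):
            raise ValueError("ld_strength must be finite and in [0, 1)")
        if not np.isfinite(self.cM_per_Mb) or self.cM_per_Mb < 0:
            raise ValueError("cM_per_Mb must be finite and non-negative")


def simulate_founder_haplotypes(params: SimParams) -> PhasedMatrix:
    """Draw ``2 * n_founders`` haplotypes from the latent copying chain.

    Marker ``j``'s minor-allele frequency ``p_j`` is drawn once from
    ``maf_law``. Each haplotype carries a latent uniform that is copied from
    the previous marker with probability rho and redrawn otherwise; the
    allele is the indicator ``u_j < p_j``. When two adjacent markers share
    the latent (probability rho) their alleles agree whenever the
    frequencies do, which reproduces the match probability
    ``rho + (1 - rho)(p^2 + q^2)`` at equal frequencies.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    m, n_hap = params.n_snps, 2 * params.n_founders
    p = np.asarray(params.maf_law(rng, m), dtype=float)
    if p.shape != (m,) or np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 0.5):
        raise ValueError("maf_law must return frequencies in (0, 0.5]")

    rho = float(params.ld_strength)
    fresh = rng.random((n_hap, m))
    if rho == 0.0:
        u = fresh
    else:
        copy = rng.random((n_hap, m)) < rho
        u = np.empty((n_hap, m))
        u[:, 0] = fresh[:, 0]
        for j in range(1, m):
            u[:, j] = np.where(copy[:, j], u[:, j - 1], fresh[:, j])
    haps = (u < p[None, :]).astype(np.int8)

    ids = np.array([f"f{i:05d}" for i in range(params.n_founders)], dtype=object)
    return PhasedMatrix.from_haplotypes(ids, haps)


class InfeasiblePedigree(ValueError):
    """Raised when the requested pedigree counts cannot coexist; the message
    names the violated constraint."""


def build_pedigree(
    n_genotyped: int,
    n_sires: int,
    n_dams: int,
    n_half_sib: int,
    n_full_sib: int,
    n_genotyped_parents: int = 0,
    seed: int = 0,
) -> Pedigree:
    """Construct a two-generation pedigree matching the requested cohort
    structure.

    The genotyped cohort of ``n_genotyped`` offspring consists of
    full-sib families (size 2, one of size 3 when ``n_full_sib`` is odd),
    paternal half-sib groups (same sire, different dams), and unrelated
    animals each from a unique sire x dam pair. Dams may be shared between
    half-sib groups of different sires so that exactly ``n_dams`` dams are
    used; this never creates extra full-sibs. ``n_genotyped_parents``
    randomly chosen parents are additionally flagged genotyped.
    """
    rng = np.random.default_rng(seed)
    if min(n_genotyped, n_sires, n_dams) <= 0:
        raise InfeasiblePedigree("n_genotyped, n_sires and n_dams must be positive")
    if n_half_sib < 0 or n_full_sib < 0:
        raise InfeasiblePedigree("sib counts must be non-negative")
    if n_half_sib + n_full_sib > n_genotyped:
        raise InfeasiblePedigree("n_half_sib + n_full_sib exceeds n_genotyped")
    if n_full_sib == 1:
        raise InfeasiblePedigree("a single full-sib animal has no sibling (n_full_sib must be 0 or >= 2)")
    if n_half_sib == 1:
        raise InfeasiblePedigree("a single half-sib animal has no sibling (n_half_sib must be 0 or >= 2)")

    n_unrel = n_genotyped - n_half_sib - n_full_sib
    # full-sib families: pairs, last one a triple when the count is odd
    n_full_fam = n_full_sib // 2
    full_sizes = [2] * n_full_fam
    if n_full_sib % 2 == 1:
        full_sizes[-1] = 3

    n_half_grp = n_sires - n_full_fam - n_unrel
    if n_half_sib == 0:
        if n_half_grp != 0:
            raise InfeasiblePedigree(
                f"n_sires must equal n_full_families + n_unrelated = {n_full_fam + n_unrel} when n_half_sib = 0"
            )
        half_sizes: list[int] = []
    else:
        if not (1 <= n_half_grp <= n_half_sib // 2):
            raise InfeasiblePedigree(
                "half-sib sire-group count n_sires - n_full_families - n_unrelated "
                f"= {n_half_grp} must lie in [1, n_half_sib//2]"
            )
        base, rem = divmod(n_half_sib, n_half_grp)
        half_sizes = [base + 1] * rem + [base] * (n_half_grp - rem)

    n_half_dams = n_dams - n_unrel - n_full_fam
    if n_half_sib == 0:
        if n_half_dams != 0:
            raise InfeasiblePedigree(
                f"n_dams must equal n_full_families + n_unrelated = {n_full_fam + n_unrel} when n_half_sib = 0"
            )
    else:
        if n_half_dams < max(half_sizes) or n_half_dams > n_half_sib:
            raise InfeasiblePedigree(
                f"half-sib dam count n_dams - n_unrelated - n_full_families = {n_half_dams} "
                f"must lie in [max half-sib group size = {max(half_sizes)}, n_half_sib = {n_half_sib}]"
            )

    sires = [f"s{i:05d}" for i in range(n_sires)]
    dams = [f"d{i:05d}" for i in range(n_dams)]
    offspring = [f"a{i:05d}" for i in range(n_genotyped)]
    rng.shuffle(offspring)
    off_iter = iter(offspring)

    records: list[tuple[str, str, str]] = []  # (animal, sire, dam)
    sire_iter = iter(sires)
    dam_iter = iter(dams)

    for size in full_sizes:
        s, d = next(sire_iter), next(dam_iter)
        for _ in range(size):
            records.append((next(off_iter), s, d))

    # dams for half-sib slots assigned round-robin: a group never repeats a
    # dam because group size <= number of half-sib dams
    half_dams = [next(dam_iter) for _ in range(max(n_half_dams, 0))]
    slot = 0
    for size in half_sizes:
        s = next(sire_iter)
        for _ in range(size):
            records.append((next(off_iter), s, half_dams[slot % len(half_dams)]))
            slot += 1

    for _ in range(n_unrel):
        records.append((next(off_iter), next(sire_iter), next(dam_iter)))

    parent_rows = [(pid, UNKNOWN_PARENT, UNKNOWN_PARENT, False) for pid in sires + dams]
    geno_parents = set()
    if n_genotyped_parents > 0:
        if n_genotyped_parents > n_sires + n_dams:
            raise InfeasiblePedigree("n_genotyped_parents exceeds the number of parents")
        geno_parents = set(rng.choice(np.asarray(sires + dams, dtype=object),
                                      size=n_genotyped_parents, replace=False))
        parent_rows = [(pid, UNKNOWN_PARENT, UNKNOWN_PARENT, pid in geno_parents)
                       for pid in sires + dams]

    rows = parent_rows + [(a, s, d, True) for a, s, d in records]
    return Pedigree(pd.DataFrame(rows, columns=["animal_id", "sire_id", "dam_id", "genotyped"]))


def _recomb_fractions(marker_map: MarkerMap, cM_per_Mb: float) -> np.ndarray:
    """Haldane recombination fraction between adjacent markers; 0.5 across
    chromosome boundaries."""
    pos = marker_map.pos_bp.astype(float)
    chrom = marker_map.chrom
    d_morgan = np.diff(pos) / 1e6 * cM_per_Mb / 100.0
    r = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
    r[chrom[1:] != chrom[:-1]] = 0.5
    return r


def gene_drop(
    pedigree: Pedigree,
    founders: PhasedMatrix,
    marker_map: MarkerMap,
    cM_per_Mb: float = 1.0,
    seed: int = 0,
) -> PhasedMatrix:
    """Drop founder haplotypes through the pedigree with Haldane
    (no-interference) recombination.

    Every non-founder receives one recombinant gamete per parent; the source
    haplotype switches between adjacent markers with probability
    ``0.5 * (1 - exp(-2d))`` for map distance ``d`` Morgans.
    """
    if marker_map.n_snps != founders.n_snps:
        raise ValueError("marker map and founder haplotypes disagree on SNP count")
    rng = np.random.default_rng(seed)
    m = marker_map.n_snps
    r = _recomb_fractions(marker_map, cM_per_Mb)

    hap_of: dict[str, np.ndarray] = {}
    for i, fid in enumerate(founders.animal_ids):
        hap_of[fid] = founders.alleles[i].T.astype(np.int8)  # (2, m)

    recorded = {row.animal_id: (row.sire_id, row.dam_id) for row in pedigree.table.itertuples()}
    needed = pedigree.founders()
    missing = [f for f in needed if f not in hap_of]
    if missing:
        raise ValueError(f"missing founder haplotypes for {missing[:5]}{'...' if len(missing) > 5 else ''}")

    def meiosis(parent: str) -> np.ndarray:
        haps = hap_of[parent]
        if m == 1:
            return haps[rng.integers(2)].copy()
        switches = rng.random(m - 1) < r
        src = np.empty(m, dtype=np.intp)
        src[0] = rng.integers(2)
        np.cumsum(switches, out=src[1:])
        src[1:] = (src[0] + src[1:]) % 2
        return haps[src, np.arange(m)]

    for aid in pedigree.topological_order():
        if aid in hap_of:
            continue
        if aid not in recorded:
            raise ValueError(f"animal {aid!r} has no haplotypes and no pedigree record")
        sire, dam = recorded[aid]
        if sire == UNKNOWN_PARENT or dam == UNKNOWN_PARENT:
            if aid in hap_of:
                continue
            raise ValueError(f"non-founder {aid!r} has an unknown parent and no founder haplotypes")
        hap_of[aid] = np.stack([meiosis(sire), meiosis(dam)])

    ids = list(founders.animal_ids) + [a for a in pedigree.animal_ids if a not in set(founders.animal_ids)]
    alleles = np.stack([hap_of[a].T for a in ids])
    return PhasedMatrix(np.asarray(ids, dtype=object), alleles)


def genotypes_from_phase(phased: PhasedMatrix) -> GenotypeMatrix:
    """Dosage = sum of the two alleles; missing if either allele is missing."""
    return phased.to_genotypes()


def random_phase(genotypes: GenotypeMatrix, seed: int = 0) -> PhasedMatrix:
    """Split genotypes into an arbitrary (random but seeded) phase; the
    inverse of :func:`genotypes_from_phase` up to haplotype order."""
    rng = np.random.default_rng(seed)
    dos = genotypes.dosage
    a = np.zeros_like(dos)
    b = np.zeros_like(dos)
    het = dos == 1
    first = rng.integers(0, 2, size=dos.shape).astype(np.int8)
    a[het] = first[het]
    b[het] = 1 - first[het]
    hom = dos == 2
    a[hom] = 1
    b[hom] = 1
    miss = dos == MISSING
    a[miss] = MISSING
    b[miss] = MISSING
    return PhasedMatrix(genotypes.animal_ids.copy(), np.stack([a, b], axis=2))


@dataclass
class PhenotypeSim:
    """A simulated polygenic phenotype with its generating components."""

    y: np.ndarray
    qtl_indices: np.ndarray
    effects: np.ndarray
    genetic_values: np.ndarray
    realized_h2: float


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    n_qtl: int,
    h2: float,
    seed: int = 0,
) -> PhenotypeSim:
    """Additive polygenic phenotype ``y = sum_k a_k g_k + e``.

    QTL positions are sampled uniformly, effects are i.i.d. standard normal,
    and the environmental variance is scaled against the realized genetic
    variance so that the realized heritability targets ``h2``.
    """
    if not (0.0 <= h2 <= 1.0):
        raise ValueError("h2 must lie in [0, 1]")
    if n_qtl > genotypes.n_snps:
        raise ValueError("n_qtl exceeds the number of SNPs")
    rng = np.random.default_rng(seed)
    n = genotypes.n_animals

    qtl = np.sort(rng.choice(genotypes.n_snps, size=n_qtl, replace=False))
    effects = rng.standard_normal(n_qtl)
    dos = genotypes.dosage[:, qtl].astype(float)
    dos[dos == MISSING] = np.nan
    col_mean = np.nanmean(dos, axis=0)
    inds = np.where(np.isnan(dos))
    dos[inds] = np.take(col_mean, inds[1])
    g = dos @ effects

    if h2 == 0.0:
        y = rng.standard_normal(n)
        g = np.zeros(n)
        e = y
    elif h2 == 1.0:
        e = np.zeros(n)
        y = g
    else:
        var_g = float(np.var(g))
        e = rng.standard_normal(n) * np.sqrt(var_g * (1.0 - h2) / h2)
        y = g + e
    var_g, var_e = float(np.var(g)), float(np.var(e))
    total = var_g + var_e
    realized = var_g / total if total > 0 else 0.0
    return PhenotypeSim(y=y, qtl_indices=qtl, effects=effects, genetic_values=g, realized_h2=realized)


@dataclass
class Population:
    """A fully simulated cohort: map, pedigree, truth phase and genotypes."""

    marker_map: MarkerMap
    pedigree: Pedigree
    phased: PhasedMatrix            # all pedigree animals, truth phase
    genotypes: GenotypeMatrix       # genotyped cohort only

    @property
    def genotyped_ids(self) -> np.ndarray:
        return self.genotypes.animal_ids


def simulate_population(
    n_genotyped: int,
    n_snps: int,
    n_sires: int,
    n_dams: int,
    n_half_sib: int,
    n_full_sib: int,
    n_genotyped_parents: int = 0,
    ld_strength: float = 0.9,
    maf_law: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None,
    cM_per_Mb: float = 1.0,
    chrom_length_bp: int = 122_680_000,
    seed: int = 0,
) -> Population:
    """Wire the generator end to end: pedigree, founder haplotypes, gene
    dropping, and the genotyped cohort's dosage matrix."""
    ss = np.random.SeedSequence(seed)
    s_ped, s_founder, s_drop = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))

    pedigree = build_pedigree(
        n_genotyped, n_sires, n_dams, n_half_sib, n_full_sib,
        n_genotyped_parents=n_genotyped_parents, seed=s_ped,
    )
    marker_map = MarkerMap.uniform(n_snps, length_bp=chrom_length_bp)
    founder_ids = pedigree.founders()
    params = SimParams(
        n_founders=len(founder_ids), n_snps=n_snps, ld_strength=ld_strength,
        maf_law=maf_law if maf_law is not None else uniform_maf(),
        cM_per_Mb=cM_per_Mb, seed=s_founder,
    )
    founders = simulate_founder_haplotypes(params)
    founders = PhasedMatrix(founder_ids, founders.alleles)

    phased = gene_drop(pedigree, founders, marker_map, cM_per_Mb=cM_per_Mb, seed=s_drop)
    cohort = phased.subset_animals(pedigree.genotyped_ids)
    genotypes = cohort.to_genotypes()
    return Population(marker_map=marker_map, pedigree=pedigree, phased=phased, genotypes=genotypes)


def standard_population(seed: int = 0, n_genotyped: int = 300, n_snps: int = 3000) -> Population:
    """The package's standard simulated cohort for evaluation studies.

    Defaults scale the structure of a 1179-dog genotyped cohort (1.63
    offspring per sire, 1.10 per dam, ~46% half-sibs, ~11% full-sibs, few
    genotyped parents, high adjacent-marker LD) down to a 300-animal,
    3000-SNP desk-scale population.
    """
    scale = n_genotyped / 1179.0
    n_sires = max(2, round(725 * scale))
    n_dams = max(2, round(1069 * scale))
    n_half = 2 * round(547 * scale / 2)
    n_full = 2 * round(131 * scale / 2)
    n_gp = max(1, round(26 * scale))
    return simulate_population(
        n_genotyped=n_genotyped, n_snps=n_snps,
        n_sires=n_sires, n_dams=n_dams,
        n_half_sib=n_half, n_full_sib=n_full,
        n_genotyped_parents=n_gp, ld_strength=0.9, seed=seed,
    )
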