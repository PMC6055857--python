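"""Two-pass genotype imputation: pedigree deduction then haplotype windows.

The engine mirrors the family of pedigree + population imputation tools
used in animal breeding. Pass one makes only deterministic Mendelian fills
from genotyped relatives. Pass two phases the reference panel and matches
each target animal's observed low-density genotypes against a library of
reference haplotypes inside overlapping sliding windows whose length
shrinks geometrically from the whole chromosome down to a few observed
markers: long windows capture close relatives sharing long haplotypes,
short windows capture population-level LD. Longer windows take precedence
for the slots they resolve; slots no consistent haplotype pair ever covers
fall back to twice the reference allele frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, Pedigree, PhasedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSchedule",
    "HaplotypeLibrary",
    "ImputationResult",
    "pedigree_impute",
    "phase_reference",
    "build_library",
    "population_impute",
    "impute",
    "PROVENANCE_LABELS",
]

# per-slot provenance codes in ImputationResult.provenance
OBSERVED, PEDIGREE, POPULATION, FALLBACK = 0, 1, 2, 3
PROVENANCE_LABELS = np.array(["observed", "pedigree", "population", "frequency_fallback"])


@dataclass
class WindowSchedule:
    """Geometric long-to-short window schedule.

    Level ``l`` has length ``max(min_window, round(L0 * (1-shrink)**l))``
    markers with ``L0`` the chromosome length (or ``init_window``);
    successive windows at a level overlap by ``overlap`` of their length.
    Defaults follow the conventional sliding-window settings
    (shrink 0.150, overlap 0.650).
    """

    init_window: int | None = None
    shrink: float = 0.150
    overlap: float = 0.650
    min_window: int = 3
    max_phase_iter: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.shrink < 1.0:
            raise ValueError("shrink must be in (0, 1)")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")
        if self.min_window < 1:
            raise ValueError("min_window must be >= 1")

    def levels(self, n_markers: int, min_window: int | None = None) -> list[int]:
        """Strictly decreasing window lengths, longest first."""
        L0 = min(self.init_window or n_markers, n_markers)
        Lmin = min(min_window if min_window is not None else self.min_window, n_markers)
        Lmin = max(1, Lmin)
        out: list[int] = []
        level = 0
        while True:
            L = int(max(Lmin, round(L0 * (1.0 - self.shrink) ** level)))
            L = min(L, n_markers)
            if not out or L < out[-1]:
                out.append(L)
            if L <= Lmin:
                return out
            level += 1

    def windows(self, length: int, n_markers: int) -> list[tuple[int, int]]:
        """(start, stop) pairs covering [0, n_markers) at one level."""
        if length >= n_markers:
            return [(0, n_markers)]
        step = max(1, round(length * (1.0 - self.overlap)))
        starts = list(range(0, n_markers - length + 1, step))
        if starts[-1] + length < n_markers:
            starts.append(n_markers - length)
        return [(s, s + length) for s in starts]


# ---------------------------------------------------------------------------
# pass one: deterministic Mendelian fills
# ---------------------------------------------------------------------------

def pedigree_impute(genotypes: GenotypeMatrix, pedigree: Pedigree) -> GenotypeMatrix:
    """Fill missing slots that are logically forced by genotyped relatives.

    Rules, applied to fixpoint:

    * both parents homozygous: offspring genotype is the sum of the two
      transmitted alleles (same homozygote -> that homozygote, opposite
      homozygotes -> heterozygote);
    * offspring evidence: a homozygous offspring forces the parent to carry
      that allele; two different forced alleles -> heterozygote;
    * one homozygous parent (fixing one allele) plus an offspring-forced
      allele different from it -> heterozygote of the two.

    Observed parent/offspring pairs that are opposing homozygotes are
    logged as Mendelian inconsistencies and the slot left untouched.
    No probabilistic fills are made.
    """
    out = genotypes.copy()
    dos = out.dosage
    row_of = {a: i for i, a in enumerate(out.animal_ids)}
    ped = pedigree.table

    parents: dict[int, tuple[int | None, int | None]] = {}
    children: dict[int, list[int]] = {}
    for rec in ped.itertuples():
        if rec.animal_id not in row_of:
            continue
        i = row_of[rec.animal_id]
        s = row_of.get(rec.sire_id)
        d = row_of.get(rec.dam_id)
        parents[i] = (s, d)
        for p in (s, d):
            if p is not None:
                children.setdefault(p, []).append(i)

    # Mendelian consistency of observed pairs (opposing homozygotes)
    n_conflict = 0
    for i, (s, d) in parents.items():
        for p in (s, d):
            if p is None:
                continue
            conflict = ((dos[i] == 0) & (dos[p] == 2)) | ((dos[i] == 2) & (dos[p] == 0))
            n_conflict += int(conflict.sum())
    if n_conflict:
        logger.warning("pedigree pass: %d Mendelian-inconsistent observed parent/offspring slots", n_conflict)

    active = set(parents) | set(children)
    for _ in range(8):
        changed = False
        for i in sorted(active):
            miss = dos[i] == MISSING
            if not miss.any():
                continue
            kids = children.get(i, [])
            forced0 = np.zeros(dos.shape[1], dtype=bool)
            forced1 = np.zeros(dos.shape[1], dtype=bool)
            for c in kids:
                forced0 |= dos[c] == 0
                forced1 |= dos[c] == 2

            fill = np.full(dos.shape[1], MISSING, dtype=np.int8)
            # offspring force both alleles
            both = forced0 & forced1
            fill[both] = 1

            s, d = parents.get(i, (None, None))
            sg = dos[s] if s is not None else None
            dg = dos[d] if d is not None else None
            if sg is not None and dg is not None:
                shom = (sg == 0) | (sg == 2)
                dhom = (dg == 0) | (dg == 2)
                bb = shom & dhom
                fill[bb] = ((sg[bb].astype(np.int16) + dg[bb]) // 2).astype(np.int8)
            # one homozygous parent + a contradicting offspring-forced allele
            for pg in (sg, dg):
                if pg is None:
                    continue
                allele1 = (pg == 2) & forced0   # parent gives 1, child forces 0
                allele0 = (pg == 0) & forced1   # parent gives 0, child forces 1
                fill[(allele1 | allele0) & (fill == MISSING)] = 1

            do = miss & (fill != MISSING)
            if do.any():
                dos[i, do] = fill[do]
                changed = True
        if not changed:
            break
    return out


# ---------------------------------------------------------------------------
# pass two: window phasing, haplotype library, consistent-pair voting
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeLibrary:
    """Distinct reference haplotypes within one marker window, with counts."""

    window: tuple[int, int]
    haplotypes: np.ndarray   # (n_distinct, window length) in {0,1}
    counts: np.ndarray       # positive ints, summing to 2 * n_reference

    @property
    def n_distinct(self) -> int:
        return len(self.counts)


def build_library(phased_ref: PhasedMatrix, window: tuple[int, int]) -> HaplotypeLibrary:
    """Count distinct reference haplotypes restricted to ``window``."""
    if phased_ref.n_animals == 0:
        raise ValueError("empty reference panel")
    s, e = window
    if not (0 <= s < e <= phased_ref.n_snps):
        raise ValueError("window outside marker bounds")
    seg = phased_ref.haplotypes()[:, s:e]
    if (seg == MISSING).any():
        raise ValueError("reference phase contains missing alleles")
    uniq, counts = np.unique(seg, axis=0, return_counts=True)
    return HaplotypeLibrary(window=(s, e), haplotypes=uniq, counts=counts)


def phase_reference(
    genotypes: GenotypeMatrix,
    schedule: WindowSchedule | None = None,
    seed: int = 0,
) -> PhasedMatrix:
    """Phase a fully genotyped panel by iterative window voting.

    Within each window, animals whose heterozygous sites are already
    resolved (or that have at most one heterozygote, whose unordered pair
    is determined) contribute their two haplotypes to the window library;
    each remaining animal adopts the most frequent library haplotype
    compatible with its constrained sites, ties broken lexicographically.
    Levels run long to short, repeated up to ``max_phase_iter`` sweeps.
    Heterozygotes never matched are assigned at random (seeded).
    """
    schedule = schedule or WindowSchedule()
    dos = genotypes.dosage
    if (dos == MISSING).any():
        raise ValueError("phase_reference requires complete genotypes")
    n, m = dos.shape
    # hapA: phased allele of the first haplotype; -1 = unresolved heterozygote
    hapA = np.where(dos == 2, 1, 0).astype(np.int8)
    hapA[dos == 1] = MISSING

    lengths = schedule.levels(m)
    for _ in range(schedule.max_phase_iter):
        changed = False
        for L in lengths:
            for s, e in schedule.windows(L, m):
                changed |= _phase_window(dos, hapA, s, e)
        if not changed:
            break

    unres = hapA == MISSING
    if unres.any():
        rng = np.random.default_rng(seed)
        hapA[unres] = rng.integers(0, 2, size=int(unres.sum()), dtype=np.int8)
    hapB = (dos - hapA).astype(np.int8)
    return PhasedMatrix(genotypes.animal_ids.copy(), np.stack([hapA, hapB], axis=2))


def _phase_window(dos: np.ndarray, hapA: np.ndarray, s: int, e: int) -> bool:
    seg = hapA[:, s:e]
    gseg = dos[:, s:e]
    n_unres = (seg == MISSING).sum(axis=1)
    pending = np.flatnonzero(n_unres > 0)
    if len(pending) == 0:
        return False
    donors = np.flatnonzero(n_unres <= 1)
    if len(donors) == 0:
        return False

    # donor haplotypes: a single unresolved het is phase-trivial as an
    # unordered pair, so contribute both orderings
    hA = np.where(seg[donors] == MISSING, 0, seg[donors]).astype(np.int8)
    hB = (gseg[donors] - hA).astype(np.int8)
    lib, counts = np.unique(np.vstack([hA, hB]), axis=0, return_counts=True)

    # mismatch counts against constrained (non-het-unresolved) sites, via BLAS
    known = (seg[pending] != MISSING)
    anchors = np.where(known, seg[pending], 0)
    U = lib.astype(np.float32)
    K = known.astype(np.float32)
    KA = (K * anchors).astype(np.float32)
    mism = U @ K.T + (K * anchors).sum(axis=1)[None, :] - 2.0 * (U @ KA.T)

    changed = False
    for col, row in enumerate(pending):
        comp = np.flatnonzero(mism[:, col] == 0)
        if len(comp) == 0:
            continue
        best = comp[np.argmax(counts[comp])]
        fill = seg[row] == MISSING
        hapA[row, s:e][fill] = lib[best][fill]
        changed = True
    return changed


@dataclass
class ImputationResult:
    """Most-likely genotypes, expected dosages, and per-slot provenance.

    ``most_likely`` rounds ``dosage`` half-to-even to the nearest value of
    {0,1,2}; observed slots pass through unchanged (provenance 0).
    """

    genotypes: GenotypeMatrix
    dosage: np.ndarray       # float, (n_animals, n_snps)
    provenance: np.ndarray   # int8 codes, see PROVENANCE_LABELS

    def provenance_labels(self) -> np.ndarray:
        return PROVENANCE_LABELS[self.provenance]

    def to_frame(self, marker_map=None) -> pd.DataFrame:
        """Long-format table of the imputed (non-observed) slots."""
        rows, cols = np.nonzero(self.provenance != OBSERVED)
        snp = marker_map.snp_ids[cols] if marker_map is not None else cols
        return pd.DataFrame({
            "animal": self.genotypes.animal_ids[rows],
            "snp": snp,
            "dosage": self.dosage[rows, cols],
            "most_likely": self.genotypes.dosage[rows, cols],
            "provenance": PROVENANCE_LABELS[self.provenance[rows, cols]],
        })

    def to_tsv(self, path, marker_map=None) -> None:
        self.to_frame(marker_map).to_csv(path, sep="\t", index=False)


def _round_half_even(dosage: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(dosage), 0, 2).astype(np.int8)


def population_impute(
    genotypes: GenotypeMatrix,
    phased_ref: PhasedMatrix,
    schedule: WindowSchedule | None = None,
    seed: int = 0,
) -> ImputationResult:
    """Impute missing slots from a phased reference by window voting.

    For each target animal and window (longest level first), library
    haplotype pairs whose dosages agree with the animal's observed alleles
    in the window vote, frequency-weighted, for every missing slot the
    window covers; a slot's expected dosage is the vote-weighted mean,
    fixed at the first (longest) level where any consistent pair exists.
    Slots never covered by a consistent pair fall back to twice the
    reference allele frequency.
    """
    schedule = schedule or WindowSchedule()
    if genotypes.n_snps != phased_ref.n_snps:
        raise ValueError("target and reference marker maps differ")
    ref_haps = phased_ref.haplotypes()
    if (ref_haps == MISSING).any():
        raise ValueError("reference phase contains missing alleles")
    n, m = genotypes.dosage.shape

    dosage = genotypes.dosage.astype(float)
    provenance = np.zeros((n, m), dtype=np.int8)
    miss = genotypes.missing_mask()
    targets = np.flatnonzero(miss.any(axis=1))
    if len(targets) == 0:
        return ImputationResult(genotypes.copy(), dosage, provenance)

    rng = np.random.default_rng(seed)
    w1 = rng.integers(1, 2**31, size=m).astype(np.int64)
    w2 = rng.integers(1, 2**31, size=m).astype(np.int64)
    p_ref = ref_haps.mean(axis=0)

    # group target rows by identical observed mask: they share all window work
    obs = ~miss[targets]
    _, grp_ids = np.unique(obs, axis=0, return_inverse=True)
    for g in np.unique(grp_ids):
        rows = targets[grp_ids == g]
        _impute_mask_group(genotypes.dosage, rows, obs[grp_ids == g][0], ref_haps,
                           schedule, w1, w2, p_ref, dosage, provenance)

    most = genotypes.dosage.copy()
    fillable = miss
    most[fillable] = _round_half_even(dosage[fillable])
    return ImputationResult(GenotypeMatrix(genotypes.animal_ids.copy(), most), dosage, provenance)


def _impute_mask_group(
    dos: np.ndarray,
    rows: np.ndarray,
    obs_mask: np.ndarray,
    ref_haps: np.ndarray,
    schedule: WindowSchedule,
    w1: np.ndarray,
    w2: np.ndarray,
    p_ref: np.ndarray,
    dosage_out: np.ndarray,
    provenance: np.ndarray,
) -> None:
    m = dos.shape[1]
    obs_idx = np.flatnonzero(obs_mask)
    n_obs = len(obs_idx)
    # stop shrinking once a window would hold fewer than ~3 observed markers
    spacing = m if n_obs == 0 else int(np.ceil(m / n_obs))
    l_min = max(schedule.min_window, min(m, 3 * spacing))

    g = len(rows)
    unresolved = (dos[rows] == MISSING)
    n_ref_hap = ref_haps.shape[0]
    MIX = np.uint64(0x9E3779B97F4A7C15)

    # prefix sums of weighted alleles at observed sites: the hash of any
    # window restriction is then one subtraction per haplotype/target
    obs_w1 = np.where(obs_mask, w1, 0)
    obs_w2 = np.where(obs_mask, w2, 0)
    R = ref_haps.astype(np.int64)
    D1 = np.cumsum(R * obs_w1[None, :], axis=1)
    D2 = np.cumsum(R * obs_w2[None, :], axis=1)
    G0 = np.where(obs_mask[None, :], dos[rows], 0).astype(np.int64)
    T1 = np.cumsum(G0 * obs_w1[None, :], axis=1)
    T2 = np.cumsum(G0 * obs_w2[None, :], axis=1)
    n_obs_cum = np.cumsum(obs_mask.astype(np.int64))

    def between(cum: np.ndarray, s: int, e: int) -> np.ndarray:
        return cum[..., e - 1] - (cum[..., s - 1] if s > 0 else 0)

    for L in schedule.levels(m, min_window=l_min):
        if not unresolved.any():
            break
        V = np.zeros((g, m))
        W = np.zeros((g, m))
        for s, e in schedule.windows(L, m):
            win_unres = unresolved[:, s:e]
            if not win_unres.any():
                continue
            active = np.flatnonzero(win_unres.any(axis=1))
            if int(between(n_obs_cum, s, e)) == 0:
                # no observations: every ordered pair is consistent and the
                # expectation is twice the window allele frequency
                seg_mean = ref_haps[:, s:e].mean(axis=0)
                W[active, s:e] += float(n_ref_hap) ** 2
                V[active, s:e] += float(n_ref_hap) ** 2 * 2.0 * seg_mean
                continue

            lib1, lib2 = between(D1, s, e), between(D2, s, e)
            key = (lib1.astype(np.uint64) * MIX) ^ lib2.astype(np.uint64)
            pat, pat_inv = np.unique(key, return_inverse=True)
            n_pat = len(pat)

            ta1 = between(T1, s, e)[active]
            ta2 = between(T2, s, e)[active]
            c1 = ta1[:, None] - lib1[None, :]
            c2 = ta2[:, None] - lib2[None, :]
            ckey = (c1.astype(np.uint64) * MIX) ^ c2.astype(np.uint64)
            pos = np.clip(np.searchsorted(pat, ckey), 0, n_pat - 1)
            hit = pat[pos] == ckey                      # (n_active, n_ref_hap)
            if not hit.any():
                continue

            # votes: sum over consistent ordered pairs of (h1 + h2),
            # decomposed into a first-haplotype term (cw @ seg) and a
            # complement-pattern-group term (q @ S)
            C = np.bincount(pat_inv, minlength=n_pat).astype(float)
            order = np.argsort(pat_inv, kind="stable")
            starts = np.flatnonzero(np.diff(pat_inv[order], prepend=-1))
            seg = ref_haps[:, s:e].astype(float)
            S = np.add.reduceat(seg[order], starts, axis=0)

            cw = np.where(hit, C[pos], 0.0)
            wsum = cw.sum(axis=1)
            ai, ii = np.nonzero(hit)
            q = np.bincount(ai * n_pat + pos[ai, ii], minlength=len(active) * n_pat)
            q = q.reshape(len(active), n_pat).astype(float)
            votes = (cw @ seg) + (q @ S)
            has = wsum > 0
            W[active[has], s:e] += wsum[has, None]
            V[active[has], s:e] += votes[has]
        newly = (W > 0) & unresolved
        if newly.any():
            for a in range(g):
                sel = newly[a]
                if sel.any():
                    dosage_out[rows[a], sel] = V[a, sel] / W[a, sel]
                    provenance[rows[a], sel] = POPULATION
            unresolved &= ~newly

    if unresolved.any():
        fb = 2.0 * p_ref
        for a in range(g):
            sel = unresolved[a]
            if sel.any():
                dosage_out[rows[a], sel] = fb[sel]
                provenance[rows[a], sel] = FALLBACK


def impute(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree | None,
    phased_ref: PhasedMatrix,
    schedule: WindowSchedule | None = None,
    seed: int = 0,
) -> ImputationResult:
    """Run the pedigree pass (if a pedigree is given) then the population
    pass; provenance is recorded per slot.

    Pedigree-resolved slots are final: the population pass runs on the
    original observation mask and its values for those slots are replaced
    by the Mendelian fills, so adding a pedigree can only change slots the
    pedigree logically determines (it never perturbs the rest).
    """
    schedule = schedule or WindowSchedule()
    miss0 = genotypes.missing_mask()
    if pedigree is not None:
        filled = pedigree_impute(genotypes, pedigree)
    else:
        filled = genotypes
    ped_slots = miss0 & ~filled.missing_mask()

    result = population_impute(genotypes, phased_ref, schedule=schedule, seed=seed)
    result.provenance[ped_slots] = PEDIGREE
    result.dosage[ped_slots] = filled.dosage[ped_slots]
    result.genotypes.dosage[ped_slots] = filled.dosage[ped_slots]
    return result
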