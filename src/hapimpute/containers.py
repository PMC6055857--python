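"""Core in-memory containers for the imputation pipeline.

Conventions used throughout the package:

* genotypes are minor-allele dosages coded ``0/1/2`` with ``-1`` for missing;
* phased alleles are ``0/1`` (1 = minor allele) with ``-1`` for missing;
* marker order is always (chromosome, bp position), ranks are 0-based;
* animal identifiers are strings, unknown parents are ``"0"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1
UNKNOWN_PARENT = "0"


@dataclass
class MarkerMap:
    """Ordered SNP map: the coordinate backbone for masking and windows.

    Parameters
    ----------
    table
        DataFrame with columns ``snp_id``, ``chrom``, ``pos_bp``. Rows are
        sorted by (chrom, pos_bp) on construction; the row rank after sorting
        is the marker index used everywhere else.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"snp_id", "chrom", "pos_bp"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"marker map needs columns {sorted(required)}")
        tab = self.table.copy()
        tab["chrom"] = tab["chrom"].astype(str)
        tab["pos_bp"] = tab["pos_bp"].astype(np.int64)
        tab = tab.sort_values(["chrom", "pos_bp"], kind="stable").reset_index(drop=True)
        for _, grp in tab.groupby("chrom", sort=False):
            pos = grp["pos_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing within a chromosome")
        if tab["snp_id"].duplicated().any():
            raise ValueError("duplicate SNP ids in marker map")
        self.table = tab

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def pos_bp(self) -> np.ndarray:
        return self.table["pos_bp"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    def subset(self, indices: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.table.iloc[np.asarray(indices)].reset_index(drop=True))

    @classmethod
    def uniform(cls, n_snps: int, chrom: str = "1", length_bp: int = 122_680_000) -> "MarkerMap":
        """Evenly spaced map over one chromosome (default length mirrors a
        large ~122.68 Mb canine autosome)."""
        pos = np.linspace(1, length_bp, n_snps, dtype=np.int64)
        pos = np.unique(pos)
        if len(pos) != n_snps:  # collisions only when n_snps ~ length_bp
            pos = np.arange(1, n_snps + 1, dtype=np.int64)
        return cls(pd.DataFrame({
            "snp_id": [f"snp{i:06d}" for i in range(n_snps)],
            "chrom": chrom,
            "pos_bp": pos,
        }))


def _as_ids(ids) -> np.ndarray:
    arr = np.asarray(list(ids), dtype=object)
    if len(set(arr)) != len(arr):
        raise ValueError("duplicate animal ids")
    return arr


@dataclass
class GenotypeMatrix:
    """Animals x SNPs minor-allele dosages in {0, 1, 2, -1=missing}."""

    animal_ids: np.ndarray
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.animal_ids = _as_ids(self.animal_ids)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2 or self.dosage.shape[0] != len(self.animal_ids):
            raise ValueError("dosage must be (n_animals, n_snps)")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2,-1}")

    @property
    def n_animals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.animal_ids.copy(), self.dosage.copy())

    def index_of(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        try:
            return np.array([lookup[a] for a in ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown animal id {exc.args[0]!r}") from None

    def subset_animals(self, ids) -> "GenotypeMatrix":
        idx = self.index_of(ids)
        return GenotypeMatrix(self.animal_ids[idx], self.dosage[idx])

    def subset_snps(self, indices: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.animal_ids, self.dosage[:, np.asarray(indices)])


@dataclass
class PhasedMatrix:
    """Animals x SNPs x 2 ordered alleles in {0, 1, -1=missing}."""

    animal_ids: np.ndarray
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.animal_ids = _as_ids(self.animal_ids)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must be (n_animals, n_snps, 2)")
        if self.alleles.shape[0] != len(self.animal_ids):
            raise ValueError("animal ids and allele array disagree")
        if not np.isin(self.alleles, (0, 1, MISSING)).all():
            raise ValueError("alleles must be in {0,1,-1}")

    @property
    def n_animals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    def haplotypes(self) -> np.ndarray:
        """Flat (2*n_animals, n_snps) haplotype matrix; rows 2i, 2i+1 belong
        to animal i."""
        n, m, _ = self.alleles.shape
        return self.alleles.transpose(0, 2, 1).reshape(2 * n, m)

    def to_genotypes(self) -> GenotypeMatrix:
        dos = self.alleles.sum(axis=2).astype(np.int8)
        miss = (self.alleles == MISSING).any(axis=2)
        dos[miss] = MISSING
        return GenotypeMatrix(self.animal_ids.copy(), dos)

    @classmethod
    def from_haplotypes(cls, animal_ids, haps: np.ndarray) -> "PhasedMatrix":
        haps = np.asarray(haps, dtype=np.int8)
        n = haps.shape[0] // 2
        alleles = haps.reshape(n, 2, -1).transpose(0, 2, 1)
        return cls(animal_ids, alleles)

    def subset_animals(self, ids) -> "PhasedMatrix":
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        idx = np.array([lookup[a] for a in ids], dtype=np.intp)
        return PhasedMatrix(self.animal_ids[idx], self.alleles[idx])


@dataclass
class Pedigree:
    """Per-animal sire/dam links with a genotyped flag.

    ``table`` has columns ``animal_id``, ``sire_id``, ``dam_id``,
    ``genotyped``; ``"0"`` marks an unknown parent. Parents that are not
    themselves records are treated as (ungenotyped) founders.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"animal_id", "sire_id", "dam_id"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"pedigree needs columns {sorted(required)}")
        tab = self.table.copy()
        for col in ("animal_id", "sire_id", "dam_id"):
            tab[col] = tab[col].astype(str)
        if "genotyped" not in tab.columns:
            tab["genotyped"] = False
        tab["genotyped"] = tab["genotyped"].astype(bool)
        if tab["animal_id"].duplicated().any():
            raise ValueError("duplicate animal ids in pedigree")
        self.table = tab.reset_index(drop=True)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parents = {
            row.animal_id: (row.sire_id, row.dam_id)
            for row in self.table.itertuples()
        }
        state: dict[str, int] = {}  # 1 = visiting, 2 = done

        for start in parents:
            if state.get(start):
                continue
            stack = [start]
            while stack:
                node = stack[-1]
                if state.get(node) == 2 or node not in parents:
                    state[node] = 2
                    stack.pop()
                    continue
                if state.get(node) == 1:
                    ps = [p for p in parents[node] if p != UNKNOWN_PARENT and state.get(p) != 2]
                    if not ps:
                        state[node] = 2
                        stack.pop()
                        continue
                    if any(state.get(p) == 1 for p in ps):
                        raise ValueError("pedigree contains a cycle (animal is its own ancestor)")
                    stack.extend(ps)
                    continue
                state[node] = 1

    @property
    def animal_ids(self) -> np.ndarray:
        return self.table["animal_id"].to_numpy()

    @property
    def genotyped_ids(self) -> np.ndarray:
        return self.table.loc[self.table["genotyped"], "animal_id"].to_numpy()

    def parents_of(self, animal_id: str) -> tuple[str, str]:
        row = self.table.loc[self.table["animal_id"] == animal_id]
        if row.empty:
            raise KeyError(animal_id)
        return row["sire_id"].iloc[0], row["dam_id"].iloc[0]

    def founders(self) -> np.ndarray:
        """Ids that appear as parents or have both parents unknown and thus
        need simulated founder haplotypes."""
        recorded = set(self.table["animal_id"])
        founder: list[str] = []
        seen = set()
        for row in self.table.itertuples():
            for p in (row.sire_id, row.dam_id):
                if p != UNKNOWN_PARENT and p not in recorded and p not in seen:
                    founder.append(p)
                    seen.add(p)
            if row.sire_id == UNKNOWN_PARENT and row.dam_id == UNKNOWN_PARENT:
                if row.animal_id not in seen:
                    founder.append(row.animal_id)
                    seen.add(row.animal_id)
        return np.asarray(founder, dtype=object)

    def topological_order(self) -> list[str]:
        """All ids (founders first) such that parents precede offspring."""
        recorded = {row.animal_id: (row.sire_id, row.dam_id) for row in self.table.itertuples()}
        order: list[str] = []
        mark: dict[str, int] = {}

        def visit(node: str) -> None:
            stack = [(node, False)]
            while stack:
                cur, expanded = stack.pop()
                if mark.get(cur) == 2:
                    continue
                if expanded or cur not in recorded:
                    mark[cur] = 2
                    order.append(cur)
                    continue
                mark[cur] = 1
                stack.append((cur, True))
                for p in recorded[cur]:
                    if p != UNKNOWN_PARENT and mark.get(p) != 2:
                        stack.append((p, False))

        for a in recorded:
            visit(a)
        return order
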