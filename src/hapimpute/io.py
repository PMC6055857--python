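"""Readers and writers for PLINK text PED/MAP, pedigree CSV and manifests.

PLINK text (not binary BED) is the canonical interchange: human-diffable
fixtures and trivial round-trip tests. Alleles are written 1/2 with the
minor allele coded 2, missing as "0 0"; on reading, the minor allele is
re-determined from the file's own allele frequencies (ties go to allele 2,
which makes write -> read the identity). Base-pair positions are 1-based
as in MAP files; internal marker ranks are 0-based.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import MISSING, UNKNOWN_PARENT, GenotypeMatrix, MarkerMap, Pedigree

__all__ = [
    "read_plink",
    "write_plink",
    "read_pedigree_csv",
    "write_pedigree_csv",
    "read_manifest",
    "read_phenotype_csv",
    "write_phenotype_csv",
]


def read_map(map_path) -> MarkerMap:
    tab = pd.read_csv(map_path, sep=r"\s+", header=None,
                      names=["chrom", "snp_id", "cm", "pos_bp"], dtype=str)
    return MarkerMap(pd.DataFrame({
        "snp_id": tab["snp_id"],
        "chrom": tab["chrom"],
        "pos_bp": tab["pos_bp"].astype(np.int64),
    }))


def read_plink(ped_path, map_path) -> tuple[GenotypeMatrix, MarkerMap, Pedigree]:
    """Read PLINK text files into dosage form.

    Dosage counts the minor allele (determined per SNP from this file);
    "0 0" allele pairs become missing. PED columns 3-4 are captured as
    sire/dam links in a light pedigree (all animals flagged genotyped).
    """
    marker_map = read_map(map_path)
    m = marker_map.n_snps

    animals, sires, dams, allele_rows = [], [], [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path} line {lineno}: expected {6 + 2 * m} fields, got {len(fields)}"
                )
            animals.append(fields[1])
            sires.append(fields[2])
            dams.append(fields[3])
            try:
                alleles = np.array(fields[6:], dtype=np.int8)
            except ValueError:
                raise ValueError(f"{ped_path} line {lineno}: non-numeric allele code") from None
            if not np.isin(alleles, (0, 1, 2)).all():
                raise ValueError(f"{ped_path} line {lineno}: allele codes must be 0/1/2 (non-biallelic?)")
            allele_rows.append(alleles)

    alleles = (np.vstack(allele_rows) if allele_rows
               else np.empty((0, 2 * m), dtype=np.int8))
    a1, a2 = alleles[:, 0::2], alleles[:, 1::2]
    half_missing = (a1 == 0) ^ (a2 == 0)
    if half_missing.any():
        raise ValueError(f"{ped_path}: half-missing allele pairs found")
    miss = (a1 == 0) & (a2 == 0)

    # minor allele from this file's own frequencies; ties -> allele 2
    count2 = ((a1 == 2).astype(np.int32) + (a2 == 2)).sum(axis=0)
    total = 2 * (~miss).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq2 = np.where(total > 0, count2 / np.maximum(total, 1), 0.0)
    minor = np.where(freq2 <= 0.5, 2, 1).astype(np.int8)

    dosage = ((a1 == minor).astype(np.int8) + (a2 == minor)).astype(np.int8)
    dosage[miss] = MISSING

    genotypes = GenotypeMatrix(np.asarray(animals, dtype=object), dosage)
    pedigree = Pedigree(pd.DataFrame({
        "animal_id": animals, "sire_id": sires, "dam_id": dams, "genotyped": True,
    }))
    return genotypes, marker_map, pedigree


def write_plink(
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    pedigree: Pedigree | None = None,
    ped_path="out.ped",
    map_path="out.map",
    phenotype: np.ndarray | None = None,
) -> None:
    """Write PLINK-conformant PED/MAP; minor allele 2, missing "0 0"."""
    if genotypes.n_snps != marker_map.n_snps:
        raise ValueError("genotypes and marker map disagree on SNP count")
    with open(map_path, "w") as fh:
        for rec in marker_map.table.itertuples():
            fh.write(f"{rec.chrom}\t{rec.snp_id}\t0\t{rec.pos_bp}\n")

    links = {}
    if pedigree is not None:
        links = {r.animal_id: (r.sire_id, r.dam_id) for r in pedigree.table.itertuples()}
    dos = genotypes.dosage
    with open(ped_path, "w") as fh:
        for i, animal in enumerate(genotypes.animal_ids):
            sire, dam = links.get(animal, (UNKNOWN_PARENT, UNKNOWN_PARENT))
            pheno = "-9" if phenotype is None else repr(float(phenotype[i]))
            a1 = np.where(dos[i] >= 1, 2, 1).astype(np.int8)
            a2 = np.where(dos[i] == 2, 2, 1).astype(np.int8)
            miss = dos[i] == MISSING
            a1[miss] = 0
            a2[miss] = 0
            pairs = np.empty(2 * len(a1), dtype=np.int8)
            pairs[0::2], pairs[1::2] = a1, a2
            fh.write(" ".join([animal, animal, sire, dam, "0", pheno]) + " "
                     + " ".join(map(str, pairs)) + "\n")


def read_pedigree_csv(path) -> Pedigree:
    """Three-column pedigree CSV animal_id,sire_id,dam_id (0 = unknown),
    optional genotyped column."""
    tab = pd.read_csv(path, dtype=str)
    if "genotyped" in tab.columns:
        tab["genotyped"] = tab["genotyped"].map(
            {"True": True, "False": False, "1": True, "0": False}
        ).fillna(False)
    return Pedigree(tab)


def write_pedigree_csv(pedigree: Pedigree, path) -> None:
    pedigree.table.to_csv(path, index=False)


def read_manifest(path) -> list[str]:
    """One SNP id per line (a PLINK extract list)."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_phenotype_csv(path) -> pd.Series:
    tab = pd.read_csv(path, dtype={0: str})
    return pd.Series(tab.iloc[:, 1].astype(float).to_numpy(), index=tab.iloc[:, 0], name="y")


def write_phenotype_csv(animal_ids, y, path) -> None:
    pd.DataFrame({"animal_id": animal_ids, "y": y}).to_csv(path, index=False)
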