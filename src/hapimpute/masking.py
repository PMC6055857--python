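"""Low-density array design by positional decimation.

A LowD array keeps every k-th SNP of the HighD panel in position order
(ranks k, 2k, 3k, ... 1-based, i.e. floor(n/k) markers). Consecutively
doubling k halves the kept set, and the kept sets are nested, which mirrors
how step-wise masking grids are usually built.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import MISSING, GenotypeMatrix, MarkerMap

__all__ = ["MaskSpec", "design_lowd", "masked_fraction", "apply_mask"]


@dataclass
class MaskSpec:
    """A LowD array: which position-ordered marker ranks stay genotyped."""

    keep_every_k: int
    kept_indices: np.ndarray      # 0-based ranks, ordered
    masked_fraction: float        # nominal percent, 100 * (1 - 1/k)

    @property
    def n_kept(self) -> int:
        return len(self.kept_indices)

    def masked_indices(self, n_snps: int) -> np.ndarray:
        mask = np.ones(n_snps, dtype=bool)
        mask[self.kept_indices] = False
        return np.flatnonzero(mask)

    def write_manifest(self, marker_map: MarkerMap, path) -> None:
        """One kept SNP id per line; usable as a PLINK extract list."""
        ids = marker_map.snp_ids[self.kept_indices]
        with open(path, "w") as fh:
            fh.write("\n".join(ids) + ("\n" if len(ids) else ""))


def masked_fraction(keep_every_k: int) -> float:
    """Nominal masked percentage 100 * (1 - 1/k), to one decimal place."""
    if keep_every_k < 1:
        raise ValueError("keep_every_k must be >= 1")
    return round(100.0 * (1.0 - 1.0 / keep_every_k), 1)


def design_lowd(marker_map: MarkerMap, keep_every_k: int) -> MaskSpec:
    """Keep markers at position-order ranks k, 2k, ... (1-based)."""
    n = marker_map.n_snps
    if not 1 <= keep_every_k <= n:
        raise ValueError(f"keep_every_k must be in [1, {n}]")
    kept = np.arange(keep_every_k - 1, n, keep_every_k, dtype=np.intp)
    return MaskSpec(
        keep_every_k=keep_every_k,
        kept_indices=kept,
        masked_fraction=masked_fraction(keep_every_k),
    )


def apply_mask(
    genotypes: GenotypeMatrix,
    spec: MaskSpec,
    validation_ids,
) -> GenotypeMatrix:
    """Set non-kept markers missing for validation animals only.

    Reference animals pass through untouched; the caller keeps the original
    matrix as the truth for scoring.
    """
    out = genotypes.copy()
    if len(list(validation_ids)) == 0:
        return out
    rows = out.index_of(validation_ids)
    masked_cols = spec.masked_indices(out.n_snps)
    out.dosage[np.ix_(rows, masked_cols)] = MISSING
    return out
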