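"""Scenario grid construction and execution.

Scenarios vary four factors: reference-population fraction (random
splits), use of pedigree information, relatedness between reference and
validation animals (one offspring per sire of the sib families in the
reference, against a size-matched random control), and LowD array density.
Replicates re-draw the membership, and a one-way ANOVA tests the
relatedness effect on the per-animal accuracy values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .accuracy import evaluate
from .containers import MISSING, Pedigree, UNKNOWN_PARENT
from .engine import WindowSchedule, impute, phase_reference
from .masking import apply_mask, design_lowd
from .qc import minor_allele_frequency
from .simulate import Population

__all__ = [
    "ScenarioSpec",
    "make_random_scenario",
    "make_rel_scenario",
    "run_scenarios",
    "ScenarioResults",
    "anova_relatedness",
]


@dataclass
class ScenarioSpec:
    """One row of the scenario grid.

    ``assignment_rule`` is ``"random"`` (uniform membership draw, with
    ``ref_fraction`` or a fixed reference size) or ``"systematic"`` (one
    offspring per sire family into the reference). ``reference_ids`` /
    ``validation_ids`` hold the initial draw; replicates re-draw by rule.
    """

    name: str
    reference_ids: np.ndarray
    validation_ids: np.ndarray
    keep_every_k: int = 8
    use_pedigree: bool = True
    assignment_rule: str = "random"
    ref_fraction: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        ref, val = set(self.reference_ids), set(self.validation_ids)
        if ref & val:
            raise ValueError("reference and validation sets overlap")
        if not ref or not val:
            raise ValueError("reference and validation sets must both be non-empty")

    @property
    def n_ref(self) -> int:
        return len(self.reference_ids)

    @property
    def n_val(self) -> int:
        return len(self.validation_ids)


def split_sizes(n: int, ref_fraction: float) -> tuple[int, int]:
    """(n_ref, n_val) under the convention that the minority side gets
    ``floor(fraction * n)`` and the complement takes the rest."""
    if not 0.0 < ref_fraction < 1.0:
        raise ValueError("ref_fraction must be in (0, 1)")
    eps = 1e-9  # guard against 0.1 * n style representation error
    if ref_fraction < 0.5:
        n_ref = int(np.floor(ref_fraction * n + eps))
    else:
        n_ref = n - int(np.floor((1.0 - ref_fraction) * n + eps))
    n_val = n - n_ref
    if n_ref < 1 or n_val < 1:
        raise ValueError(f"n = {n} too small for a non-empty {ref_fraction:.0%} split")
    return n_ref, n_val


def make_random_scenario(
    animal_ids,
    ref_fraction: float,
    use_pedigree: bool = True,
    keep_every_k: int = 8,
    seed: int = 0,
    name: str | None = None,
) -> ScenarioSpec:
    """Randomly assign ``ref_fraction`` of the animals to the reference."""
    ids = np.asarray(list(animal_ids), dtype=object)
    n_ref, _ = split_sizes(len(ids), ref_fraction)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return ScenarioSpec(
        name=name or f"Ref{round(100 * ref_fraction)}" + ("" if use_pedigree else "NoPed"),
        reference_ids=ids[perm[:n_ref]],
        validation_ids=ids[perm[n_ref:]],
        keep_every_k=keep_every_k,
        use_pedigree=use_pedigree,
        assignment_rule="random",
        ref_fraction=ref_fraction,
        seed=seed,
    )


def _sib_families(pedigree: Pedigree) -> dict[str, list[str]]:
    """Genotyped full-sib / paternal half-sib families: sire -> offspring,
    restricted to sires with at least two genotyped offspring."""
    tab = pedigree.table
    gen = tab[tab["genotyped"] & (tab["sire_id"] != UNKNOWN_PARENT)]
    fams: dict[str, list[str]] = {}
    for rec in gen.itertuples():
        fams.setdefault(rec.sire_id, []).append(rec.animal_id)
    return {s: kids for s, kids in fams.items() if len(kids) >= 2}


def make_rel_scenario(
    pedigree: Pedigree,
    seed: int = 0,
    keep_every_k: int = 8,
    use_pedigree: bool = True,
) -> tuple[ScenarioSpec, ScenarioSpec]:
    """(REL, REL-C): sib-structured reference vs size-matched random control.

    REL restricts to full-sib and paternal half-sib animals, putting one
    randomly chosen offspring of each sire into the reference and the
    remaining sibs into the validation set. REL-C draws sets of the same
    two sizes uniformly from all genotyped animals.
    """
    rng = np.random.default_rng(seed)
    fams = _sib_families(pedigree)
    if not fams:
        raise ValueError("no sire family with >= 2 genotyped offspring")
    ref, val = [], []
    for sire in sorted(fams):
        kids = sorted(fams[sire])
        pick = rng.integers(len(kids))
        ref.append(kids[pick])
        val.extend(k for i, k in enumerate(kids) if i != pick)
    if not val:
        raise ValueError("every sire has exactly one genotyped offspring; validation set empty")
    rel = ScenarioSpec(
        name="REL",
        reference_ids=np.asarray(ref, dtype=object),
        validation_ids=np.asarray(val, dtype=object),
        keep_every_k=keep_every_k,
        use_pedigree=use_pedigree,
        assignment_rule="systematic",
        seed=seed,
    )
    ids = pedigree.genotyped_ids
    perm = rng.permutation(len(ids))
    rel_c = ScenarioSpec(
        name="REL-C",
        reference_ids=ids[perm[: len(ref)]],
        validation_ids=ids[perm[len(ref): len(ref) + len(val)]],
        keep_every_k=keep_every_k,
        use_pedigree=use_pedigree,
        assignment_rule="random",
        seed=seed,
    )
    return rel, rel_c


def _redraw(spec: ScenarioSpec, population: Population, seed: int) -> ScenarioSpec:
    if spec.assignment_rule == "systematic":
        rel, _ = make_rel_scenario(
            population.pedigree, seed=seed, keep_every_k=spec.keep_every_k,
            use_pedigree=spec.use_pedigree,
        )
        rel.name = spec.name
        return rel
    ids = population.genotyped_ids
    if spec.ref_fraction is not None:
        out = make_random_scenario(
            ids, spec.ref_fraction, use_pedigree=spec.use_pedigree,
            keep_every_k=spec.keep_every_k, seed=seed, name=spec.name,
        )
        return out
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return ScenarioSpec(
        name=spec.name,
        reference_ids=ids[perm[: spec.n_ref]],
        validation_ids=ids[perm[spec.n_ref: spec.n_ref + spec.n_val]],
        keep_every_k=spec.keep_every_k,
        use_pedigree=spec.use_pedigree,
        assignment_rule="random",
        seed=seed,
    )


@dataclass
class ScenarioResults:
    """Per-replicate per-animal accuracy values and the pooled summary."""

    per_animal: pd.DataFrame   # scenario, replicate, animal, percent_correct, corr
    summary: pd.DataFrame      # scenario, mean/SD of % correct and corr, n

    def to_tsv(self, path) -> None:
        self.summary.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def animal_values(self, scenario: str, metric: str = "corr") -> np.ndarray:
        sel = self.per_animal["scenario"] == scenario
        return self.per_animal.loc[sel, metric].dropna().to_numpy()


def run_scenarios(
    specs: list[ScenarioSpec],
    population: Population,
    replicates: int = 10,
    schedule: WindowSchedule | None = None,
    seed: int = 0,
) -> ScenarioResults:
    """Run every scenario for ``replicates`` membership re-draws.

    Each replicate re-draws reference/validation membership by the
    scenario's rule, masks the validation animals at the scenario's LowD
    density, imputes (with the pedigree pass if requested), and scores.
    Reference phasing is cached per reference set, so scenarios differing
    only in masking density or pedigree use share the phasing work.
    The summary pools the per-animal values of all replicates.
    A failed replicate is logged and skipped, not fatal.
    """
    import logging

    logger = logging.getLogger(__name__)
    schedule = schedule or WindowSchedule()
    genotypes = population.genotypes
    highd_maf = minor_allele_frequency(genotypes.dosage)
    phase_cache: dict[tuple, object] = {}
    rows = []

    rep_seeds = np.random.SeedSequence(seed).spawn(replicates)
    for r, ss in enumerate(rep_seeds):
        r_seed = int(ss.generate_state(1)[0] % (2**31))
        for spec in specs:
            try:
                drawn = _redraw(spec, population, seed=r_seed)
                key = tuple(sorted(drawn.reference_ids))
                if key not in phase_cache:
                    g_ref = genotypes.subset_animals(drawn.reference_ids)
                    phase_cache[key] = phase_reference(g_ref, schedule, seed=r_seed)
                phased_ref = phase_cache[key]

                mask_spec = design_lowd(population.marker_map, drawn.keep_every_k)
                g_masked = apply_mask(genotypes, mask_spec, drawn.validation_ids)
                masked_slots = (g_masked.dosage == MISSING) & (genotypes.dosage != MISSING)

                ped = population.pedigree if drawn.use_pedigree else None
                result = impute(g_masked, ped, phased_ref, schedule=schedule, seed=r_seed)
                report = evaluate(genotypes, result.genotypes, masked_slots, highd_maf=highd_maf)
                for animal, vals in report.per_animal.iterrows():
                    rows.append({
                        "scenario": spec.name, "replicate": r, "animal": animal,
                        "percent_correct": vals["percent_correct"], "corr": vals["corr"],
                    })
            except Exception:  # pragma: no cover - defensive
                logger.exception("scenario %s replicate %d failed; skipping", spec.name, r)

    per_animal = pd.DataFrame(rows)
    summary_rows = []
    for spec in specs:
        sub = per_animal[per_animal["scenario"] == spec.name]
        summary_rows.append({
            "scenario": spec.name,
            "n_ref": spec.n_ref,
            "n_val": spec.n_val,
            "snps_masked_pct": design_lowd(population.marker_map, spec.keep_every_k).masked_fraction,
            "pedigree": spec.use_pedigree,
            "mean_percent_correct": sub["percent_correct"].mean(),
            "sd_percent_correct": sub["percent_correct"].std(),
            "mean_corr": sub["corr"].mean(),
            "sd_corr": sub["corr"].std(),
            "n_values": len(sub),
        })
    return ScenarioResults(per_animal=per_animal, summary=pd.DataFrame(summary_rows))


def anova_relatedness(values_rel, values_relc) -> tuple[float, float]:
    """One-way fixed-effects ANOVA (two groups) on per-animal accuracy.

    For two groups F equals the square of the pooled-variance t statistic.
    Zero within-group variance is short-circuited by exact equality.
    """
    a = np.asarray(values_rel, dtype=float)
    b = np.asarray(values_relc, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf"), 0.0
    f, p = stats.f_oneway(a, b)
    return float(f), float(p)
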