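"""Imputation engine: Mendelian pass, window phasing, haplotype library
and consistent-pair population imputation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hapimpute.containers import MISSING, GenotypeMatrix, MarkerMap, Pedigree, PhasedMatrix
from hapimpute.engine import (
    FALLBACK,
    OBSERVED,
    PEDIGREE,
    POPULATION,
    WindowSchedule,
    build_library,
    impute,
    pedigree_impute,
    phase_reference,
    population_impute,
)
from hapimpute.masking import apply_mask, design_lowd
from hapimpute.simulate import simulate_population


def trio(sire_g, dam_g, child_g, n_snps=1):
    ped = Pedigree(pd.DataFrame({
        "animal_id": ["s", "d", "c"],
        "sire_id": ["0", "0", "s"],
        "dam_id": ["0", "0", "d"],
        "genotyped": True,
    }))
    dos = np.array([[sire_g] * n_snps, [dam_g] * n_snps, [child_g] * n_snps], dtype=np.int8)
    return GenotypeMatrix(np.array(["s", "d", "c"], dtype=object), dos), ped


def mendel_possible(sire_g, dam_g):
    """Brute-force enumeration of child genotypes transmittable by a trio."""
    def alleles(g):
        return {MISSING: {0, 1}, 0: {0}, 1: {0, 1}, 2: {1}}[g]
    return {a + b for a in alleles(sire_g) for b in alleles(dam_g)}


class TestWindowSchedule:
    def test_levels_strictly_decreasing_to_min(self):
        lv = WindowSchedule().levels(3000)
        assert lv[0] == 3000 and lv[-1] == 3
        assert all(b < a for a, b in zip(lv, lv[1:]))

    def test_windows_cover_the_chromosome(self):
        sch = WindowSchedule()
        for L in (7, 50, 400):
            wins = sch.windows(L, 400)
            covered = np.zeros(400, dtype=bool)
            for s, e in wins:
                assert e - s == min(L, 400)
                covered[s:e] = True
            assert covered.all()

    @pytest.mark.parametrize("kwargs", [dict(shrink=0.0), dict(shrink=1.0),
                                        dict(overlap=1.0), dict(min_window=0)])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            WindowSchedule(**kwargs)


class TestPedigreePass:
    @pytest.mark.parametrize("sire_g,dam_g",
                             list(itertools.product([0, 1, 2, MISSING], repeat=2)))
    def test_matches_bruteforce_mendelian_deduction(self, sire_g, dam_g):
        g, ped = trio(sire_g, dam_g, MISSING)
        out = pedigree_impute(g, ped)
        possible = mendel_possible(sire_g, dam_g)
        expected = possible.pop() if len(possible) == 1 else MISSING
        assert out.dosage[2, 0] == expected

    def test_opposite_homozygotes_force_heterozygote(self):
        g, ped = trio(0, 2, MISSING)
        assert pedigree_impute(g, ped).dosage[2, 0] == 1

    def test_same_homozygote_forces_homozygote(self):
        g, ped = trio(2, 2, MISSING)
        assert pedigree_impute(g, ped).dosage[2, 0] == 2

    def test_ungenotyped_parents_leave_slot_missing(self):
        g, ped = trio(MISSING, MISSING, MISSING)
        assert pedigree_impute(g, ped).dosage[2, 0] == MISSING

    def test_offspring_evidence_fills_parent(self):
        # two homozygous offspring of opposite type force the shared parent
        ped = Pedigree(pd.DataFrame({
            "animal_id": ["x", "m1", "m2", "c1", "c2"],
            "sire_id": ["0", "0", "0", "x", "x"],
            "dam_id": ["0", "0", "0", "m1", "m2"],
            "genotyped": True,
        }))
        dos = np.array([[MISSING], [0], [2], [0], [2]], dtype=np.int8)
        g = GenotypeMatrix(ped.animal_ids, dos)
        assert pedigree_impute(g, ped).dosage[0, 0] == 1

    def test_hom_parent_plus_contradicting_offspring_allele(self):
        # x's sire is 2/2 (gives allele 1); x's child is 0/0 (x carries 0) -> x het
        ped = Pedigree(pd.DataFrame({
            "animal_id": ["gs", "x", "d2", "c"],
            "sire_id": ["0", "gs", "0", "x"],
            "dam_id": ["0", "0", "0", "d2"],
            "genotyped": True,
        }))
        dos = np.array([[2], [MISSING], [0], [0]], dtype=np.int8)
        g = GenotypeMatrix(ped.animal_ids, dos)
        assert pedigree_impute(g, ped).dosage[1, 0] == 1

    def test_inconsistent_observed_trio_logged_and_left_alone(self, caplog):
        g, ped = trio(0, 0, 2)  # impossible: opposing homozygote pair
        with caplog.at_level("WARNING"):
            out = pedigree_impute(g, ped)
        assert "Mendelian-inconsistent" in caplog.text
        assert (out.dosage == g.dosage).all()

    def test_fills_on_simulated_data_are_always_correct(self):
        # deterministic fills can only be the true genotype in noiseless data
        pop = simulate_population(n_genotyped=60, n_snps=300, n_sires=37, n_dams=54,
                                  n_half_sib=28, n_full_sib=6, n_genotyped_parents=40, seed=3)
        g = pop.genotypes
        tab = pop.pedigree.table
        offspring = tab.loc[tab["genotyped"] & (tab["sire_id"] != "0"), "animal_id"]
        masked = apply_mask(g, design_lowd(pop.marker_map, 4), list(offspring))
        out = pedigree_impute(masked, pop.pedigree)
        filled = (masked.dosage == MISSING) & (out.dosage != MISSING)
        assert filled.sum() > 0
        assert (out.dosage[filled] == g.dosage[filled]).all()


class TestPhaseReference:
    def test_all_homozygous_is_exact(self):
        dos = np.array([[0, 2, 0, 2, 2]], dtype=np.int8)
        ph = phase_reference(GenotypeMatrix(np.array(["a"], dtype=object), dos))
        assert (ph.alleles[0, :, 0] == ph.alleles[0, :, 1]).all()
        assert (ph.to_genotypes().dosage == dos).all()

    def test_identical_animals_get_identical_phase(self):
        dos = np.tile(np.array([0, 2, 1, 0, 2], dtype=np.int8), (2, 1))
        g = GenotypeMatrix(np.array(["a", "b"], dtype=object), dos)
        ph = phase_reference(g, WindowSchedule(min_window=5), seed=0)
        assert (ph.alleles[0] == ph.alleles[1]).all()

    def test_recovers_duplicated_founder_haplotypes(self):
        rng = np.random.default_rng(42)
        founders = rng.integers(0, 2, size=(4, 100)).astype(np.int8)
        rows, ids = [], []
        for k, (i, j) in enumerate(2 * [(i, j) for i in range(4) for j in range(i, 4)]):
            rows += [founders[i], founders[j]]
            ids.append(f"x{k}")
        truth = PhasedMatrix.from_haplotypes(np.array(ids, dtype=object), np.vstack(rows))
        est = phase_reference(truth.to_genotypes(), seed=0)
        assert {h.tobytes() for h in est.haplotypes()} == {h.tobytes() for h in founders}

    def test_phase_is_genotype_consistent(self, small_pop):
        sub = small_pop.genotypes.subset_animals(small_pop.genotypes.animal_ids[:40])
        ph = phase_reference(sub, seed=1)
        assert (ph.to_genotypes().dosage == sub.dosage).all()

    def test_missing_input_rejected(self):
        dos = np.array([[MISSING, 1]], dtype=np.int8)
        with pytest.raises(ValueError, match="complete"):
            phase_reference(GenotypeMatrix(np.array(["a"], dtype=object), dos))


class TestHaplotypeLibrary:
    def test_identical_reference_collapses_to_one_entry(self):
        hap = np.ones((10, 6), dtype=np.int8)
        ph = PhasedMatrix.from_haplotypes(np.array([f"a{i}" for i in range(5)], dtype=object), hap)
        lib = build_library(ph, (0, 6))
        assert lib.n_distinct == 1
        assert lib.counts[0] == 10

    def test_single_snp_window_has_at_most_two_entries(self, small_pop):
        ph = phase_reference(small_pop.genotypes.subset_animals(
            small_pop.genotypes.animal_ids[:30]), seed=0)
        lib = build_library(ph, (10, 11))
        assert lib.n_distinct <= 2

    def test_counts_conserved(self, small_pop):
        sub = small_pop.genotypes.subset_animals(small_pop.genotypes.animal_ids[:30])
        ph = phase_reference(sub, seed=0)
        lib = build_library(ph, (0, 50))
        assert lib.counts.sum() == 2 * 30

    def test_empty_reference_rejected(self):
        ph = PhasedMatrix(np.array([], dtype=object), np.empty((0, 4, 2), dtype=np.int8))
        with pytest.raises(ValueError, match="empty"):
            build_library(ph, (0, 2))


def unique_pair_fixture(seed=11, m=80, n_founders=6):
    """Reference of known haplotypes plus one target whose true pair is the
    only library-consistent diplotype given its observed markers."""
    rng = np.random.default_rng(seed)
    founders = rng.integers(0, 2, size=(n_founders, m)).astype(np.int8)
    rows, ids = [], []
    k = 0
    for i in range(n_founders):
        for j in range(n_founders):
            rows += [founders[i], founders[j]]
            ids.append(f"r{k}")
            k += 1
    ref = PhasedMatrix.from_haplotypes(np.array(ids, dtype=object), np.vstack(rows))

    true_pair = (0, 3)
    truth = (founders[true_pair[0]] + founders[true_pair[1]]).astype(np.int8)
    obs_idx = np.arange(7, m, 8)
    target = np.full(m, MISSING, dtype=np.int8)
    target[obs_idx] = truth[obs_idx]

    # brute-force oracle: enumerate every ordered founder pair
    consistent = [
        (i, j) for i in range(n_founders) for j in range(n_founders)
        if ((founders[i] + founders[j])[obs_idx] == truth[obs_idx]).all()
    ]
    assert set(consistent) == {true_pair, true_pair[::-1]}, "fixture must be uniquely consistent"
    g = GenotypeMatrix(np.array(["v"], dtype=object), target[None, :])
    return ref, g, truth


class TestPopulationImpute:
    def test_uniquely_consistent_pair_recovered_exactly(self):
        ref, g, truth = unique_pair_fixture()
        res = population_impute(g, ref, seed=0)
        assert (res.genotypes.dosage[0] == truth).all()

    def test_monomorphic_snp_imputed_to_fixed_allele(self):
        hap = np.zeros((8, 5), dtype=np.int8)
        hap[:, 1] = [0, 1] * 4  # SNP 1 polymorphic, others fixed at 0
        ref = PhasedMatrix.from_haplotypes(np.array([f"r{i}" for i in range(4)], dtype=object), hap)
        dos = np.array([[MISSING, 1, MISSING, 0, MISSING]], dtype=np.int8)
        res = population_impute(GenotypeMatrix(np.array(["v"], dtype=object), dos), ref, seed=0)
        assert res.genotypes.dosage[0, 0] == 0
        assert res.genotypes.dosage[0, 4] == 0

    def test_no_information_limit_is_frequency_fill(self, small_pop):
        sub = small_pop.genotypes.subset_animals(small_pop.genotypes.animal_ids[:30])
        ph = phase_reference(sub, seed=0)
        p_ref = ph.haplotypes().mean(axis=0)
        dos = np.full((1, small_pop.marker_map.n_snps), MISSING, dtype=np.int8)
        res = population_impute(GenotypeMatrix(np.array(["v"], dtype=object), dos), ph, seed=0)
        np.testing.assert_allclose(res.dosage[0], 2 * p_ref, atol=1e-9)

    def test_most_likely_is_half_even_rounding_of_dosage(self):
        ref, g, _ = unique_pair_fixture()
        res = population_impute(g, ref, seed=0)
        expect = np.clip(np.rint(res.dosage), 0, 2).astype(np.int8)
        filled = g.dosage[0] == MISSING
        assert (res.genotypes.dosage[0, filled] == expect[0, filled]).all()

    def test_marker_map_mismatch_rejected(self):
        ref, g, _ = unique_pair_fixture()
        with pytest.raises(ValueError, match="differ"):
            population_impute(g.subset_snps(np.arange(10)), ref, seed=0)


class TestImputeCombined:
    def test_without_pedigree_equals_population_pass(self, small_pop):
        g = small_pop.genotypes
        val = list(g.animal_ids[100:])
        gm = apply_mask(g, design_lowd(small_pop.marker_map, 8), val)
        ph = phase_reference(g.subset_animals(g.animal_ids[:100]), seed=0)
        a = impute(gm, None, ph, seed=0)
        b = population_impute(gm, ph, seed=0)
        assert (a.genotypes.dosage == b.genotypes.dosage).all()
        np.testing.assert_allclose(a.dosage, b.dosage)

    def test_trio_slot_resolved_by_pedigree(self):
        ref, g, truth = unique_pair_fixture()
        ped = Pedigree(pd.DataFrame({
            "animal_id": ["s", "d", "v"],
            "sire_id": ["0", "0", "s"],
            "dam_id": ["0", "0", "d"],
            "genotyped": True,
        }))
        m = g.n_snps
        dos = np.vstack([np.zeros(m, dtype=np.int8), np.full(m, 2, dtype=np.int8), g.dosage[0]])
        gm = GenotypeMatrix(np.array(["s", "d", "v"], dtype=object), dos)
        res = impute(gm, ped, ref, seed=0)
        vrow = 2
        filled = g.dosage[0] == MISSING
        assert (res.provenance[vrow, filled] == PEDIGREE).all()
        assert (res.genotypes.dosage[vrow, filled] == 1).all()

    def test_fully_observed_input_is_identity(self, small_pop):
        g = small_pop.genotypes
        ph = phase_reference(g.subset_animals(g.animal_ids[:30]), seed=0)
        res = impute(g, small_pop.pedigree, ph, seed=0)
        assert (res.genotypes.dosage == g.dosage).all()
        assert (res.provenance == OBSERVED).all()

    def test_observed_slots_never_altered(self, small_pop):
        g = small_pop.genotypes
        val = list(g.animal_ids[100:])
        gm = apply_mask(g, design_lowd(small_pop.marker_map, 8), val)
        res = impute(gm, small_pop.pedigree, phase_reference(
            g.subset_animals(g.animal_ids[:100]), seed=0), seed=0)
        obs = gm.dosage != MISSING
        assert (res.genotypes.dosage[obs] == gm.dosage[obs]).all()
        assert (res.provenance[obs] == OBSERVED).all()

    def test_pedigree_pass_is_a_strict_refinement(self):
        # slots the Mendelian pass resolves are exactly right, so adding the
        # pedigree can only increase the number of correctly imputed slots
        pop = simulate_population(n_genotyped=60, n_snps=300, n_sires=37, n_dams=54,
                                  n_half_sib=28, n_full_sib=6, n_genotyped_parents=40, seed=5)
        g = pop.genotypes
        val = list(g.animal_ids[40:])
        gm = apply_mask(g, design_lowd(pop.marker_map, 8), val)
        ph = phase_reference(g.subset_animals(g.animal_ids[:40]), seed=0)
        with_ped = impute(gm, pop.pedigree, ph, seed=0)
        without = impute(gm, None, ph, seed=0)
        masked = gm.dosage == MISSING
        forced = with_ped.provenance == PEDIGREE
        assert forced.sum() > 0
        n_ped = (with_ped.genotypes.dosage[masked & forced] == g.dosage[masked & forced]).sum()
        n_nop = (without.genotypes.dosage[masked & forced] == g.dosage[masked & forced]).sum()
        assert n_ped >= n_nop
        assert (with_ped.genotypes.dosage[forced] == g.dosage[forced]).all()
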