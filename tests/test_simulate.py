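"""Synthetic population generator: LD model, pedigree structure, gene
dropping and phenotype simulation."""

import numpy as np
import pytest

from hapimpute.containers import MISSING, MarkerMap, PhasedMatrix
from hapimpute.simulate import (
    InfeasiblePedigree,
    SimParams,
    build_pedigree,
    gene_drop,
    genotypes_from_phase,
    random_phase,
    simulate_founder_haplotypes,
    simulate_phenotype,
)


def fixed_maf(p):
    return lambda rng, size: np.full(size, p)


class TestFounderHaplotypes:
    def test_shape_contract(self):
        haps = simulate_founder_haplotypes(SimParams(n_founders=10, n_snps=5, seed=1))
        flat = haps.haplotypes()
        assert flat.shape == (20, 5)
        assert set(np.unique(flat)) <= {0, 1}

    def test_independence_at_rho_zero(self):
        params = SimParams(n_founders=300, n_snps=50, ld_strength=0.0, seed=2)
        dos = genotypes_from_phase(simulate_founder_haplotypes(params)).dosage.astype(float)
        r = np.array([np.corrcoef(dos[:, j], dos[:, j + 1])[0, 1] for j in range(49)])
        assert np.abs(r).mean() < 3 / np.sqrt(300)

    def test_adjacent_concordance_matches_copying_closed_form(self):
        # Pr(match) = rho + (1 - rho)(p^2 + q^2); rho = 0.95, p = 0.5 -> 0.975
        params = SimParams(n_founders=500, n_snps=200, ld_strength=0.95,
                           maf_law=fixed_maf(0.5), seed=3)
        flat = simulate_founder_haplotypes(params).haplotypes()
        match = (flat[:, 1:] == flat[:, :-1]).mean()
        assert match == pytest.approx(0.975, abs=0.01)

    def test_r2_monotone_in_rho(self):
        r2 = []
        for rho in (0.0, 0.5, 0.95):
            params = SimParams(n_founders=400, n_snps=100, ld_strength=rho,
                               maf_law=fixed_maf(0.4), seed=4)
            flat = simulate_founder_haplotypes(params).haplotypes().astype(float)
            vals = [np.corrcoef(flat[:, j], flat[:, j + 1])[0, 1] ** 2 for j in range(99)]
            r2.append(np.mean(vals))
        assert r2[0] < r2[1] < r2[2]

    def test_founder_frequency_law_of_large_numbers(self):
        params = SimParams(n_founders=5000, n_snps=100, seed=5)
        flat = simulate_founder_haplotypes(params).haplotypes()
        # mean frequency over many SNPs converges to the Uniform(0.01, 0.5) mean
        assert flat.mean() == pytest.approx(0.255, abs=0.05)
        # and each marker's empirical frequency matches its own draw
        rng = np.random.default_rng(5)
        p = rng.uniform(0.01, 0.5, 100)
        np.testing.assert_allclose(flat.mean(axis=0), p, atol=0.03)

    @pytest.mark.parametrize("bad", [
        dict(n_founders=0, n_snps=5),
        dict(n_founders=5, n_snps=0),
        dict(n_founders=5, n_snps=5, ld_strength=1.0),
        dict(n_founders=5, n_snps=5, ld_strength=float("nan")),
        dict(n_founders=5, n_snps=5, cM_per_Mb=-1.0),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate_founder_haplotypes(SimParams(**bad))


class TestBuildPedigree:
    def test_cohort_structure_at_full_scale(self):
        ped = build_pedigree(n_genotyped=1179, n_sires=725, n_dams=1069,
                             n_half_sib=547, n_full_sib=131, seed=0)
        tab = ped.table
        off = tab[tab["genotyped"]]
        assert len(off) == 1179
        assert off["sire_id"].nunique() == 725
        assert off["dam_id"].nunique() == 1069
        assert round(len(off) / off["sire_id"].nunique(), 2) == 1.63
        assert round(len(off) / off["dam_id"].nunique(), 2) == 1.10
        # classify sib status from the pedigree itself
        sire_counts = off["sire_id"].value_counts()
        pair_counts = off.groupby(["sire_id", "dam_id"]).size()
        full = off.apply(lambda r: pair_counts[(r["sire_id"], r["dam_id"])] >= 2, axis=1)
        half = off["sire_id"].map(sire_counts).ge(2) & ~full
        assert int(full.sum()) == 131
        assert int(half.sum()) == 547

    def test_unrelated_limit_shares_no_parents(self):
        ped = build_pedigree(n_genotyped=20, n_sires=20, n_dams=20,
                             n_half_sib=0, n_full_sib=0, seed=1)
        off = ped.table[ped.table["genotyped"]]
        assert off["sire_id"].is_unique and off["dam_id"].is_unique

    def test_genotyped_parents_flagged(self):
        ped = build_pedigree(n_genotyped=40, n_sires=30, n_dams=34,
                             n_half_sib=10, n_full_sib=4, n_genotyped_parents=5, seed=2)
        parents = ped.table[ped.table["sire_id"] == "0"]
        assert int(parents["genotyped"].sum()) == 5

    @pytest.mark.parametrize("kwargs,fragment", [
        (dict(n_genotyped=10, n_sires=5, n_dams=5, n_half_sib=8, n_full_sib=4), "exceeds"),
        (dict(n_genotyped=10, n_sires=5, n_dams=5, n_half_sib=0, n_full_sib=1), "full-sib"),
        (dict(n_genotyped=10, n_sires=3, n_dams=10, n_half_sib=0, n_full_sib=0), "n_sires"),
        (dict(n_genotyped=20, n_sires=19, n_dams=2, n_half_sib=2, n_full_sib=0), "dam"),
    ])
    def test_infeasible_configurations_name_constraint(self, kwargs, fragment):
        with pytest.raises(InfeasiblePedigree, match=fragment):
            build_pedigree(seed=0, **kwargs)


def _two_marker_map(gap_mb):
    import pandas as pd
    return MarkerMap(pd.DataFrame({
        "snp_id": ["a", "b"], "chrom": "1",
        "pos_bp": [1, 1 + int(gap_mb * 1e6)],
    }))


class TestGeneDrop:
    def test_homozygous_parent_forces_allele(self, small_pop):
        # checkable exhaustively: no parent-offspring opposing homozygotes
        ped = small_pop.pedigree
        phased = small_pop.phased
        dos = {a: phased.alleles[i].sum(axis=1) for i, a in enumerate(phased.animal_ids)}
        for rec in ped.table.itertuples():
            for parent in (rec.sire_id, rec.dam_id):
                if parent == "0" or parent not in dos:
                    continue
                child, par = dos[rec.animal_id], dos[parent]
                assert not (((child == 0) & (par == 2)) | ((child == 2) & (par == 0))).any()

    def test_no_recombination_transmits_intact_haplotypes(self):
        import pandas as pd
        ped = build_pedigree(n_genotyped=30, n_sires=30, n_dams=30,
                             n_half_sib=0, n_full_sib=0, seed=3)
        founders = ped.founders()
        params = SimParams(n_founders=len(founders), n_snps=80, ld_strength=0.2, seed=3)
        fh = simulate_founder_haplotypes(params)
        fh = PhasedMatrix(founders, fh.alleles)
        mmap = MarkerMap.uniform(80)
        dropped = gene_drop(ped, fh, mmap, cM_per_Mb=0.0, seed=3)
        hap_pool = {h.tobytes() for h in fh.haplotypes()}
        for i, a in enumerate(dropped.animal_ids):
            if a in set(founders):
                continue
            for c in range(2):
                assert dropped.alleles[i, :, c].tobytes() in hap_pool

    def test_coinheritance_matches_haldane(self):
        # two markers 1 Morgan apart: P(same parental source) = (1 + e^-2)/2
        import pandas as pd
        rows = [("p0", "0", "0", False)] + [(f"c{i}", "p0", "m_", False) for i in range(2000)]
        rows.insert(1, ("m_", "0", "0", False))
        from hapimpute.containers import Pedigree
        ped = Pedigree(pd.DataFrame(rows, columns=["animal_id", "sire_id", "dam_id", "genotyped"]))
        alle = np.zeros((2, 2, 2), dtype=np.int8)
        alle[0, :, 0] = 0   # p0 haplotypes [0,0] and [1,1]: co-inheritance observable
        alle[0, :, 1] = 1
        alle[1] = 0         # dam homozygous 0/0
        founders = PhasedMatrix(np.array(["p0", "m_"], dtype=object), alle)
        dropped = gene_drop(ped, founders, _two_marker_map(100), cM_per_Mb=1.0, seed=4)
        kids = [i for i, a in enumerate(dropped.animal_ids) if a.startswith("c")]
        paternal = dropped.alleles[kids, :, 0]  # sire listed first
        same = (paternal[:, 0] == paternal[:, 1]).mean()
        expected = 0.5 * (1 + np.exp(-2.0))
        assert same == pytest.approx(expected, abs=0.03)

    def test_missing_founder_haplotypes_raise(self):
        import pandas as pd
        from hapimpute.containers import Pedigree
        ped = Pedigree(pd.DataFrame({
            "animal_id": ["x"], "sire_id": ["s"], "dam_id": ["d"], "genotyped": [True],
        }))
        empty = PhasedMatrix(np.array([], dtype=object), np.empty((0, 2, 2), dtype=np.int8))
        with pytest.raises(ValueError, match="missing founder"):
            gene_drop(ped, empty, _two_marker_map(1), seed=0)


class TestGenotypesFromPhase:
    def test_dosage_definition_and_missing(self):
        alle = np.array([[[0, 0], [0, 1], [1, 1], [1, MISSING]]], dtype=np.int8)
        g = genotypes_from_phase(PhasedMatrix(np.array(["a"], dtype=object), alle))
        assert g.dosage.tolist() == [[0, 1, 2, MISSING]]

    def test_phase_split_round_trip(self, small_pop):
        g = small_pop.genotypes
        again = genotypes_from_phase(random_phase(g, seed=9))
        assert (again.dosage == g.dosage).all()


class TestPhenotype:
    def _hwe_genotypes(self, n, m, seed):
        from hapimpute.containers import GenotypeMatrix
        r = np.random.default_rng(seed)
        p = r.uniform(0.1, 0.5, m)
        dos = (r.random((n, m)) < p).astype(np.int8) + (r.random((n, m)) < p)
        return GenotypeMatrix(np.array([f"i{i}" for i in range(n)], dtype=object), dos)

    def test_h2_zero_is_independent_of_genotypes(self):
        g = self._hwe_genotypes(400, 60, 1)
        sim = simulate_phenotype(g, n_qtl=20, h2=0.0, seed=1)
        X = g.dosage[:, sim.qtl_indices].astype(float)
        beta, *_ = np.linalg.lstsq(np.column_stack([np.ones(400), X]), sim.y, rcond=None)
        r2 = 1 - np.var(sim.y - np.column_stack([np.ones(400), X]) @ beta) / np.var(sim.y)
        assert r2 < 0.15

    def test_h2_one_is_exact_linear_function(self):
        g = self._hwe_genotypes(100, 40, 2)
        sim = simulate_phenotype(g, n_qtl=10, h2=1.0, seed=2)
        pred = g.dosage[:, sim.qtl_indices].astype(float) @ sim.effects
        np.testing.assert_allclose(sim.y, pred)

    def test_realized_h2_targets_request(self):
        realized = []
        for seed in range(20):
            g = self._hwe_genotypes(1000, 60, 100 + seed)
            sim = simulate_phenotype(g, n_qtl=50, h2=0.5, seed=seed)
            realized.append(sim.realized_h2)
        assert all(0.4 < h < 0.6 for h in realized)

    def test_h2_out_of_range_rejected(self):
        g = self._hwe_genotypes(10, 5, 3)
        with pytest.raises(ValueError):
            simulate_phenotype(g, n_qtl=2, h2=1.5, seed=0)
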