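# hapimpute

Genotype imputation from low-density (LowD) SNP arrays back to a
high-density (HighD) panel, and the machinery to evaluate it, for
pedigreed populations such as dog breeds.

Genotyping every animal at high density is expensive. A common strategy is
to genotype a *reference* population at HighD, type everyone else on a
cheap decimated LowD array, and statistically infer ("impute") the masked
markers from shared haplotypes and pedigree logic. Whether that works
depends on the LowD density, the size of the reference, the relatedness
between reference and target animals, and the allele frequency of each
marker. This package implements the full evaluation loop:

- **`simulate`** — pedigreed cohorts with LD-structured genotypes: founder
  haplotypes from a latent copying chain (one knob, `ld_strength`, sets
  adjacent-marker association; per-marker MAF drawn from a configurable
  law), a sire/dam pedigree with half-sib, full-sib and unrelated animals,
  Haldane gene dropping, and polygenic phenotypes.
- **`qc`** — marker filters: call rate, MAF, Hardy-Weinberg chi-square.
- **`masking`** — LowD design by positional decimation (keep every k-th
  SNP; masking 50-98.4%) applied to validation animals only.
- **`engine`** — two-pass imputation: deterministic Mendelian fills from
  the pedigree, then an overlapping sliding-window haplotype library
  (window lengths shrink geometrically, shrink 0.150, overlap 0.650;
  long windows capture relatives, short windows capture population LD).
  For each window, reference haplotype pairs consistent with the observed
  LowD genotypes vote, frequency-weighted, on every missing slot.
- **`accuracy`** — animal-wise % correct and MAF-standardized correlation
  over masked slots, SNP-wise correlation by MAF bin, genomic-relatedness
  summaries.
- **`scenarios`** — reference-fraction / pedigree-use / relatedness /
  density grids with replicates and a two-group ANOVA for the relatedness
  effect.
- **`quant`** — centered GRM, EMMAX-style mixed-model GWAS, cross-validated
  GBLUP, and real-vs-imputed scan concordance.
- **`io` / `cli`** — PLINK text PED/MAP, pedigree CSV, manifests, TSV
  reports, and a `hapimpute` subcommand CLI
  (`simulate | qc | mask | impute | evaluate | scenarios | gwas | gblup`).

## Worked example

Simulate a 150-animal cohort on a 1000-SNP chromosome, split it 50/50 into
reference and validation, mask 87.5% of the validation animals' markers
(every 8th SNP kept), impute, and score:

```python
import hapimpute as hi
from hapimpute.scenarios import make_random_scenario
from hapimpute.masking import design_lowd, apply_mask
from hapimpute.accuracy import evaluate
from hapimpute.containers import MISSING

pop  = hi.standard_population(seed=1, n_genotyped=150, n_snps=1000)
g    = pop.genotypes
spec = make_random_scenario(g.animal_ids, 0.5, keep_every_k=8, seed=0)

phased = hi.phase_reference(g.subset_animals(spec.reference_ids), seed=0)
masked = apply_mask(g, design_lowd(pop.marker_map, 8), spec.validation_ids)
result = hi.impute(masked, pop.pedigree, phased, seed=0)

slots  = (masked.dosage == MISSING) & (g.dosage != MISSING)
report = evaluate(g, result.genotypes, slots)
print(f"mean % correct = {report.mean_percent_correct:.2f}")
print(f"mean corr      = {report.mean_corr:.3f}")
print(report.maf_bins.to_string(index=False))
```

prints

```
mean % correct = 65.79
mean corr      = 0.314
     maf_bin  n_snps  mean_corr
   [0,0.025)      26   0.107475
[0.025,0.05)      54   0.165384
[0.05,0.075)      37   0.238875
 [0.075,0.1)      44   0.239927
   [0.1,0.2)     187   0.319291
   [0.2,0.3)     161   0.364907
   [0.3,0.4)     191   0.376556
   [0.4,0.5)     171   0.323203
```

`% correct` is the share of masked genotypes whose most-likely imputation
equals the truth; `corr` is the Pearson correlation between true and
imputed genotypes after per-SNP standardization, which removes the free
accuracy that rare alleles hand to % correct. The MAF-bin table shows the
characteristic rise of SNP-wise accuracy with allele frequency: rare
alleles ride on rare haplotypes that the reference covers poorly. Absolute
values on this small synthetic cohort are far below what strong
within-breed LD and thousand-animal references give on real data — the
package's tests assert directions and orderings, not breed-specific
accuracies.

The same loop from a shell:

```sh
hapimpute simulate --n-animals 150 --n-snps 1000 --seed 1 --out-dir sim/
hapimpute scenarios --n-animals 300 --n-snps 3000 --replicates 10 --out-dir grid/
```

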