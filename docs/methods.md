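# Methods

`hapimpute` evaluates genotype imputation from low-density (LowD) SNP
arrays back to a high-density (HighD) panel in pedigreed dog-like
populations, together with the downstream effect of imputed genotypes on
mixed-model GWAS and GBLUP prediction. Everything runs on simulated
cohorts, so every claim the test suite makes is a claim about the model
below, not about any real breed.

## Synthetic population model

**Founder haplotypes.** A chromosome of `n_snps` ordered biallelic markers
(uniform spacing over 122.68 Mb by default, the scale of a large canine
autosome). Marker `j` draws a minor-allele frequency `p_j` from `maf_law`
(default Uniform(0.01, 0.5], the support of a post-QC panel). Linkage
disequilibrium comes from a first-order copying chain on a latent uniform:
each haplotype carries `u_j`, equal to `u_{j-1}` with probability
`rho = ld_strength` (default 0.9) and redrawn Uniform(0, 1) otherwise; the
allele is `1{u_j < p_j}`.

Copying the quantile rather than the realized allele has three
consequences worth spelling out:

* marginal frequencies are exactly `p_j` — an allele-level copying chain
  would shrink them toward their running mean and (at rho = 0.9) leave the
  panel with no rare variants at all;
* for two adjacent markers with equal frequency the probability their
  alleles match is exactly `rho + (1 - rho)(p^2 + q^2)`, the closed form
  used as a simulator oracle in the tests;
* a rare marker's correlation with a common neighbour is capped by the
  frequency ratio (`r = rho * sqrt(p(1-P) / ((1-p)P))` for `p < P`), as in
  real genomes — this is what makes rare alleles genuinely hard to impute
  and gives the MAF-accuracy profile its characteristic rise.

**Pedigree.** Two generations. The genotyped cohort consists of full-sib
families (pairs, one triple if the count is odd), paternal half-sib groups
(same sire, different dams), and unrelated animals from unique parent
pairs; dams may be shared between half-sib groups of different sires so
that the sire and dam totals are hit exactly without creating extra
full-sibs. A configurable number of parents is itself genotyped. The
standard population scales the structure of a 1179-dog cohort (1.63
offspring/sire, 1.10 offspring/dam, ~46% half-sibs, ~11% full-sibs, ~2%
genotyped parents) down to 300 genotyped animals x 3000 SNPs.

**Gene dropping.** Each non-founder receives one recombinant gamete per
parent; the source haplotype switches between adjacent markers with the
Haldane probability `(1 - exp(-2d))/2` at map distance `d` Morgans
(uniform 1 cM/Mb by default — no canine map is assumed). Gene-dropped data
are Mendelian-consistent by construction, which the tests check
exhaustively.

**Phenotype.** `y = sum_k a_k g_k + e` over `n_qtl` uniformly placed QTL
with i.i.d. standard-normal effects; the environmental variance is scaled
against the realized genetic variance so the realized heritability matches
the request.

What the generator does *not* emulate: breed history and bottlenecks
(haplotype sharing between "unrelated" animals is only what the copying
chain induces, far weaker than real within-breed LD), multi-generation
pedigrees, genotyping error, and the X chromosome. Passing tests therefore
demonstrate correct machinery and the direction of effects, not the
absolute accuracies reachable on real breed data — on the standard
population the animal-wise corr at 87.5% masking is ~0.36, whereas studies
on real cohorts with strong LD and thousand-animal references report
0.92-0.97.

## Quality control

Marker-wise filters in a fixed order — call rate < 98.4%, MAF < 0.01, and
a Hardy-Weinberg 1-d.f. Pearson chi-square at `hwe_alpha` (default 1e-6;
no specific test or threshold is standard, so both are exposed). A SNP
failing several filters is attributed to the first. No animal-wise filter
is applied. Intensity-based filters are out of scope (they need raw array
data).

## LowD design and masking

A LowD array keeps every k-th SNP in position order (ranks k, 2k, ...;
`floor(n/k)` markers — 728 of 5826 at k = 8, 91 at k = 64), so doubling k
halves the panel and the kept sets are nested. The quoted masking
percentage is the nominal `100(1 - 1/k)`, matching the conventional labels
50 / 75 / 87.5 / 93.8 / 96.9 / 98.4. Masking applies only to validation
animals; reference animals always stay at HighD.

## Imputation engine

Two passes, pedigree first.

**Pedigree pass.** Only deterministic Mendelian fills: both parents
homozygous fixes the offspring; a homozygous offspring forces each parent
to carry that allele; two distinct forced alleles, or one forced allele
plus a contradicting homozygous parent, fix a heterozygote. Rules iterate
to fixpoint; observed opposing-homozygote parent/offspring pairs are
logged and left alone. No probabilistic fills.

**Window schedule.** Level lengths shrink geometrically from the
chromosome length by a factor (1 - shrink) with shrink = 0.150, and
windows at a level overlap by 0.650 of their length — the conventional
sliding-window defaults. The shortest level is 3 markers for phasing; for
imputation it is three times the observed-marker spacing, so a window
always spans about three typed markers.

**Reference phasing.** Iterative window voting, long to short, up to three
sweeps: animals whose heterozygotes inside a window are already resolved
(or number at most one, making the unordered pair trivial) contribute
their two haplotypes to the window library; every other animal adopts the
most frequent library haplotype compatible with its constrained sites
(ties broken lexicographically, so phasing is deterministic). Heterozygotes
never matched are assigned by the seeded RNG. Switch errors are possible
and simply propagate into the library as rare haplotypes.

**Population pass.** For each target animal and window, every ordered pair
of reference haplotypes whose dosages reproduce the animal's observed
alleles in the window votes — frequency-weighted — for the missing slots
the window covers; the slot's expected dosage is the vote-weighted mean.
Longer windows take precedence: a slot is fixed at the first (longest)
level where any consistent pair exists, which trusts long shared segments
(close relatives) before population-level LD. Slots never covered by any
consistent pair fall back to twice the reference allele frequency. The
most-likely genotype rounds the expected dosage half-to-even.

Consistency matching is implemented with two independent 31-bit random
weight vectors and prefix sums, so the hash of any window restriction of a
haplotype or target is one subtraction, and a consistent complement is an
exact hash-pair lookup (collision probability ~2^-42 per comparison; all
sums stay below 2^53 and are exact in the integer arithmetic used). This
is purely an implementation of enumerate-consistent-pairs, verified
against the direct unique-rows implementation.

**Pass combination.** The population pass runs on the original LowD
observation mask; pedigree fills then overwrite its output at the slots
they determine. The alternative — feeding pedigree fills into the
population matching as observations — lets a handful of fills perturb the
votes at unrelated slots, turning the pedigree-vs-no-pedigree comparison
into noise around zero; with pass isolation the pedigree can only change
slots it logically resolves, so adding it never hurts. Per-slot provenance
(observed / pedigree / population / frequency_fallback) is recorded.

## Accuracy statistics

Animal-wise, over masked slots only: **% correct** (most-likely genotype
equals truth) and **corr**, the Pearson correlation of true and imputed
genotypes after per-SNP standardization `z = (g - mu_j)/sd_j` with `mu_j`,
`sd_j` the empirical mean and SD of the *true* genotypes of the validation
animals. Standardizing by empirical moments (rather than `2p` and
`sqrt(2pq)`) was chosen because it makes `corr = 1` exact for perfect
imputation regardless of Hardy-Weinberg excess; SNPs with zero truth SD
are excluded, and an animal with fewer than two usable slots is undefined
and excluded from scenario means rather than zeroed. Scenario summaries
pool each animal's value from every replicate, then take mean and SD.

SNP-wise: Pearson across validation animals on raw dosages (per-SNP
standardization is linear and cancels), averaged within MAF bins
[0, 0.025), [0.025, 0.05), [0.05, 0.075), [0.075, 0.1), [0.1, 0.2),
[0.2, 0.3), [0.3, 0.4), [0.4, 0.5) using the HighD (full-data) MAF. A SNP
whose truth varies but whose imputation is constant — typically a rare
allele whose carriers were all missed — scores 0 (a constant predictor
carries no information); a SNP with constant truth is undefined. % correct
is deliberately not reported per MAF bin, since it overstates accuracy for
rare alleles.

Relatedness context: per validation animal, the mean and maximum of its
(VanRaden-centered) genomic relationship with the reference set.

## Scenario engine

Random splits follow the convention that the minority side gets
`floor(fraction * n)` (reproducing 590/589 and 117/1062 at n = 1179
despite the two roundings being inconsistent with each other). The
relatedness scenario (REL) restricts to full-sib and paternal half-sib
animals, samples one offspring per sire into the reference, and the rest
into validation; its control (REL-C) draws the same two sizes uniformly
from all genotyped animals. Replicates re-draw membership (REL included,
for power in the ANOVA; set replicates to 1 to mimic a single systematic
assignment). Reference phasing is cached per reference set, so masking
densities and pedigree toggles share the work. The relatedness effect is
tested with a two-group one-way ANOVA on the per-animal accuracy values;
for two groups F is exactly the squared pooled t (asserted in tests), with
zero-variance groups short-circuited.

## Quantitative applications

The GRM is the centered `W W' / c` with columns centered at `2p_j`;
the default denominator is VanRaden's `2 * sum p_j q_j` (mean diagonal ~1
under HWE), with the plain `/m` convention available as `scale="mean"` —
the choice only rescales the variance component downstream.

GWAS uses the EMMAX/FaST-LMM recipe: null REML for
`V = sg2 K + se2 I` via one eigendecomposition (negative eigenvalues
clipped at zero and logged; delta optimized on a log grid refined by
bounded Brent), then per-SNP GLS with the ratio fixed, Wald t p-values,
zero-variance SNPs flagged untested. An `exact=True` flag re-estimates the
ratio per SNP; at desk sizes the two agree closely. With an identity GRM
the scan is exactly OLS (machine precision, asserted).

GBLUP cross-validation fits per-fold REML variance components on training
animals and predicts held-out EBVs as conditional means
`sg2 K_tv V^-1 (y - mu)`; a singular training V gets a 1e-8 ridge
(logged). Three accuracy numbers are emitted because the field's usage is
inconsistent: `r` (mean held-out cor(EBV, y) across folds), `pa_pooled`
(one correlation over all held-out animals), and `r_h2_scaled`
(`r / sqrt(h2_hat)`, the accuracy-style rescaling). None is singled out as
canonical.

Scan concordance between two GWAS is the Pearson correlation of raw
p-values (a `-log10` option exists, since "correlation of p-values" is
genuinely ambiguous) and of effect sizes, with outliers flagged beyond 3
robust SDs (1.4826 x MAD; an exact-agreement MAD of zero falls back to
flagging any strict deviation) and annotated with MAF.

## Problem sizes and determinism

The evaluation studies use one simulated population of 300 genotyped
animals x 3000 SNPs with 10 membership re-draws — chosen as the smallest
grid on which all trend comparisons are comfortably clear of their noise
floors. The GWAS null calibration uses 10 cohorts of 200 animals x 500
independent markers. Every source of randomness descends from one integer
seed through `numpy.random.SeedSequence`; identical configuration and seed
give byte-identical outputs, which the tests assert on serialized tables.

## Known limitations

* The phasing heuristic has no explicit switch-error control between
  windows that share no resolved heterozygote.
* The engine imputes one chromosome at a time; there is no cross-chromosome
  scheduling.
* Genotype likelihoods, imputation to sequence, and MAF- or LD-optimized
  LowD selection are out of scope.
* The ANOVA treats per-animal accuracies as independent observations, as
  in the analysis it mirrors; repeated use of animals across replicates is
  ignored.
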