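# Methods

`epiblup` implements genomic prediction of phenotypic values under mixed
models with additive and epistatic genetic effects, together with the
supporting machinery: genomic relationship matrices, REML variance
components, per-individual reliabilities, cross-validated accuracy
measures, analytic calculators for the transmission of nonadditive
effects, and a seeded synthetic-data generator.

## Model

The phenotype vector (pre-adjusted residuals; fixed non-genetic effects
removed upstream) is modeled as

    y = 1·mu + Z g + e,        g = a + d + aa + ad + dd (+ third order),
    V = Var(y) = Z G Z' + sigma2_e I,
    G = sigma2_alpha A + sigma2_delta D + sigma2_alphaalpha AA
        + sigma2_alphadelta AD + sigma2_deltadelta DD (+ ...),

with one record per individual, so Z is the identity.  Any subset of
components may be fitted; the package's central comparison is the
additive-only model (A) against the additive plus additive-by-additive
model (A + A×A).

## Relationship matrices

* **Additive**: A = Z_c Z_c' / Σ_k 2 p_k q_k, with Z_c the column-centered
  allele counts (z_ik = g_ik − 2p_k).  This is the standard
  centered-count construction; monomorphic SNPs contribute nothing.
* **Dominance**: codes (−2p², 2pq, −2q²) for genotypes (2, 1, 0), with
  normalizer Σ_k (2 p_k q_k)²; orthogonal to the additive component under
  Hardy–Weinberg proportions, chosen because dominance variance is treated
  as a separate component.
* **Pairwise epistasis, approximate**: Hadamard products AA = A∘A,
  AD = A∘D, DD = D∘D.  The Hadamard square implicitly includes each locus
  "interacting with itself".
* **Pairwise epistasis, exact**: intra-locus terms are removed, leaving
  only genuine cross-locus pair products; for A×A the unnormalized entry
  is (Σ_k z_ik z_jk)² − Σ_k (z_ik z_jk)², identical (up to scale) to the
  Gram matrix of the explicit pairwise-interaction design with columns
  z_·k ∘ z_·l over pairs k < l.  AD and DD subtract the analogous single
  sums.  Exact matrices can carry small negative entries; Hadamard squares
  cannot.
* **Third order**: triple Hadamard products only.  The intra-locus
  correction is not implemented at third order — the pairwise
  exact-vs-approximate differences are already in the third decimal on
  realistic panels, and the correction's complexity grows combinatorially.
* **Intra/inter-chromosome A×A**: the exact (or per-chromosome Hadamard)
  construction is aggregated over locus pairs on the same chromosome
  (intra) versus different chromosomes (inter).  Both parts are divided by
  one shared scalar — the mean diagonal of the total A×A matrix — so
  intra + inter equals the total elementwise.

**Scale convention.** Every epistasis matrix is rescaled to mean diagonal
one and the scalar is recorded in the `normalizer` field.  REML variance
components absorb any fixed kernel scale, so estimates of heritability are
invariant to this choice; the convention keeps per-component
heritabilities directly comparable.  Whether to renormalize the exact
matrix after the intra-locus subtraction is a genuinely open choice; we
renormalize and flag the scalar in metadata.

## GREML

Variance components maximize the REML log-likelihood
l = −½(log|V| + log|X'V⁻¹X| + y'Py), with
P = V⁻¹ − V⁻¹X(X'V⁻¹X)⁻X'V⁻¹ and X a column of ones.  Two updates are
combined:

* **EM**: sigma2_k ← sigma2_k + sigma2_k² (y'P K_k P y − tr(K_k P)) / n;
  monotone in the likelihood, slow near the optimum; used for 3 warm-up
  iterations (and as terminal fallback).
* **AI**: quasi-Newton with the average-information matrix
  AI_jk = ½ y'P K_j P K_k P y and score
  s_k = −½(tr(K_k P) − y'P K_k P y).

Because a variance component whose optimum lies on the zero boundary makes
every unconstrained AI proposal infeasible, the AI step uses an active-set
refinement: components whose Newton move crosses the variance floor are
pinned at the floor and the AI system is re-solved over the free
components; the step is halved up to 5 times if the likelihood would still
decrease, and only then does the iteration fall back to EM.  Without this,
boundary fits crawl at EM speed and routinely hit the iteration cap.  The
plain accept-or-EM rule is available as `n_halvings=0`.

Defaults: tolerance 1e−6 on the largest relative parameter change, cap 200
iterations, variance floor 1e−8 × var(y) (a component estimated "zero"
rests at the floor), starting values an equal split of var(y) across all
components.  X being a column of ones, the projection P is a rank-one
correction of V⁻¹, which keeps every iteration at one Cholesky plus O(q)
matrix products.  Heritability uses the denominator
Σ_k sigma2_k·meandiag(K_k) + sigma2_e, which reduces to the simple
variance ratio for mean-diagonal-one kernels.

## GBLUP and reliability

With validation phenotypes masked, the mean is estimated by GLS on the
training records and each component's BLUP is
ĝ_k = sigma2_k K_k[·, train] V⁻¹ (y_train − 1·mu_hat), evaluated for all
individuals.  The reliability (squared accuracy) of individual i is

    rel_i = (G Ztr' P Ztr G)_ii / G_ii,

with G the genetic covariance of the components in the model and P the
REML projection over the training block.  For the total genetic value
under A + A×A the numerator carries all four blocks (additive, epistatic
and both cross blocks); per-component reliabilities use the component's
own diagonal block over its own denominator — the cross terms belong to
the total-value reliability, since the component predictions are
correlated.  An individual with nonpositive genetic variance gets
reliability zero with a warning.

## Cross-validation and accuracy measures

Individuals are randomly permuted into k folds (first k−1 of size
⌊n/k⌋, the last takes the remainder; n = 6215, k = 10 gives nine folds of
621 and one of 626).  Per fold, variance components are re-estimated on
the training records only, and four accuracy measures are collected:
observed phenotype-prediction accuracy R̂0p = corr(ĝ_total, y) in the
fold; expected phenotype-prediction accuracy R0p = mean(R0i)·√h²_k with
h²_k the training-fold total heritability; expected genetic-value
accuracy R̃0 = R̂0p/√h²_k; and the mean square-root reliability R0.
Model comparisons report 100·(acc_B − acc_A)/acc_A.  Correlation is
Pearson throughout.  The reliability-level analysis pools validation
individuals across folds, cuts them into levels by one model's
total-genetic-value reliability at user-supplied thresholds, and holds the
competing model to the same count per level (sorted by its own
reliability, ties broken by stable sample-id order), so per-level accuracy
differences cannot be a sample-size artifact.  Thresholds are a required
input: no canonical set exists.

## Inheritance of nonadditive effects

Under a sire-with-many-dams system with dams as an infinite random-mating
pool at frequency p, daughters' heterozygote frequency is q, ½, p for sire
genotypes AA, Aa, aa.  The relative daughter difference
λ = (het_daughters − 2pq)/2pq quantifies indirect inheritance; it is
maximized by the homozygote of the rarer allele and vanishes as p → ½.
Two-locus transmission of a favorable allelic combination (unlinked loci,
linkage equilibrium) is classified from the sire's allele doses: direct
(both favorable alleles fixed), mixed (one fixed, one heterozygous), none
(double heterozygote — no allele guaranteed — or neither allele present),
indirect otherwise.

## Synthetic data

The generator emulates the structure the analysis assumes: n individuals,
m biallelic SNPs in contiguous blocks on n_chrom chromosomes, allele
frequencies uniform on `maf_range` (default 0.05–0.95), loci in linkage
equilibrium across the population.  Phenotypes are built from Gaussian
per-SNP additive and dominance effects and Gaussian per-locus-pair A×A
effects (pairs sampled within chromosomes, across chromosomes, or
anywhere), each component rescaled so its realized variance hits the
requested fraction of a unit phenotypic variance; planted outliers sit at
8 clean-data SDs for exercising the 4-SD filter.

Design choices that matter:

* **Family structure.** Optional half-sib families (n_sires ×
  daughters_per_sire); with `dams_per_sire` set, dams are explicit and
  reused, mixing full sibs (a ≈ ½) and half sibs (a ≈ ¼).  In family mode
  parents are phased and transmit whole chromosome haplotypes without
  recombination, so chromosomes segregate as units.  Two consequences are
  load-bearing.  First, identifiability: with a single relatedness level
  the additive and A×A kernels have proportional family blocks and the
  two variances separate only weakly; mixed relatedness levels (½, ¼ and
  chromosome-sharing variation) make the (a, a²) relation informative.
  Second, the intra/inter distinction: co-transmitted intra-chromosome
  locus pairs give sibs elevated intra-pair covariance, which is what
  lets intra-chromosome A×A signal masquerade as additive signal — the
  confounding pattern seen in real livestock data — and what makes the
  intra/inter split estimable at all.  Without linkage the split is
  structurally unidentifiable, which is itself informative: the
  distinction is a linkage phenomenon.
* **Pair sampling density.** A×A effects use sampled locus pairs, default
  5,000.  Sparse-pair architectures have realized covariance that deviates
  from the dense A×A kernel, which inflates variance-recovery noise;
  recovery experiments in the tests use ~100,000 pairs (capped at the
  number available) so the architecture is effectively polygenic.
* **Founder LD.** `founder_ld_rho` draws founder haplotypes from an AR(1)
  Gaussian copula along each chromosome (ρ between adjacent SNPs, marginal
  frequency preserved), giving block-correlated haplotypes.  Besides
  decorrelating the intra/inter kernels, LD reduces the effective number
  of independent loci, which strengthens per-individual epistatic
  prediction the way dense LD does in real panels.
* **Effects are Gaussian** — the model class GBLUP/GREML assumes; no
  realistic cattle LD map, no selection, drift or genotyping error.
  Passing tests on this generator demonstrate internal correctness of the
  estimators under the assumed model, not robustness to real-data LD
  patterns or ascertainment.

A note on what the confounding experiment can and cannot show: when a
genuinely epistatic intra-chromosome signal is simulated, REML attributes
it to the intra kernel even with the additive kernel present — the
generative experiment identifies the true component.  The
additive/intra-A×A confounding reported on real data appears here in the
causal direction that is reproducible: an additive-only signal is claimed
by the epistasis kernels when the additive kernel is left out of the
model, and reclaimed by the additive kernel when it is included, flipping
the apparent intra-chromosome A×A heritability between near zero and
substantial.  Observational confounding on real data cannot distinguish
these directions; the generator can, and the tests document both.

## Problem sizes used in the test suite

Analytic and oracle checks run at n ≤ 60 in well under a second each.
Stochastic checks use the smallest sizes at which the targeted effect is
clearly resolved, chosen once from the statistics of the problem:

* **Variance-component recovery**: n = 1000, m = 2000, mixed full/half-sib
  families (100 sires × 10 daughters, 3 dams each), 30 replicates.  The
  per-replicate SD of the A×A heritability estimate is ≈ 0.1 under this
  design, so the mean over 30 replicates resolves a ±0.05 band.
* **Intra/inter confounding**: n = 1000, m = 1000, the same family design
  plus founder LD (AR(1) ρ = 0.95), which decorrelates the intra- and
  inter-chromosome kernels enough for the split to be estimable.
* **Cross-validated model comparison**: n = 1000, m = 500, larger families
  (50 sires × 20 daughters, 4 dams each) and founder LD ρ = 0.95.  The
  per-fold paired accuracy difference between the A-only and A + A×A
  models has SD ≈ 0.03 at 100-individual validation folds; the epistatic
  gain must exceed that for the fold-wise comparison to be informative,
  which requires LD to concentrate the epistatic signal on fewer
  effective loci (as strong LD does in real livestock panels).  Sparser
  panels or LE founders leave the comparison dominated by fold noise.
* **Half-sib expectation checks**: 2,000 sib pairs × 5,000 SNPs.

Dense linear algebra throughout; the intended scale for real use is n up
to ~10,000.

## Known limitations

* Exact intra-locus corrections stop at second order; third-order
  matrices are Hadamard products.
* One record per individual (Z = I); repeated records are out of scope.
* No SNP-effect backsolving, no multi-trait models, no sparse or low-rank
  kernel approximations.
* GREML standard errors from the inverse AI matrix are not reported;
  across-fold SDs play that role in the cross-validation reports.
* The outlier filter is single-pass by design (mean/SD from the
  unfiltered data).
* The package is a library: the importable API plus the `examples/`
  scripts are the interface; there is no console entry point.
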