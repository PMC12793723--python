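# Methods

## Model

Each trio contributes a child phenotype `Y` and unphased biallelic
genotypes `(Zm, Zp, G)` coded as counts of the coded allele. The trait model
per locus is `Y = α0 I(G=0) + α1 I(G=1) + α2 I(G=2) + γ`, with `γ` an
arbitrary random background (other loci, environment, structure) that may be
dependent on the parental genotypes but not on which allele a heterozygous
parent transmits. Genetic effects are assumed monotone in the allele count
but not additive. Under Mendelian segregation `P(A=1|Z) = 0, 1/2, 1` for
`Z = 0, 1, 2`, so only heterozygous parents provide randomizations; the
transmission-distortion-adjusted variant (P(A=1|Z=1) ≠ 1/2) is out of scope.

The causal estimand is the half-sum of expected within-parent
potential-outcome differences given parental heterozygosity (δ); it is zero
iff the locus has no average causal effect of the child genotype on the
trait. The TMT estimator `d`, its variance estimate, the standardized
statistic τ and the TDT counts/χ² are exactly the formulas in the README.

## Assignment

`(W0, W1)` per (SNP, trio) is derived mechanistically: enumerate the
transmitted-allele pairs consistent with `(Zm, Zp, G)`; if none, the cell is
Mendelian-inconsistent. Every consistent phase resolution yields the same
counts, including the `(1,1,1)` configuration, where the statistic needs
only `W0 = W1 = 1` and the per-parent alleles are never resolved or stored.
Inconsistent cells are excluded per cell (an isolated genotyping error
should not discard a family genome-wide), counted per SNP, and SNPs whose
exclusion rate exceeds 5% are flagged in a warning column. Missing genotypes
in any trio member likewise exclude only that cell.

## Numerical and procedural choices

- **Variance estimate.** Assignment classes with fewer than two members
  contribute zero to the variance sum (the unbiased ddof=1 variance is
  undefined there); if every contributing class is degenerate the SNP is
  flagged and not tested. This is conservative and keeps the remaining terms
  unbiased.
- **min_N.** The Normal(0,1) null relies on the CLT across randomizations;
  rows with fewer than `min_N = 10` heterozygous parents (CLI-overridable)
  are flagged rather than tested.
- **Centering.** The centered estimator subtracts the assignment-weighted
  mean `mu_hat`. Exact enumeration on tiny cohorts shows the uncentered
  statistic is exactly unbiased for the heterozygous-slot-pooled conditional
  estimand, while centering introduces an O(1/N) term (the `mu_hat`
  self-term; cross-family terms vanish). At the cohort sizes the test is
  meant for (hundreds of trios) the term is far inside Monte Carlo
  resolution, as the replicated experiments verify. The uncentered statistic
  is exposed as `d_tmt_nc`; on an all-affected binary cohort it coincides
  with the TDT estimand, which the centered form cannot (it degenerates to
  zero when the trait carries no contrast).
- **Oracle δ (TMT).** Computed conditionally on the realized parental
  genotypes: the mean over heterozygous parent slots of
  `(α1−α0)(1−z_other/2) + (α2−α1) z_other/2`. This pooled form is what the
  estimator targets at fixed parents; it converges to the per-side
  population definition as the cohort grows (the two differ only when
  maternal and paternal heterozygote counts are unbalanced in finite
  cohorts).
- **Oracle δ (TDT) and scale.** The TDT parameter includes the factor
  η = P(Y=1|Z=1) (disease prevalence given a heterozygous parent), which is
  exactly what makes it coincide with the TMT parameter for binary traits.
  The matching unbiased estimator therefore normalizes `N1 − N0` by the
  cohort-level heterozygous-parent count; the user-facing `tdt_test` reports
  the conventional affected-only normalization `d = 2(N1−N0)/(N0+N1)`
  (which estimates δ/η) because the χ² test is invariant to the choice. The
  oracle is computed by brute-force Monte Carlo over the simulator's own
  mechanism at fixed parents, pooling the conditional expectations across
  replicates, with independent batches supplying the oracle's own Monte
  Carlo error.
- **Permutation null.** Full permutation of `Y` across trios with genotypes
  fixed, recomputing τ each time; `p = (1 + #{|τ_b| ≥ |τ_obs|})/(B+1)` with
  ties counted against the null. A replicate with both `d = 0` and zero
  variance estimate is scored τ = 0; a nonzero `d` with zero variance
  estimate is undefined (NaN).
- **Multiple testing.** Raw p-values are primary; Benjamini–Hochberg or
  Bonferroni columns are optional flags.
- **TDT discreteness.** The χ² p-value is a function of binomial counts and
  is therefore discrete and slightly conservative; at thousands of null
  SNPs a raw Kolmogorov–Smirnov test against Uniform(0,1) can reject purely
  from the atoms (mass ≈ √(2/πN) at p = 1). Null-distribution checks for
  the TDT therefore use the randomized probability integral transform of
  |N1 − N0| under its exact Binomial(N, 1/2) law, which is exactly uniform
  under the null; the empirical FPR at fixed α is checked directly as well.

## Simulator

The generator emulates a population-sampled trio cohort with confounding by
ancestry; its defaults are the study conditions the experiments use.

- **Structure.** Per-SNP ancestral frequencies ~ Uniform(0.05, 0.95);
  Balding–Nichols subpopulation frequencies for K = 4 subpopulations;
  per-trio admixture weights from a symmetric Dirichlet(0.3), shared by the
  two parents of a trio (assortment by ancestry maximizes structure
  confounding; independent parents are configurable). The Balding–Nichols
  inbreeding parameter is tuned analytically so the *individual-level*
  fixation index hits the target (default F_ST = 0.2): the individual-level
  index equals `F_BN · E[Σ_k q_k²]` and `E[Σ_k q_k²] = (a+1)/(Ka+1)` for
  Dirichlet(a) weights. `realized_fst` measures it as a Wright-style ratio
  of sums using the simulator's own individual frequencies and known
  ancestral frequencies.
- **Traits.** Quantitative: `Y = ι + Σ_{i∈C} α[G_i] + βE + ε` with
  ι = 100, ε ~ Normal(0, σ_e²), and `E` a structure-correlated environment —
  a standardized linear combination of the trio's admixture weights mixed
  50/50 in variance with independent Normal noise (mixing configurable).
  The per-genotype effects have shape `(0, 1, 1+r)` (r the dominance ratio,
  1 = additive) and are rescaled by a single factor so the realized
  Var(genetic)/Var(total) equals the target h² on the cohort; because the
  causal genotypes and `E` are correlated under structure, the factor solves
  the quadratic that includes their covariance. Binary: the same latent
  scale thresholded at the empirical (1 − prevalence) quantile, so the
  realized prevalence is exact.
- **Confounded single-locus design.** `Y = ι + bG + sκ + ε` with
  `κ = (Zm + Zp − λ)·I(Zm ≠ 1, Zp ≠ 1)`, ι = 100, λ = 10. The confounder
  tracks parental genotypes but vanishes for heterozygous parents, so the
  transmission randomization is unconfounded while the Y-on-G regression is
  biased; the null contrast uses b = 0, s = 1 (a confounding grid tied to b
  degenerates at the null).
- **Two-locus linkage.** Parents carry diplotypes drawn from haplotype
  frequencies whose double-heterozygote coupling probability is η_cd
  (solved from the frequency odds); transmission picks one haplotype and
  recombines the linked locus with probability θ_cd. The implied joint
  transmission law is available both in closed form and by enumerating the
  gamete mechanism, and the empirical transmissions are checked against it.
  Genome-scale coalescent simulation is out of scope; externally simulated
  VCFs can be analyzed through the ordinary loaders.

What the generator does *not* emulate: genome-wide LD beyond the two-locus
model, genotyping error beyond Mendelian inconsistencies, missingness
patterns, sibling or multi-child pedigrees, sex chromosomes, and
transmission distortion. Passing experiments therefore show correctness of
the statistics under the stated sampling model, not robustness to data
artifacts real cohorts may carry.

## Experiment designs and problem sizes

The replicated experiments use desk-scale sizes, chosen so Monte Carlo error
bars make each claim checkable statistically: unbiasedness — 1000 replicates
of transmission + trait at fixed parents, 500 trios, 40 SNPs (4 causal), at
h² ∈ {0.3, 0.6, 0.9} for the TMT and with prevalence 0.2 for the
affected-only TDT, each causal SNP's mean estimate within 3 combined Monte
Carlo SE of its oracle; type-I error — one cohort of 2000 noncausal SNPs
(500 trios for the TMT; 2500 trios at prevalence 0.2, i.e. ≈500 affected,
for the TDT) under F_ST = 0.2 structure with the confounded environment,
checking the α = 0.05 FPR within 3 binomial SE and p-value uniformity at
the 1% KS level; confounding contrast — 2000 single-locus replicates at 500
trios (b = 0, s = 1), OLS failing and the TMT passing KS uniformity;
causal linkage — 400 two-locus replicates at 500 trios with
(η, θ) = (0.8, 0.1) for the attenuated-signal check and η = 0.5 for the
linkage-equilibrium null.

## Known limitations

- The variance estimator is conservative under the alternative (it
  underestimates the sampling variance of `d` only asymptotically and from
  below per the framework's theory), so confidence statements from τ are
  test-oriented, not interval-oriented.
- SNPs with very few heterozygous parents are not testable; in strongly
  drifted cohorts this thins the usable genome.
- Phenotype missingness excludes the trio from all randomizations at every
  SNP; no imputation is attempted.
- The TDT path requires the affected-only design; supplying unaffected
  children silently drops them (logged), which is intended but means a
  mislabeled phenotype column fails quietly rather than loudly.
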