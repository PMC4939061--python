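# Methods

## The statistic

`gcore_dsp` tests for gene–gene (SNP×SNP) interaction in nuclear families
using discordant sib pairs (DSPs): one affected and one unaffected full sib
per family. The affected sibs play the role of cases and the unaffected sibs
of controls, and interaction is measured as a contrast of allelic odds
ratios between the two classes.

For a SNP pair, the genotypes of the k affected sibs form a 3×3 table
(rows AA/Aa/aa at the first SNP, columns BB/Bb/bb at the second, uppercase
= minor allele), and likewise for the unaffected sibs. Each 3×3 table is
collapsed to a 2×2 table of phase-unknown allele-pair counts: a genotype
with i copies of A and j copies of B contributes i·j to cell (A,B),
(2−i)·j to (a,B), and so on, which yields the familiar weights
4n₁₁ + 2n₁₂ + 2n₂₁ + n₂₂ for cell (A,B). The double heterozygote
contributes 1 to every cell, i.e. no phase is inferred. The collapsed
total is always four times the genotype-table total.

With case cells (a,b,c,d) and control cells (a′,b′,c′,d′),

    OR_case = ad/(bc),   OR_control = a′d′/(b′c′)

and the test statistic is

    G = [log OR_case − log OR_control] / sqrt(4 · Var(log OR_case)),

referred to N(0,1), two-sided. Under Hardy–Weinberg and linkage
equilibrium, log OR measures the allelic association between the two SNPs
within a phenotype class; a difference between classes indicates
interaction on the disease. Because alleles are counted additively in the
collapse, the test implicitly assumes an additive allelic model.

## The null variance

Conditional on each family's observed genotypes, the null hypothesis of no
interaction makes the affected label exchangeable between the two sibs —
per family, the affected sib's cell count vector is a draw of 1 of 2
without replacement (a multivariate hypergeometric draw). If u_s and v_s
are the 3×3 cells of the two sibs in family s, the family contributes

    (1/4)(e_{u_s} − e_{v_s})(e_{u_s} − e_{v_s})ᵀ

to the covariance of the affected-table cell counts; genotype-concordant
families contribute nothing (but still enter the tables and odds ratios).
The collapsed cells are linear in the cell counts, so the variance of
log OR_case follows by the delta method, with the gradient
(1/a, −1/b, −1/c, 1/d) pushed through the collapse weights.

Two consequences of this sampling model shape the statistic:

* the same within-family swap that moves a count into the case table moves
  it out of the control table, so to first order
  Cov(log OR_case, log OR_control) = −Var(log OR_case) =
  −Var(log OR_control), and Var of the difference is 4·Var(log OR_case) —
  the factor 4 in the denominator;
* the gradient is evaluated at the **null-expected** collapsed cells — half
  the combined affected+unaffected (R/2) table — rather than at the
  observed case cells. This keeps the case and control variances identical
  by construction, makes |G| exactly invariant under swapping the
  affected/unaffected labels (an invariance the permutation null demands of
  any exact implementation), and agrees more closely with the
  enumerated permutation variance than the observed-count plug-in.

`permutation_oracle` enumerates all 2^k within-family label swaps (k ≤ 20;
Monte-Carlo beyond) and reports the exact null moments. The oracle
satisfies Var(log OR_case) = Var(log OR_control) exactly — the valid swap
set is closed under complementation — while Cov = −Var holds at the order
of the delta approximation: log OR is not linear in the cell counts, so
the anticorrelation is exactly −1 only for the linearized statistic. On
cohorts of 12 families with every collapsed cell ≥ 5, the delta variance
agrees with the enumerated variance to about 10% on average; individual
cohorts can deviate more when permutations push a collapsed cell near
zero, where the curvature of the log dominates. At the cohort sizes the
test is meant for (hundreds of DSPs) the cell counts are large, the
linearization is accurate, and the null distribution of G is
indistinguishable from N(0,1) (Kolmogorov–Smirnov, 5,000 replicates).

## Testability rules

A SNP pair is scored from the families with complete genotypes at both
SNPs for both sibs (pair-wise deletion; k′ families used). The pair is
NOT_TESTABLE when any of the eight collapsed cells is zero (no Haldane
correction by default; `--haldane` adds 0.5 to every collapsed cell for
exploratory use) or when every family is genotype-concordant (zero
variance). Refusing zero-cell tables is conservative; the rate of
untestable pairs is reported alongside results.

## The simulator

The generator emulates the ascertainment behind the published type I error
and power experiments. Two SNPs are parameterised by their minor allele
frequencies and the LD measure r²; haplotype frequencies are
h_AB = p₁p₂ + D with D = sqrt(r² p₁(1−p₁) p₂(1−p₂)) taken positive, and an
r² beyond the Lewontin feasibility bound is rejected with the maximum
feasible value named. r² = 0 factorizes the four frequencies, so one
code path covers both linkage equilibrium (the unlinked-genes design) and
the LD robustness designs: parents are two independent haplotype draws
each, children receive one intact haplotype per parent, and with r² = 0
this is distributionally identical to independent per-SNP transmission.

Affection is assigned per offspring by the logistic penetrance
P(Affected|X) = expit(ρ + λ₁X₁ + λ₂X₂ + λ₃X₁X₂), with X coding the
genotype as minor-allele count (additive), carrier status (dominant), or
homozygous-minor status (recessive). The intercept ρ is calibrated by
monotone root-finding so the population prevalence over the founder
genotype distribution matches a target to 1e-10; calibration happens once
per design, not per replicate. Families have exactly two offspring (the
minimal sibship containing a DSP) and are kept iff exactly one offspring
is affected; rejection sampling repeats in vectorized batches until the
requested number of DSPs is collected, aborting if the acceptance rate
falls below 1e-5.

Defaults mirror the published study conditions: MAF 0.2/0.2 (alt grid
0.3/0.15), 250/500/1000 DSPs, prevalence 0.01/0.05/0.1 for the main-effect
scenarios, effect sizes log(2) and log(2.25), 5,000 replicates for type I
error and 1,000 for power. The null scenarios use prevalence 0.05; with no
genetic effects the type I error is prevalence-free, so the choice only
affects the rejection-sampling rate.

What the generator does **not** emulate: real haplotype backgrounds
(flanking markers in LD with the disease SNPs), sibships larger than two,
parental phenotypes, genotyping error or missingness. Passing simulation
checks therefore demonstrates calibration of the statistic under the
idealized two-SNP sampling model, not robustness to those real-data
features. One visible consequence: the type I inflation under strong
dual main effects (dominant, λ₁=λ₂=log 2, prevalence 0.01) reproduces in
direction — rate ≈ 0.06 at 500 DSPs with the 95% CI excluding 0.05 — but
not at the published magnitude (0.167), which plausibly depends on the
real-haplotype simulation backend used there.

## Experiment sizes and numerical choices

* Clean-null type I error grid: 2,000 replicates per scenario in the test
  suite (estimates at this size resolve the published rates to within the
  3-binomial-SE comparison used); LD robustness, main-effect robustness and
  the normality check use 5,000 replicates, the scale the published
  estimates were computed at.
* Power checks are ordinal only (monotone in the number of families and in
  the interaction effect size); published power values are read from a
  figure and are not comparison targets.
* Replicate seeds are spawned from a single experiment seed via numpy's
  `SeedSequence`, making every reported rate bit-reproducible; the scan
  engine partitions the pair stream and merges results in enumeration
  order, so output is byte-identical for any worker count.
* Minor alleles are defined from allele counts over the whole file, ties
  broken toward the lexicographically smaller symbol; the statistic's
  magnitude is invariant to allele-label flips, so this fixes only the
  sign/reporting orientation.
* One DSP per nuclear family: the first affected and first unaffected sib
  in file order. Half-sibs are not treated as a sibship (the null model
  assumes exchangeable full sibs). Families with no discordant pair are
  dropped.
* Gene intervals are 1-based inclusive by default with a BED (0-based
  half-open) dialect flag; "between genes" pairs require both SNPs genic
  with disjoint gene sets.

## Limitations

* No covariate adjustment; the test is a screening statistic. Candidate
  pairs can be followed up with a regression framework that models
  covariates and within-family correlation.
* Phase is never inferred; the double-heterozygote weighting is the
  phase-agnostic collapse.
* Main-effect-free calibration: with strong main effects at both SNPs the
  test can reject in excess of the nominal level (as published); interpret
  interaction hits alongside main-effect tests at the same SNPs.
* X-chromosome SNPs receive no special handling; imputation, Mendelian
  error checking and binary PLINK input are out of scope.
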