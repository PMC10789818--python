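# Methods

## The haplotypic aFC model

A cis-regulatory variant scales the expression of the haplotype that
carries it. For a gene with N conditionally independent eQTLs, the
expression of one haplotype carrying alleles `i_1 … i_N` is
`e = e_R · Π_n δ_n^{i_n}` where δ_n is the allelic fold change (aFC) of
eQTL n and e_R the expression of an all-reference haplotype. Writing
`s_n = log2 δ_n` and collecting the phased alternative-allele indicators of
an individual's two haplotypes into binary vectors `h1, h2`, total
expression is

    log2 e_total = log2( 2^(s·h1) + 2^(s·h2) ) + log2 e_R .

Conditional independence of the eQTLs (they come from stepwise mapping,
each significant given the others) is what makes the N effects jointly
identifiable without shrinkage. Arbitrary correlated SNP sets are out of
scope; they would need a penalty.

Two quantities follow directly from a fitted model: the predicted log2
allelic imbalance `AI = s·h1 − s·h2`, and, through the base-2 logit link,
the reference-allele ratio of ASE reads `r = 2^s / (1 + 2^s)`.

## Estimation

**Noise model.** Counting noise on expression is multiplicative to first
order, so the model is fitted by least squares on log2-transformed counts
(log-normal approximation). Counts are scaled to the median library size,
floored with a pseudo-count of 1, and log2-transformed. Covariates (PEER
factors, genotype PCs, platform, sex — supplied as a matrix, never
computed here) are removed in two steps: a joint OLS of the gene's
expression on all covariates keeps those with coefficient p < 0.01
(two-sided t, strict inequality), and the residuals of a second regression
on the kept set are the corrected expression. The step-1 selection uses
one joint regression rather than per-covariate marginal regressions; with
correlated covariates (PEER factors are near-orthogonal) the joint variant
is the conservative choice. Both corrected and merely normalized
expression are accepted by the fitter.

**Optimization.** Bounded nonlinear least squares (scipy's trust-region
reflective method) with an analytic Jacobian; the haplotype-1 weight
`w = 2^(s·h1) / (2^(s·h1) + 2^(s·h2))` gives ∂pred/∂s_k = w·h1_k +
(1−w)·h2_k. Gradient/step/function tolerances are 1e-8 — well below the
counting-noise floor — with at most 1000 function evaluations. Effects are
initialized from the linear regression of expression on per-variant
alternative-allele dosage (h1+h2), whose intercept initializes log2 e_R;
this starts the optimizer near the optimum, and the returned objective is
never worse than the initialization. Estimates are clamped to
|s| ≤ log2(100) to keep pathological genes from producing unbounded
fold changes; log2 e_R is free (when the input is zero-mean residualized
expression it simply absorbs the centering). Predictions use
`log-sum-exp` base 2 throughout, so extreme effects cannot overflow.

**Degenerate inputs.** An eQTL monomorphic in the analyzed samples has no
gradient; its s is fixed at 0 and reported in `fixed_zero` while the rest
of the gene is fitted. A rank-deficient genotype design (duplicated
variant columns, or too few usable samples) raises an identifiability
error naming the collinear columns rather than returning arbitrary
numbers. Samples with missing or unphased calls at any of the gene's
eQTLs are excluded for that gene — never imputed — and counted.

**Confidence intervals.** 95% CIs come from the asymptotic covariance
σ²(JᵀJ)⁻¹ at the optimum with a Student-t quantile (the usual nonlinear
least-squares practice); a singular curvature leaves the CI marked
unavailable. Coverage is verified by simulation in the test suite (null
effects are covered at ~95%).

**Single-eQTL reduction.** For N = 1 the problem is one-dimensional after
profiling out e_R (for fixed s the optimal offset is the mean residual),
and `fit_afc_single` solves it by bounded scalar minimization. This is the
classic single-variant aFC computation; the joint fit agrees with it to
1e-3 on one-eQTL genes, and it doubles as the marginal estimator in the LD
experiments.

**Ancestry stratification.** Stratum-specific effect vectors `s_0, s_1`
enter through the per-sample indicator I as `s_eff = s_0(1−I) + s_1·I` and
are estimated in a single joint optimization with a shared log2 e_R (the
model is one equation, not two independent fits). Per eQTL the stratified
estimate is reported only where the two strata's 95% CIs do not overlap —
a deliberately conservative selection, since stratified estimates from
small strata are noisy — otherwise the pooled estimate stands. A stratum
smaller than the parameter count refuses stratification and returns the
pooled model with a warning.

## Prediction and its scoring

Predicted expression is the genetic part `log2(2^(s·h1)+2^(s·h2))`;
observed expression is scored as fold change from the cohort mean, so both
sides are centered across the evaluated samples before applying the
uncentered-denominator coefficient of determination

    R² = 1 − Σ(obs − pred)² / Σ obs² .

This convention makes a zero predictor score exactly 0 and allows R² < 0
for a predictor worse than nothing. Observed allelic imbalance is
`log2((c_h1+0.5)/(c_h2+0.5))` with a minimum total coverage of 100 reads
(8 for the top-eQTL concordance check, which also requires >10
heterozygous carriers); AI needs no centering. Haplotype 1 is everywhere
the left allele of the phased GT — the ASE counts must share this frame —
and AI > 0 means haplotype 1 is higher; the concordance check re-signs AI
so the alternative allele of the eQTL under test is the numerator.

The permutation audit refits the model after permuting the sample labels
of the expression vector, which decouples genotype from expression while
preserving allele frequencies, LD and sample size. The refitted training
R² has expectation ≈ (number of parameters)/n, so a mean near zero across
permutations rules out systematic overfitting; the identity permutation
reproduces the unpermuted R² as a sanity reference.

## Power analysis and the excess-imbalance caller

ASE reads at a gene are modelled as Binomial(coverage, r). The eQTL model
supplies each gene-and-sample's own null ratio r0 = 2^AI/(1+2^AI). Power
to resolve a log2 fold deviation `fc` is the rejection rate of the exact
two-sided binomial test at α = 0.01 under an alternative placed at
logit2(r0) ± fc (half the mass each side). The default computation mirrors
the 1000-draw simulation of the reference procedure; an enumeration mode
sums alternative probabilities over the rejection region and is exact,
deterministic and faster — audits use it. Two-sidedness follows the
"minlike" convention — the p-value sums all outcomes no more
probable than the observed one — matching `scipy.stats.binomtest`; a
normal-approximation variant was considered and rejected since exact
enumeration is cheap at any realistic coverage.

A gene-and-sample shows *excess* allelic imbalance when the exact test
rejects AND the observed deviation |AI_obs − AI_pred| is at least the fold
cutoff (0.5 or 1 log2 units). The cutoff is an effect-size guard: at high
coverage the test rejects trivially small deviations. The per-sample audit
restricts to genes above 1 TPM (TPM is an input column; gene lengths are
out of scope) with power > 80% at the mode's own null, runs the caller
once with the eQTL predictions and once against a no-eQTL balanced
baseline, and reports the flagged fractions plus their relative decrease
(the "eQTL gain" — the regulatory knowledge contributed by the eQTL set).

## The simulator

The generator reproduces the validation conditions end to end: log2
effects ~ Normal(0, σ=1); phased genotypes at given MAFs (default drawn
Uniform(0.05, 0.5), a realistic common-variant spectrum) — independent, or
for variant pairs drawn from the two-locus haplotype table with D solved
from a target r² (the feasibility bound r²max is checked and reported);
expected haplotypic expressions from the aFC model; totals ~ Poisson;
haplotype counts ~ Binomial(total, r) at the true reference ratio. No
biological variance beyond genotype and counting noise is added — by
design, so estimator error is isolated — and a gamma-Poisson dispersion
knob exists but defaults off. e_R is solved so the cohort-mean expected
total equals `mean_expression` (default 500 reads, a moderately expressed
gene); library sizes are uniform since library variation is a
normalization concern, not an estimation one. One master seed fans out to
named substreams (effects, haplotypes, counts) via `SeedSequence`, so runs
are bit-reproducible and components independently so.

What the simulator does **not** emulate: biological trans variation and
over-dispersion, mapping bias in ASE reads (WASP-style filtering is
upstream), multi-locus LD blocks beyond pairs, covariate structure, and
genotyping/phasing error. Passing tests therefore demonstrate correctness
of the inference machinery under the stated noise model, not performance
on real tissue data.

## Validation scale

The shipped validations run at desk scale, chosen to keep the full suite
in the low minutes while leaving Monte-Carlo error far below the margins
tested: effect-size recovery uses 500 genes × 500 individuals (1–14
eQTLs), the LD experiment 50 pairs per r² bin at n = 839, the permutation
null 200 permutations of a 3-eQTL gene, power checks a
4-coverage × 2-resolution grid at 1000 draws, and caller calibration ~2000
gene-sample pairs at coverage ~2000 (where 0.5-fold resolution is fully
powered) plus 500 injected 1-fold deviations at coverage 200.

## Known limitations

- Effects are assumed constant across individuals within a stratum;
  gene–environment or cell-composition interactions masquerade as noise.
- The log-normal approximation degrades for very low counts (the +1
  pseudo-count floors the transform); estimates for genes under ~50 mean
  reads carry visible small-sample bias.
- CI-based selection in the ancestry model controls false positives at the
  expense of power; genuinely different but noisy stratum effects will
  often fall back to the pooled estimate.
- The excess-imbalance caller inherits any error in the fitted effects:
  a mis-estimated aFC shifts the null and can create or mask excess calls.
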