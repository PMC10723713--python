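# Methods

## Problem setting

Let S⁺ be the set of SNPs with nonzero *marginal* effects in the base GWAS
and S the set of causal variants in the target population. The working
assumption of the transfer-learning construction is that base data — being
larger and often multi-ancestry — covers the target's causal architecture
(S ⊆ S⁺ in the nested model), while the effect *sizes* do not transfer.
Only SNP identities are therefore carried from base to target; all effects
are re-estimated on target individuals.

## Signal-count estimation

The FNP estimator needs ŝ ≈ |S⁺|. We ship a Meinshausen–Rice-style
lower-bound estimator: under the null, #{pᵢ ≤ t} ≈ m·t, so the excess
count at any threshold bounds the signal count from below,

ŝ = ⌈ sup_t ( #{pᵢ ≤ t} − m·t − η_m(t) ) / (1 − t) ⌉₊,
η_m(t) = c·√(2·m·t(1−t)·log log m).

The bounding function η absorbs the fluctuations of the uniform empirical
process (law-of-the-iterated-logarithm scaling); `bounding_scale` c
defaults to 1. The supremum is evaluated on the observed p-values **not
exceeding 0.5**. The upper half of the threshold range carries no
information about sparse signals, while the 1/(1 − t) factor amplifies
empirical-process noise as t → 1: in Monte-Carlo null calibration the
untruncated supremum overestimates on roughly 10% of pure-noise panels,
versus essentially never with the truncated grid, and the truncation leaves
every signal regime we test unchanged. The estimator is deliberately biased
low on marginal evidence but, crucially for this pipeline, any
*over*-estimate only makes downstream screening keep more SNPs — a
conservative failure mode the joint re-training step absorbs.

The exact estimator used by the original FNC literature is not fixed by a
printed formula; `method=` is a plug-in point (an `oracle` mode exists for
testing against planted truth), and results should not be expected to be
bit-compatible with other implementations of the same estimand.

No LD information enters this step: marginal counting may overcount signals
that are merely in LD with causal variants, which again errs conservative
and keeps the step O(m log m).

## FNC screening

With p₍₁₎ ≤ … ≤ p₍ₘ₎ (ties broken by SNP id via a stable sort),

FNP̂(j) = max{ 1 − j/ŝ + (m − ŝ)·p₍ⱼ₎/ŝ , 0 },   j = 1..m,

which approximates (missed signals)/(all signals) when keeping the top j:
of the top j, about (m − ŝ)·p₍ⱼ₎ are expected false positives, so
TP ≈ j − (m − ŝ)·p₍ⱼ₎ and FNP ≈ 1 − TP/ŝ. For a control level ε the
cutoff is j\*(ε) = min{ j : FNP̂(j) < ε } — *strict* inequality, ties at
equality do not qualify. Because the true FNP is non-increasing in j, the
first crossing yields the smallest set controlling FNP at ε with high
probability. The default grid ε ∈ {0.02, 0.04, …, 0.40} (K = 20) produces
nested candidate sets; adjacent levels frequently select identical sets,
which are fit once and shared.

Degenerate and edge inputs: ŝ = 0 raises a degenerate-signal error
(screening is meaningless with no estimated signal); if no j crosses below
ε the cutoff falls back to j\* = m (keep everything — the conservative
continuation, reachable only for pathological inputs since FNP̂(m) ≈ 0
whenever p₍ₘ₎ ≈ 1); p = 0 underflow is accepted as the smallest rank; the
curve is clamped below at 0 but may exceed 1 at small j.

## Joint model and candidate selection

For each distinct candidate set, a Lasso regression of the phenotype on the
set's genotype columns is fit on the target training sample. Numerical
choices: columns are standardized to mean 0/variance 1 before fitting and
coefficients mapped back to the dosage scale; the regularization path has
100 points down to 0.01·α_max (the usual n < p convention); penalty chosen
at the CV-error minimum (not the 1-SE rule); K-fold assignment is derived
deterministically from the call's seed, so identical inputs give identical
fits; coordinate-descent tolerance 1e-4 with Gram precomputation.

Candidates are compared by **cross-validated** R² = 1 − CV-MSE/Var(y). The
choice matters: in-sample R² is monotone in set size and would always pick
the largest candidate set, collapsing the screening grid. Ties break toward
the smaller SNP set, then the smaller ε. The default fold count is 10; the
replicate benchmarks in the test suite and examples use 5 folds, which
selects indistinguishable models at half the cost.

Covariates (PCs, sex, age…) enter unpenalized: they are projected out of
the phenotype by OLS before the Lasso stage, and the genetic score is
reported separately from the covariate model — evaluation regresses the
held-out phenotype jointly on score, covariates and intercept. A logistic
(binomial) family is provided for binary traits via L1-penalized logistic
regression with CV over the penalty; its selection criterion is the mean CV
log-loss-based score rather than an R².

## Baselines

*SIS+Lasso*: keep the min(m, n_train − 1) SNPs with smallest base p-values
(ties by id), then the identical Lasso stage. A fixed-size, non-adaptive
analogue of FNC screening. *Lasso*: the Lasso stage on all target SNPs,
ignoring base data. *Clumping+thresholding*: greedy clumping by ascending
p (each surviving index SNP removes SNPs within 250 kb at r² > 0.1),
followed by p-value thresholding over the grid {1e-8, 1e-6, 1e-4, 1e-3,
0.01, 0.05, 0.1, 0.5, 1}; the threshold maximizing training R² of the PRS
wins and weights stay the *base* marginal effects — no re-estimation, per
the classical construction. The clumping defaults are the conventional
ones and fully configurable; SNPs missing from the LD reference are treated
as unlinked with a warning. lassosum and LDpred are substantial published
methods and are not reimplemented; the benchmark harness accepts externally
computed score tables for them.

## Metrics

Predictive R² is the squared Pearson correlation between the held-out
phenotype and the fitted values of the evaluation regression (phenotype ~
score + covariates + intercept); without covariates this reduces to
corr²(score, y) and is invariant to affine transformations of the score.
AIC = 2q + n_test·log(RSS/n_test) with natural log and q the number of
SNPs in the model; RSS comes from the *same* evaluation regression, so both
metrics share one set of residuals. Zero-variance scores (e.g. q = 0)
yield R² = 0 with a warning. Evaluation refuses samples that were seen in
training (sample-id bookkeeping travels with the fitted model).

## Simulation engine

**What it emulates.** Base summary statistics as draws Z ~ N_m(μ⁺, Σ/n₀)
around marginal means, target phenotypes from a sparse linear model
Y = Xβ + N(0, I), and an LD structure Σ. Two signal architectures:

- *Nested*: S ⊆ S⁺, |S⁺| = 50, |S| = round(δ·50); μ⁺ and β drawn
  independently from Uniform(0.05, 0.15) on their supports (all-positive
  effects by design). With standardized genotypes the expected heritability
  is |S|·E[β²]/(|S|·E[β²] + 1), E[β²] = (a² + ab + b²)/3 ≈ 0.0108 —
  about 0.14 / 0.21 / 0.28 for δ = 0.3 / 0.5 / 0.7, which the acceptance
  script verifies empirically.
- *Non-nested*: causal sets S and S⁺_β of equal size 50 overlapping in
  round(δ\*·50) variants; shared effect pairs bivariate normal with scale τ
  and correlation ρ, unshared effects N(0, τ²); LD enters the base mean
  (μ⁺ = Σβ⁺) as well as the covariance. τ defaults to 0.1, fixed by pilot
  calibration (`scripts/calibrate_tau.py`) to a mean realized heritability
  of ≈ 0.33 at the default Σ; the closed form E[V(Xβ)] = |S|·τ² gives the
  same number.

P-values are two-sided normal on z = √n₀·Z (the marginal z-score, since Σ
has unit diagonal). Default dimensions m = 5053, n₀ = 4000, n = 1000.

**Default LD.** Σ is AR(1) with ρ_LD = 0.5 inside disjoint blocks of 20
adjacent SNPs and independent across blocks — a coarse stand-in for LD
blocks between recombination hotspots. Structured Σ is never materialized:
sampling uses the AR(1) innovation recursion and μ⁺ = Σβ⁺ a two-pass
geometric identity, both O(m).

**What it does not emulate**, hence what passing tests do not show about
real data: realistic LD (long-range, variable block sizes, population-
specific patterns), allele-frequency-dependent effect sizes, genotyping
error and missingness beyond the IO layer's imputation path, binary traits
at realistic prevalence, and confounding/population structure. Genotypes
default to Gaussian rows N(0, Σ) (exactly standardized, matching the
heritability arithmetic); a thresholded Gaussian-copula dosage mode with
Hardy–Weinberg margins exists for realism checks.

**Randomness.** Every generator consumes a single integer seed. The
benchmark harness derives per-replicate seeds from the top-level seed via
`numpy.random.SeedSequence.generate_state` (kept below 2³¹), so any
replicate is reproducible in isolation; each replicate re-splits the target
sample 1:1 into training and testing halves.

## Benchmark scales

The replicate benchmark in the test suite runs the nested scheme at
m = 1000, (n₀, n) = (4000, 1000), δ = 0.5 with 50 replicates and 5-fold
CV; the calibration checks run the full m = 5053 with 100 replicates.
These sizes give stable method orderings (FNC+Lasso ≥ SIS+Lasso ≥ Lasso on
mean R², FNC at least as parsimonious as SIS) with tight Monte-Carlo error.

## Known limitations

- ŝ is a lower-bound-style estimator; heavy LD inflates it (harmless
  direction) and very weak signal deflates it, shrinking the screening sets.
- Candidate-selection R² reuses the training sample that also tunes the
  Lasso penalty; a nested CV would remove the slight optimism at extra cost.
- The clumping step is O(m²) in the worst case and intended for panels up
  to a few thousand SNPs per chromosome arm, not whole-genome dense sets.
- The logistic family is functional but not calibrated against any
  reference benchmark; the shipped experiments are continuous-trait only.
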