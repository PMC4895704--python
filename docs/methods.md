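# Methods

`replipower` estimates the statistical power of a GWAS replication study
from the primary study's summary statistics alone, correcting the
selection bias ("winner's curse") that inflates the observed effect
sizes of the SNPs chosen for replication. This note records the models,
the estimators, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Model and notation

Each SNP in a case-control study is summarised by an allele-based 2×2
table (controls/cases × non-effect/effect allele). The observed log
odds ratio is

    μ̂ = log n00 − log n01 − log n10 + log n11,

with Woolf's asymptotic standard error
σ = √(1/n00 + 1/n01 + 1/n10 + 1/n11) and Wald statistic z = μ̂/σ.
Superscripts (1) and (2) denote the primary and replication stage. The
primary test is two-sided at level α₁ (rejection |z⁽¹⁾| > z_{α₁/2},
strict); replication uses the sign-consistent one-sided test
sgn(z⁽¹⁾)·Z⁽²⁾ > z_{α₂}. The power of the replication test at true
effect μ is

    β⁽²⁾(μ) = Φ(sgn(z⁽¹⁾)·μ/σ⁽²⁾ − z_{α₂}),

which equals α₂ at μ = 0 and is strictly increasing in sgn(z⁽¹⁾)·μ. At
the design stage σ⁽²⁾ is unknown; it is projected from primary allele
frequencies,

    σ⁽²⁾ ≈ √( (n₀⁽¹⁾/n₀⁽²⁾)(1/n00 + 1/n01) + (n₁⁽¹⁾/n₁⁽²⁾)(1/n10 + 1/n11) ),

all counts from the primary table. When the two group-size ratios are
equal this reduces to σ⁽¹⁾·√ρ.

## Effect-size prior and Empirical-Bayes power

Genome-wide, effect sizes are modelled by a spike-and-slab prior

    μ ~ π₀ δ₀ + (1 − π₀) N(0, σ₀²),

so the marginal of the Wald statistic is
Z ~ π₀ N(0,1) + (1−π₀) N(0, 1 + (σ₀/σ⁽¹⁾)²). Under the Gaussian
component the posterior of μ given z⁽¹⁾ is conjugate-normal,
N(λμ̂⁽¹⁾, λ(σ⁽¹⁾)²) with shrinkage factor λ = 1/(1 + (σ⁽¹⁾/σ₀)²).

The **Bayesian predictive power** is the posterior expectation of
β⁽²⁾(μ), available in closed form:

    η⁽²⁾ = Φ( (sgn(z⁽¹⁾)·z* − z_{α₂}) / σ* ),
    z* = λμ̂⁽¹⁾/σ⁽²⁾,  σ* = √(1 + λ(σ⁽¹⁾/σ⁽²⁾)²).

It is the Bayes-risk-optimal power estimator under squared error
conditioned on primary significance (verified here numerically, not
re-proved). The package also implements the comparison estimators: the
naive plug-in β⁽²⁾(μ̂⁽¹⁾), the conditional-MLE plug-in (effect size
maximising the likelihood of z⁽¹⁾ conditioned on |Z⁽¹⁾| > z_{α₁/2},
both tails in the denominator) and the EB effect-size plug-in
β⁽²⁾(λμ̂⁽¹⁾).

## Hyperparameter estimation

π₀ uses Storey's p-value census π̂₀(γ) = #{pᵢ > γ}/(m(1−γ)) on the grid
γ = 0, 0.05, …, 0.90, smoothed by a natural cubic smoothing spline
whose penalty is calibrated to 3 effective degrees of freedom on that
grid; the estimate is the smooth carried to γ = 1 by the natural
boundary condition (linear continuation past 0.90), clamped into
[1/m, 1]. Below 100 SNPs the spline is unstable and the fixed-threshold
estimator at γ = 0.5 is used instead, with a warning. On the benchmark
generator (below) this recovers π₀ = 0.9 with mean ≈ 0.904 and
per-dataset standard deviation ≈ 0.027 at m = 10⁴ — the spread is
dominated by the binomial noise of the census near γ = 0.9 and is
irreducible at this m.

σ₀² uses the moment identity
E(Σzᵢ²) = mπ₀ + (1−π₀)(m + σ₀²·Σ1/σᵢ²), inverted and floored at 0.
Two degenerate regimes are honoured exactly: mean z² ≤ 1 (no
over-dispersion beyond the null) gives σ̂₀² = 0, collapsing the
predictive power to α₂; π̂₀ = 1 with mean z² > 1 gives the +∞ sentinel,
under which λ = 1 exactly and shrinkage disappears. π̂₀ from the same
dataset is always plugged in unless the caller overrides it.

## Local true discovery rate and average power

The ltdr is the posterior probability of a genuine association given
z⁽¹⁾ under the two-component marginal. The non-null component density
is properly normalised — φ(z/s)/s with s = √(1 + (σ₀/σ⁽¹⁾)²) — which is
the Bayes-consistent form; an `unnormalized=True` compatibility flag
reproduces the variant without the 1/s factor found in some software.
Computation is in log space so extreme z do not underflow.

The design criterion is the ltdr-weighted average of the per-SNP EB
predictive powers over *all* SNPs identified in the primary study
(false positives included — the ltdr weights are what discount them).
The replication sample size is the smallest case count (controls =
ratio × cases, default ratio 1) whose average power reaches the target
(default 80%), found by integer bisection: the predictive power is
provably increasing in 1/σ⁽²⁾, hence in the group sizes, so bisection
is exact. The returned object carries a power-versus-size curve on a
geometric grid for reporting.

## Credible intervals

The power transform is bounded and nonlinear, so normal-theory
intervals are avoided. Per-SNP intervals are equal-tailed sample
quantiles (linear interpolation) of Monte-Carlo power draws obtained
by sampling μ from its posterior and mapping through β⁽²⁾. Because the
fitted hyperparameters carry error, a pure Monte-Carlo interval
under-covers; the combined method resamples the genome-wide (z, σ)
pairs with replacement N₁ times (study-level, one set of resamples
shared by every SNP in a run), re-fits **both** π₀ and σ₀² per
resample — the resample should reflect total hyperparameter
uncertainty, and re-estimating σ₀² at a fixed π̂₀ would understate it —
draws N₂ power values per resample, and pools all N₁N₂ draws. Defaults
N₁ = N₂ = 100, both exposed. The reported point estimate is the
closed-form estimator under the original (non-resampled) prior.

For the average power, each bootstrap resample re-fits the prior,
recomputes the ltdr weights, and generates N₂ coherent sets of per-SNP
draws (one effect draw per SNP per set); the weighted average of each
set is pooled across resamples. A resample whose weights are all zero
(π̂₀ clamped to 1) is logged and contributes no draws.

Randomness: every top-level sampling routine takes one seed (or
generator); substreams are consumed deterministically in resample
order, so results are bit-reproducible on a fixed platform.

## Synthetic-data generator

The generator emulates a two-stage independent-SNP case-control GWAS:
m = 10⁴ SNPs; effect-allele frequency ~ U(0.05, 0.5); prevalence 1%;
primary 1000 cases / 1000 controls; replication 500/500; α₁ = 5×10⁻⁵,
α₂ = 5×10⁻³; effect sizes from one of three mixtures —
0.9δ₀ + 0.1 N(0, 0.04) (Gaussian benchmark),
0.9δ₀ + 0.1·0.2·t₅ (heavy-tailed), or
0.9δ₀ + 0.07 N(0, 0.04) + 0.03 N(0, 0.16) (two-scale Gaussian). These
defaults are the study conditions of the experiment harness, not
tuning knobs.

Case/control allele frequencies come from a per-allele odds disease
model: the disease odds of an effect-allele copy are e^μ times those of
a non-effect copy, with the baseline risk solved (in closed form — the
prevalence constraint is a quadratic) so that the allele-marginal
prevalence equals the configured value. This makes the expected-table
allele odds ratio equal e^μ *exactly* and preserves
K·f_case + (1−K)·f_control = maf. Allele counts are binomial over 2n
chromosomes per group, independently per stage. A table with a zero
cell receives the Haldane–Anscombe +0.5 correction to all four cells
(on by default, logged); with MAF ≥ 0.05 this is rare.

Not emulated: linkage disequilibrium between SNPs, genotype-level
(Hardy–Weinberg) sampling, population stratification, covariates, and
allele re-polarisation (the simulated MAF belongs to the effect allele;
a negative μ simply means a protective allele). Passing tests therefore
demonstrate the estimators' behaviour under independent SNPs with a
correctly specified (or deliberately misspecified-tail) effect prior —
not robustness to LD or confounding.

"True power" in the experiments is β⁽²⁾(μ) evaluated with the
design-phase σ⁽²⁾ projected from each SNP's primary counts — the
quantity the estimators target — not the realised replication-stage SE.
"Truly non-null" means μ ≠ 0 exactly (spike-component membership).

## Numerical choices

- Normal quantiles/cdfs via scipy's inverse-cdf routines throughout; no
  approximations. Rejection at exactly the critical value is *not*
  significant.
- CMLE: the conditional log-likelihood is optimised on the standardised
  scale t = μ/σ over [−2|z|, 2|z|] via an 801-point coarse scan
  augmented with restarts at {0, z/2, z}, followed by bounded Brent
  refinement over a full coarse step on each side of the best point
  (the objective can be nearly flat near 0 for z just past the
  threshold). Near-ties resolve toward the sign of z, and the estimate
  is clipped to |t̂| ≤ |z| (selection only shrinks).
- Sample-size bisection returns the ceiling integer; per-SNP σ⁽²⁾ is
  recomputed from the frozen primary-count coefficients at every
  candidate size; the search errors out with the achieved power if the
  target is unreachable below `n_max` (default 10⁶), since the
  predictive power is bounded by Φ(√λ·|z⁽¹⁾|) as n → ∞.
- Experiment problem sizes: the bias/RMSE tables use 5 runs of m = 10⁴
  (3 runs for the heavy-tailed variants in the test suite), the
  coverage study 3 runs with N₁ = 50, N₂ = 100 — sizes at which the
  Monte-Carlo error of the reported averages is a few times smaller
  than the effects being demonstrated.

## Known limitations

- Single-run EB quantities inherit the sampling noise of π̂₀ (sd ≈ 0.03
  at m = 10⁴): an occasional census overshoot inflates σ̂₀² and halves
  the shrinkage for that dataset. Averaging over runs, or the bootstrap
  interval, is the intended guard.
- The Gaussian slab is thin-tailed; under the scaled-t generator the EB
  estimators remain best among those implemented but are not optimal
  for the true prior.
- The allele-based test assumes the allele-level 2×2 table is the unit
  of inference; genotype-level association models (dominance,
  covariate-adjusted logistic regression) and quantitative traits are
  out of scope, as are multi-stage and cost-optimal designs.
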