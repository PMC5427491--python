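# Methods

## Model and augmentation

The observed response is a count per (environment *i*, line *j*,
replicate *k*, trait *l*). Conditionally on the random effects the count
is Poisson with log mean

    η_ijk(l) = β_i(l) + b_j(l) + b_ij(l) + c_ijk(l).

The random-effect hierarchy is

* line main effects        b1 ~ N(0, G ⊗ Σt)             (JL-vector, trait innermost)
* line-by-environment      b2 ~ N(0, ΣE ⊗ G ⊗ Σt)        (IJL, env outer / line / trait inner)
* observation-level        c_u ~ iid N(0, Σc)             (one L-vector per unit)

so trait correlation enters twice (Σt for genetic, Σc for residual
sharing) and environment correlation once (ΣE). Marginally over c the
model is Poisson-lognormal, hence overdispersed.

Exact Gibbs sampling relies on a negative-binomial approximation with a
large fixed size r: NB(r, mean μ) → Poisson(μ) as r → ∞. In logit form
the NB pmf is proportional to exp(η\*)^y / (1+exp(η\*))^{y+r} with
η\* = η − log r, which the Pólya-Gamma identity converts into a Gaussian
likelihood in η\* given latents ω ~ PG(y + r, η\*): the working response
is ystar = (y − r)/2 and the augmented log likelihood is
ystarᵀη\* − ½ η\*ᵀ diag(ω) η\*. `nb_poisson_tv` evaluates the closed-form
total-variation distance of the approximation: below 0.01 for all
μ ≤ 10 at the default r = 1000. r is a fixed approximation constant,
never estimated.

Replicates are **summed** per (environment, line, trait) cell before
fitting (a sum of Poissons is Poisson, and the NB approximation only
requires r large relative to the summed mean). No log K offset is used;
the intercepts absorb the replicate scale, so the reported count-scale
intercept is β + log K when all cells have K replicates. After
collapsing, b2 and c are both indexed by cell and are distinguished only
by their priors (Kronecker-correlated vs iid).

## Priors

* β\* ~ N(0, s·I) with s = 1e4 by default. The prior scale is read as a
  *variance* (weakly informative). A `literal_sigma_v` switch instead
  treats it as a precision, for users who want the tight alternative
  reading; nothing else changes.
* Each covariance gets the Huang–Wand hierarchy, e.g.
  Σt | a ~ IW(νt + L − 1, 2νt diag(1/a)), a_l ~ IG(1/2, 1/A²), with
  ν = 2 and A = 1e4 by default: marginal half-t(ν) priors with scale A
  on each standard deviation.

## Full conditionals and update order

All conditionals are conjugate. Location blocks (β\*, b1, b2, c) are
Gaussian with precision ZᵀDZ + P (D = diag(ω), P the prior precision);
covariances are inverse-Wishart with degrees of freedom augmented by the
number of Gaussian vectors they govern (Σt pools both the J vectors of
b1 and the IJ vectors of b2); auxiliaries are inverse-gamma with rate
ν(Σ⁻¹)_ll + 1/A². The sweep order is β\*, b1, b2, c, Σt, a_t, ΣE, a_E,
ω, Σc, a_c.

These derivations are *validated, not trusted*: the test suite checks
(i) that every conditional, evaluated as an unnormalized density, is
proportional to the joint posterior on perturbation grids (differences
constant to 1e-8), with the Gaussian conditionals additionally compared
to a dense generalized-least-squares oracle; and (ii) a Geweke
successive-conditional ("getting it right") comparison between prior
forward simulation and Gibbs-with-data-refresh on an I=2, J=3, L=2
instance, requiring ≥ 90% of 16 monitored functionals to agree at the
0.001 level. The data refresh clips η\* at ±30 purely as an overflow
guard; the event has probability ~1e-6 per sweep and is irrelevant to
decile-based tests.

## Computational structure

When G is diagonal (identity G is the default and the benchmark
setting), the b1 conditional factors into J independent L×L blocks and
the b2 conditional into J independent (I·L)×(I·L) blocks; both are drawn
with batched Cholesky solves. For a general (marker-derived) G, dense
precision-Cholesky sampling over the JL- and IJL-vectors is used. The
GRM caches its inverse and log-determinant.

## Pólya-Gamma sampling at large shape

The sampler needs PG(b, d) with b = y + r ≥ 1000, outside the range of
the classic b = 1 rejection samplers. PG(b, d) is an infinite weighted
sum of Gamma(b) variables with weights 1/(2π²((k−½)² + d²/4π²)). We
draw the first `trunc` (default 40) terms exactly and replace the
remainder with a Gaussian matched to the remainder's *exact* mean and
variance, both available in closed form from the series sums
Σ 1/((k−½)²+h) and Σ 1/((k−½)²+h)². The remainder aggregates thousands
of independent terms each a near-Gaussian Gamma(b), so the approximation
error is far below Monte-Carlo resolution; the first two moments are
exact by construction at any truncation depth. Moment oracles
(`pg_mean`, `pg_var`) and empirical checks at b up to 1e4 guard this.

## Genomic relationship matrix

G = WWᵀ/m_eff with W the column-centered, mean-imputed dosage matrix
after filtering markers at MAF ≥ 0.05 and missing-call rate ≤ 10%.
m_eff = 2Σp(1−p) for 0/1/2 dosages, or the marker count for 0/1
presence/absence coding. A relative jitter (1e-8 of the mean diagonal,
escalating tenfold to at most 1e-4) is added until the matrix
factorizes, since G must be invertible inside the Kronecker precisions.

## Initialization and degenerate inputs

Chains start at β\* = log(mean count per env-trait, floored at 0.5)
− log r, zero random effects, 0.1·I covariances, unit auxiliaries, and
one ω refresh — an overdispersion-safe start. An all-zero trait is
allowed with a logged warning (the model has no zero-inflation
component). Default chain settings are 40,000 iterations, 20,000
burn-in, thinning 5; the experiments below use reduced chains.

## Cross-validation and accuracy

CV1 masks whole (environment, line) cells, all traits jointly, never
leaving a line unobserved in every environment; `floor(fraction ×
n_cells)` cells per partition, 10 partitions by default. An optional
`by_line` mode instead selects a fraction of lines and masks each in a
random nonempty, proper subset of its environments. Masked cells are
dropped from the training design entirely (a leakage test asserts
bit-identical chains when masked counts are perturbed); their b2
coordinates remain in the state vector and are informed only through
the Kronecker prior — this cross-environment borrowing is the mechanism
CV1 measures. Predictions are posterior means of exp(β + b1 + b2) with
the unobserved cell's c fixed at its prior mean 0 (a point prediction;
drawing c would only add rank noise). Accuracy is Spearman's rank
correlation (average ranks on ties) computed per trait-environment
combination within each partition, then averaged over partitions; the
grand average is the mean of the per-combination means. A combination
with fewer than two masked cells in a partition contributes no rank
information and is skipped in the aggregation.

## Simulator and benchmark scenarios

`simulate_dataset` draws from exactly the generative hierarchy above, at
replicate level (c per replicate), and the analysis pipeline then sums
replicates — mirroring how such data are collected and fitted. Scenario
constants: 3 environments, 2 traits, 200 genotypes, 5 replications,
identity G, β = (0.20, 0.25, 0.15, 0.20, 0.30, 0.32) on the
per-replicate Poisson log scale, and scenario-specific Σt/ΣE/Σc with
trait correlation ≈ 0.8 (S1) or ≈ 0.3 (S2).

**What these constants imply.** The scenario covariances put the
genetic log-scale signal at sd ≈ 0.07 against Poisson noise of counts
with mean ≈ 6 after replicate summing. An oracle knowing the true cell
means achieves Spearman ≈ 0.10–0.27 per combination on such data, so
any fitted model's CV1 accuracy under these constants is near zero and
accuracy differences between the multivariate and univariate models are
within Monte-Carlo noise. With covariances large enough to be
identified (e.g. 100-fold larger, trait variances ≈ 0.4 — the order of
magnitude estimated from the real wheat data), the same pipeline
delivers grand-average accuracies of 0.6–0.8 with the multivariate
model at or above the univariate one, and the posterior recovers the
generating Σt and trait correlation (tests/test_recovery.py). Passing
tests at the scenario constants therefore demonstrate calibration and
honesty of the machinery, not high predictive accuracy; under-powered
regimes genuinely have low accuracy. The simulator also does not
emulate marker genotyping, zero inflation, or non-identity relationship
structure beyond accepting a user G.

## Problem sizes used in the shipped experiments

* Sampler validation: grid proportionality on I=2, J=3, L=2 with r=5;
  Geweke with 4000 prior draws vs 9000 sweeps.
* Intercept recovery: one S1 replicate at J=50, chain 4000/2000/5;
  posterior means of β cover the generating values within 3 posterior
  SDs (after removing log K).
* Benchmark accuracy table: one simulated dataset per scenario at full
  J=200, 10 CV1 partitions, single testing fraction per scenario
  (10% for S1, 30% for S2), chains 4000/2000/5.

## Known limitations

* The NB approximation degrades for cell means approaching r; keep r
  large relative to summed counts.
* After replicate collapsing, b2 and c are likelihood-confounded; their
  separation (and hence Σt vs Σc attribution) rests on the prior and
  needs multi-environment replication of lines to be sharp.
* Variance components much smaller than the observation noise floor are
  reported near zero with small posterior SDs (hierarchical shrinkage),
  as the recovery analysis above shows.
* No zero-inflated or hurdle variant; no Metropolis fallback; r is
  never estimated.
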