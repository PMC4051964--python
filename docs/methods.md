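# Methods

This note records the statistical model the package implements, the
choices made where the construction was genuinely open, and what the
simulation harness does and does not demonstrate.

## Imputation model and proper draws

One continuous variable `x` is incomplete; covariates `z` (an intercept
plus the analysis outcome `y`, or any complete numeric columns) are fully
observed. The imputation model is the normal-errors linear regression

    x_h ~ N(α' z_h, σ²)    over the observed cases h,

fitted by OLS through a QR decomposition (no explicit (Z'Z)⁻¹ is formed;
the stored triangular factor suffices for coefficient draws). Rank
deficiency is detected by pivoted QR with a relative diagonal threshold
of 1e−10 and reported with the implicated column indices.

Imputation is *proper*: each of the M imputations starts from a fresh
parameter draw. Two draw schemes are provided.

* **Posterior draws** (default): the standard noninformative-prior
  scheme, σ²\* = RSS/g with g ~ χ²(n_h − p), then
  α\* | σ²\* ~ N(α̂, σ²\*(Z'Z)⁻¹). The literature this implementation
  follows refers to "proper" imputation without printing formulas; this
  is the canonical construction used by mainstream MI software, so it is
  the default.
* **Approximate Bayesian bootstrap**: refit on a with-replacement
  resample of the observed cases. Singular resamples are redrawn at most
  100 times and then the failure is raised; silently falling back to the
  full-sample fit would understate parameter uncertainty.

A degenerate exact fit (RSS = 0) collapses the σ² posterior; the draw
substitutes the smallest positive double so downstream machinery stays
defined, which matters only for pathological exact-linear inputs.

## Matching, donor pools, sampling

The matching distance is δ_hj = α^mis z_j − α^obs z_h with match types
0/1/2 selecting (α̂, α̂), (α\*, α̂), (α\*, α\*). With a single complete
covariate the type-0 and type-2 |δ| rankings coincide (both scales are
affine in y), which the tests verify. Signed δ is retained: the package
reports per recipient whether all pool distances share a sign — the
situation in which PMM is locally biased — as a diagnostic only.

Donor pools: fixed k (the k smallest |δ|), caliper (|δ| < δ_max),
adaptive (caliper, expanded to the 2 nearest when it holds fewer than 2
donors), and proportional (all donors eligible). An empty caliper pool is
an error, never a silent fallback — the adaptive strategy is the
sanctioned fallback. Ties at a pool boundary are broken by a uniformly
random permutation before a stable sort; deterministic tie-breaks would
let the same donors be reused by the same recipients across imputations,
understating between-imputation variance. The default fixed-k/simple
path is vectorised with `argpartition`; rows whose boundary order
statistics tie fall back to the randomised ordering, so the two code
paths are distributionally identical (tested).

Sampling rules: `simple` (uniform over the pool), `constrained` (each
donor gives at most once per imputation; requires n_mis ≤ n_obs and
raises when a pool is exhausted), `slightly_constrained` (weights
multiplied by penalty^donations, default penalty 0.5), and proportional
with weight (|δ| + 1e−8)^(−closeness) over all donors. The proportional
weight function is a documented choice — the source construction is
described only as "proportional to a function of |δ|" — and the
closeness exponent is exposed; ε = 1e−8 guards exact predictive-mean
ties.

LRD imputation types mirror match types: type 0 `α̂z_j + (x_h − α̂z_h)`,
type 1 `α*z_j + (x_h − α̂z_h)`, type 2 `α*z_j + (x_h − α*z_h)`. Only
type 1 centres imputations at the drawn linear predictor as parametric
imputation does, and it is the default.

Defaults follow the recommended practice: match type 1, fixed k = 10
(PMM) / 20 (LRD), simple sampling, type-1 LRD imputation. k = 1 is
permitted but triggers a prominent warning.

## Engine and pooling

One model fit per dataset; one fresh draw and one fresh donor assignment
per imputation. A master seed spawns an independent `SeedSequence`
substream per imputation, so results are invariant to M and to execution
order. Passive columns (currently the square transform, in an extensible
registry) are recomputed in every completed copy.

Rubin's rules: Q̄, W, B, T = W + (1+1/M)B. Reference degrees of freedom
default to the Barnard–Rubin small-sample adjustment
ν = (1/ν_old + 1/ν_obs)⁻¹ with ν_obs = (d+1)/(d+3)·d·(1−λ) capped by the
complete-data residual dof d — at n = 500 and M = 10 this is exactly the
regime the adjustment targets, and it is what mainstream implementations
apply. The classic large-sample ν_old = (M−1)/λ² is available
(`dof_method="classic"`); since ν_BR ≤ ν_old the adjusted intervals are
never shorter, a useful sensitivity check on coverage. Analysis-model
fits use conventional (non-robust) OLS standard errors via statsmodels,
matching the normal-errors analysis models.

## Simulation designs

* **Study 1 (correct specification)**: x ~ N(0,1), y = βx + N(0, 100),
  n = 500, β ∈ {0, 3.33, 10}. β₀ = 0 — the intercept value is
  inconsequential because all metrics target the slope. All normal
  second parameters are variances: with var(x) = 1 and residual variance
  100, β = 10 gives R² = 100/200 = 0.5, which anchors the convention.
  (β = 3.33 implies R² ≈ 0.1; a printed source value of 0.99 for that β
  is arithmetically inconsistent and is not used.)
* **Study 2 (misspecification)**: x ~ N(1,1), y = βx² + N(0, 100); the
  analysis model regresses y on x and x² while the imputation model for
  x | y remains normal-linear — an incompatible pair by construction.
  Scenarios are anchored on β (the values the results discuss), not on
  nominal R² values, which are mutually inconsistent with the stated
  model.
* **Missingness**: MCAR with π = 0.25, or logistic MAR
  logit P(missing) = γ₀ + γ₁y with γ₁ > 0 (large y more likely missing).

### MAR calibration

γ₀, γ₁ are found numerically so that the marginal missingness proportion
is 25% and the AUC of y against the missingness indicator R is 0.65
(weak) or 0.75 (strong). The calibration draws a large Monte Carlo sample
of y (default 10⁶) per (study, β) pair — the y-marginal depends on both —
and runs nested Brent root finds: the inner solve sets γ₀ for the
proportion at each candidate γ₁, the outer drives the AUC to target. The
AUC objective is the *expected* AUC given the per-unit missingness
probabilities (a ratio of expected concordant to comparable pairs,
computed in O(n) after one sort), which is smooth in γ and concentrates
to the realised Mann–Whitney AUC at calibration sample sizes. Achieved
values verify to within ±0.005 on fresh 10⁶-draw samples. Calibrations
from the default (fixed) calibration stream are cached per
(study, β, mechanism, proportion, draws); `simulate` writes the solved γ
next to its output for exact reproducibility.

### Metrics

Per method over R replications: bias (mean estimate − β) with a normal
Monte Carlo interval ±1.96·SD/√R; coverage of the nominal 95% interval
with a binomial normal-approximation interval; empirical SE (SD of
estimates) with a χ² pivot interval — the pivot assumes approximate
normality of the estimator, a documented approximation. A failed method
in a replicate is recorded, not fatal.

### Problem sizes

The full factorial design runs 1,000 replications per scenario. The
package's statistical acceptance tests run the correct-specification
suite at 500 replications per scenario (nine scenarios, six methods:
parametric, PMM/LRD type 1 at the k extremes 1 vs 10/20, plus the
complete-data gold standard), the misspecification sign-pattern check at
300 replications, and the null misspecified-design coverage check at 500
replications — sizes at which the qualitative claims are decided well
beyond their Monte Carlo noise while a full run stays a desk-scale job.
Coverage bands are judged against the binomial Monte Carlo interval of
the estimated rate, so the checks reject genuine miscoverage rather than
replication noise.

## What the generators do and do not emulate

The synthetic designs reproduce the two evaluation settings exactly:
single incomplete continuous covariate, complete outcome, normal errors,
monotone single-variable missingness, and logistic MAR depending on the
outcome only. They do not emulate multivariable missingness patterns,
chained-equations cycling, non-normal or heteroscedastic errors beyond
the quadratic mean structure, categorical covariates, or survival
outcomes. Passing the suite therefore shows the machinery is correct and
reproduces the known behaviour of these methods in these settings — not
that PMM/LRD are safe in arbitrary real data; the misspecification suite
itself demonstrates settings where all the imputation methods fail.

## Known limitations

* One incomplete variable per dataset; no chained equations.
* Imputation model is linear-normal only (no GLMs); priors other than
  the standard noninformative one are out of scope.
* Pooling is per-coefficient; no multi-parameter Wald combination.
* Donor matching is on the predictive mean only — no Mahalanobis or
  covariate-space matching.
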