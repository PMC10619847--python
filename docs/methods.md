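# Methods

## Model

Point-referenced observations follow the spatial linear model
`y = Xβ + ε`, `var(ε) = V(θ)`, with V built entrywise from a stationary,
isotropic covariance function of Euclidean distance. Two families are built
in — exponential `τ² exp(−d/ρ)` and spherical
`τ² (1 − 3d/(2ρ) + d³/(2ρ³)) 1{d<ρ}` — plus a callable contract
`f(distance, (τ², η², ρ), on_diagonal)` for any other valid construction.
The parameters are the partial sill τ² > 0 (spatially structured variance),
nugget η² ≥ 0 (micro-scale/measurement variance) and range ρ > 0 (distance
scale of correlation decay); the stationary variance is σ² = τ² + η².

**Nugget placement.** The nugget is added only on the true diagonal of a
same-point-set covariance matrix, i.e. it is treated as measurement error
attached to individual observations. Cross-covariances — between distinct
observations at duplicated coordinates, or between data and prediction
sites — never include it. A literal reading that adds η² whenever d = 0
would make duplicated coordinates produce a singular V; the convention here
keeps V nonsingular and is the standard kriging treatment of measurement
error. Consequently prediction at an observed site interpolates exactly
only when η² = 0.

Coordinates are planar and unitless; no projection handling is attempted
(the simulations live on the unit square).

## Blocked REML

Observations are indexed into P blocks — randomly, by k-means on the
coordinates ("compact"), or compact with a fraction reassigned at random
("mixed") — with P = ⌈n / target size⌉. Covariance parameters minimise the
REML criterion evaluated under the block-diagonal part of V (additive
constant dropped):

```
L(θ) = Σᵢ log|Vᵢᵢ| + r' V_part⁻¹ r + log|Σᵢ Xᵢ'Vᵢᵢ⁻¹Xᵢ|,
r = y − X β̂_θ,   β̂_θ = blocked GLS at θ.
```

Only block-sized factorizations are needed, so cost grows linearly in n at
fixed block size. The pooled log-determinant term distinguishes this from
composite likelihood (which sums per-block log-determinants and fails when
a block's design matrix has an all-zero column, e.g. a rare categorical
level).

Numerical choices:

- **Optimizer**: derivative-free Nelder–Mead on (log τ², log η², log ρ), so
  every trial point is in the valid domain. Initial values: half the OLS
  residual variance for τ² and η², 10% of the maximum pairwise distance for
  ρ (computed from the convex hull when n is large). Termination:
  `xatol = 2e-3`, `fatol = 5e-3`, at most 400 evaluations, plus a plateau
  rule — stop once the best value has not improved by a relative 1e-6 over
  40 iterations. The plateau rule exists because a fitted nugget (or range)
  that runs to its boundary leaves a flat direction in which the simplex
  otherwise spends ~40% of its evaluations after the optimum is found to
  six figures.
- **Non-PD parameters** return a penalty `1e10 + Σ|log θ|` instead of
  raising, so the simplex can back out of degenerate corners.
- Log-parameters are clipped at ±40 to avoid overflow.
- All block work runs batched on (P, s, s) arrays padded to the largest
  block size; pad positions carry a unit diagonal, zero covariates and zero
  response, which is equivalent to appending independent phantom
  observations and changes no blocked quantity. Padding costs at most
  (s_max/s̄)³ in flops, small for k-means blocks.

## Fixed effects and their covariance

The pooled estimator is `β̂_bd = T_xx⁻¹ t_xy` with
`T_xx = Σ Xᵢ'V̂ᵢᵢ⁻¹Xᵢ`, `t_xy = Σ Xᵢ'V̂ᵢᵢ⁻¹yᵢ`; it equals dense GLS when
P = 1 and ordinary least squares when V is (a multiple of) the identity.
Writing `β̂_bd = Q y` makes it linear in y, so its covariance can be
computed exactly under the full V:

```
var(β̂_bd) = T_xx⁻¹ + T_xx⁻¹ W_xx T_xx⁻¹,
W_xx = Σ_{i<j} [ Xᵢ'Vᵢᵢ⁻¹ Vᵢⱼ Vⱼⱼ⁻¹ Xⱼ + (·)' ].
```

The identity `var(Q y) = Q V Q'` is the module's central correctness oracle
and is asserted in the tests. Each cross-block Vᵢⱼ is built on the fly (in
chunks of 256 pairs, a cache-friendly size) and discarded; the pair loop is
quadratic in P but only an R×R accumulator is kept. Two cheaper estimators
are provided: the empirical covariance of per-block GLS estimates
(`Σ (β̂ᵢ − β̂_bd)(·)' / (P(P−1))`, requires P ≥ 2, drops rank-deficient
blocks with a logged warning) and the pooled per-block information inverses
(`Σ (Xᵢ'V̂ᵢᵢ⁻¹Xᵢ)⁻¹ / P²`). Wald tables use the standard normal reference
with no degrees-of-freedom correction; a zero standard error reports a
missing p-value.

The fixed-effects partition may differ from the REML partition; when it
does, the exact-variance C is the one from the fixed-effects fit, and that
C is what prediction consumes.

## Nearest-neighbor point prediction

For site s_j with the m nearest observations (exact Euclidean k-NN,
ties broken by lowest observation index for reproducibility, neighborhoods
recomputed independently per site):

```
Ŷ(s_j) = x_j'β̂_bd + ĉ_j'V̂_j⁻¹(y_j − X_j β̂_bd)
var    = σ̂² − ĉ_j'V̂_j⁻¹ĉ_j + d_j' Ĉ d_j,   d_j = x_j − X_j'V̂_j⁻¹ĉ_j
```

with Ĉ any estimate of var(β̂_bd). The predictor is linear in the data,
`Ŷ(s_j) = λ_j'y`, with weights supported on the neighborhood plus the
pooled-estimator term, and satisfies the unbiasedness identity
`λ_j'X = x_j'`. With m = n and P = 1 it reduces exactly to dense universal
kriging. σ̂² defaults to τ̂² + η̂² — the interval targets a new noisy
observation, which is what the simulation studies compare against (their
realized values include the nugget); `target="surface"` predicts the
noise-free surface (σ̂² = τ̂², ĉ unchanged).

A purely local-β variant re-estimates β by GLS inside every neighborhood
(implicitly a varying-coefficient model). Local design columns that are
identically zero are collapsed before solving; designs still rank-deficient
after collapse raise an error naming the columns. In the studies the
global-β predictor has the lower prediction error, especially at small m.

## Block prediction

The regional average is approximated by the uniform average of point
predictions on a dense in-region grid (cell centres, row-major; the
40×40 grid of the studies has 1600 points with weights 1/1600). Averaging
the weight vectors gives a single `a*` with the block prediction `a*'y_o`
and exact variance

```
a*'V_oo a* − 2 a*'V_ou a + a'V_uu a,
```

accumulated one row-chunk at a time so peak extra storage is a chunk of
covariance rows plus scalar accumulators. When n exceeds a configurable
cap (default 5000) the observed-data quadratic form may be estimated from
a seeded simple random sample with Horvitz–Thompson inclusion weights
(diagonal and off-diagonal parts weighted separately); the experiment
harness uses the exact computation at its problem sizes. For a one-point
grid this variance agrees with the point-prediction variance to ~0.3% but
not exactly: the exact linear-form variance retains cross-covariances
between β̂_bd and the local data that the plug-in point formula drops.

## Simulators

Both generators place n observed sites uniformly on the unit square and
append the prediction grid, and both return covariates and response at
every site so prediction error and interval coverage are evaluated against
a correlated realized truth.

- **GEOSTAT**: ε = Lz at all observed + grid sites jointly, with LL' the
  Cholesky factor of a spherical-model covariance (defaults: sill 10,
  nugget 0.1). One factorization serves both ε and the spatially patterned
  covariate (independent z draws). Cubic cost; guarded at 6000 total sites.
- **SUMSINE**: the sum of 100 randomly rotated 2-D sine components with
  linearly decreasing expected amplitude and increasing frequency
  (component i has amplitude `u₂(1 − (i−1)/100)`, frequencies `i u 2π`,
  coordinate shifts `u π`; all underlying uniforms are U(0,1), which the
  source description leaves open). Each realization is standardized to
  mean 0, variance 10, then independent N(0, 0.1) noise is added per site
  in the role of a nugget. Linear cost; 100,000 sites take ~2 s.

The response is `y = 1 + x₁ + x₂ + ε` with x₁ i.i.d. standard normal and
x₂ an independent realization of the same surface generator (including its
micro-noise). With `standardize=True`, ε and x₂ are rescaled to unit
variance before the fixed effects are added — used by the fixed-scale
benchmark design. Standardization of x₂ alongside ε is this package's
choice; it affects only scale-sensitive coefficient-RMSE summaries.

What the simulators do *not* emulate about real data: irregular or
clustered sampling designs, anisotropy, nonstationary variance, non-Gaussian
or heavy-tailed errors, and covariates measured with error. Passing tests
therefore demonstrate correctness of the estimators and honesty of the
intervals under stationary, correctly-located covariates — not robustness
to those features.

## The experiment harness and study scales

`run_experiment` draws replicate datasets (a fair coin between GEOSTAT with
n ~ U{1000..2000}, range ~ U(0, 2), and SUMSINE with n ~ U{2000..10000},
for the wide-ranging "mixed" design), always fits an exponential model — a
deliberate misspecification for both generators — and applies one or more
analysis designs to the same data (common random numbers; REML fits are
shared between designs requesting the same partition). Summaries follow
the standard Monte-Carlo definitions: RMSE/RMSPE as root mean squared
(prediction) error over replicates (and grid sites), CI90/PI90 as coverage
of intervals formed with the 1.645 normal quantile.

Problem sizes used by the shipped studies (`tests/test_acceptance.py`,
`scripts/acceptance.py`): 56–100 replicates per design rather than 1000,
and the large-n SUMSINE variance-estimator study draws n from
[6000, 12000]. These sizes keep the full recomputation within minutes on a
single CPU; Monte-Carlo standard errors on coverage proportions are then
~0.03, which the ±0.05 assertion bands accommodate. Coverage of the
spatially patterned coefficient's CI at partition size 50 increases with n
over this range (≈0.86 for n in [4k, 10k], ≈0.93 for n in [8k, 14k]), so
results at the reduced scale bracket the large-n behavior.

## Known limitations

- The exact fixed-effects variance is quadratic in the number of blocks;
  beyond ~10⁵ observations the empirical or pooled estimators are the
  practical choice (both are linear), at the cost of coverage that is
  reliable mainly near block size 50.
- Only the nugget enters as a random effect; no additional variance
  components, anisotropy, or non-Euclidean (e.g. stream-network) distance
  metrics, although any user-supplied covariance callable that encodes such
  structure will be used verbatim by every estimator and predictor.
- Blocked REML discards cross-block information about θ; with very small
  blocks (≤25) the downstream intervals can under- or over-cover, which is
  why the default target block size is 50.
- The local-β predictor ignores the uncertainty of θ̂ and of its per-site
  β̂_j beyond the plug-in GLS variance, as is conventional.
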