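# Methods

`postsel` implements and evaluates confidence intervals for linear-model
coefficients *after* variable selection by the Lasso or adaptive Lasso.
This note records the statistical model, the estimators, the numerical
choices, and what the simulation harness does and does not demonstrate.

## The inference problem and its target

Data are `y = X beta + eps`, `eps ~ N(0, sigma^2 I)`, with a standardized
design (`p` candidate predictors, columns mean 0 / SD 1, outcome
centered).  A selection procedure returns an active set `M`; the object of
inference is the **submodel target**

    beta_M = Sigma_MM^{-1} Sigma_{M,F} beta,

the population coefficients of the best linear approximation to
`E[y | X]` using only the variables in `M` (`Sigma` is the population
covariance/correlation of the predictors, `F` the full index set).  This
is *not* `beta` restricted to `M` unless the predictors are uncorrelated;
it is the parameter a practitioner implicitly estimates when they refit
OLS on the selected variables.  Because `M` is data-dependent, classical
coverage statements do not apply; the three constructions below restore
them in different senses.

## Selection stage

* **Lasso**: minimize `(1/2n)||y - Xb||^2 + lambda ||b||_1`.  Final fits
  use scikit-learn's coordinate descent with a tight tolerance (exact
  zeros; KKT conditions checked in the test suite to 1e-7).
* **Adaptive Lasso**: penalty weights `w_j = 1/|b_hat_j,full|^gamma` with
  `gamma = 1` by default (exposed as a parameter), where `b_hat_full` is
  the unpenalized full-model OLS fit (hence `n > p` required).
  Implemented by rescaling column `j` by `1/w_j`, running the plain
  Lasso, and back-transforming; the equivalence to direct minimization of
  the weighted objective is verified against an independent
  coordinate-descent oracle.  A full-model coefficient of exactly zero
  would give an infinite weight; the variable is then excluded a priori
  with a warning.
* **Tuning**: a log-spaced path of 100 penalties from `lambda_max =
  max_j |x_j'y|/n` down to `1e-3 lambda_max`.  Tenfold cross-validation
  picks the minimum mean squared prediction error (minimum rule, not
  1-SE); AIC/BIC use the Gaussian log-likelihood with the active-set size
  as degrees of freedom.  Ties in a discrete criterion break towards the
  smallest (densest) penalty, which is deterministic.  The
  outcome-independent alternative is the universal-threshold penalty
  `lambda = c sigma_hat sqrt(2 log(p)/n)` with `c = 2` and `sigma_hat`
  from the full model; the constant is a package default and
  configurable, since only the form of the rule is standard.
* Tuning criteria are scanned with an in-package numba coordinate-descent
  path on the Gram matrix (`X'X/n`, `X'y/n`), which for the small `p`
  targeted here is orders of magnitude faster than generic solvers; the
  selected penalty is then refitted with the reference solver.

## Inference stage

**Variance estimate.**  SI and PoSI use
`sigma2_hat = RSS_full / (n - p - 1)` from the unpenalized full model
(the `-1` accounts for the centered-out intercept).

**Sample splitting.**  Rows are split 50/50 at random (half A gets the
extra row when `n` is odd); the selector runs on half A and classical
t-intervals are computed on half B for the selected set, with half-B
residual variance and `df = n_B - |M| - 1`.  Selection and inference data
are independent, so coverage of `beta_M` is exact.  Variables not
estimable on half B are dropped with a flag rather than failing the
iteration.

**Exact post-selection inference (SI).**  At a *fixed* penalty, the event
that the Lasso selects `(M, s)` (active set and signs — the sharper,
computationally simple conditioning) is a polyhedron `{A y <= b}` built
from the active-sign and inactive-subgradient KKT conditions.  For a
contrast `eta` (here the OLS contrast of one selected coefficient),
holding the component of `y` orthogonal to `eta` fixed reduces the event
to `eta'y ∈ [V-, V+]`; the conditional law of `eta'y` is then
`N(eta'beta_M, sigma^2 ||eta||^2)` truncated to that interval, and
confidence limits invert this pivot.  In practice the penalty is *tuned*
and then treated as fixed — exactly the usage evaluated here, and the
source of the modest undercoverage the simulations quantify.  For the
adaptive Lasso the polyhedron is built on the weight-rescaled design
(weights treated as fixed, although they depend on `y` — a second reason
for its larger undercoverage), while the contrast and point estimate use
the original design.

*Numerics*: the truncated-Gaussian CDF is evaluated through log-CDFs (or
log survival functions via symmetry) so far-tail truncations retain
relative precision; a truncation mass below 1e-12 is treated as
degenerate at the boundary nearest the mean.  Limits are found by
bisection over a bracket of ±20 interval-SDs around the observed
contrast (tolerance 1e-8, at most 200 iterations); when the pivot cannot
reach the required quantile inside the bracket the limit is reported as
infinite and flagged.  At `lambda = 0` the Lasso selects everything for
almost every outcome, so the selection event is unrestricted and SI
reduces exactly to the plug-in Wald interval (verified to 1e-6).

**PoSI.**  Simultaneous intervals `b_hat_{j,M} ± K se(b_hat_{j,M})` whose
multiplier `K` bounds `max_{M, j∈M} |t_{j,M}|` over *all* nonempty
submodels at the requested level, hence validity for any selection rule
(family-wise error control).  `K` is approximated by Monte Carlo
(default 5000 draws) after projecting onto the `p`-dimensional column
space of `X`; all `2^p - 1` submodels are enumerated for `p <= 12`, a
random subsample of models (with a warning) beyond that.  Because the
plugged-in variance is itself estimated on `n - p - 1` degrees of
freedom, the default reference divides each Monte-Carlo maximum by an
independent `sqrt(chi2_df/df)` — the simultaneous-t construction; with
few residual degrees of freedom the pure Gaussian reference (available
via `df=None`) measurably undercovers, which the package's own null-model
simulations exposed.

**Stability flag.**  An interval set is "unstable" when any limit is
non-finite or any interval fails to contain its point estimate.  An
optional width-ratio alarm (width > 100x the plug-in Wald width) exists
but is off by default.

## Synthetic data generator

A latent Gaussian `Z ~ N(0, Sigma_corr)` with a blocked equicorrelation
structure is transformed column-wise (identity, affine, exponential,
threshold) and standardized per dataset (mean 0, SD 1, divisor `n-1`).
The noise SD solves `sigma^2 = beta' Sigma beta (1 - R^2)/R^2` so the
*population* R² of the linear predictor equals the target; `Sigma` is the
population correlation of the transformed predictors (analytic for
identity transforms, otherwise estimated once on a 10^6-row calibration
sample with a fixed internal seed and cached), making the target R² a
scenario property independent of `n` and of the realized design.  A
validation outcome reuses the same `X` with an independent error draw.
For an all-zero coefficient vector there is no signal to calibrate
against; those scenarios use `sigma = 1`.

Two default scenario families:

* **Toy grid** (4 Gaussian predictors): 7 correlation structures
  (independence; pairs/triples/all four at rho 0.8; a pair and all four at
  rho 0.4) × 10 coefficient patterns (null, single strong in and outside
  a block, strong pairs, strong+weak mixtures, dense weak, dense strong)
  × target R² {0.2, 0.5, 0.8} × observations-per-variable {5, 10, 50} =
  630 scenarios.  The counts and the "no or strong correlation" contrast
  are fixed; the individual patterns are package defaults, documented
  here, chosen to span the qualitative cases (signals inside vs outside
  correlated blocks, sparse vs dense, strong vs weak).
* **Realistic-like grid** (17 mixed predictors): a fixed blocked
  correlation (a 9-variable block at 0.65 mimicking anthropometric
  measurements, a 4-variable block at 0.30, weak cross-block correlation
  0.05), 9 affine + 4 log-normal + 4 binary margins, 13 coefficient
  patterns × 3 R² × 3 n/p = 117 scenarios.

What the generator does **not** emulate: non-linear effects,
heteroscedastic or non-Gaussian noise, missing data, and outcome-dependent
sampling.  Passing tests therefore demonstrate the frequentist properties
of the interval constructions under a correctly specified sparse linear
model with controlled correlation — not robustness to real-data
violations of it.

## Simulation harness and performance measures

Per iteration: draw one dataset, run every roster method (Table of
methods: Full, Oracle, and {Lasso, ALasso} × {CV, Neg} × {Split, SI,
PoSI} combinations), compute the submodel target for the model each
method actually selected, and record intervals, flags, the tuned penalty
and validation R².  A failing method is caught and recorded as a missing
entry; it never aborts the iteration.  All randomness derives from
`SeedSequence([master_seed, scenario_index, iteration_index, stream])`
with named substreams (data, each selector's CV folds, the split
permutation, the PoSI Monte Carlo), so results are bit-reproducible and
invariant to the worker count.

Measures marginalize over selected models and variables, pair-weighted
(each selected (variable, iteration) pair counts once): selective
coverage (CI contains `beta_{j,M}`), selective power (0 excluded when the
target is nonzero), selective type-1 error (0 excluded when the target is
zero, with |target| < 1e-12 as the zero test — block-structured defaults
give exactly-zero targets up to floating point).  For methods without
data-driven selection these reduce to the classical definitions.  Width
median/IQR pool finite widths on the standardized scale; infinite-width
intervals are excluded there but counted in the unstable rate, whose
denominator is iterations with nonempty selection.  Iterations with empty
selection contribute to selection metrics and validation R² only.
Scenario summaries carry the binomial 95% Monte-Carlo band
`1.96 sqrt(l(1-l)/n_iter)`; because pairs within an iteration are
correlated, this iteration-count band — not a pair-count one — is the
yardstick used when comparing coverage to nominal.

**Problem sizes.**  The full study design is 630 (toy) + 117
(realistic-like) scenarios at 900 iterations.  The package's desk-scale
profile — used by its own acceptance checks — is a systematic 1-in-10
subsample of the toy grid (63 scenarios, spread over all correlation and
coefficient structures) at 250 iterations for the reported summaries and
150 iterations inside the test suite, plus a single-scenario
2000-iteration benchmark for classical Wald coverage.  Medians over
scenarios are stable at this scale; individual scenario rates carry
Monte-Carlo error of a few points.

## Design choices where the design was open

* SI conditions on the (active set, signs) pair, not the union over
  signs: sharper, computationally finite, and the default of the
  reference software for this method.
* The CV rule is "minimum", not "1-SE".
* Validation predictions use each method's own final coefficients:
  penalized coefficients for the path methods, OLS for Full/Oracle,
  half-B OLS (applied to all rows, with its intercept) for Split.
* Subsampling selection frequencies in the real-data workflow use 100
  resamples of size `ceil(0.632 n)` without replacement (fraction
  configurable); 0.632 matches common stability-analysis practice.
* The real-data original-scale back-transform divides standardized
  estimates and limits by the covariate SD; the intercept is reported
  separately.

## Known limitations

* SI validity is exact only for a truly fixed penalty; tuned-then-fixed
  usage (the realistic scenario evaluated here) undercovers by design,
  and the package quantifies rather than corrects this.  Tuning-aware SI
  and data carving are out of scope.
* The adaptive Lasso's weights are treated as fixed in its SI polyhedron;
  the resulting intervals are the ones practitioners obtain from standard
  software, not a corrected construction.
* PoSI cost grows as `2^p`; beyond `p = 12` the constant is approximated
  on a model subsample and intervals become approximate.
* Logistic regression, elastic net, group/relaxed Lasso, de-biased Lasso,
  knockoffs and stability selection are out of scope.
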