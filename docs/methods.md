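# Methods

`dose` treats the benchmarking of penalized regression methods as a
designed computer experiment: instead of varying one simulation
parameter at a time over a handful of grid points, it draws the whole
simulation-parameter space with a space-filling design, runs one
stochastic simulation per design point, and then analyzes the
performance results with the design parameters as covariates.  This
note records the model, the defaults, and the design choices that were
genuinely open.

## The experimental design

Five parameters define a simulation scenario:

| parameter | meaning | default range |
|---|---|---|
| `n` | samples per training/testing half | 100 – 1000 (integer) |
| `p` | number of features | 1001 – 40000 (integer) |
| `psi` | saturation: probability a feature enters the true model | (0, 1) |
| `delta` | signal-to-noise ratio: mean nonzero effect / residual variance | 0.1 – 10 |
| `rho` | within-block Toeplitz correlation of features | 0 – 0.95 |

The ranges target the "large p, small n" regime of genomic prediction:
`p > n` in every scenario (the constraint `max(n) <= min(p) - 1` is
enforced), `p` tops out near the probe counts of expression arrays, and
`n` spans the sample sizes typical of omics studies.

Scenarios are placed by a maximin Latin hypercube: `n_candidates`
(default 20) random Latin hypercubes on the unit 5-cube are scored by
`mindist` (minimal nearest-neighbour distance, larger = more regular)
and `coverage` (relative dispersion of nearest-neighbour distances,
`sqrt(mean((g_i - g_bar)^2))/g_bar`, zero for a regular mesh), and the
candidate with the largest `mindist` wins (ties: smaller coverage, then
lower index).  Rather than exchange-type optimization of a single
design, generating many candidates and picking the best matches how
such designs are produced by the standard R tooling (`lhs` +
`DiceDesign`) and scales to 10,000-point designs in seconds.
Nearest-neighbour distances are computed exactly with a k-d tree.

Unit-cube coordinates map to parameter values linearly,
`t = L + u (U - L)`, with half-up rounding for the discrete `n` and
`p`.  The signal-to-noise coordinate uses a piecewise-linear map —
`u < 0.5` onto [0.1, 1], `u >= 0.5` onto [1, 10], continuous at
`u = 0.5 -> delta = 1` — so that half of the design mass lies in the
noise-dominated regime and half in the signal-dominated one; a plain
linear map would spend 90% of scenarios on `delta > 1`.

Per-scenario seeds are `master_seed + scenario_id`, recorded in the
scenario table, so any single scenario can be regenerated in isolation.

## The data-generating process

For a scenario `(n, p, psi, delta, rho)` with seed `s`:

1. **Features.** The p features are partitioned into blocks with sizes
   drawn uniformly on {20, ..., 300} (a final remainder below 20 is
   absorbed into the last block, so one block may reach 319 — the
   simplest rule that never violates the minimum block size).  Each
   block is i.i.d. multivariate normal across rows with covariance
   `rho^|i-j|` (unit variances); blocks are independent.  Blocked
   Toeplitz structures mimic the grouped correlation of real omics
   matrices and keep the Cholesky factorizations cheap.  2n rows are
   drawn.
2. **True model.** Inclusion indicators `gamma_j ~ Bernoulli(psi)`
   i.i.d.; raw effects `b_j` standard normal (configurable to
   uniform(-1, 1); the published description of this distribution is
   not recoverable from our source, and the rescaling below makes the
   choice immaterial for the signal-to-noise ratio).  Coefficients are
   `beta_j = c * b_j * gamma_j` with `c` chosen so that
   `mean(|beta_j| : gamma_j = 1) / sigma^2 = delta` **exactly** (not in
   expectation).  An empty support (`sum gamma = 0`) is retained as a
   legitimate pure-noise scenario, flagged, never redrawn.
3. **Response.** `y = X beta + eps`, `eps ~ N(0, 1)` (`sigma^2 = 1`).

The first n rows become the training set, the last n the testing set.
Each half is standardized independently — columns and response to mean
0 and standard deviation 1 with the `n - 1` denominator.  Independent
(rather than train-statistics) standardization is what makes the
intercept-only benchmark exact: the zero predictor's test MSE is
exactly `(n-1)/n`, i.e. "close to 1".  Zero-variance columns are
standardized to all zeros with a warning.

What the generator does **not** emulate: non-Gaussian noise,
heteroscedasticity, outliers, batch effects, or measurement error —
passing benchmarks here say nothing about robustness to those.  The
contract with the original study is statistical, not bitwise: no
attempt is made to reproduce another RNG's stream.

## Model fitting

All three methods minimize

    (1/(2n)) ||y - X beta||^2 + lam [ (1-alpha)/2 ||beta||^2 + alpha ||beta||_1 ]

with no intercept (the data are centered).  `alpha` is the elastic-net
mixing: 0 = ridge, 1 = lasso.  Tuning:

* **lambda path** (lasso/elastic net): 100 log-spaced values from
  `lam_max = max_j |x_j' y| / (n alpha)` (the smallest penalty with an
  all-zero solution) down to `0.01 lam_max` — the p > n convention of
  coordinate-descent elastic-net software, on whose objective scale the
  mixing grid is meaningful.
* **mixing grid** (elastic net): 0.001, 0.01, 0.10, 0.15, ..., 0.95
  (20 values).
* **ridge path**: 100 log-spaced values from `1e3 * max_j |x_j' y| / n`
  down to 1e-4 of that — a data-driven bracket spanning
  effectively-null to effectively-unpenalized fits (in the p > n
  regime the held-out error is flat well before the lower end).  The published
  construction of this grid is not recoverable from our source; the
  bracket is this package's own stand-in and is configurable.
* **selection**: 10-fold cross-validation on the training half, pooled
  held-out squared error, minimum-MSE rule (no one-standard-error
  rule).  The fold assignment is seeded and **shared across the three
  methods** within a scenario, so method contrasts are free of fold
  noise.  The chosen pair is refit on the whole training half and
  scored on the testing half by `(1/n) sum (y_i - x_i' beta)^2`.

### The path solver

Ridge is solved in closed form through whichever Gram matrix is
smaller (`p x p` or `n x n`); the CV path uses the eigendecomposition
of `X X'` so all 100 penalties cost one decomposition per fold.

Lasso and elastic net use an in-package pathwise coordinate-descent
engine (`dose._cd`) built for the p >> n, many-folds workload:
warm starts along the decreasing path, sequential strong-rule screening
(`|x_j' r| >= m alpha (2 lam_k - lam_{k-1})`), active-set inner loops,
and full KKT verification of every solution over all p coordinates.
The verification reuses the gradient `X' r` that screening needs
anyway, computed for all 10 folds at once as a single BLAS product per
path step; a fold with screening violations is repaired and re-verified
on the next step.  Numerics: convergence when the largest single-
coordinate objective decrease falls below `tol * m` (default
`tol = 1e-7` on unit-variance responses, the usual coordinate-descent
threshold); cross-validation runs in float32 (its ~1e-6 relative error
is orders of magnitude below fold noise) while final refits run in
float64.  The test suite verifies the solver against scikit-learn's
coordinate descent on small instances (1e-5 in coefficients) and
against the ridge normal equations (1e-8), so the objective convention
is checked, not assumed.

## Analysis of the results

Responses: per-method test MSE for absolute performance, and pairwise
differences oriented so positive values mean the first-named method
won (e.g. `ridge_vs_lasso = mse_lasso - mse_ridge`).  The response
distributions are far from Gaussian and the parameter effects
non-linear, so the analysis is non-parametric throughout:

* each parameter's design range is cut into `G` equal-width bins
  (default 10; 5 and 15 supported for robustness reruns; the value
  equal to the upper bound joins the last bin);
* **main effects**: DISCO (distance components) — the F-like ratio
  `(S_B/(K-1)) / (W/(N-K))` of between- to within-group mean powered
  distances `|x - y|^a`.  At exponent `a = 2` the statistic reduces
  exactly to the one-way ANOVA F (verified against scipy to 1e-10);
  at the default `a = 1` (the energy-statistics convention — the
  published exponent is not recoverable from our source) it also
  detects dispersion differences;
* **interactions**: the two-way ANOVA interaction F computed as a
  full-model (one mean per occupied cell) versus additive-model
  least-squares comparison, with `df_int = cells - levels_A -
  levels_B + 1` and `df_resid = N - cells`.  The model-comparison form
  is used deliberately: Latin-hypercube bins are only near-balanced,
  so balanced-design sums-of-squares formulas do not apply.  Both
  factors use `G x G` bins by default (interaction *plots* use 10
  x-bins and 3 curve-bins);
* **p-values**: label permutation, `p = (1 + #{T*_b >= T_obs})/(B+1)`,
  default `B = 999` (floor 0.001).  Raw responses are permuted (not
  residuals): under the null of no parameter effect the observations
  are exchangeable by construction of the design.  Degenerate
  statistics (zero within-group dispersion or zero within-cell
  residual) return `inf` with a warning and participate in the
  permutation comparison by IEEE semantics — never silently dropped.

## Orchestration and problem sizes

A study is a `StudyConfig` (ranges, counts, master seed); runs are
deterministic given the seed, append per-scenario results to CSV as
they finish, and resume by scenario id after interruption.  Failures
are logged and left as missing rows, never imputed.

Two presets ship with the package.  `paper-full` (10,000 scenarios,
full ranges) is the scale of the original cluster-computed study and
is not exercised by the tests.  `desk-small` — 100 scenarios, `n` in
[100, 500], `p` in [1001, 5000], all other ranges full — is the
package's scaled-down reproduction: small enough for a single CPU
(roughly 10–15 minutes), large enough that the headline win
proportions are stable to a few percentage points.  The design-only
saturation check runs at the full 10,000-scenario scale in seconds,
since it needs one binomial draw per scenario and no fitting.

## Known limitations

* The elastic-net and lasso penalty paths stop at `0.01 lam_max` (the
  p > n convention), while the ridge bracket reaches much weaker
  effective penalties.  In saturated scenarios, where the elastic
  net's cross-validated optimum sits at its path floor for every
  mixing value, this asymmetry decides many of the near-tied
  ridge-versus-elastic-net comparisons in ridge's favour.  How the
  ridge grid is bracketed therefore matters for that one contrast;
  the bracket is configurable (`RIDGE_UPPER_FACTOR`, `RIDGE_SPAN`).

* The one-way DISCO implementation does not provide factorial
  decompositions; interactions are covered by the permutation F-tests.
* Win proportions from 100 scenarios carry binomial noise of ~3–5
  percentage points; the desk-scale checks use tolerances accordingly.
* No multiple-testing adjustment is applied across the 15 tests per
  contrast; tables report raw permutation p-values.
* Alternative scoring metrics (concordance, Pearson, MAE) and
  categorical-parameter designs (factorials) are out of scope.
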