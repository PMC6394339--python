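# Methods

## The model and its assumptions

glvkit models a community of `n` taxa with the generalized
Lotka-Volterra (gLV) equations

    dx_i/dt = x_i ( r_i + Σ_j α_ij x_j ),

a mean-field, deterministic description: each pairwise influence is a
single averaged coefficient, there is no stochastic fluctuation term,
no spatial structure, and no time-varying environment. Abundances are
nonnegative and extinction is absorbing (`x_i = 0` is invariant). The
framework is a forecasting and hypothesis-generation tool, not a
mechanistic ground truth; all the usual caveats of extrapolating a
nonlinear fitted system apply, and interaction coefficients inferred
from compositional sequencing data inherit that data's biases.

Units: `r_i` is 1/time; `α_ij` is 1/(abundance·time) in whatever
units the input table uses. Time units are the input table's.

## Estimation

Dividing the ODE by `x_i` gives the per-capita (log-derivative) form,
and integrating over one sampling interval `[t_k, t_{k+1}]` with the
implicit trapezoid rule yields, per taxon,

    ( ln x_i(t_{k+1}) − ln x_i(t_k) ) / Δt_k
        = r_i + Σ_j α_ij ( x_j(t_{k+1}) + x_j(t_k) ) / 2  + error.

We place `Δt` on the response side (dividing the log difference by
each interval's own `Δt_k`) rather than multiplying the right side;
the two forms are algebraically identical, and this one keeps the
design matrix free of `Δt` under irregular sampling. Each taxon's
`(r_i, α_i·)` row is a separate regression sharing one design matrix
of interval midpoints.

**Unconstrained fit** — partial least squares with `k` latent
components, default `k = min(n, usable intervals − 1)`. With maximal
components on a full-column-rank design PLS coincides with ordinary
least squares (asserted to 1e-8 in the tests); fewer components give
a shrunk, collinearity-robust fit when intervals are scarce. No
ridge/lasso-style regularization is offered.

**Constrained fit** — per-taxon bounded-variable least squares
(`scipy.optimize.lsq_linear`, BVLS) with `r_i ≥ 0` and `α_ii ≤ 0`,
off-diagonals free. "Positive growth" is implemented as the closed
constraint `r_i ≥ 0` because strict inequalities are not
representable in a quadratic program. BVLS keeps the bounds exactly
(no tolerance slack). Constrained solutions need not be unique when
the design is ill-conditioned; we guarantee constraint satisfaction
and residual optimality, not a particular representative. If the
solver fails the result is flagged `feasible=False` and carries the
unconstrained fallback; the CLI then exits with an error unless
`--fallback-unconstrained` is given.

**Zeros.** `ln 0` is undefined, so intervals where the focal taxon is
zero at either endpoint are dropped from that taxon's regression and
recorded in `dropped_intervals`; the shared design keeps those rows
for other taxa. An alternative pseudocount mode (`pseudocount=0`
auto-selects half the smallest positive value in the table) keeps all
intervals at the cost of fabricating dynamics near detection limits;
dropping is the default because absent taxa carry no rate
information. Identifiability requires at least `n + 1` usable
intervals per taxon; fewer raise `UnderdeterminedSystemError` (an
`allow_underdetermined` escape hatch exists for exploratory
minimum-norm fits).

**Degenerate input.** If a taxon's responses or the whole design are
constant, PLS is undefined (zero centered variance); the fit falls
back to the minimum-norm least-squares solution of the interceptful
system — for an all-constant table this returns `r = 0, α = 0`, which
reproduces the zero responses with zero residual — and the result is
flagged as non-unique in `EstimationResult.warnings`.

## Simulation

`scipy.integrate.solve_ivp` with a solver menu {rk45 (default), rk23,
lsoda, bdf}; output is evaluated on the regular grid via the solver's
adaptive dense machinery rather than forcing steps onto grid points.
Default tolerances are rtol 1e-8, atol 1e-11 (configurable). They are
chosen so that the one-species logistic benchmark (r=1, α=−1,
x₀=0.5, 100 grid points at step 0.1) tracks its closed form to better
than 1e-6 relative error with an order of magnitude of margin
(measured 3.7e-8); looser tolerances around 1e-6 leave no margin on
that benchmark.

Nonnegativity is analytic in gLV, so numerical excursions in
(−1e-8, 0) are floored to 0, while anything at or below −1e-8 is
treated as solver failure and raises `SimulationError` carrying the
last valid time. Taxa starting at exactly 0 are pinned to 0. The
10-species / 100-output-point caps mirror a service-protection
convention, not mathematics: the CLI enforces them (override with
`--force`), the library only on request (`enforce_caps=True`).

## Evaluation

DTW uses the plain unconstrained recursion with absolute-difference
local cost, no warping window and no step weights; boundary cells map
(1,1)→(1,1) and (m,n)→(m,n), so unequal lengths are handled
naturally. Every series is min-max scaled to [0, 1] first (a
`scaled=False` escape exists), making the score a shape distance;
constant series scale to all zeros — preserving "flat" semantics and
avoiding 0/0. The cumulative score is the unweighted sum of per-taxon
distances with no length normalization, so comparing cumulative
scores is only meaningful at matched series lengths and taxon sets.

All-vs-all DTW matrices (within the observed set and within the
predicted set) are clustered agglomeratively — UPGMA by default,
single/complete selectable. The clustering is implemented directly
(taxon counts here are ≤ 10, so the O(n³) loop is irrelevant) to pin
down a deterministic tie-break: among equally distant pairs, the pair
whose lexicographically smallest representative labels sort first is
merged. Heights are clamped monotone root-ward. Dendrograms serialize
to canonical newick (children ordered by smallest leaf; branch length
= parent height − child height); tests cross-check merge heights
against `scipy.cluster.hierarchy.linkage` on tie-free matrices.

## Exploration

Core taxa: strictly fewer than 30% exactly-zero entries (so a taxon
with 3 zeros in 10 points is excluded). The Pearson network is built
on raw (untransformed) abundances over all time points; an edge needs
`r ≥ 0.5` or `r ≤ −0.5`. Pairs with a constant series are skipped
with a logged warning (correlation undefined). Moving-average
smoothing is centered with odd window and edge truncation and is a
visualization aid only — estimation never sees smoothed data, since
smoothing biases the log-difference rates the regression consumes.

## Synthetic data

`random_stable_model` draws `r_i ~ U(0.3, 1)`, off-diagonal
`α_ij ~ U(−0.05, 0.05)` (mixed sign), and diagonals
`α_ii = −(margin · Σ_{j≠i}|α_ij| + U(0.2, 0.6))`, giving diagonal
dominance (default margin 2) and bounded trajectories — checked
empirically over 20 seeds.

`generate_dataset` integrates the ODE tightly (rtol 1e-9) on the
sampling grid, multiplies each value by `exp(N(0, σ²))` and then
zeroes cells with probability `zero_inflation`. Multiplicative
log-normal noise is the natural choice for nonnegative,
heteroscedastic sequencing-derived abundances; zero inflation mimics
detection dropouts. Defaults are a 50-point grid on [0, 12] with
initial abundances drawn at 5-30% of carrying capacity: the growth
transient is what identifies the parameters — a community sampled
only at its plateau yields a nearly constant design column collinear
with the intercept, and `r` becomes unidentifiable regardless of
noise level. Pilot runs with these defaults put the median relative
growth-rate error near 8% at σ = 0.05 (50 points, 3 taxa), within the
20% working tolerance used in the tests.

What the generator does **not** emulate: compositional closure
(relative abundances summing to 1), read-count discreteness and
library-size variation, autocorrelated measurement error, or
environmental perturbations. Passing recovery tests on this
generator therefore demonstrates correctness of the estimation
machinery under the model's own assumptions, not robustness to real
sequencing pipelines.

`exact_discrete_fixture` solves the implicit trapezoid relation
forward by fixed-point iteration (tolerance 1e-12, cap 1000
iterations; non-convergence advises a smaller Δt). Its output
satisfies the regression identity exactly, so full-component
unconstrained estimation must recover the generating parameters to
float precision — the sharpest end-to-end check in the suite.

## Numerical choices and problem sizes

- File I/O is TSV, UTF-8, '.' decimals, header mandatory; floats are
  written at 17 significant digits and read with pandas'
  round-trip parser, so writer∘reader is the identity. Duplicate
  times and missing cells are rejected (the discretization needs
  Δt > 0; no imputation rule is offered). Taxon matching is exact
  after whitespace trimming, case-sensitive.
- The DTW correctness sweep enumerates all pairs of integer series of
  length ≤ 5 over {0, 1, 2} against a branch-and-bound path
  enumeration oracle (~132k pairs, seconds).
- Recovery experiments use 3-5 taxa, 20-130 time points, 10-50 seeds;
  these sizes make the full suite run in well under a minute while
  leaving every claim at its stated tolerance.

## Known limitations

- Forecast quality degrades with horizon like any nonlinear
  extrapolation; DTW scores of long forecasts near equilibrium mostly
  reflect noise shape, not dynamics.
- The constrained fit can be feasible yet biologically implausible in
  the off-diagonals; constraints apply only to `r_i` and `α_ii`.
- No uncertainty quantification (no bootstrap or Bayesian posterior);
  residual norms are the only fit diagnostics.
- Correlation networks on raw abundances are subject to compositional
  bias; they are an exploration aid, not an inference method.
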