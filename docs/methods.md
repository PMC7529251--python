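# Methods

This note documents the statistical model behind `censnet`, the numerical
choices made where the construction is genuinely open, what the simulation
bench does and does not emulate, and the package's known limitations.

## Data model

For `N` samples and `J ≥ 2` events the observable is the pair of `N × J`
matrices `(X, Δ)`: `x_nj = min(t_nj, c_nj)` and `δ_nj = I(t_nj ≤ c_nj)`,
with `T` the latent true times and `C` the censoring times.  The estimand is
the sparsity pattern of `Θ = Σ⁻¹`, the precision matrix of the true times:
an edge `i–j` means `T_i` and `T_j` are partially correlated given the other
events.  Only right censoring is handled; censoring is assumed independent
of the event times when the data are simulated, but the estimator itself
does not use that assumption.

Kaplan–Meier estimation uses the events-before-censorings convention at
tied times (a sample censored at `t` is at risk for events at `t`).  One
consequence worth recording: under this convention a censored observation
always has strictly positive KM survival at its own time, so the
"no mass available beyond a censored time" fallback in the mass allocator
is purely defensive.  Times equal to zero are accepted (a KM step at 0);
simulated log-normal times are strictly positive, so this only affects user
data.

## Pair-density estimation

**Mass allocation.**  Each sample's unit mass is laid out along each axis:

* uncensored at `x` — a point mass at `x` (always a KM event time);
* censored at `x` — mass on KM event times `t > x` proportional to the
  survival increments `S(t⁻) − S(t)`, normalized by `S(x)`; the residual
  tail mass `S(t_last)/S(x)` is spread uniformly on
  `(max(x, t_last), root_hi]`.  Starting the per-sample tail at
  `max(x, t_last)` rather than at `t_last` keeps all redistributed mass
  above the observed time, which is what conditioning on `T > x` requires.

The two-dimensional mass of a sample is the product of its two axis
distributions.  This product form uses only marginal KM information, is
normalized by construction, and reduces exactly to a point mass in the
plane when both coordinates are uncensored.

**Sample space.**  The root rectangle is
`[0, tail_factor · max(X_i)] × [0, tail_factor · max(X_j)]` with
`tail_factor = 1.5` by default.  The bound is a genuine tuning knob: the
censored tail mass needs room beyond the largest observation, and the
conditional expectations used for imputation are sensitive to it (a larger
bound pushes imputed values of late-censored samples up).  It is exposed in
the configuration and echoed in run manifests.

**OPT recursion.**  For a region `A` with fractional count `N(A) = N·P_A`,

    Φ(A) = ½ Φ₀(A) + ¼ Σ_m [B(N(A_m1)+½, N(A_m2)+½) / B(½,½)] Φ(A_m1) Φ(A_m2),

where `m` indexes the two split directions, children are midpoint (dyadic)
splits, and `Φ₀(A) = |A|^(−N(A))` is the stopped/uniform likelihood.  The
base-measure constants of `Φ₀` cancel because every comparison involves the
same data over the same region.  All arithmetic is in log space with Beta
terms via log-gamma, so fractional counts and `N` up to at least `1e4`
are safe.  The recursion terminates with `Φ = Φ₀` at `max_depth` (default 8,
i.e. a 256 × 256 finest grid).

The estimator runs top-down: a region is kept as a uniform leaf with
density `N(A)/(N|A|)` when `Φ₀(A)` exceeds the Beta-weighted sum of the two
split likelihoods, when `N(A) < min_count` (default 5 fractional samples —
regions this sparse cannot support a meaningful split), or at `max_depth`;
otherwise it splits along the axis with the larger weighted child product,
ties going to axis 1 for reproducibility.  The final density is renormalized
to integrate to exactly 1 (the raw leaf masses already sum to 1 up to
float round-off).

Implementation: because all regions are dyadic, per-sample masses are
binned exactly onto the finest grid once per event (point masses fall in
single cells; the uniform tail is split by overlap length, both exact for
dyadic boundaries), and the whole Φ table for every level pair `(l1, l2)`
with `l1 + l2 ≤ max_depth` is computed by vectorized matrix products —
about 4 100 region values at depth 8.  A direct region-recursive
implementation (`opt_log_likelihood`) is kept as the reference form; the
two agree to 1e-10 relative and the test suite asserts it.  Axis
allocations depend only on a single event, so they are shared across the
J−1 pairs each event participates in.

## Imputation and covariance

Marginals `f̂_j^(k)` come from exact strip integration of the
piecewise-constant pair densities.  A censored `x_nj` is replaced by

    t̂_nj = (1/(J−1)) Σ_{k≠j} E_{f̂_j^(k)}[T_j | T_j > x_nj],

with each expectation computed in closed form from the bin integrals of
`t·f(t)` over `(x, root_hi]`.  The average runs over the J−1 partner events:
no self-pair density exists, so a `1/J` weighting including `k = j` has no
consistent interpretation.  A Monte Carlo path (inverse-CDF sampling of the
tail, `mc_samples` draws) is kept behind a configuration flag as a fidelity
check; the closed form is exact for piecewise-constant densities and is the
default.  If a marginal has no mass beyond `x` (possible only through
numerical underflow or user-supplied densities), the observed time is kept
with a warning.

The covariance is `M̂ = (1/N)(T̂ − 1μ̂′)′(T̂ − 1μ̂′)` with divisor `N`
(not `N − 1`).  As a Gram matrix it is positive semidefinite regardless of
how the imputation behaves.  The direct double-integral covariance of a
fitted pair density is provided only as `density_covariance_diagnostic`:
assembling a matrix from those pairwise values does not guarantee
semidefiniteness, which is exactly why the imputation route is the mainline.

## Inverse-covariance estimation

`graphical_lasso` maximizes `log det Θ − tr(M̂Θ) − ρ‖Θ‖₁` by Friedman-style
block coordinate descent (one working-covariance column at a time, each an
L1 regression solved by coordinate descent; numba-compiled inner kernel).
The penalty applies to off-diagonal entries only, the common convention
(configurable); the working covariance's diagonal is then fixed at
`diag(M̂)`.  Convergence is declared when the maximum absolute change of the
working covariance in one sweep falls below `glasso_tol` (default 1e-7);
non-convergence is flagged on the result, not raised.  `ρ = 0` returns the
unpenalized MLE `M̂⁻¹` directly.  Inputs whose smallest eigenvalue is below
1e-8 are ridge-repaired by shifting the spectrum up to that floor (logged).
The implementation agrees with an independent reference implementation to
1e-4 entrywise on random covariances when both are run tight, and its
objective matches a generic numerical maximizer to 1e-6 on small instances.

**Penalty path and edge scores.**  The default grid is 50 log-spaced values
from `ρ_max = max |off-diagonal of M̂|` (the exact threshold above which the
solution is diagonal) down to `1e-3·ρ_max`, warm-started downwards.  An
edge's score is the largest grid value at which `|Θ_ij| > zero_tol`
(1e-8); edges that never enter score 0.  Grid resolution bounds the score
resolution: with 50 points, ties across edges entering between adjacent
grid values are expected and are handled by the tie-aware ROC.

**Cross-validation.**  `k`-fold (default 5) selection maximizes the mean
held-out Gaussian log-likelihood `log det Θ − tr(M_valid Θ)`.  Imputation is
performed once on the full sample and only the fold covariances are
recomputed from row subsets: per-fold re-estimation of all pair densities
would multiply cost by `k`, and the imputation is a smooth functional of
the pooled KM curves, so the leakage caveat is modest — but it is a caveat,
and it is recorded here deliberately.  Ties on the grid resolve to the
larger (sparser) penalty.

## Simulation bench

The generator reproduces the benchmark conditions used throughout the
tests: a ground-truth graph (scale-free: preferential attachment with one
edge per node, hence J−1 edges; random: independent edges with `p = 2/J`;
small-world: ring lattice rewired with probability 0.15), an initial
precision `P = I + σ̃·adjacency` with `σ̃ = 0.8`, off-diagonal rescaling by
twice the row's off-diagonal absolute sum, symmetrization by averaging,
`Σ = cor(A⁻¹)` on the non-isolated block with isolated nodes reinserted at
unit variance, `log T ~ N(0, Σ)` and independent `C_j ~ Exp(λ)`.  With unit
log-variance and `λ = 1` the mean censoring rate sits at 55–65 %.

Two generator details deserve flagging:

* The rescaling pins each pre-symmetrization row's off-diagonal sum at
  exactly 1/2, but averaging with the transpose re-inflates the rows of
  high-degree hubs, and for hub-heavy scale-free draws the symmetrized
  matrix is occasionally indefinite (roughly a fifth of J=100 scale-free
  draws).  Such draws parameterize no Gaussian and are rejected and
  redrawn from the same seed stream, with a warning.  The retained
  ensemble is therefore the PD-conditioned one, which is the only one a
  log-normal sampler can realize.
* The small-world base lattice uses one neighbour per side (J edges before
  rewiring), keeping edge density comparable to the scale-free setting;
  the lattice degree is configurable.

All randomness flows from a single integer seed through one generator
stream; identical configurations give bit-identical data.

**What the bench does not emulate.**  Real multivariate survival data have
dependent censoring (a shared end-of-study date censors all events at
once), covariate-driven heterogeneity, discrete/tied observation times, and
non-log-normal margins.  Passing the bench shows the pipeline recovers
conditional-dependence structure under independent exponential censoring of
log-normal times; it does not certify performance under informative
censoring, which is outside the model.

## Evaluation

Edges are conditional positives among the `J(J−1)/2` pairs.  AUC is the
trapezoidal area, identical to the Mann–Whitney statistic with half credit
for ties (so it is invariant to monotone score transforms and well defined
for the tied penalty-entry scores).  TPR at FPR 0.05 and 0.1 is read off
the curve by linear interpolation between adjacent ROC points — a step
reading would bias TPR down at the 50-point score resolution.  Experiments
redraw the ground-truth network each repetition (configurable to a fixed
network), with repetition `r` seeded `base + r`; summaries report mean and
standard error over repetitions.

Reference methods: *upper bound* — penalty-entry scores on the covariance
of the true times; *lower bound* — the same on the observed times ignoring
censoring; *baseline* — absolute Pearson correlation over jointly
uncensored samples (score 0 with a warning when fewer than 3 such samples
exist for a pair).  At zero censoring all of cne/upper/lower coincide
exactly, which the tests assert.

**Problem sizes used in the shipped runs.**  The acceptance script and the
heavier tests run the reference methods at scale-free J=100, N=1000 and the
full pipeline at J=20, N=100 (10 repetitions each), plus a censoring sweep
at J=10, N=300 over `λ = 2⁻⁵ … 2²`; these sizes exercise every code path
while keeping a complete run in the minutes range on one CPU.  The full
pipeline at J=100, N=1000 is supported (about 5 000 pair densities per
repetition) and is intended for extended `censnet benchmark` runs.

## Known limitations

* Bivariate-only densities: the imputation averages pairwise conditional
  expectations instead of conditioning jointly on all other events.
* The product-form 2-D mass layout ignores within-pair dependence of the
  censored mass (it uses marginal KM information only).
* Penalty-entry scores inherit the grid resolution; bisection-refined entry
  points would remove the ties at extra cost.
* CV penalty selection reuses globally imputed times (see above).
* No left/interval censoring, no covariates, no directed or time-varying
  networks.
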