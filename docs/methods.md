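# Methods

`dynpath` treats causality and mediation as properties of processes evolving
in time.  Influence flows from process to process through local
characteristics — drifts of diffusions, intensities of counting processes,
conditional increment means of discrete-time panels — and direct/indirect
effects are defined as flow along directed paths rather than as contrasts
between counterfactual manipulations of a mediator.  This note records the
models, the estimators, the numerical choices, and what the synthetic-data
suites do and do not establish.

## 1. Linear dynamic systems and path-specific effects

**Model.** `LinearSDEModel` is the constant-coefficient linear system

    dX_t = A X_t dt + u(t) dt + dW_t,

with `A[i, j]` the rate (1/time) at which the level of process *j* moves the
drift of process *i*, an optional deterministic input `u` (level/time), and
Brownian disturbance with diffusion matrix `noise_cov` (level²/time,
symmetric PSD within an eigenvalue tolerance of 1e-10).  With zero input,
`E(X_t | X_0) = exp(A t) X_0`; `expected_state` computes this with
`scipy.linalg.expm` (scaling-and-squaring).  A nonzero input makes the
closed form invalid, so `expected_state`, `total_effect` and `path_effects`
raise rather than silently ignoring it.

**Local-independence structure.** `drift_to_graph` draws an edge *j → i*
exactly when `|A[i, j]| > tol` off the diagonal: process *i*'s drift
genuinely involves process *j*'s level.  Diagonal entries express
self-relaxation, not graph structure, and never create edges.

**Path-specific effects by node splitting.** For a source perturbation Δ at
time 0, the total effect on a target at horizon *t* is
`(exp(A t))[target, source] · Δ` — defined for any drift, cyclic or not.
The decomposition over individual directed paths is computed by unfolding
the source→target sub-system into the *prefix tree* of its simple paths:
each distinct path becomes one root-to-leaf route, shared prefixes are
shared tree nodes, nodes lying on diverging routes are duplicated per
prefix, and every leaf is a copy of the target fed only by the final edge
of its path.  Solving the split system with the matrix exponential and
reading the leaves gives per-path effects that sum exactly to the total.
For an acyclic zero-diagonal sub-system a path with *k* edges and weight
product π contributes `π · t^k / k! · Δ`, because `(A^k)[target, source]`
sums weight products over length-*k* paths; the test suite uses this closed
form, evaluated by explicit path enumeration, as an independent oracle.

Path decomposition is restricted to acyclic, zero-diagonal ancestries of
the target.  Under feedback the set of paths is infinite and no finite
splitting exists, so cyclic systems get `total_effect` only and
`split_paths` raises a structure error.  The path registry is ordered
lexicographically by node sequence for reproducible output.

**Simulation.** `simulate` is Euler–Maruyama with the step equal to the
grid spacing — users control accuracy by refining the grid (the noise-free
error over `t ∈ [0, 2]` at step 1e-3 is verified below 1e-3 relative).
Noise is factorized through a symmetric PSD square root with small negative
eigenvalues clipped at the 1e-10 tolerance.  Identical seeds give
byte-identical ensembles.

## 2. Local-independence graphs and delta-separation

A local-independence graph is directed, may contain cycles (mutual
dependence is meaningful for processes), and never self-loops.  The
delta-separation test of "does C block the influence of A on B" runs:

1. ancestral restriction to A∪B∪C (reachability-based, hence well defined
   with cycles — no acyclicity check is imposed);
2. deletion of all directed edges leaving B (this encodes the direction of
   the question and makes the criterion asymmetric in (A, B));
3. moralization (co-parents of every child joined, directions dropped);
4. undirected separation of A from B by C (breadth-first search avoiding C).

`separation_oracle` re-decides step 4 by exhaustively enumerating simple
paths; it is exponential and guarded at 10 nodes.  The randomized suite
cross-validates the two on 500+ random graphs.  Node roles (treatment,
mediator, outcome, censoring, unobserved) are carried in the JSON schema as
documentation only; they never alter the algorithm.

Censoring enters this vocabulary directly: censoring is *independent*
exactly when all other processes are locally independent of the censoring
process.  The package's reference graphs encode the two canonical cases —
censoring driven only by treatment (separated from the outcome by the
treatment history) and censoring driven by an internal mediator (not
separated; a marginal analysis ignoring the mediator is biased).

## 3. Dynamic path analysis for event-history data

**Data contract.** Counting-process rows (id, start, stop, event,
covariates), intervals per subject contiguous and non-overlapping, event
only on the last interval (single-event survival).  The at-risk convention
is `(start, stop]` ∋ t iff `start < t ≤ stop`, with events attributed to
stop times; this is the standard counting-process convention, stated
explicitly because it decides which regression each subject enters.
Covariates are step functions: intermittently measured mediators are
carried forward (LOCF) between measurement times by construction of the
intervals.

**Additive hazard layer.** At each distinct event time the coefficient
increment solves ordinary least squares of the event indicator on the
at-risk design; increments accumulate into cumulative regression functions.
Tied event times are processed once with a multi-event indicator.
Covariance increments use the least-squares sandwich with the event
indicator as squared-residual proxy.  Singular designs (Gram eigenvalue
below 1e-10 relative) are *skipped and logged* — never pseudo-inverted —
and the fraction of event mass at skipped times is reported.  The
intercept-only fit reduces exactly to the occurrence/exposure
(Nelson–Aalen) step estimator, which the tests verify against an
independent survival-analysis implementation.

**Mediator layer.** At each event time, OLS of the mediator's current value
on intercept + treatment (+ extras) over the at-risk set — per-event-time
path coefficients θ(t) with classical OLS standard errors.

**Decomposition.**

    direct(t)   = cumulative treatment coefficient of the full fit (X, Z),
    indirect(t) = Σ_{t_k ≤ t} θ₁(t_k) · dB̂_Z(t_k),
    total(t)    = cumulative treatment coefficient of the marginal fit (X).

When no time is skipped in any layer, `total = direct + indirect` holds at
machine precision at every event time: per event time it is the in-sample
nested-OLS identity (marginal slope = direct slope + mediator-on-treatment
slope × mediator slope) on the shared at-risk sample.  Skips break the
shared-sample premise, so the fit flags the identity as approximate and
reports the gap rather than hiding it.

**Uncertainty.** Pointwise percentile bootstrap, resampling subjects with
replacement; replicate curves are evaluated at the original event times by
last-value-carried-forward, and replicates with no events are dropped and
counted.  Simultaneous bands are out of scope.  The bootstrap is the
package's own choice of band construction; coverage is checked by
simulation at moderate n, where percentile bands are known to undercover
slightly.

## 4. Linear increment models for panels

For variables on a common discrete time grid, the per-time regression is

    Y(t_k) − Y(t_{k−1})  ~  intercept + X(t_{k−lag}) (+ adjusters),

across subjects, complete cases per time (no imputation: a subject missing
any needed value at a time is dropped for that time only).  The response
increment is always the lag-1 difference; `lag` applies to the predictors
and is counted in grid steps, not calendar units.  Cumulative coefficient
curves are running sums with variances accumulated as if estimates were
independent across times; estimates in fact share subjects (notably through
lagged dependent variables), so these accumulated variances are
approximate, which is one reason a permutation alternative exists for
testing.

**Local-dependence test.** The aggregate statistic
`Q = Σ_t (coef_t / SE_t)²` over fitted times is the package's own
construction for turning a per-time coefficient series into a single
direction-specific verdict.  `method="chi2"` refers Q to χ² with one degree
of freedom per fitted time — approximate because of the shared-subject
dependence.  `method="permutation"` permutes the candidate driver's whole
trajectory across subjects (keeping each subject's own trajectory intact,
preserving the response's autocorrelation) and is the safer reference.
Times with degenerate standard errors (exact in-sample fits, SEs at
rounding level) are dropped from Q with a log entry.  The calibration suite
shows the two references agree in their rejection decision on the large
majority of moderate panels.

## 5. Synthetic scenarios

**Mediation survival scenario.** Binary treatment X ~ Bernoulli(p); the
mediator is updated at regular visits as
`Z = θ₀ + θ₁ X + b_i + ε` with a persistent subject effect `b_i` and fresh
visit noise, carried forward between visits; the event intensity is
`β₀ + β₁ X + β₂ Z` clipped at zero.  Defaults — unit horizon, visit step
0.1, β = (0.1, 0.3, 0.5), θ₀ = 0.5, θ₁ = 1.0, subject/visit noise
(0.15, 0.25), n = 500 — describe a calibrated two-arm cohort with two
coupled processes measured at regular visits, in which the linear hazard
stays positive for all but a negligible share of evaluations (the clipped
fraction is recorded and kept below 1%; clipping is unavoidable in
principle because a linear hazard is not sign-constrained).

Events are simulated by fine-grid Bernoulli discretization (default step
0.01; per step, an event fires with probability `1 − exp(−λ Δ)`), which
handles time-varying and covariate-dependent intensities uniformly; all
clocks run in integer step units so interval boundaries, visit times and
event times compare exactly.  Censoring is `none`, `independent` (constant
rate), or `mediator` (rate increasing in Z).  The mediator-dependent
variant is a *negative control*: the marginal fit ignoring Z is then
demonstrably biased in the recovery suite, while the graph emitted with the
scenario yields the corresponding separation verdict — the data-level and
graph-level conclusions are cross-checked automatically.

A structural point worth recording: because the hazard is *additive* in Z,
the survival tilt on the subject effect, `exp(−β₂ ∫ Z)`, factors identically
across treatment arms, so at-risk selection does not differentially distort
the mediator regression — the per-time θ̂₁ stays unbiased for θ₁ and the
recovery suite confirms cumulative slopes (β₁, β₂) and indirect slope
β₂·θ₁ within Monte-Carlo error at the default n.

**Coupled panel scenario.** Each subject's variables evolve by
`V(t) = V(t−1) + coupling · V(t−1) + noise`, missingness completely at
random (informative missingness is out of scope).  The one-way helper
builds the pattern of a driver process feeding a response process and not
conversely — the structure of a viral-load process driving immune-marker
increments — with the driver mean-reverting (stationary) and the response
coefficient calibrated so that `coef · sd(driver) / noise_sd` equals a
requested standardized effect (default 0.5 at n = 200 over 15 times).
Under these conditions the reverse-direction test holds the nominal 5%
level within binomial error and the forward direction rejects essentially
always.

**What passing tests show, and what they do not.** The generators share the
exact functional forms the estimators assume (linear hazard, linear
mediator law, linear increments, MCAR missingness, common grids).  Passing
recovery and calibration suites therefore establishes internal correctness
of the estimators under their own model, not robustness to misspecified
hazards, informative observation times, measurement error in the mediator,
or irregular per-subject grids — none of which the generators emulate.
Cohort-scale features (multi-year follow-up, detection limits, treatment
switching) are emulated only in qualitative structure.

## 6. Problem sizes and determinism

Simulation-based checks use 100–500 replicates at n = 150–800 subjects and
2000 paths for Monte-Carlo means — sizes at which Monte-Carlo standard
errors are small enough to separate truth from bias for the effect sizes
involved, while a full suite run stays comfortably interactive.  All
randomness flows through `numpy.random.default_rng` seeds; every generator
is byte-reproducible under its seed, the bootstrap and permutation tests
are deterministic under theirs, and the acceptance script derives all
stream seeds from its single `--seed` argument.

The bias-shrinkage check (n = 200 vs n = 800) is formulated as seeded
noninferiority — the larger-n bias must not exceed the smaller-n bias
beyond Monte-Carlo resolution — because for an unbiased estimator both
measured "biases" are noise and a strict inequality would be a coin flip.

## 7. Known limitations

- Time-varying drift matrices A(t) are not supported (constant A only);
  nonlinear systems and estimation of A from data are out of scope.
- Path decomposition is undefined under feedback (see §1); cyclic systems
  get totals only.
- Additive-hazard and mediator standard errors are per-time; no
  within-subject correlation adjustment across times is attempted, and the
  χ² reference for the panel test inherits that approximation.
- Counterfactual (controlled/natural) effect estimation, inverse-probability
  weighting for dependent censoring, and likelihood factorization over
  dynamic path diagrams are deliberately not implemented; the
  dependent-censoring scenario exists only as a negative control.
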