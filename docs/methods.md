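# Methods

## Scope and model class

`odeident` handles deterministic ODE models `dx/dt = f(x,u,p)`,
`y = g(x,u,p)`, `x(0) = x0`, with expressions built from `+ − * / ^`,
`exp`, `log` and `sqrt` over declared states, parameters, inputs and
constants.  No events, delays, DAEs or piecewise right-hand sides; a
piecewise-linear *input signal* is supported, but handled by the
simulation and design layers, never inside the symbolic RHS — this keeps
symbolic differentiation total.  Every quantity is declared known (with a
value) or unknown; the unknown-quantity vector is **unknown parameters
first, unknown initial conditions second**, and every matrix in the
package uses that column order (declaration order within each group).

## Structural identifiability

The structural module implements the observability rank condition on
stacked output Lie derivatives.

* **Inputs.** Under the default `generic_smooth` assumption the input time
  derivatives `u⁽ʲ⁾` enter as free indeterminates (the experimenter may
  excite the system arbitrarily); under `constant` they vanish.  Batch
  models have no inputs and are unaffected.
* **Known initial conditions** fix their states, so the Jacobian is taken
  only with respect to the unknown quantities, evaluated at a generic
  initial state.  This is algebraically equivalent to the formulation
  that keeps all state columns and adds a unit row per known IC.  A
  diagnostic re-evaluates the final Jacobian at the *specific* known IC
  values and warns when the rank drops there: particular initial
  conditions (e.g. starting a compartment at zero) can destroy
  identifiability that holds generically.
* **Exact rank.** The Jacobian is evaluated at random integer points in
  [1, 999] (default 3 points, seeded) and the rank computed in exact
  rational arithmetic, so there is no SVD tolerance to tune.  For
  non-rational models, after point substitution every `exp` atom has a
  rational argument; since `e^q` is transcendental for rational `q ≠ 0`,
  all such atoms are integer powers of one transcendental generator,
  which is replaced by a fresh symbol and the rank taken over the
  resulting rational-function field.  This keeps exactness for the
  exponential growth kinetics of the methanogenesis model.
* **Stopping rule.** Derivative orders are added until the rank is
  unchanged for one extra order or full, capped at
  `n_states + n_unknowns − 1`; an expression-node budget (default 5·10⁵
  nodes) guards against blowup.  Rank disagreement across evaluation
  points beyond one unlucky point is surfaced as a warning, never
  averaged away.
* **Verdicts** use column elimination: a quantity is locally identifiable
  iff deleting its column strictly lowers the rank.  Null-space basis
  vectors are reduced to smallest-integer form and expose locally
  compensable directions.
* **Solution counting.** For models with ≤ 4 unknowns and ≤ 3 states,
  the first `n_unknowns + 1` Taylor coefficients of each measured output
  are equated between a random rational reference parameterization and a
  free one and solved exactly (sympy).  Admissible solutions are real
  with declared-positive quantities strictly positive.  Solver failure is
  reported as `symbolic-failure`, never as a silent count.  The package
  claims only *local* verdicts; "identifiable with count 1" is the
  strongest statement it makes in lieu of a differential-algebra global
  certificate (out of scope).

## Simulation and sensitivities

LSODA (stiff-capable, via scipy) with the analytic state Jacobian
supplied symbolically; defaults `rtol 1e-8`, `atol 1e-10`.  Forward
sensitivities integrate `dS/dt = (∂f/∂x)S + ∂f/∂θ` jointly with the
states, `S(0)` an identity block in the unknown-IC rows; output
sensitivities follow by the chain rule.  The methanogenesis model mixes
fast gas–liquid transfer (`kLa = 8 h⁻¹`) with slow growth, which is why a
stiff-capable method is the default.

The synthetic-data generator adds independent Gaussian noise to the
noise-free outputs — additive (constant SD per output, the default) or
relative (SD ∝ |y|) — seeded through `numpy.random.default_rng`.  The
additive default is the simplest noise model compatible with the
weighted-least-squares/FIM machinery.  It emulates measurement error
only: no model misspecification, no input uncertainty, no correlated or
heteroscedastic errors beyond the relative option, and no missingness.
Passing tests therefore demonstrate correctness of the machinery under
the assumed error model, not robustness of any conclusion to real-data
pathologies.

## Practical identifiability

The estimation objective is the weighted residual sum of squares
`Σ ((y_obs − y_model)/σ)²`; the FIM uses the same weights, so Cramér–Rao
SDs are in parameter units and the χ² calculus applies directly.

* **FIM.** `FIM = Σₖ S_yᵀ W S_y`, `W = diag(1/σ²)`.  Eigenvalues below
  `1e-10 ×` the largest flag the matrix singular: SDs are then undefined
  and the small-eigenvalue directions are reported instead of inverting a
  numerically meaningless matrix.
* **Fitting.** Multistart (default 20) Latin-hypercube starts in
  log-space within user bounds, each refined by scipy's bounded
  trust-region least squares; all termini are retained so that distinct
  equal-RSS solutions can be clustered (termini within 1e-3 relative
  distance merge) — that clustering is how the two-compartment swap
  ambiguity is detected numerically.
* **Profile likelihood.** One quantity fixed on a grid, all others
  re-optimized, warm-started from the neighbouring grid point outward
  from the estimate.  CI threshold default 3.84 (χ², 1 df, 95%); a
  profile whose total variation is below threshold/100 is flagged flat —
  the practical signature of structural non-identifiability.  Note the
  flatness is *local*: the compensating parameter directions of a
  structurally deficient model may leave the positive orthant away from
  the estimate, so flat profiles are asserted on grids around the truth.

## D-optimal experiment design

The design problem maximizes `log det(FIM)` (log scale for conditioning;
ratios are reported on the det scale) over a constant level or a
piecewise-linear profile on equally spaced nodes.  Defaults for the
chemostat example, chosen once as a plausible bench-scale configuration:
horizon [0, 50] h, 20 uniform sampling times, 5 nodes, feed concentration
u ∈ [0, 100], σ = 0.05 per output, dilution `D = 0.05 h⁻¹`, initial
biomass 0.5 and substrate 1, nominal `k = 2`, `kI = 50`.  The reference
comparison this module is benchmarked against does not state its horizon,
grid, σ or initial conditions, so its absolute det/SD values are *not*
claimed —
only the qualitative ordering (dynamic ≥ constant, smaller SDs) and the
exact ratio arithmetic on the reference table are reproduced.

The objective is non-convex, so candidates combine seeded random starts,
a coarse constant-level scan (the nesting warm start — constant signals
are a subspace of piecewise-linear ones, making the design-space nesting
property hold up to optimizer tolerance), and bang-bang node patterns
(all 2^d for d ≤ 6, a seeded sample otherwise), the shapes D-optimal
inputs typically take.  The two best candidates are polished with bounded
Powell search, and the returned design is the best input evaluated
anywhere, so its `log det` dominates every evaluated candidate by
construction.

## Fixture models and placeholder values

The zoo's physical constants and initial conditions that the source
material does not print are documented placeholders flagged in each
model's metadata (`methanogenesis`: `Vg = VL = 0.1 L`, `kLa = 8 h⁻¹`,
`KH_CO2 = 0.025 M/bar`, `R = 0.08314`, `T = 312 K`; ICs `xH2 = 0.001`,
`sCO2 = 0.005`, `ng_H2 = 0.01`, `ng_CO2 = 0.005`, `ng_CH4 = 0`).
Structural verdicts are generic in these constants (they are randomized
in the rank test); the values only affect simulation demos.  Nominal
unknown-parameter values for demos satisfy the stoichiometric constraint
`Y < 0.1` so the H₂ fraction `f = 1 − 10Y` is a valid fraction, with
`YCO2 = (1+10Y)/4` and `YCH4 = (1−10Y)/4`.

## Study sizes used by the tests and the acceptance script

* Two-compartment ambiguity: 30 noise-free samples on [0, 8] h; the
  multistart oracle uses 50 random starts.
* β-casein: 25–50 samples on [0, 30] min; truth `k=1, Km=3, kI=1.5`
  (`Km > kI` keeps the reduced parameters positive).
* Methanogenesis: symbolic only (no data needed).
* Design comparison: the default configuration above; 4 constant / 6
  piecewise random starts plus the deterministic candidate sets.
* Wald coverage: 100 replicate datasets under the designed constant feed
  `u = 100` (the D-optimal constant level), n = 40 samples, σ = 0.05,
  one trust-region fit per replicate from a fixed start; the 95% Wald
  interval for `k` is checked for covering the truth 90–99 times —
  FIM-based intervals are exact only under linearity and asymptotics, so
  a band around the nominal 95 is the honest assertion.  An uninformative
  feed (e.g. u = 20) makes `kI` practically non-identifiable (its Wald SD
  comparable to its value) and estimates pile up at the bounds — the
  designed input is part of the study conditions, illustrating the
  upstream workflow the package implements.

## Known limitations

* Verdicts are local; global identifiability is only approached through
  exact solution counting on very small models.
* The rank test's generic points are random: a conspiracy of unlucky
  points is detected (warning) but not impossible at 3 points; raise
  `n_points` for certainty-critical runs.
* Expression growth limits the Lie-derivative order on large models; the
  node budget fails loudly rather than silently truncating.
* No SBML import, Bayesian estimation, bootstrap CIs, A-/E-optimality,
  or joint sampling-time optimization.
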