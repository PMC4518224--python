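# Methods

`dynamap` maps how the qualitative dynamics of small biochemical ODE
networks — monostability, sustained oscillation, bistability, excitable or
mixed regimes — are distributed over multi-dimensional parameter spaces,
and renders the result as parallel-coordinates ("MD") plots. This note
documents the models, the numerical procedures, the defaults that matter,
and the limits of what the bundled synthetic experiments demonstrate.

## The classification model

For a parameter point θ of an autonomous system dx/dt = f(x, θ), x ∈ ℝⁿ≥0,
the dynamics class is read off the steady-state inventory:

1. enumerate the roots of f(·, θ) inside the admissible box [0, u(θ)];
2. at each root, compute the eigenvalues λ of the Jacobian ∂f/∂x and label
   the root stable (max Re λ < −ε), unstable (max Re λ > +ε) or marginal;
3. apply the rule table: one stable root → monostable; one unstable root →
   oscillatory; three roots with two stable → bistable; three roots with
   one stable → excitable_or_mixed; any marginal root → undetermined; any
   other pattern → other.

This is local stability analysis, not continuation: "oscillatory" asserts
a unique locally unstable equilibrium, which in these dissipative
concentration models almost always coincides with a limit cycle but is not
a proof of one; an `excitable_or_mixed` call cannot distinguish true
excitability from fixed-point/limit-cycle coexistence by eigenvalues
alone. Both caveats are addressed by the opt-in simulation pass
(`confirm_oscillation`), which integrates the system from randomised
initial conditions, inventories the attractors, and refines
`excitable_or_mixed` into `excitable` vs `mixed_bistable`. The marginality
threshold is ε = 1e-8 · max(1, spectral radius): eigenvalue signs are
meaningless exactly on a bifurcation surface, so such points are reported
as undetermined rather than force-classified, and they are excluded from
ensemble statistics.

Points with more than three steady states are reported as `other`, never
dropped: the bundled cascades have S-shaped nullcline structure with
root counts in {1, 3}, so anything else signals either a genuinely richer
model (user-supplied SBML) or a near-degenerate parameterisation.

## Root finding

Steady states are found by a multi-start damped Newton method, vectorised
across starts:

- **Starts** (48 by default, seeded): the origin, the upper-bound corner,
  and 46 Latin-hypercube points in the admissible box.
- **Iteration**: full Newton step from a batched linear solve (Tikhonov
  regularisation on singular batches), then a backtracking line search on
  the residual max-norm with an Armijo-style sufficient-decrease test, at
  most 40 halvings and 200 iterations. The damping factor is carried
  between iterations (re-entering near the last working step size) so
  starts that need heavy damping do not re-pay the full backtracking cost
  every iteration. A start whose line search cannot decrease the residual
  is discarded — with 48 starts, losing wanderers is cheaper than letting
  them drift.
- **Convergence** requires both a small residual (max-norm below
  `tol_root` = 1e-9 · max(1, max uᵢ)) and a negligible Newton step
  (max-norm below 1e-9 · (1 + ‖x‖∞)). The step criterion is essential:
  when kinetic rates are slow, |f| ≈ rate · error, and the residual test
  alone accepts a wide interval of pseudo-roots around the true
  equilibrium.
- **Polish and dedup**: converged roots get up to five undamped Newton
  steps (quadratic convergence to machine precision), then greedy
  deduplication at max-norm distance 1e-5 · (1 + max uᵢ), ties resolved by
  the smaller residual. Iterates are clipped to [0, u]: negative
  concentrations are meaningless and integer-exponent Hill terms are
  undefined there.

Zero converged roots is a flagged error (`RootFindingError`), which the
classifier converts to `undetermined` — never an empty silent success.

## The simulation oracle

`attractors_by_simulation` is the independent cross-check used both in the
test suite and by the confirmation pass. It integrates the system (LSODA,
rtol 1e-8, per-state atol 1e-11 · max(1, uᵢ)) from `n_init` uniform draws
in the box plus two perturbed starts around every unstable steady state —
limit cycles born at Hopf bifurcations can have basins much smaller than
the box, and local perturbation is how they are reached reliably.

The horizon is 20× the slowest local relaxation time and at least 10× the
slowest rotation period (from Re λ and Im λ of the enumerated roots),
capped at 1e5 time units. The trailing 20% of each trajectory is split
into two windows; the verdict per trajectory is:

- **fixed point** if every state's peak-to-trough amplitude in the final
  window is below 1e-4 of the trajectory's own magnitude (plus a floor of
  1e-8 · uᵢ);
- **oscillation** if some state's amplitude exceeds 1e-2 of that scale in
  *both* windows, does not decay between them (amp₂ ≥ 0.5 · amp₁), and
  the window is non-monotone (≥ 2 turning points) — a slowly drifting
  stiff transient must not masquerade as an oscillation;
- **undetermined** otherwise, including integrator failures and
  trajectories whose integration exceeds a wall-clock budget (10 s per
  trajectory by default; extreme stiffness occurs in the multisite system
  when Michaelis constants are far below substrate levels).

Amplitudes are measured against the trajectory's own scale rather than
the box bound because heuristic bounds (e.g. the Goodwin cascade product
k₁k₂k₃/(k_d1·k_d2·k_d3)) can sit orders of magnitude above the attractor.

## Bundled models

All models use nM and seconds, with conservation laws substituted at
definition time (states are the free/phosphorylated forms; totals are
parameters). Hill repression is Kⁿ/(Kⁿ + xⁿ), activation xⁿ/(Kⁿ + xⁿ).

- **goodwin** — three-stage synthesis/degradation loop with end-product
  repression. Unique steady state for all positive parameters (monotone
  scalar reduction); the classical secant condition makes n > 8 necessary
  for instability, which the ensemble experiments recover empirically.
- **mapk_nfb** (and `_mm2`, `_mm246` variants) — three-tier
  phosphorylation cascade, output represses the first phosphorylation.
  Dephosphorylation is first-order by default; any of reactions 2, 4, 6
  can be switched to Michaelis–Menten (Vᵢ, Kmᵢ), introducing saturation
  (zero-order ultrasensitivity) as a second nonlinearity source. The Vᵢ
  are free parameters, sampled independently of the first-order kᵢ.
- **pfb2** — two-tier cascade with output-to-input positive feedback
  entering *additively* on the basal rate, (k₁ + α·Hill(pS₂)). Defaults
  are the published bistable parameterisation; the additive form is
  validated against it (three roots; the low branch matches the
  closed-form k₁S₁t/(k₁+k₂) when the Hill term is negligible).
- **mixed** — three-tier cascade with negative feedback (pS₃ on reaction
  1) and positive feedback as a *multiplicative* gain on reaction 3,
  k₃·(1 + α·Hill(pS₃)). The multiplicative form is the reconstruction
  that reproduces all three published regime parameterisations
  (oscillatory; bistable 2 stable + 1 unstable; mixed 1 stable + 2
  unstable) — an additive form yields a unique steady state at those
  values and was rejected. The three sets ship as
  `MIXED_FEEDBACK_SETS`.
- **multisite** (and `_eqkm`) — dual-site phosphorylation with a shared
  kinase (steps 1–2) and shared phosphatase (steps 3–4) under the
  quasi-steady-state assumption with competitive (shared-enzyme)
  Michaelis–Menten denominators. This is the standard QSSA derivation
  for substrate competition; its self-consistency check is that under
  equal Km the classified ensembles reproduce the analytic bistability
  condition β = Km/Mt < 1/2 and k₂k₄/(k₁k₃) > (1+β)²/(1−2β)².
- **hopf** — supercritical Hopf normal form, the closed-form oracle for
  the classifier (eigenvalues μ ± iω, cycle radius √μ).

### Default sampling ranges

Ranges are documented per model and overridable per run. Where the
figures fix a convention we follow it (Goodwin degradation rates
log-uniform on [1e-3, 1e-1] s⁻¹; feedback thresholds log-uniform over
[1e-2, 1e1] or [1e-1, 1e2] nM; Hill coefficients integer-uniform on
[1, 12]); elsewhere the choices are a practitioner's plausible-kinetics
ranges: first-order rates log-uniform [1e-3, 1] s⁻¹, bimolecular rates
log-uniform [1e-4, 1e-1] nM⁻¹s⁻¹, totals uniform [1, 100] nM, feedback
strength α uniform [0, 100], multisite rates log-uniform [1e-3, 1e1] s⁻¹
with Km log-uniform [1, 1e3] nM and Mt uniform [10, 500] nM. MM-variant
maximal rates Vᵢ are log-uniform [1e-1, 1e2] nM·s⁻¹ and Kmᵢ log-uniform
[1e-2, 1e3] nM — the lower decades put the reaction deep in saturation,
which is the regime the shared-nonlinearity experiment depends on.

## Sampling

Monte Carlo draws each parameter independently: uniform on [low, high],
log-uniform (uniform in log₁₀) for scale parameters, uniform on the
integer grid for Hill coefficients. The Latin-hypercube sampler is the
full-factorial stratified design (s strata per parameter, one draw per
stratum, per-parameter permutation, s^d combinations; refused above 10⁶
sets) — the design whose 5⁵ = 3125-set example the ensemble experiments
use; `classic_lhs` provides the usual n-point variant for high dimension.
Integer parameters stratify on integer sub-ranges; a stratum narrower than
one integer collapses to its nearest integer. All randomness flows through
`numpy.random.default_rng(seed)`; a seed reproduces every ensemble, start
layout and initial-condition set bit-identically.

## MD plots

Ensembles are normalised per axis to [0, 1] (log-linearly for log-scale
parameters) for plotting; raw values are kept alongside and all
transformations (class filtering, conjunctive keep-brushes, highlight
brushes with inclusive boundaries, axis reordering, axis inversion as a
render-time reflection u → 1−u) return new objects. The folded 3-D layout
places the axes as vertical unit segments on a regular n-gon (or an
accordion zig-zag), with any of the C(n,2) axis pairs carrying a panel of
connecting segments; two axes degenerate to the standard PC plot. CSV and
JSON exports serialise floats via `repr` and round-trip bit-exactly.

## Suite problem sizes

The test suite runs the threshold experiments at 5,000 sets, the
multisite inequality checks at 6,000 (their assertions are per-set
analytic necessities, so sample size only adds opportunities to find a
violation), and the eigenvalue-vs-simulation agreement property at 20
points per model (threshold ≥ 95% of points with determinate verdicts on
both routes). `scripts/acceptance.py` recomputes the headline quantities
at 5,000/5,000/10,000 sets. The thresholds themselves (n ≥ 8, n ≥ 3,
ratio > 1, β < 1/2) are analytic or published properties and are never
adjusted.

One empirical threshold does not survive scaling up: in the two-layer
positive-feedback cascade, sampling {α, n, K} at 5,000 sets turns up a
genuinely bistable parameterisation with n = 2 (α ≈ 3.5, K ≈ 82, about
one set in five thousand), confirmed by independent root-scanning and by
forward integration to both stable states. With K far above the
reachable pS₂ range the Hill term degenerates to a (pS₂/K)ⁿ power law
and the substrate-depletion factor (S₂t − pS₂) supplies the remaining
effective nonlinearity, so n = 3 is not a hard floor — it is the
practical floor at small sample sizes, where such rare sets are simply
never drawn. The corresponding suite check asserts the n ≥ 3 threshold
at its stated conditions and fails on exactly this phenomenon;
`scripts/acceptance.py` reports the minimum it actually measures.

## What the synthetic experiments do and do not show

The generator samples independent parameters from broad, flat (or
log-flat) ranges. That matches the exploratory use of the tool —
unbiased coverage of a plausible kinetic space — but real cellular
parameters are correlated, and regime *fractions* (e.g. how rare
bistability is) depend strongly on the chosen ranges; only the
threshold-type statements (minimum nonlinearity for oscillation or
bistability, necessary rate-ratio inequalities) are range-robust, which
is why those are what the tests assert. Classification is local: chaotic
or quasiperiodic dynamics, subcritical-Hopf hysteresis, and
basin-of-attraction geometry are out of scope, and the simulation oracle
can miss attractors whose basins are small and far from every unstable
equilibrium.

## Known limitations

- The SBML reader covers the ODE-compatible subset (species, reactions
  with MathML kinetic laws, global/local parameters, function
  definitions, assignment rules, rate rules on species). Events,
  algebraic rules, delays and explicit time dependence are rejected with
  an error naming the construct. Species bounds for imported models use
  the heuristic max(10, 10 × initial concentration), since SBML carries
  no conservation structure explicitly.
- Steady-state enumeration is heuristic-complete: 48 starts recover the
  {1, 3}-root structure of the bundled cascades reliably (validated
  against the simulation oracle), but there is no global certification;
  exotic user models with tight root clusters may need more starts or a
  tighter dedup tolerance.
- `oscillatory` without the confirmation pass is a statement about
  eigenvalues, not a proof of a limit cycle.
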