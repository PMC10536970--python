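# Methods

## Problem statement

Two electronic states, "0" (initial) and "1" (final), are described by
potential energy surfaces E₀(**q**) and E₁(**q**) over shared Cartesian
coordinates (Bohr).  An external force holds a structure as an
equilibrium on state 0 when it cancels the internal force,
**F**_ext(**q**) = ∇E₀(**q**), so the applied-force magnitude at any
structure is ‖∇E₀(**q**)‖.  The object of interest is the variation of
the energy gap, ΔΔE(**q**) = [E₁(**q**) − E₀(**q**)] − ΔE(**q**_ref),
relative to the unforced reference (normally the state-0 minimum), as a
function of the applied force magnitude — specifically its extremal
(optimal-force) envelope.

Maximizing or minimizing ΔΔE subject to ‖**F**_ext‖² = C by Lagrange
multipliers yields the optimality condition

    ∇ΔE(q)  ∥  ∇‖F_ext‖²(q),

whose angle cosine, cos α, is the universal convergence diagnostic: a
point is optimal when |cos α| = 1 (0° for the gap-increasing, 180° for
the gap-decreasing family).

## Closed form on quadratic surfaces

With second-order expansions at the state-0 minimum (g₀ = 0), the
stationary points of the Lagrangian solve a linear system

    M(λ) Δq = g₁,

where M(λ) combines 2λH₀² with the relative gap curvature H₁ − H₀.  Two
sign bookkeepings of λ and of the curvature term circulate for this
system; they describe λ-reparametrized mirror families, and only one of
them satisfies the parallelism condition identically in more than one
dimension (for it, ∇ΔE = λ∇‖F_ext‖² holds exactly at the solution, so λ
is the sensitivity of the gap to the squared force).  Rather than
privileging either convention a priori, `optimal_structure` solves one
form, evaluates cos α numerically at the solution, and falls back to the
sign-resolved variant when the check fails, recording the validated
convention in the solution metadata.  The check is convention-independent
ground truth; in one dimension and in effectively one-dimensional
(block-diagonal) problems both conventions pass it and only relabel λ.

Useful derived objects:

* `lambda_scan` — the solution family over a λ grid, partitioned into
  gap-increasing/decreasing branches by the sign of ΔΔE and sorted by
  achieved force magnitude (λ-to-force is not globally monotone; force
  is).  λ values at a spectrum point of the pencil (smallest singular
  value below 1e-8 of the largest) are flagged and dropped, not
  extrapolated through.
* `optimal_at_force` — the member of the continuation family through the
  unforced minimum at a prescribed force magnitude.  On each side of the
  pencil spectrum the force magnitude is strictly monotone in λ (proved
  from the sign-definiteness of M(λ) there), so the matching λ is found
  by safeguarded bracketing to machine precision.  This is the oracle
  every iterative ramp is tested against.
* `nosym_eigenvalues` — in symmetry coordinates the gap gradient lives in
  the totally symmetric block; the gradient-free complement admits
  non-trivial optimal distortions only when λ equals an eigenvalue of the
  block pencil, solved as the generalized symmetric problem
  (H₀ − H₁)v = 2λH₀²v.  At such λ the solver reports the free directions
  instead of fabricating a particular solution.
* `initial_response_slope` — the zero-force limit ‖H₀⁻¹g₁‖ of
  d(ΔΔE)/d‖F‖, the maximum linear mechanical response.

`equilibrium_structure` solves H₀Δq = F by Cholesky factorization and
refuses singular or indefinite H₀, naming the offending eigenvalue.

## Iterative ramps on arbitrary surfaces

`run_ramp` grows the two branches from an optimized state-0 structure
(gradient norm < 1e-6) by repeating, per scheduled force magnitude:

1. **Predictor.**  Displace along the continuation direction (the
   previous displacement; ±∇ΔE at the first point) by the scalar s > 0
   solving ‖g₀ + sH₀d̂‖ − ‖g₀‖ = Δ‖F‖ on the local quadratic model
   (safeguarded 1D root bracketing).
2. **Corrector.**  On the model, decompose ∇ΔE into components parallel
   and perpendicular to ∇‖F‖² and displace so as to remove ∇ΔE⊥, then
   retract onto the constant-force level set; stop when |cos α| reaches
   the tolerance.  The displacement is the Lagrange–Newton (SQP) step of
   the model's constrained stationarity system where that solve is
   well-posed, and a proportional move along ±∇ΔE⊥ (sign per branch)
   otherwise, both under a trust radius.
3. **Verification.**  Recompute gradients (and Hessians, per policy)
   directly from the surfaces at the candidate and re-evaluate cos α.  On
   failure the expansion is refreshed at the candidate and the corrector
   resumes there.
4. **Force budget.**  Accept only points whose exact force magnitude is
   within 5% (configurable, at most 5%) of the scheduled one; otherwise
   the constant-force condition is recalculated from the refreshed
   expansion and the point is redone.
5. **Hessian policy.**  `exact` evaluates true second derivatives at
   every accepted point; `bfgs` applies the rank-two quasi-Newton update
   H′ = H − (H dq dqᵀH)/(dqᵀH dq) + (y yᵀ)/(yᵀ dq) with y the gradient
   difference between consecutive optimized points.  Both states are
   treated symmetrically (the corrector needs H₁ as much as H₀; which
   state the update serves is otherwise an open choice).  The update is
   skipped — with an exact evaluation requested instead — when the
   curvature dqᵀy falls below 1e-12‖dq‖‖y‖.

A step that fails to converge is retried twice at half the force
increment; persistent failure truncates the branch with its termination
reason recorded (`ceiling`, `non-convergence` or
`constraint-unreachable`).  The engine is deterministic given its inputs;
random seeds exist only in fixture generation.

### Numerical choices

* **Level-set retraction.**  The corrector's "constant force" promise is
  enforced by a damped Newton iteration on the model force magnitude
  along the (re-evaluated) constraint normal.  A trial move whose
  retraction fails is rejected and the step constant halved; accepted
  iterates therefore never leave the constraint and the perpendicular
  residual ‖∇ΔE⊥‖ is non-increasing by construction.  Trial moves are
  additionally capped at half the level-set radius ‖H₀⁻¹F‖ — near the
  minimum ∇ΔE can exceed the force scale by orders of magnitude, and an
  uncapped first step would orbit the (tiny) level set.
* **Corrector step control.**  The SQP step solves
  ``[W, ∇c; ∇cᵀ, 0]·[δ, δλ] = [−∇ΔE⊥, 0]`` with
  ``W = (H1−H0) − λ·2H0²`` and the least-squares multiplier λ; it removes
  every perpendicular component at once and is locally quadratically
  convergent, where single-direction moves along ∇ΔE⊥ zigzag on
  ill-conditioned tangent spaces (observed stalls of >800 iterations at
  tolerances near 1 on 29-dof pairs; the SQP step converges in under a
  dozen).  A trust radius — halved when a move is rejected because the
  perpendicular residual grew or the retraction failed, doubled on
  acceptance, never above half the level-set radius — keeps every move
  within the first-order validity of ΔE.  The proportional constant
  (default 0.5 Bohr²/Hartree, an inverse force constant) scales the
  fallback move used when the KKT solve is singular.
* **Degenerate seeding.**  When ∇ΔE vanishes at the start (stationary
  gap), the branches are seeded from the extreme eigenvectors of the
  curvature pencil (H₁ − H₀)v = 2μH₀²v — the fastest gap-raising and
  gap-lowering directions at fixed force; the same fallback reseeds a
  branch whose first point duplicates the other's sign.
* **Degenerate vectors in cos α.**  A vanishing ∇ΔE or ∇‖F‖² (e.g. the
  unforced start point) makes the parallelism condition trivial; cos α
  is reported as 1 there.
* **Tolerances.**  cos tolerance default 0.999, accepted range
  [0.99, 1]; values very close to 1 are legitimate for high-accuracy
  work and are what the closed-form comparison tests use.  Singularity
  threshold for λ solves: 1e-8 relative smallest singular value.

## Units

All computation is in Hartree, Bohr and Hartree/Bohr.  Conversions to
kcal/mol, Å and nN are derived from CODATA constants
(`scipy.constants`) in one table (`lgmf.units`); files and CSV reports
use the community units, with the boundary conversion confined to
`lgmf.io`.  Default force increment 0.05 nN ≈ 6.1e-4 Hartree/Bohr;
default ceiling 2 nN.

## Fixtures: what they emulate and what they do not

* `make_quadratic_pair(n_dof, seed, ...)` — spectral synthesis (random
  orthogonal basis × prescribed eigenvalues) of H₀ (positive definite,
  eigenvalues 0.2–2.0 Ha/Bohr², typical molecular force constants) and
  H₁ (0.1–2.5), with a random gap gradient of norm 0.05 Ha/Bohr, the
  scale of an excited-state gradient at a ground-state minimum.
  Identical seeds are bit-identical.  Quadratic pairs make the local
  model exact, so they isolate the *algorithmic* correctness of the
  ramp: any deviation from the closed form is implementation error, and
  the suite requires agreement to 1e-6 Hartree (measured ~1e-14).
* `make_model_2d_pair()` — one stiff harmonic coordinate
  (0.9 Ha/Bohr²) and one soft, strongly anharmonic coordinate (Morse
  curvature 2Da² ≈ 0.115 plus a weak harmonic 0.02), with the state-1
  minimum displaced mostly along the soft mode.  This reproduces the
  known failure regime of a single second-order expansion: moderate
  forces along a soft anharmonic mode.  The weak harmonic term exceeds
  the Morse force dip Da²/4, keeping the restoring force monotone so
  every force level set is a single closed curve; the continuation
  optimum is then also the global constrained optimum, which is what the
  dense grid oracle verifies.  Without it the surface has disconnected
  far-field level-set components near dissociation that a continuation
  method deliberately does not chase.
* What the fixtures do **not** model: electronic-structure noise,
  near-degeneracies/conical intersections between the two states,
  rotational/translational redundancy of real molecular Hessians (the
  abstract coordinate spaces have none; `tr_projector` exists for
  molecular frames), and multi-minimum landscapes.  Passing tests
  demonstrate the optimizer's correctness against exact oracles, not the
  quality of any electronic-structure method a backend supplies.

The brute-force oracle (`brute_force_optimum`, ≤ 2 dof by design) scans
a dense grid for the force level set and polishes the best candidates
with SLSQP equality-constrained optimization on the exact surfaces —
independent of every code path it validates.  Higher-dimensional
validation uses the quadratic closed form instead.

## Comparison with the single second-order prediction

The second-order prediction's geometry, evaluated on the true surface,
carries a true force different from its nominal one (force errors
dominate the failure mode, since the force depends only on the state-0
surface).  The suite therefore compares at matched *true* force: for
each ramp point, the nominal quadratic force whose predicted geometry
has the same exact ‖∇E₀‖ is found by bracketing, and the true-surface
gap variations are compared.  At matched true force the ramp point is
the exact constrained optimum, so it is never worse; the measured margin
(up to ~0.05 kcal/mol over the soft-mode ramp) quantifies the genuine
second-order suboptimality.

## Problem sizes used by the acceptance script

20 quadratic pairs of 4–30 dof ramped to 0.5 nN in 0.05 nN steps at cos
tolerance 1−1e-12; the 2D soft-mode fixture ramped to 1.2 nN in 0.1 nN
steps with grid-oracle cross-checks at three points per branch
(121-point grids); five 4-dof block-diagonal eigenproblem fixtures;
three BFGS-vs-exact ramp pairs (4, 8, 15 dof).  These sizes exercise
every code path while the closed-form and grid oracles remain exact.

## Known limitations

* Continuation only: branches are followed from the start point; optima
  on disconnected level-set components are out of scope by design.
* Cartesian coordinates throughout, as is standard for this family of
  methods; mode mixing between low- and high-frequency coordinates is a
  known error source of *single* second-order predictions that the
  iterative engine absorbs by re-expanding, but no internal-coordinate
  machinery is provided.
* No electronic structure: real molecular applications require a backend
  implementing the adapter protocol (energies/gradients per state;
  Hessians optional, finite-differenced from gradients when absent).
* `tr_projector` linearizes rotations at the instantaneous geometry;
  finite-rotation effects are negligible at the displacement scales
  involved but the projector is not exact for large rigid rotations.
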