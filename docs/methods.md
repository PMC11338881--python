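# Methods

This note documents the models implemented in `relframe`, the parameter
choices that matter, what the packaged scenarios do and do not emulate, and
the numerical decisions taken where the design was genuinely open.

## Relational algebra

A trained relation is a triple `(x, y, rel)` with a non-negative weight
(default 1).  Relation types live in a registry carrying three properties:
an optional *opposite* (with `opposite(opposite(r)) = r` enforced at
registration), *symmetry* (the type is its own opposite; the mirrored
triple is implied at query time and materialised only by closure), and
*transitivity* (same-type chains entail the end-to-end relation).  The
preloaded registry (comparatives, coordination, distinction, opposition,
hierarchy, causality, containment, kinship, deictic/temporal/spatial) is
exemplary; users register their own types.

`derive_relation(a, b)` evaluates, in order, direct lookup, mutual
entailment via the registered opposite, and combinatorial entailment
through same-type transitive chains of *any* length (graph reachability
with a visited set, so cycles terminate).  Chains are deliberately
restricted to a single relation type: composing, say, `greater_than` with
`causality` has no defined semantics, and cross-type composition is
therefore not derived.  All derivation routes are evaluated; if they
disagree the engine returns `"inconsistent"` rather than electing an
arbitrary winner, because silent arbitration would hide modelling errors in
the trained network.  A pair with no route returns `"cannot be
determined"`.

`entailment_closure` iterates mirroring and same-type transitive joins to a
fixpoint.  It is idempotent and monotone (tested properties).  Pairs that
end up carrying both a type and its registered opposite (e.g. `a > b` and
`a < b`) are listed in an inconsistency report; both triples are retained,
since deleting either would be an undeclared repair of the input.

**ToF direction.**  The transfer rule for `(s1, s2, crel)` admits two
readings: the bearer of the function can be either end.  The default,
`acquire_from_target`, has `s1` acquire `s2`'s function — this is the
direction in which "the woods *contain* the snake" makes the woods
frightening — and a flag flips it.  One call is one simultaneous pass
(labels are read from the input map), so a chain A←B←C propagates one hop
per call; `fixpoint=True` iterates until stable, with the pass count capped
at the number of licensed relations plus one so that contradictory cycles
(two stimuli each instructed to copy the other's differing label) terminate
rather than oscillate.

## Deictic frames and belief rules

The three deictic dimensions are pole pairs ((I, YOU), (HERE, THERE),
(NOW, THEN)); `shift_perspective` is an involution and anything else is a
domain error.  State labels are an open vocabulary — the machinery is
indifferent to whether labels are emotions or values.  `take_perspective`
is transient by design: it returns an event recording the prior state, and
`revert_perspective` restores it; persistence is an explicit flag on the
event.

The reference-measurement probability rule
`p(j) = Σ_{i=1..d²} [(d+1)p(i) − 1/d]·r(j|i)` is implemented over a
validated belief model (p on the simplex, r row-stochastic, absolute
tolerance 1e−9 — pure arithmetic, no data noise, so a tight tolerance is
appropriate).  Outcome indices are 1-based at the interface to mirror the
conventional Σ_{i=1}^{d²} notation.  For valid models the rule's outputs
normalise exactly: Σ_j p(j) = (d+1) − d²/d = 1, which the suite checks on
random models.  The Born rule `|⟨Φ|Ψ⟩|²` operates on unit-norm complex
vectors and is clipped to [0, 1] only against floating-point overshoot.

## Hypergraphs, I_See and RDT

Relation stores map to hypergraphs one-vertex-per-stimulus,
one-edge-per-relation, with relation types mapped to frame families
(C/D/T/S/P/HoR) through a configurable table; an unmapped type is a
configuration error, not a silent drop.  `detect_i_see(A, B)` checks, for
each required family, that some edge of that family joins {A, pA} to
{B, pB} — `pX` being agent X's perspective node by convention (overridable).
The check is a pure conjunction, hence monotone in the edge set.

**Density with parallel edges.**  The simple-dialect density
`Rp = 2E/(N(N−1))` counts *all* labeled edges among the members, parallels
included.  This is the only reading under which a three-vertex cluster
with four frame edges has density 4/3 > 1 — multigraph saturation above 1
is intended and documented, not a bug.  The weighted dialect divides the
within-cluster weight sum by a user-declared maximum.  Volume has a linear
dialect `αN + βE` (defaults α = β = 1, the scalars being introduced in the
theory without values) and a degree-weighted dialect
`Σ degreeᵢ·interaction-weightᵢ`.  Both dialect choices are config fields
because the theory states both forms without saying when each applies.

**DBSCAN.**  The clusterer is written from scratch: cores are points with
≥ MinPts neighbors within ε (self included), clusters grow by breadth-first
expansion from cores, non-core points within ε of a cluster's core become
border, the rest noise.  Points are processed in sorted order, so cluster
ids are deterministic and input-order invariant up to renaming (tested by
permutation).  The test suite cross-checks the labeling against both an
exhaustive density-reachability oracle and scikit-learn's DBSCAN.  The
metric used for hypergraph clustering is shortest-path hop count on the
2-section (clique expansion, parallel edges collapsed for distance
purposes); the theory prescribes density-based clustering but no metric,
and hop distance is the natural intrinsic choice for a labeled network.

**The `person_abc` scenario is a reconstruction.**  The published
two-cluster figure reports (density 0.60, volume 52, mass 31.20) and
(density 1.33, volume 5, mass 6.67) without printing the underlying graph.
The packaged hypergraph uses two disconnected components with (N=5, E=6)
and (N=3, E=4) — the smallest integer counts reproducing densities 0.60 and
4/3 under the simple dialect — and degree-weighted volume with packaged
per-node interaction weights chosen to give volumes 52 and 5.  DBSCAN at
ε=1, MinPts=3 over hop distance recovers exactly the two components.  The
fixture demonstrates the metric pipeline on realistic structure; it is
synthetic and should not be read as the original figure's data.

## Replicator dynamics

Discrete map `x_i' = x_i π_i(x)/φ(x)` and continuous field
`ẋ_i = x_i(f_i(x) − φ(x))`; fitness models are constant vectors or linear
frequency dependence `π_i = k_i x_i + c_i`, which covers both packaged
scenarios (prosocial `π = 3x` vs constant 1; cluster densities 4/3 vs 0.6).
All arithmetic is full precision — published chains that round
intermediates to three decimals are matched to within the propagated
rounding (±0.002 on shares, ±0.005 on payoffs that multiply a rounded share
by 3), and the cluster fitness is stored as the exact fraction 4/3 because
only the exact value reproduces the ~4.577×10⁻¹⁸ minority share after 50
generations.  Proportions are never clipped or renormalised beyond the map
itself, so extinction-level shares down to the subnormal range remain
representable.  Continuous mode integrates with classical fixed-step RK4,
default dt = 0.01 (no integrator is prescribed by the theory; RK4 at this
step is far below the model's meaningful resolution), renormalising the
simplex after each step against drift.  The Nash check declares equilibrium
iff every positive-share strategy attains the maximal current payoff and no
extinct strategy would earn strictly more.

## Contextual utility and shaped MDPs

Expected utility is computed over discrete contexts (w, s, t, i) from
explicit probability/utility tables; a row failing to sum to 1 (tolerance
1e−9) is a validation error, not a warning.  Policy evaluation solves
`V = R'_π + γP_πV` directly (LU solve) for up to 500 states and by value
iteration to residual 1e−12 beyond that; the fixed point is unique for
γ < 1 and the suite verifies Bellman residuals < 1e−10, agreement of the
two solvers, and agreement with a vectorized Monte-Carlo rollout estimator
within three standard errors.  `AV(s, a)` is a user-supplied table: the
theory does not define its construction, only its role.  The packaged
`cauldron` MDP operationalises the classic misalignment story: flooding
the workshop maximises base reward (3 vs 1) but carries AV = −2 against
+1 for the careful fill, so the shaped rewards `3 − 2λ` and `1 + λ` cross
at λ = 2/3 — below the threshold the evaluator ranks the flooding policy
higher, above it the safe policy wins.  AV is stationary; a time-varying
values signal is out of scope.

## Problem sizes and limitations

All packaged computations are desk-scale (≤ 10 vertices, ≤ 50 generations,
6-state MDPs) and run in milliseconds; property tests use ≤ 10-stimulus
stores and ≤ 32-point clouds, sizes at which the brute-force oracles are
exact.  The synthetic scenarios exercise the algebra and dynamics under
clean, noiseless conditions: they do not emulate graded or probabilistic
relational responding, relation extraction from text, learning of relation
weights from reinforcement histories, or stochastic (Moran/Wright–Fisher)
population dynamics — all explicitly out of scope.  Passing tests
demonstrate the correctness of the formal machinery, not the psychological
validity of any particular relational network.
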