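# relframe

A toolkit for computational modelling of **relational framing** — the
behavioral-psychology account of language and cognition in which verbal
behavior is responding to *derived relations* between stimuli.  It is aimed
at researchers in contextual behavioral science, computational psychology
and AI-alignment who want executable, testable versions of the constructs
they usually draw as diagrams: entailment networks, perspective-taking
frames, relational-density clusters, and values-weighted utility.

## What it computes

**Derived relational responding.**  Trained relations are triples
`(x, y, rel)` in a store with a relation-type registry (opposites, symmetry,
transitivity).  The engine derives what was never trained:

* *mutual entailment*: `(a, b, rel)` ⟹ `(b, a, opposite(rel))` — from the
  single fact "Tom Cruise is Mary Lee Pfeiffer's child" it answers the
  reverse question "who is Mary Lee Pfeiffer's child's parent-of relation"
  that purely associative systems famously fail;
* *combinatorial entailment*: same-type transitive chains of any length
  (`╪ > ╢`, `╢ > ⁂` ⟹ `⁂ < ╪`), with cycle detection and an explicit
  `"inconsistent"` verdict when derivation paths conflict;
* *transformation of stimulus function (ToF)*: with `Cfunc(snake) = fear`
  and the cue-licensed relation `(woods, snake, contains)`, the woods
  acquire the fear function.

**Deictic perspective-taking.**  The I/YOU, HERE/THERE, NOW/THEN frames as
involutive pole shifts; `i_see(A, B)` reads the observer's representation of
the target's state; `take_perspective` transforms the observer's state to
temporarily match the target's (reversibly).  Two observer-centric belief
rules are included: the subjective-Bayesian reference-measurement rule
`p(j) = Σ_i [(d+1)p(i) − 1/d]·r(j|i)` and the Born rule `|⟨Φ|Ψ⟩|²`.

**Theory-of-mind hypergraphs and Relational Density Theory (RDT).**
Relational networks become hypergraphs with frame-family labels (C, D, T, S,
P, HoR).  The composite perspective-taking structure
`I_See(A,B) ≡ C ∧ D ∧ T ∧ S` over two agents' perspective nodes is detected
by conjunction.  Clusters (found by a from-scratch DBSCAN over hop distance
on the 2-section) are scored with density `Rp = 2E/(N(N−1))`, volume
`Rv = αN + βE` (or degree-weighted), mass `Rm = Rp·Rv`, and resistance to
change `ΔR = −x/Rm`.

**Replicator dynamics.**  Discrete (`x_i' = x_i π_i / φ`) and continuous
(`ẋ_i = x_i(f_i − φ)`) selection over strategy or cluster populations with
constant or frequency-dependent fitness, plus a Nash-equilibrium check.

**Values-shaped utility.**  Contextual expected utility
`EU(A) = Σ_o P_A(o|w,s,t,i)·U(o,w,s,t,i)` and tabular-MDP policy evaluation
under the shaped reward `R'(s,a) = R(s,a) + λ·AV(s,a)`, where `AV` is a
user-supplied values-alignment table.

## Worked example

```sh
$ relframe demo --only replicator
relframe 0.1.0 demo (seed=0)
[PASS] replicator: prosocial mean fitness at t=0: computed 1.08, expected 1.08
[PASS] replicator: prosocial share after one generation: computed 0.4444444444444445, expected 0.444
[PASS] replicator: generation-1 prosocial payoff: computed 1.3333333333333335, expected 1.332
[PASS] replicator: generation-1 mean fitness: computed 1.1481481481481481, expected 1.147
[PASS] replicator: prosocial share after two generations: computed 0.5161290322580646, expected 0.515
[PASS] replicator: generation-2 prosocial payoff: computed 1.548387096774194, expected 1.545
[PASS] replicator: mixed state is not an equilibrium: computed False, expected False
[PASS] replicator: all-cooperator state is a Nash equilibrium: computed True, expected True
[PASS] replicator: cluster AB share after one generation: computed 0.6896551724137931, expected 0.688
[PASS] replicator: cluster AB dominates after 50 generations: computed 1.0, expected 1.0
[PASS] replicator: cluster C extinction share after 50 generations: computed 4.577471919127268e-18, expected 4.577e-18
11/11 checks passed
```

Cooperators earning a frequency-dependent payoff `π = 3x` overtake
constant-payoff isolates from a 40/60 minority start (`0.400 → 0.444 →
0.516`), and the all-cooperator state is the Nash equilibrium.  When two
relational clusters compete with fitness equal to their densities (4/3 vs
0.60), the sparser cluster's share collapses to ~4.6×10⁻¹⁸ in 50
generations — denser relational networks are evolutionarily dominant.
`relframe demo` with no filter additionally runs the entailment, ToF,
perspective-taking, density-clustering and cauldron-MDP examples
(29 checks); it exits non-zero if any check fails.

From Python:

```python
from relframe import Relation, RelationStore, derive_relation

store = RelationStore()
store.add(Relation("╪", "╢", "bigger_than"))
store.add(Relation("╢", "⁂", "bigger_than"))
print(derive_relation(store, "⁂", "╪"))   # smaller_than
```

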