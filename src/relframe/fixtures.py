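"""Packaged worked-example scenarios.

Each builder returns in-memory objects; :func:`generate_fixture` writes the
same scenario to disk deterministically (identical name + seed → byte
identical files; the seed is recorded in a manifest next to the data).

Scenarios
---------
snake_woods
    Transformation of stimulus function: a feared snake and the woods that
    contain it, plus the two-agent pain/neutral perspective-taking states.
person_abc
    Reconstruction of a two-cluster perspective-taking hypergraph: a rich
    five-vertex cluster around Person A (simple density 0.60, degree-weighted
    volume 52, mass 31.20) and a sparse three-vertex cluster around Person B
    (density 4/3, volume 5, mass 6.67).  The underlying vertex/edge counts
    and interaction weights are a synthetic reconstruction chosen to realise
    those published cluster metrics; they are not measured data.
prosocial
    Frequency-dependent replicator model: cooperators earn π = 3x, isolates
    a constant 1, starting from a 40/60 split.
cluster_evolution
    Constant-fitness replicator model where two relational clusters compete
    with fitness equal to their densities (4/3 vs 0.6) from an equal start.
    The exact fraction 4/3 (not the printed 1.33) is used: only the exact
    value reproduces the ~4.6e-18 minority share after 50 generations.
reversal_curse
    A single trained child_of relation from which mutual entailment answers
    the reverse (parent_of) query.
cauldron
    Toy values-alignment MDP: flooding the workshop maximises base reward,
    a careful fill maximises the values score; the shaping weight λ flips
    the better policy at the documented threshold 2/3.
"""

from __future__ import annotations

import json
from pathlib import Path

from .deictic import AgentState, AgentStateMap
from .errors import ConfigurationError
from .hypergraph import DbscanParams, FrameEdge, Hypergraph, RdtConfig
from .relations import ContextCue, FunctionMap, Relation, RelationStore, default_registry
from .replicator import FitnessModel, Population
from .values import TabularMDP
from . import io as rio

__all__ = [
    "FIXTURE_NAMES",
    "snake_woods",
    "person_abc",
    "prosocial",
    "cluster_evolution",
    "reversal_curse",
    "cauldron",
    "CAULDRON_LAMBDA_THRESHOLD",
    "generate_fixture",
]

FIXTURE_NAMES = (
    "snake_woods",
    "person_abc",
    "prosocial",
    "cluster_evolution",
    "reversal_curse",
    "cauldron",
)

#: λ above which the cauldron MDP's optimal policy flips to the safe action
#: (shaped rewards 1 + λ vs 3 − 2λ cross at λ = 2/3).
CAULDRON_LAMBDA_THRESHOLD = 2.0 / 3.0


def snake_woods() -> tuple[RelationStore, FunctionMap, ContextCue, AgentStateMap]:
    """ToF inputs plus the p1/p2 perspective-taking states."""
    store = RelationStore(default_registry())
    store.add(Relation("woods", "snake", "contains"))
    fmap = FunctionMap({"snake": "fear", "woods": "neutral"})
    cue = ContextCue("contains")
    states = AgentStateMap(
        [
            AgentState("p1", "neutral", "t1"),
            AgentState("p2", "pain", "t1"),
        ]
    )
    return store, fmap, cue, states


def person_abc() -> tuple[Hypergraph, DbscanParams, RdtConfig]:
    """Two disconnected perspective-taking clusters with packaged RDT config.

    Cluster around Person A: vertices {A, pA, pAB, snake, woods} (pA = A's
    own perspective node, pAB = A's representation of B) with 6 frame
    edges; cluster around Person B: {B, pB, pBA} with 4 edges.  Hop-distance
    DBSCAN at ε=1, MinPts=3 recovers exactly these two components.
    """
    h = Hypergraph(["A", "pA", "pAB", "snake", "woods", "B", "pB", "pBA"])
    for e in [
        FrameEdge(("A", "pA"), "P"),
        FrameEdge(("pA", "pAB"), "C"),
        FrameEdge(("pA", "pAB"), "D"),
        FrameEdge(("pA", "snake"), "T", context=(("t1", "THEN"), ("t2", "NOW"))),
        FrameEdge(("pA", "woods"), "S", context=(("loc1", "THERE"), ("loc2", "HERE"))),
        FrameEdge(("snake", "woods"), "C"),
        FrameEdge(("B", "pB"), "P"),
        FrameEdge(("pB", "pBA"), "C"),
        FrameEdge(("pB", "pBA"), "D"),
        FrameEdge(("B", "pBA"), "C"),
    ]:
        h.add_edge(e)
    params = DbscanParams(eps=1.0, min_pts=3)
    config = RdtConfig(
        density_dialect="simple",
        volume_dialect="degree_weighted",
        interaction_weights={
            "pA": 8.0, "pAB": 2.0, "snake": 2.0, "A": 2.0, "woods": 1.0,
            "B": 1.0, "pB": 0.5, "pBA": 0.5,
        },
    )
    return h, params, config


def prosocial() -> tuple[Population, FitnessModel]:
    """Prosocial (π = 3x) vs isolate (π = 1) from a 40/60 split."""
    pop = Population(["prosocial", "isolate"], [0.4, 0.6])
    fm = FitnessModel(
        "linear_frequency", {"prosocial": (3.0, 0.0), "isolate": (0.0, 1.0)}
    )
    return pop, fm


def cluster_evolution() -> tuple[Population, FitnessModel]:
    """Two relational clusters competing with density-valued fitness."""
    pop = Population(["AB", "C"], [0.5, 0.5])
    fm = FitnessModel("density_table", {"AB": 4.0 / 3.0, "C": 0.6})
    return pop, fm


def reversal_curse() -> RelationStore:
    """One trained child_of triple; the reverse query is derived, not trained."""
    store = RelationStore(default_registry())
    store.add(Relation("Tom Cruise", "Mary Lee Pfeiffer", "child_of"))
    return store


def cauldron(lam: float = 0.0, gamma: float = 0.9) -> TabularMDP:
    """Toy workshop MDP: fast flooding pays, careful filling aligns.

    From ``filling`` the agent either fills carefully (always reaches
    ``full``, base reward 1, values score +1) or floods the workshop for
    speed (reward 3, values score −2, half the time ending ``flooded``).
    Terminal states absorb with zero reward.  Unshaped (λ = 0) the flooding
    action dominates; above λ = 2/3 the shaped reward favors the careful
    fill.
    """
    states = ("filling", "full", "flooded")
    actions = ("careful", "fast")
    transition = {
        ("filling", "careful"): {"full": 1.0},
        ("filling", "fast"): {"full": 0.5, "flooded": 0.5},
    }
    base = {("filling", "careful"): 1.0, ("filling", "fast"): 3.0}
    av = {("filling", "careful"): 1.0, ("filling", "fast"): -2.0}
    for s in ("full", "flooded"):
        for a in actions:
            transition[(s, a)] = {s: 1.0}
            base[(s, a)] = 0.0
            av[(s, a)] = 0.0
    return TabularMDP(states, actions, transition, base, av, gamma, lam)


def generate_fixture(name: str, outdir: str | Path, seed: int = 0) -> list[Path]:
    """Write the named scenario's files under ``outdir``; returns the paths.

    Every scenario is fully determined; the seed is recorded in the
    manifest so downstream runs can propagate it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(path: Path) -> Path:
        written.append(path)
        return path

    if name == "snake_woods":
        store, fmap, cue, states = snake_woods()
        rio.write_relations(store, emit(outdir / "relations.csv"))
        rio.write_function_map(fmap, emit(outdir / "functions.csv"))
        lines = ["agent,time,state"] + [
            f"{a},{t},{s}" for (a, t), s in states.items()
        ]
        emit(outdir / "states.csv").write_text("\n".join(lines) + "\n", encoding="utf-8")
        emit(outdir / "cue.json").write_text(
            json.dumps({"crel": cue.crel}) + "\n", encoding="utf-8"
        )
    elif name == "person_abc":
        h, params, config = person_abc()
        emit(outdir / "hypergraph.json").write_text(
            json.dumps(rio.hypergraph_to_json(h), indent=1, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        emit(outdir / "rdt_config.json").write_text(
            json.dumps(
                {
                    "eps": params.eps,
                    "min_pts": params.min_pts,
                    "density_dialect": config.density_dialect,
                    "volume_dialect": config.volume_dialect,
                    "alpha": config.alpha,
                    "beta": config.beta,
                    "interaction_weights": config.interaction_weights,
                },
                indent=1,
                sort_keys=True,
            )
            + "\n",
            encoding="utf-8",
        )
    elif name in ("prosocial", "cluster_evolution"):
        pop, fm = prosocial() if name == "prosocial" else cluster_evolution()
        params = {
            k: list(v) if isinstance(v, tuple) else v for k, v in fm.params.items()
        }
        config = {
            "labels": list(pop.labels),
            "x0": [float(v) for v in pop.proportions],
            "fitness": {"kind": fm.kind, "params": params},
            "steps": 50,
            "mode": "discrete",
        }
        emit(outdir / "replicator.json").write_text(
            json.dumps(config, indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )
    elif name == "reversal_curse":
        store = reversal_curse()
        rio.write_relations(store, emit(outdir / "relations.csv"))
        emit(outdir / "query.json").write_text(
            json.dumps(
                {"a": "Mary Lee Pfeiffer", "b": "Tom Cruise", "expect": "parent_of"},
                indent=1,
                sort_keys=True,
            )
            + "\n",
            encoding="utf-8",
        )
    elif name == "cauldron":
        mdp = cauldron()
        data = {
            "states": list(mdp.states),
            "actions": list(mdp.actions),
            "transition": _nest(mdp.transition),
            "base_reward": _nest(mdp.base_reward),
            "act_value": _nest(mdp.act_value),
            "gamma": mdp.gamma,
            "lambda": mdp.lam,
            "lambda_threshold": CAULDRON_LAMBDA_THRESHOLD,
        }
        emit(outdir / "mdp.json").write_text(
            json.dumps(data, indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )
    else:
        raise ConfigurationError(
            f"unknown fixture {name!r}; known fixtures: {', '.join(FIXTURE_NAMES)}"
        )

    emit(outdir / "manifest.json").write_text(
        json.dumps({"fixture": name, "seed": int(seed)}, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return written


def _nest(table: dict) -> dict:
    out: dict = {}
    for (s, a), v in sorted(table.items()):
        out.setdefault(s, {})[a] = v
    return out
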