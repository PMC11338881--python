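"""Readers and writers for the toolkit's file formats.

Tabular formats are UTF-8 CSV with a required header, comma separator and
"." decimal point; structured formats are JSON (YAML accepted for
replicator configs).  All writers are deterministic: keys are emitted in
sorted order and floats are formatted with 12 significant digits, so
identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .deictic import AgentState, AgentStateMap, BeliefModel
from .errors import InputFormatError
from .hypergraph import ClusterMetrics, FrameEdge, Hypergraph
from .relations import (
    FunctionMap,
    Relation,
    RelationStore,
    RelationType,
    TypeRegistry,
    default_registry,
)
from .replicator import FitnessModel, Population, Trajectory
from .values import TabularMDP

__all__ = [
    "read_relations",
    "write_relations",
    "read_registry",
    "write_registry",
    "read_function_map",
    "write_function_map",
    "read_agent_states",
    "read_belief_model",
    "hypergraph_to_json",
    "hypergraph_from_json",
    "write_graphml",
    "write_dot",
    "write_cluster_report",
    "read_replicator_config",
    "write_trajectory",
    "read_mdp",
    "write_value_table",
    "fmt",
]


def fmt(x: float) -> str:
    """Deterministic float formatting: 12 significant digits."""
    return format(float(x), ".12g")


def _infer_format(path: str | Path, fmt_arg: str | None) -> str:
    if fmt_arg:
        return fmt_arg
    suffix = Path(path).suffix.lower().lstrip(".")
    return {"yml": "yaml"}.get(suffix, suffix or "csv")


# -- relation stores -------------------------------------------------------------


def read_relations(
    path: str | Path,
    format: str | None = None,
    registry: TypeRegistry | None = None,
    *,
    normalize: bool = False,
) -> RelationStore:
    """Load a relation edge list (CSV ``x,y,rel,weight`` or JSON array).

    ``normalize=True`` opt-in trims whitespace and casefolds stimulus ids;
    by default labels are case-sensitive exact strings.
    """
    path = Path(path)
    fmt_ = _infer_format(path, format)
    store = RelationStore(registry or default_registry())

    def norm(s: str) -> str:
        return s.strip().casefold() if normalize else s

    if fmt_ == "csv":
        try:
            df = pd.read_csv(path, dtype=str)
        except pd.errors.EmptyDataError:
            raise InputFormatError(f"empty relation file {path}") from None
        required = {"x", "y", "rel"}
        if not required <= set(df.columns):
            raise InputFormatError(
                f"missing header columns {sorted(required - set(df.columns))} in {path}"
            )
        for pos, row in df.iterrows():
            line = int(pos) + 2  # header is line 1
            if row[["x", "y", "rel"]].isna().any():
                raise InputFormatError("row is missing x/y/rel", line=line)
            weight = 1.0
            if "weight" in df.columns and pd.notna(row.get("weight")):
                try:
                    weight = float(row["weight"])
                except ValueError:
                    raise InputFormatError(
                        f"bad weight {row['weight']!r}", line=line
                    ) from None
            store.add(Relation(norm(row["x"]), norm(row["y"]), row["rel"].strip(), weight))
    elif fmt_ == "json":
        rows = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(rows, list):
            raise InputFormatError(f"{path}: JSON relations must be an array of objects")
        for k, row in enumerate(rows):
            try:
                store.add(
                    Relation(
                        norm(row["x"]), norm(row["y"]), row["rel"],
                        float(row.get("weight", 1.0)),
                    )
                )
            except KeyError as e:
                raise InputFormatError(f"object {k} is missing key {e}") from None
    else:
        raise InputFormatError(f"unknown relation format {fmt_!r}")
    if len(store) == 0:
        raise InputFormatError(f"no relations found in {path}")
    return store


def write_relations(store: RelationStore, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt_ = _infer_format(path, format)
    rows = [
        {"x": r.x, "y": r.y, "rel": r.rel, "weight": float(r.weight)} for r in store
    ]
    if fmt_ == "csv":
        lines = ["x,y,rel,weight"]
        lines += [f"{r['x']},{r['y']},{r['rel']},{fmt(r['weight'])}" for r in rows]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif fmt_ == "json":
        path.write_text(json.dumps(rows, indent=1, sort_keys=True) + "\n", encoding="utf-8")
    else:
        raise InputFormatError(f"unknown relation format {fmt_!r}")


def read_registry(path: str | Path) -> TypeRegistry:
    """JSON mapping name → {opposite, symmetric, transitive}."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    reg = TypeRegistry()
    for name, spec in sorted(data.items()):
        reg.register(
            RelationType(
                name,
                opposite=spec.get("opposite"),
                symmetric=bool(spec.get("symmetric", False)),
                transitive=bool(spec.get("transitive", False)),
            )
        )
    return reg


def write_registry(reg: TypeRegistry, path: str | Path) -> None:
    data = {
        t.name: {
            "opposite": t.opposite,
            "symmetric": t.symmetric,
            "transitive": t.transitive,
        }
        for t in reg
    }
    Path(path).write_text(json.dumps(data, indent=1, sort_keys=True) + "\n", encoding="utf-8")


# -- function maps and agent states ----------------------------------------------


def read_function_map(path: str | Path, format: str | None = None) -> FunctionMap:
    path = Path(path)
    fmt_ = _infer_format(path, format)
    if fmt_ == "csv":
        df = pd.read_csv(path, dtype=str)
        if not {"stimulus", "function"} <= set(df.columns):
            raise InputFormatError(f"function map {path} needs header stimulus,function")
        return FunctionMap(dict(zip(df["stimulus"], df["function"])))
    if fmt_ == "json":
        return FunctionMap(json.loads(path.read_text(encoding="utf-8")))
    raise InputFormatError(f"unknown function-map format {fmt_!r}")


def write_function_map(fmap: FunctionMap, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt_ = _infer_format(path, format)
    if fmt_ == "csv":
        lines = ["stimulus,function"]
        lines += [f"{s},{f}" for s, f in sorted(fmap.entries.items())]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif fmt_ == "json":
        path.write_text(
            json.dumps(fmap.entries, indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )
    else:
        raise InputFormatError(f"unknown function-map format {fmt_!r}")


def read_agent_states(path: str | Path) -> AgentStateMap:
    """CSV ``agent,time,state`` → state map."""
    df = pd.read_csv(path, dtype=str)
    if not {"agent", "time", "state"} <= set(df.columns):
        raise InputFormatError(f"agent states {path} need header agent,time,state")
    return AgentStateMap(
        [AgentState(row["agent"], row["state"], row["time"]) for _, row in df.iterrows()]
    )


def read_belief_model(path: str | Path) -> BeliefModel:
    """JSON {d, p: [...], r: [[...], ...]} with r rows indexed by i."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    try:
        return BeliefModel(int(data["d"]), data["p"], data["r"])
    except KeyError as e:
        raise InputFormatError(f"belief model {path} is missing key {e}") from None


# -- hypergraphs -----------------------------------------------------------------


def hypergraph_to_json(h: Hypergraph) -> dict:
    return {
        "vertices": sorted(h.vertices),
        "edges": [
            {
                "members": list(e.members),
                "label": e.label,
                "weight": float(e.weight),
                "context": dict(e.context),
            }
            for e in sorted(h.edges, key=lambda e: (e.label, e.members))
        ],
    }


def hypergraph_from_json(data: dict | str | Path) -> Hypergraph:
    if not isinstance(data, dict):
        data = json.loads(Path(data).read_text(encoding="utf-8"))
    h = Hypergraph(data.get("vertices", []))
    for e in data.get("edges", []):
        h.add_edge(
            FrameEdge(
                tuple(e["members"]),
                e["label"],
                float(e.get("weight", 1.0)),
                tuple(sorted((e.get("context") or {}).items())),
            )
        )
    return h


def write_graphml(h: Hypergraph, path: str | Path) -> None:
    """GraphML export with each hyperedge reified as an auxiliary labeled node.

    GraphML has no native hyperedges, so edge k becomes a node ``he<k>`` of
    kind "hyperedge" connected to each of its members; vertex nodes carry
    kind "vertex".  Structure-preserving and lossless up to edge ordering.
    """
    import networkx as nx

    g = nx.Graph()
    for v in sorted(h.vertices):
        g.add_node(v, kind="vertex")
    for k, e in enumerate(sorted(h.edges, key=lambda e: (e.label, e.members))):
        he = f"he{k}"
        g.add_node(he, kind="hyperedge", label=e.label, weight=float(e.weight))
        for m in e.members:
            g.add_edge(he, m)
    nx.write_graphml(g, str(path))


def write_dot(h: Hypergraph, path: str | Path, layout_hint: str | None = None) -> None:
    """DOT export with the same hyperedge reification as the GraphML writer.

    ``layout_hint`` is written as a graph attribute annotation only; it
    never alters the structure.
    """
    lines = ["graph relframe {"]
    if layout_hint:
        lines.append(f'  layout="{layout_hint}";')
    for v in sorted(h.vertices):
        lines.append(f'  "{v}" [shape=ellipse];')
    for k, e in enumerate(sorted(h.edges, key=lambda e: (e.label, e.members))):
        he = f"he{k}"
        lines.append(
            f'  "{he}" [shape=point, xlabel="{e.label}", weight="{fmt(e.weight)}"];'
        )
        for m in e.members:
            lines.append(f'  "{he}" -- "{m}";')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_cluster_report(rows: list[ClusterMetrics], path: str | Path) -> None:
    lines = ["cluster_id,n_vertices,n_edges,Rp,Rv,Rm"]
    for m in rows:
        lines.append(
            f"{m.cluster_id},{m.n_vertices},{m.n_edges},{fmt(m.Rp)},{fmt(m.Rv)},{fmt(m.Rm)}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# -- replicator ------------------------------------------------------------------


def read_replicator_config(path: str | Path) -> tuple[Population, FitnessModel, dict]:
    """YAML/JSON {labels, x0, fitness: {kind, params}, steps, mode, dt}."""
    path = Path(path)
    fmt_ = _infer_format(path, None)
    text = path.read_text(encoding="utf-8")
    data = yaml.safe_load(text) if fmt_ in ("yaml",) else json.loads(text)
    try:
        labels = list(data["labels"])
        pop = Population(labels, data["x0"])
        fitness = data["fitness"]
        params = {
            k: tuple(v) if isinstance(v, (list, tuple)) else v
            for k, v in fitness["params"].items()
        }
        fm = FitnessModel(fitness["kind"], params)
    except KeyError as e:
        raise InputFormatError(f"replicator config {path} is missing key {e}") from None
    options = {
        "steps": int(data.get("steps", 50)),
        "mode": data.get("mode", "discrete"),
        "dt": float(data.get("dt", 0.01)),
    }
    return pop, fm, options


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """CSV ``generation,<label>...,phi``."""
    header = ["generation", *traj.labels, "phi"]
    lines = [",".join(header)]
    for g, x, phi in zip(traj.generations, traj.proportions, traj.mean_fitness):
        lines.append(",".join([str(g), *(fmt(v) for v in x), fmt(phi)]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# -- MDPs ------------------------------------------------------------------------


def read_mdp(path: str | Path) -> TabularMDP:
    """JSON {states, actions, transition, base_reward, act_value, gamma, lambda}.

    ``transition`` is nested ``{state: {action: {next_state: prob}}}``;
    reward and AV tables are nested ``{state: {action: value}}``.
    """
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    try:
        transition = {
            (s, a): dict(row)
            for s, by_action in data["transition"].items()
            for a, row in by_action.items()
        }
        base = {
            (s, a): float(v)
            for s, by_action in data["base_reward"].items()
            for a, v in by_action.items()
        }
        av = {
            (s, a): float(v)
            for s, by_action in data["act_value"].items()
            for a, v in by_action.items()
        }
        return TabularMDP(
            states=tuple(data["states"]),
            actions=tuple(data["actions"]),
            transition=transition,
            base_reward=base,
            act_value=av,
            gamma=float(data["gamma"]),
            lam=float(data.get("lambda", 0.0)),
        )
    except KeyError as e:
        raise InputFormatError(f"MDP spec {path} is missing key {e}") from None


def write_value_table(V: Mapping[str, float], path: str | Path) -> None:
    lines = ["state,V"]
    lines += [f"{s},{fmt(v)}" for s, v in sorted(V.items())]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
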