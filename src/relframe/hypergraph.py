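"""Relational-frame hypergraphs, theory-of-mind detection and density metrics.

A relational network is carried as a hypergraph H = (V, E): vertices are
concepts or agents, each hyperedge groups ≥2 vertices under a frame-family
label — C (coordination), D (distinction), T (temporal), S (spatial),
P (deictic/perspective), HoR (higher-order relation).  Parallel edges with
different labels are allowed: the same pair of concepts is routinely related
by several frames at once, and that multiplicity is exactly what the density
metrics measure.

Relational Density Theory (RDT) treats such networks with physics-style
quantities:

* density   Rp = 2E / (N(N−1))   (simple dialect; E counts *all* labeled
  edges among the members, parallels included, so Rp may exceed 1),
* volume    Rv = αN + βE         (linear dialect) or Σ degreeᵢ·weightᵢ
  (degree-weighted dialect),
* mass      Rm = Rp × Rv,
* resistance to change ΔR = −x / Rm for a counterforce x.

Dense, voluminous clusters are behaviorally dominant and resist change.
Clusters are found with DBSCAN over hop distance on the hypergraph's
2-section; the DBSCAN here is written from scratch because the tailored
core/border/noise bookkeeping over graph distances is itself part of the
method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx

from .errors import ConfigurationError, DomainError
from .relations import RelationStore

__all__ = [
    "FRAME_FAMILIES",
    "DEFAULT_FAMILY_MAP",
    "FrameEdge",
    "Hypergraph",
    "ClusterMetrics",
    "DbscanParams",
    "DbscanLabeling",
    "RdtConfig",
    "build_hypergraph",
    "detect_i_see",
    "relational_density",
    "relational_volume",
    "relational_mass",
    "resistance_to_change",
    "hop_distance",
    "dbscan",
    "cluster_report",
]

FRAME_FAMILIES = ("C", "D", "T", "S", "P", "HoR")

#: Default relation-type → frame-family mapping used by :func:`build_hypergraph`.
DEFAULT_FAMILY_MAP: dict[str, str] = {
    "coordination": "C",
    "distinction": "D",
    "temporal": "T",
    "spatial": "S",
    "deictic": "P",
    "opposition": "D",
    "hierarchy": "HoR",
    "causality": "HoR",
    "contains": "HoR",
    **{f: f for f in FRAME_FAMILIES},
}


@dataclass(frozen=True)
class FrameEdge:
    """A labeled frame hyperedge over ≥2 vertices."""

    members: tuple[str, ...]
    label: str
    weight: float = 1.0
    context: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise DomainError("a frame edge needs at least two members")
        if self.label not in FRAME_FAMILIES:
            raise ConfigurationError(
                f"unknown frame family {self.label!r}; known: {FRAME_FAMILIES}"
            )
        if self.weight <= 0:
            raise ConfigurationError("edge weight must be positive")

    @property
    def context_dict(self) -> dict[str, str]:
        return dict(self.context)


class Hypergraph:
    """Vertices plus labeled frame hyperedges (parallel edges allowed)."""

    def __init__(self, vertices: Iterable[str] = (), edges: Iterable[FrameEdge] = ()):
        self.vertices: set[str] = set(vertices)
        self.edges: list[FrameEdge] = []
        for e in edges:
            self.add_edge(e)

    def add_vertex(self, v: str) -> None:
        self.vertices.add(v)

    def add_edge(self, e: FrameEdge) -> None:
        missing = set(e.members) - self.vertices
        if missing:
            raise DomainError(f"edge members {sorted(missing)} are not vertices")
        if e not in self.edges:  # parallel edges differ in label/weight/context
            self.edges.append(e)

    def edges_among(self, members: set[str]) -> list[FrameEdge]:
        """Edges whose member set lies entirely within ``members``."""
        return [e for e in self.edges if set(e.members) <= members]

    def degree(self, v: str) -> int:
        """Number of edge incidences of ``v`` (parallel edges all count)."""
        return sum(1 for e in self.edges if v in e.members)

    def two_section(self) -> nx.Graph:
        """Clique expansion with parallel edges collapsed (for distances)."""
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        for e in self.edges:
            m = list(e.members)
            for i in range(len(m)):
                for j in range(i + 1, len(m)):
                    g.add_edge(m[i], m[j])
        return g


def build_hypergraph(
    store: RelationStore,
    states: Mapping[str, str] | None = None,
    family_map: Mapping[str, str] | None = None,
) -> Hypergraph:
    """Deterministic structure-preserving map from a relation store to a hypergraph.

    One vertex per stimulus, one frame edge per relation (label via
    ``family_map``, weight carried over).  Optional agent states are attached
    as edge context on nothing — they become vertex annotations via the
    returned graph's ``vertex_states`` attribute.
    """
    fmap = dict(DEFAULT_FAMILY_MAP)
    if family_map:
        fmap.update(family_map)
    h = Hypergraph(store.stimuli)
    for r in store:
        if r.rel not in fmap:
            raise ConfigurationError(
                f"relation type {r.rel!r} has no frame-family mapping"
            )
        h.add_edge(FrameEdge((r.x, r.y), fmap[r.rel], r.weight))
    h.vertex_states = dict(states or {})  # type: ignore[attr-defined]
    return h


def detect_i_see(
    h: Hypergraph,
    a: str,
    b: str,
    required: Iterable[str] = ("C", "D", "T", "S"),
    *,
    perspective_nodes: Mapping[str, str] | None = None,
) -> tuple[bool, list[FrameEdge]]:
    """Detect the composite I_See(A,B) perspective-taking structure.

    I_See(A,B) holds iff for *every* required frame family there is an edge
    of that family containing both ``a`` and ``b`` — or both their
    perspective nodes.  By convention agent X's perspective node is ``pX``;
    pass ``perspective_nodes`` to override the mapping.  Returns the truth
    value and the witnessing edges (one per family when true).  Monotone:
    adding edges can only turn false into true.
    """
    if a not in h.vertices or b not in h.vertices:
        raise DomainError(f"unknown agent among {a!r}, {b!r}")
    pmap = dict(perspective_nodes or {})
    targets = {a, pmap.get(a, f"p{a}")}, {b, pmap.get(b, f"p{b}")}
    witnesses: list[FrameEdge] = []
    for fam in required:
        found = None
        for e in sorted(h.edges, key=lambda e: (e.label, e.members)):
            if e.label != fam:
                continue
            mem = set(e.members)
            if mem & targets[0] and mem & targets[1]:
                found = e
                break
        if found is None:
            return False, []
        witnesses.append(found)
    return True, witnesses


@dataclass(frozen=True)
class ClusterMetrics:
    """RDT metrics of one cluster; Rm = Rp × Rv holds exactly."""

    cluster_id: int
    members: tuple[str, ...]
    n_vertices: int
    n_edges: int
    Rp: float
    Rv: float

    @property
    def Rm(self) -> float:
        return self.Rp * self.Rv


def relational_density(
    h: Hypergraph,
    members: set[str],
    dialect: str = "simple",
    *,
    max_possible_weight: float | None = None,
) -> float:
    """Relational density Rp of the sub-network induced by ``members``.

    simple:   2E / (N(N−1)) with E counting all labeled edges (parallel
              edges included) among the members — a multigraph can exceed 1.
    weighted: Σ within-cluster edge weights / ``max_possible_weight``.
    """
    if len(members) < 2:
        raise DomainError("density needs at least two member vertices")
    edges = h.edges_among(members)
    n = len(members)
    if dialect == "simple":
        return 2.0 * len(edges) / (n * (n - 1))
    if dialect == "weighted":
        if not max_possible_weight or max_possible_weight <= 0:
            raise ConfigurationError(
                "weighted density needs a positive max_possible_weight"
            )
        return sum(e.weight for e in edges) / max_possible_weight
    raise ConfigurationError(f"unknown density dialect {dialect!r}")


def relational_volume(
    h: Hypergraph,
    members: set[str],
    alpha: float = 1.0,
    beta: float = 1.0,
    dialect: str = "linear",
    *,
    interaction_weights: Mapping[str, float] | None = None,
) -> float:
    """Relational volume Rv of a cluster.

    linear:          αN + βE  (α, β ≥ 0 weigh vertices against edges).
    degree_weighted: Σ over members of degree × interaction weight, with
                     per-vertex interaction weights defaulting to 1.
    """
    if alpha < 0 or beta < 0:
        raise ConfigurationError("volume scaling factors must be non-negative")
    if not members:
        return 0.0
    if dialect == "linear":
        return alpha * len(members) + beta * len(h.edges_among(members))
    if dialect == "degree_weighted":
        w = dict(interaction_weights or {})
        return float(sum(h.degree(v) * w.get(v, 1.0) for v in members))
    raise ConfigurationError(f"unknown volume dialect {dialect!r}")


def relational_mass(Rp: float, Rv: float) -> float:
    """Relational mass Rm = Rp × Rv."""
    if Rp < 0 or Rv < 0:
        raise DomainError("density and volume must be non-negative")
    return Rp * Rv


def resistance_to_change(Rm: float, counterforce: float) -> float:
    """Change in relational responding ΔR = −x / Rm under counterforce x."""
    if Rm == 0:
        raise ZeroDivisionError("resistance to change undefined for zero mass")
    if Rm < 0:
        raise DomainError("relational mass must be positive")
    return -counterforce / Rm


@dataclass(frozen=True)
class DbscanParams:
    """ε-neighborhood radius and MinPts core threshold."""

    eps: float
    min_pts: int

    def __post_init__(self) -> None:
        if self.eps < 0:
            raise ConfigurationError("eps must be non-negative")
        if self.min_pts < 1:
            raise ConfigurationError("min_pts must be at least 1")


@dataclass
class DbscanLabeling:
    """Cluster assignment plus the core/border/noise role of every point."""

    cluster: dict[str, int | None] = field(default_factory=dict)
    role: dict[str, str] = field(default_factory=dict)  # core | border | noise

    @property
    def cluster_ids(self) -> list[int]:
        return sorted({c for c in self.cluster.values() if c is not None})

    def members_of(self, cid: int) -> set[str]:
        return {p for p, c in self.cluster.items() if c == cid}


def hop_distance(h: Hypergraph) -> Callable[[str, str], float]:
    """Shortest-path hop count on the 2-section; disconnected pairs are ∞."""
    g = h.two_section()
    lengths = dict(nx.all_pairs_shortest_path_length(g))

    def dist(u: str, v: str) -> float:
        return float(lengths.get(u, {}).get(v, float("inf")))

    return dist


def dbscan(
    points: Sequence[str],
    distance: Callable[[str, str], float],
    params: DbscanParams,
) -> DbscanLabeling:
    """Density-based clustering with explicit core/border/noise roles.

    A point is *core* when its ε-neighborhood (itself included) holds at
    least MinPts points.  Clusters are grown by recursive expansion from
    unassigned cores: every neighbor of a core joins the cluster, and
    neighbors that are themselves cores propagate the expansion.  Points
    within ε of a core that are not cores become *border*; the rest is
    *noise*.  Points are visited in sorted order so cluster ids are
    deterministic and independent of input order (up to renaming).
    """
    pts = sorted(points)
    neigh = {
        p: {q for q in pts if distance(p, q) <= params.eps} for p in pts
    }
    core = {p for p in pts if len(neigh[p]) >= params.min_pts}

    labeling = DbscanLabeling(
        cluster={p: None for p in pts},
        role={p: "noise" for p in pts},
    )
    next_id = 0
    for p in pts:
        if p not in core or labeling.cluster[p] is not None:
            continue
        cid = next_id
        next_id += 1
        # expandCluster: breadth-first over density-reachable points
        queue = [p]
        labeling.cluster[p] = cid
        labeling.role[p] = "core"
        while queue:
            q = queue.pop(0)
            if q not in core:
                continue
            for m in sorted(neigh[q]):
                if labeling.cluster[m] is None:
                    labeling.cluster[m] = cid
                    labeling.role[m] = "core" if m in core else "border"
                    if m in core:
                        queue.append(m)
                elif labeling.role[m] == "noise":
                    # previously unreachable point within ε of this core
                    labeling.cluster[m] = cid
                    labeling.role[m] = "border"
    return labeling


@dataclass
class RdtConfig:
    """Which RDT dialects and parameters a cluster report uses."""

    density_dialect: str = "simple"
    volume_dialect: str = "linear"
    alpha: float = 1.0
    beta: float = 1.0
    max_possible_weight: float | None = None
    interaction_weights: dict[str, float] = field(default_factory=dict)


def cluster_report(
    h: Hypergraph,
    labeling: DbscanLabeling,
    config: RdtConfig | None = None,
) -> list[ClusterMetrics]:
    """Per-cluster RDT metrics, noise excluded, sorted by descending Rm."""
    config = config or RdtConfig()
    missing = h.vertices - set(labeling.cluster)
    if missing:
        raise DomainError(f"labeling does not cover vertices {sorted(missing)}")
    rows = []
    for cid in labeling.cluster_ids:
        members = labeling.members_of(cid)
        rp = relational_density(
            h, members, config.density_dialect,
            max_possible_weight=config.max_possible_weight,
        )
        rv = relational_volume(
            h, members, config.alpha, config.beta, config.volume_dialect,
            interaction_weights=config.interaction_weights,
        )
        rows.append(
            ClusterMetrics(
                cluster_id=cid,
                members=tuple(sorted(members)),
                n_vertices=len(members),
                n_edges=len(h.edges_among(members)),
                Rp=rp,
                Rv=rv,
            )
        )
    rows.sort(key=lambda m: (-m.Rm, m.cluster_id))
    return rows
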