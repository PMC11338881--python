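"""Frame hypergraphs, I_See detection, RDT metrics and DBSCAN clustering."""

import itertools

import numpy as np
import pytest

from relframe.errors import ConfigurationError, DomainError
from relframe.fixtures import person_abc
from relframe.hypergraph import (
    DbscanParams,
    FrameEdge,
    Hypergraph,
    RdtConfig,
    build_hypergraph,
    cluster_report,
    dbscan,
    detect_i_see,
    hop_distance,
    relational_density,
    relational_mass,
    relational_volume,
    resistance_to_change,
)
from relframe.relations import Relation, RelationStore


def triangle_graph():
    h = Hypergraph(["a", "b", "c"])
    h.add_edge(FrameEdge(("a", "b"), "C"))
    h.add_edge(FrameEdge(("b", "c"), "D"))
    h.add_edge(FrameEdge(("a", "c"), "T"))
    return h


class TestBuildHypergraph:
    def test_bijective_mapping(self):
        store = RelationStore()
        store.add(Relation("x", "y", "coordination"))
        store.add(Relation("y", "z", "distinction"))
        store.add(Relation("x", "z", "temporal"))
        h = build_hypergraph(store)
        assert len(h.vertices) == 3
        assert len(h.edges) == 3
        assert sorted(e.label for e in h.edges) == ["C", "D", "T"]

    def test_empty_store_empty_graph(self):
        h = build_hypergraph(RelationStore())
        assert not h.vertices and not h.edges

    def test_counts_match_person_scenario_relations(self):
        # Person A / Person B / snake / woods scenario as an edge list
        store = RelationStore()
        rows = [
            ("Person A", "Person B", "coordination"),
            ("Person A", "Person B", "distinction"),
            ("Person A", "snake", "temporal"),
            ("Person A", "woods", "spatial"),
        ]
        for x, y, rel in rows:
            store.add(Relation(x, y, rel))
        h = build_hypergraph(store)
        assert len(h.vertices) == len({s for row in rows for s in row[:2]})
        assert len(h.edges) == len(rows)

    def test_unmapped_relation_family_rejected(self):
        from relframe.relations import RelationType, TypeRegistry

        reg = TypeRegistry([RelationType("quuxes")])
        store = RelationStore(reg)
        store.add(Relation("a", "b", "quuxes"))
        with pytest.raises(ConfigurationError):
            build_hypergraph(store)


class TestDetectISee:
    def perspective_graph(self):
        h = Hypergraph(["A", "B", "pA", "pB"])
        h.add_edge(FrameEdge(("pA", "pB"), "C"))
        h.add_edge(FrameEdge(("pA", "pB"), "D"))
        h.add_edge(FrameEdge(("A", "B"), "P"))
        return h

    def test_conjunction_over_required_families(self):
        ok, witnesses = detect_i_see(self.perspective_graph(), "A", "B", {"C", "D", "P"})
        assert ok
        assert {e.label for e in witnesses} == {"C", "D", "P"}

    def test_missing_conjunct_fails(self):
        h = self.perspective_graph()
        h.edges = [e for e in h.edges if e.label != "D"]
        ok, witnesses = detect_i_see(h, "A", "B", {"C", "D", "P"})
        assert not ok and witnesses == []

    def test_unknown_agent_rejected(self):
        with pytest.raises(DomainError):
            detect_i_see(self.perspective_graph(), "A", "Z", {"C"})

    def test_monotone_and_agrees_with_exhaustive_scan(self):
        """Over 50 random graphs the detector equals a brute-force scan over
        all edges, and adding edges never turns true into false."""
        rng = np.random.default_rng(7)
        vertices = ["A", "B", "pA", "pB", "x"]
        for _ in range(50):
            h = Hypergraph(vertices)
            n_edges = rng.integers(0, 7)
            for _ in range(n_edges):
                pair = tuple(rng.choice(vertices, size=2, replace=False))
                label = str(rng.choice(["C", "D", "T", "S", "P"]))
                h.add_edge(FrameEdge(pair, label))
            required = {"C", "D"}
            got, _ = detect_i_see(h, "A", "B", required)
            expect = all(
                any(
                    e.label == fam
                    and set(e.members) & {"A", "pA"}
                    and set(e.members) & {"B", "pB"}
                    for e in h.edges
                )
                for fam in required
            )
            assert got == expect
            h.add_edge(FrameEdge(("pA", "pB"), "C"))
            h.add_edge(FrameEdge(("pA", "pB"), "D"))
            after, _ = detect_i_see(h, "A", "B", required)
            assert after  # adding the full conjunction can only help


class TestRdtMetrics:
    def test_parallel_edges_push_density_above_one(self):
        h = Hypergraph(["a", "b", "c"])
        for label in ["C", "D", "T", "S"]:
            h.add_edge(FrameEdge(("a", "b") if label in "CD" else ("b", "c"), label))
        assert relational_density(h, {"a", "b", "c"}) == pytest.approx(4 / 3)

    def test_complete_simple_graph_saturates(self):
        for n in (3, 4, 6):
            h = Hypergraph([f"v{i}" for i in range(n)])
            for i, j in itertools.combinations(range(n), 2):
                h.add_edge(FrameEdge((f"v{i}", f"v{j}"), "C"))
            assert relational_density(h, set(h.vertices)) == pytest.approx(1.0)

    def test_five_vertices_six_edges(self):
        h, _, _ = person_abc()
        members = {"A", "pA", "pAB", "snake", "woods"}
        assert relational_density(h, members) == pytest.approx(0.60)

    def test_density_monotone_in_edges_and_label_invariant(self):
        h = Hypergraph(["a", "b", "c"])
        h.add_edge(FrameEdge(("a", "b"), "C"))
        before = relational_density(h, set(h.vertices))
        h.add_edge(FrameEdge(("b", "c"), "D"))
        assert relational_density(h, set(h.vertices)) > before
        relabeled = Hypergraph(["x1", "x2", "x3"])
        relabeled.add_edge(FrameEdge(("x1", "x2"), "C"))
        relabeled.add_edge(FrameEdge(("x2", "x3"), "D"))
        assert relational_density(relabeled, set(relabeled.vertices)) == pytest.approx(
            relational_density(h, set(h.vertices))
        )

    def test_weighted_density_dialect(self):
        h = Hypergraph(["a", "b"])
        h.add_edge(FrameEdge(("a", "b"), "C", weight=3.0))
        assert relational_density(
            h, {"a", "b"}, "weighted", max_possible_weight=6.0
        ) == pytest.approx(0.5)

    def test_degenerate_cluster_rejected(self):
        with pytest.raises(DomainError):
            relational_density(triangle_graph(), {"a"})

    def test_linear_volume(self):
        h = Hypergraph(["a", "b", "c"])
        for label in ["C", "D", "T", "S"]:
            h.add_edge(FrameEdge(("a", "b") if label in "CD" else ("b", "c"), label))
        assert relational_volume(h, {"a", "b", "c"}) == pytest.approx(7.0)
        assert relational_volume(h, set()) == 0.0

    def test_person_a_volume_is_52_under_packaged_config(self):
        h, _, config = person_abc()
        members = {"A", "pA", "pAB", "snake", "woods"}
        rv = relational_volume(
            h, members, dialect="degree_weighted",
            interaction_weights=config.interaction_weights,
        )
        assert rv == pytest.approx(52.0)

    def test_negative_scaling_rejected(self):
        with pytest.raises(ConfigurationError):
            relational_volume(triangle_graph(), {"a", "b"}, alpha=-1.0)

    @pytest.mark.parametrize(
        "rp,rv,expected", [(0.60, 52.0, 31.20), (4 / 3, 5.0, 6.67), (0.0, 9.0, 0.0)]
    )
    def test_mass_is_product(self, rp, rv, expected):
        assert round(relational_mass(rp, rv), 2) == pytest.approx(expected)

    def test_resistance_to_change(self):
        assert resistance_to_change(2.0, 1.0) == pytest.approx(-0.5)
        assert resistance_to_change(2.0, 0.0) == 0.0
        assert resistance_to_change(4.0, 1.0) == pytest.approx(
            resistance_to_change(2.0, 1.0) / 2
        )
        with pytest.raises(ZeroDivisionError):
            resistance_to_change(0.0, 1.0)


def dbscan_oracle(points, distance, eps, min_pts):
    """Exhaustive density-reachability closure: cores, then the transitive
    closure of direct reachability, then border assignment."""
    neigh = {p: {q for q in points if distance(p, q) <= eps} for p in points}
    cores = {p for p in points if len(neigh[p]) >= min_pts}
    # density-connected core components
    clusters = []
    unassigned = set(cores)
    while unassigned:
        seed = min(unassigned)
        comp = {seed}
        frontier = [seed]
        while frontier:
            c = frontier.pop()
            for other in list(unassigned - comp):
                if other in neigh[c]:
                    comp.add(other)
                    frontier.append(other)
        clusters.append(comp)
        unassigned -= comp
    # borders join (any) cluster owning a core within eps
    full = []
    for comp in clusters:
        borders = {
            p for p in points
            if p not in cores and any(p in neigh[c] for c in comp)
        }
        full.append(comp | borders)
    noise = set(points) - set().union(*full) if full else set(points)
    return full, cores, noise


def as_partition(labeling):
    return {frozenset(labeling.members_of(c)) for c in labeling.cluster_ids}


class TestDbscan:
    def euclidean_points(self, seed=11, outliers=True):
        rng = np.random.default_rng(seed)
        blob1 = rng.normal([0, 0], 0.3, size=(15, 2))
        blob2 = rng.normal([10, 10], 0.3, size=(15, 2))
        pts = np.vstack([blob1, blob2])
        if outliers:
            pts = np.vstack([pts, [[5.0, 5.0], [-7.0, 8.0]]])
        names = [f"p{i:02d}" for i in range(len(pts))]
        coords = dict(zip(names, pts))

        def dist(u, v):
            return float(np.linalg.norm(coords[u] - coords[v]))

        return names, coords, dist

    def test_min_pts_exceeding_point_count_gives_all_noise(self):
        names, _, dist = self.euclidean_points(outliers=False)
        lab = dbscan(names, dist, DbscanParams(eps=0.5, min_pts=len(names) + 1))
        assert all(role == "noise" for role in lab.role.values())

    def test_zero_distance_min_pts_one_single_cluster(self):
        names = ["a", "b", "c"]
        lab = dbscan(names, lambda u, v: 0.0, DbscanParams(eps=0.0, min_pts=1))
        assert lab.cluster_ids == [0]
        assert lab.members_of(0) == set(names)

    def test_two_blobs_match_reachability_oracle(self):
        names, _, dist = self.euclidean_points()
        params = DbscanParams(eps=1.0, min_pts=4)
        lab = dbscan(names, dist, params)
        clusters, cores, noise = dbscan_oracle(names, dist, params.eps, params.min_pts)
        assert as_partition(lab) == {frozenset(c) for c in clusters}
        assert {p for p, r in lab.role.items() if r == "core"} == cores
        assert {p for p, r in lab.role.items() if r == "noise"} == noise

    def test_agrees_with_sklearn_reference(self):
        from sklearn.cluster import DBSCAN as SkDBSCAN

        names, coords, dist = self.euclidean_points(seed=3)
        X = np.array([coords[n] for n in names])
        params = DbscanParams(eps=1.0, min_pts=4)
        sk = SkDBSCAN(eps=params.eps, min_samples=params.min_pts).fit(X)
        lab = dbscan(names, dist, params)
        sk_partition = {
            frozenset(names[i] for i in np.flatnonzero(sk.labels_ == c))
            for c in set(sk.labels_) if c != -1
        }
        assert as_partition(lab) == sk_partition
        sk_noise = {names[i] for i in np.flatnonzero(sk.labels_ == -1)}
        assert {p for p, r in lab.role.items() if r == "noise"} == sk_noise

    def test_order_invariance_up_to_renaming(self):
        names, _, dist = self.euclidean_points(seed=5)
        params = DbscanParams(eps=1.0, min_pts=4)
        base = dbscan(names, dist, params)
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = list(rng.permutation(names))
            assert as_partition(dbscan(perm, dist, params)) == as_partition(base)

    def test_parameter_validation(self):
        with pytest.raises(ConfigurationError):
            DbscanParams(eps=-0.1, min_pts=3)
        with pytest.raises(ConfigurationError):
            DbscanParams(eps=1.0, min_pts=0)


class TestClusterReport:
    def test_fixture_reproduces_published_metrics(self):
        h, params, config = person_abc()
        lab = dbscan(sorted(h.vertices), hop_distance(h), params)
        report = cluster_report(h, lab, config)
        assert [(round(m.Rp, 2), m.Rv, round(m.Rm, 2)) for m in report] == [
            (0.60, 52.0, 31.20),
            (1.33, 5.0, 6.67),
        ]

    def test_single_cluster_single_row(self):
        h = triangle_graph()
        lab = dbscan(sorted(h.vertices), hop_distance(h), DbscanParams(1.0, 2))
        report = cluster_report(h, lab)
        assert len(report) == 1
        assert report[0].n_vertices == 3

    def test_mass_identity_on_random_graphs(self):
        rng = np.random.default_rng(19)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            h = Hypergraph([f"v{i}" for i in range(n)])
            for _ in range(int(rng.integers(n, 2 * n))):
                pair = tuple(rng.choice(sorted(h.vertices), 2, replace=False))
                h.add_edge(FrameEdge(pair, str(rng.choice(["C", "D", "T"]))))
            lab = dbscan(sorted(h.vertices), hop_distance(h), DbscanParams(1.0, 2))
            for row in cluster_report(h, lab, RdtConfig(alpha=0.5, beta=2.0)):
                assert row.Rm == row.Rp * row.Rv
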