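import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from plaquekg.graphio import OntologyDAG, PatientRecord, plq, sym
from plaquekg.features import (
    SemanticSimilarity,
    association_stats,
    build_patient_matrices,
    lift,
    lift_table,
    semsim,
    shortest_paths,
    symptom_profiles,
    term_similarity,
    topo_features,
    wang_svalues,
)
from tests.conftest import random_dag


class TestShortestPaths:
    def test_unit_chain(self, chain_graph):
        d = shortest_paths(chain_graph, "a")
        assert d["c"] == 2 and d["b"] == 1 and d["a"] == 0

    def test_longer_direct_edge_ignored(self, chain_graph):
        chain_graph.add_edge("a", "c", length=3.0)
        assert shortest_paths(chain_graph, "a")["c"] == 2

    def test_unreachable_is_inf(self, chain_graph):
        chain_graph.add_node("z")
        assert shortest_paths(chain_graph, "a")["z"] == math.inf

    def test_unknown_source(self, chain_graph):
        with pytest.raises(KeyError):
            shortest_paths(chain_graph, "nope")

    def test_matches_bellman_ford_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(5, 51))
            g = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(2**31)))
            for u, v in g.edges:
                g[u][v]["length"] = float(rng.uniform(0.1, 2.0))
            src = int(rng.integers(n))
            mine = shortest_paths(g, src)
            oracle = nx.single_source_bellman_ford_path_length(g, src, weight="length")
            for node in g.nodes:
                assert mine[node] == pytest.approx(oracle.get(node, math.inf))


class TestTopoFeatures:
    @pytest.fixture
    def two_symptom_graph(self):
        g = nx.Graph()
        g.add_node(sym("s1"), kind="symptom")
        g.add_node(sym("s2"), kind="symptom")
        g.add_node(plq("calcified"), kind="plaque")
        g.add_edge(sym("s1"), plq("calcified"), length=1.0)
        g.add_edge(sym("s2"), plq("calcified"), length=3.0)
        return g

    def test_hand_centroid_arithmetic(self, two_symptom_graph):
        # profiles (1) and (3) -> centroid (2) -> euclids (1, 1)
        _d1, e1 = topo_features(two_symptom_graph, "s1", ["calcified"], ["s1", "s2"])
        _d2, e2 = topo_features(two_symptom_graph, "s2", ["calcified"], ["s1", "s2"])
        assert e1 == pytest.approx(1.0) and e2 == pytest.approx(1.0)

    def test_centroid_symptom_has_zero_euclid(self, two_symptom_graph):
        g = two_symptom_graph
        g.add_node(sym("s3"), kind="symptom")
        g.add_edge(sym("s3"), plq("calcified"), length=2.0)  # exactly the centroid
        _d, e = topo_features(g, "s3", ["calcified"], ["s1", "s2", "s3"])
        assert e == pytest.approx(0.0)

    def test_disconnected_symptom_capped_and_flagged(self, two_symptom_graph):
        g = two_symptom_graph
        g.add_node(sym("s4"), kind="symptom")
        with pytest.warns(UserWarning, match="disconnected"):
            d, _e = topo_features(g, "s4", ["calcified"], ["s1", "s2", "s4"])
        assert d["calcified"] == pytest.approx(2 * 3.0)  # 2x max finite length

    def test_profiles_match_pairwise_dijkstra(self, small_world):
        from plaquekg.graphio import PLAQUE_LABELS, build_clinical_network, fuse_graph

        w = small_world
        kg = fuse_graph(build_clinical_network(w["records"]), w["symptom_sets"],
                        w["plaque_sets"], w["ppin"])
        symptoms = sorted(w["symptom_sets"])
        profiles, raw = symptom_profiles(kg, symptoms, list(PLAQUE_LABELS))
        for j, t in enumerate(PLAQUE_LABELS):
            oracle = nx.single_source_bellman_ford_path_length(kg, plq(t), weight="length")
            for i, s in enumerate(symptoms):
                assert raw[i, j] == pytest.approx(oracle.get(sym(s), math.inf))


class TestLift:
    def make_records(self, n, in_a, in_b, in_both):
        recs = []
        for i in range(n):
            syms = set()
            if i < in_both or (in_both <= i < in_a):
                syms.add("A")
            plqs = {"calcified"} if (i < in_both or in_a <= i < in_a + in_b - in_both) else set()
            recs.append(PatientRecord(f"p{i}", frozenset(syms), frozenset(plqs)))
        return recs

    def test_hand_counted_value(self):
        # 10 records, A in 4, B in 5, both in 3 -> lift 0.3 / (0.4 * 0.5) = 1.5
        recs = self.make_records(10, 4, 5, 3)
        assert lift(recs, "A", "calcified") == pytest.approx(1.5)

    def test_ubiquitous_item_gives_one(self):
        recs = [
            PatientRecord(f"p{i}", frozenset({"A"}), frozenset({"calcified"} if i < 3 else set()))
            for i in range(10)
        ]
        assert lift(recs, "A", "calcified") == pytest.approx(1.0)

    def test_never_cooccurring_gives_zero(self):
        recs = self.make_records(10, 4, 5, 0)
        # rebuild with disjoint occurrence
        recs = [PatientRecord("p1", frozenset({"A"}), frozenset()),
                PatientRecord("p2", frozenset(), frozenset({"calcified"}))]
        assert lift(recs, "A", "calcified") == 0.0

    def test_zero_support_is_nan_not_zero(self, toy_records):
        val = lift(toy_records, "ghost", "calcified")
        assert math.isnan(val)

    def test_symmetry(self, small_world):
        recs = small_world["records"]
        for s, t in [("S01", "calcified"), ("S05", "mixed")]:
            assert lift(recs, s, t) == pytest.approx(lift(recs, t, s))

    def test_matches_direct_counting_on_random_cohorts(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(10, 101))
            recs = []
            for i in range(n):
                syms = {f"s{j}" for j in range(4) if rng.random() < 0.4}
                plqs = {p for p in ("calcified", "mixed") if rng.random() < 0.4}
                recs.append(PatientRecord(f"p{i}", frozenset(syms), frozenset(plqs)))
            for a, b in [("s0", "calcified"), ("s1", "mixed")]:
                na = sum(1 for r in recs if a in r.symptoms)
                nb = sum(1 for r in recs if b in r.plaques)
                nab = sum(1 for r in recs if a in r.symptoms and b in r.plaques)
                if na and nb:
                    assert lift(recs, a, b) == pytest.approx(nab * n / (na * nb))

    def test_shuffled_labels_mean_lift_one(self):
        """Independence null: permuting plaque labels across patients drives lift to 1."""
        rng = np.random.default_rng(5)
        base = [
            PatientRecord(f"p{i}", frozenset({"A"} if rng.random() < 0.4 else set()),
                          frozenset({"calcified"} if rng.random() < 0.5 else set()))
            for i in range(400)
        ]
        vals = []
        plaques = [r.plaques for r in base]
        for _ in range(30):
            perm = rng.permutation(len(base))
            shuffled = [
                PatientRecord(r.patient_id, r.symptoms, plaques[perm[i]])
                for i, r in enumerate(base)
            ]
            vals.append(lift(shuffled, "A", "calcified"))
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 1.0) < 4 * se + 0.02


class TestPatientMatrices:
    @pytest.fixture
    def lifts(self):
        return pd.DataFrame(
            [[1.5, 0.2, 0.9], [0.7, 1.1, 0.3]],
            index=["s1", "s2"], columns=["calcified", "noncalcified", "mixed"],
        )

    def test_symptomless_patient_all_zero(self, lifts):
        recs = [PatientRecord("p", frozenset(), frozenset({"mixed"}))]
        (m,) = build_patient_matrices(recs, lifts)
        assert not m.matrix.any()

    def test_single_symptom_row(self, lifts):
        recs = [PatientRecord("p", frozenset({"s1"}), frozenset())]
        (m,) = build_patient_matrices(recs, lifts)
        np.testing.assert_allclose(m.matrix[0], [1.5, 0.2, 0.9])
        assert not m.matrix[1].any()

    def test_identical_symptom_sets_identical_matrices(self, lifts):
        recs = [
            PatientRecord("p1", frozenset({"s1", "s2"}), frozenset({"mixed"})),
            PatientRecord("p2", frozenset({"s1", "s2"}), frozenset()),
        ]
        m1, m2 = build_patient_matrices(recs, lifts)
        np.testing.assert_array_equal(m1.matrix, m2.matrix)

    def test_grid_fixed_across_patients(self, lifts, small_world):
        recs = small_world["records"][:20]
        tbl = lift_table(recs, sorted({s for r in recs for s in r.symptoms}),
                         ["calcified", "noncalcified", "mixed"])
        mats = build_patient_matrices(recs, tbl)
        shapes = {m.matrix.shape for m in mats}
        assert shapes == {tbl.shape}


class TestWangSimilarity:
    def test_identity(self, root_child_dag):
        assert term_similarity("A", "A", root_child_dag) == pytest.approx(1.0)
        assert semsim({"g1"}, {"g1"}, root_child_dag) == pytest.approx(1.0)

    def test_root_child_closed_form(self, root_child_dag):
        # T_A={A}, SV=1; T_B={A,B}, S_B(A)=0.8, SV=1.8; sim=(1+0.8)/(1+1.8)
        assert term_similarity("A", "B", root_child_dag) == pytest.approx(1.8 / 2.8)
        assert semsim({"g1"}, {"g2"}, root_child_dag) == pytest.approx(1.8 / 2.8)

    def test_part_of_weight(self):
        dag = OntologyDAG({"A", "B"}, {"A": [], "B": [("A", "part_of")]}, {"A"})
        assert term_similarity("A", "B", dag) == pytest.approx(1.6 / 2.6)

    def test_svalues_match_exhaustive_path_oracle(self):
        """S_A(t) equals the max over all downward paths of the edge-weight product."""
        rng = np.random.default_rng(21)
        w = {"is_a": 0.8, "part_of": 0.6}
        for _ in range(15):
            dag = random_dag(rng, int(rng.integers(5, 31)))
            term = sorted(dag.terms)[int(rng.integers(len(dag.terms)))]

            def oracle(t):  # max product over all paths term -> t following parents
                best = {term: 1.0}
                frontier = [term]
                while frontier:
                    nxt = []
                    for node in frontier:
                        for parent, rel in dag.parents[node]:
                            cand = best[node] * w[rel]
                            if cand > best.get(parent, 0.0):
                                best[parent] = cand
                                nxt.append(parent)
                    frontier = nxt
                return best.get(t, 0.0)

            sv = wang_svalues(term, dag)
            for t in dag.terms:
                assert sv.get(t, 0.0) == pytest.approx(oracle(t))

    def test_symmetry_and_bounds(self, small_world):
        dag = small_world["dag"]
        sets = list(small_world["symptom_sets"].values())[:4]
        simmer = SemanticSimilarity(dag)
        for a in sets:
            for b in sets:
                v = simmer.set_sim(a, b)
                assert 0.0 <= v <= 1.0 + 1e-12
                assert v == pytest.approx(simmer.set_sim(b, a))

    def test_removing_shared_term_never_increases_similarity(self, root_child_dag):
        dag = root_child_dag
        dag.terms.add("C")
        dag.parents["C"] = [("A", "is_a")]
        dag.annotations = {"x": {"B", "C"}, "y": {"B", "C"}}
        with_shared = semsim({"x"}, {"y"}, dag)
        dag.annotations = {"x": {"B", "C"}, "y": {"C"}}
        without = semsim({"x"}, {"y"}, dag)
        assert without <= with_shared + 1e-12

    def test_fully_unannotated_sets_error(self, root_child_dag):
        root_child_dag.annotations = {"g1": set(), "g2": set()}
        with pytest.raises(ValueError, match="unannotated"):
            semsim({"g1"}, {"g2"}, root_child_dag)
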