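import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from lakecohorts import (
    AbundanceMatrix,
    cluster_greedy_modularity,
    degree_within_cohort,
    environmental_preference,
    extract_cohorts,
    modularity_significance,
)
from lakecohorts.cohorts import _rewire, graph_from_edges


def two_triangles() -> nx.Graph:
    return nx.Graph([(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)])


class TestGreedyModularity:
    def test_two_triangles_q_half(self):
        comms, q = cluster_greedy_modularity(two_triangles())
        assert q == pytest.approx(0.5)
        assert {frozenset(c) for c in comms} == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_complete_graph_single_community(self):
        comms, q = cluster_greedy_modularity(nx.complete_graph(5))
        assert len(comms) == 1
        assert q == pytest.approx(0.0)

    def test_edgeless_graph_singletons(self):
        g = nx.empty_graph(4)
        comms, q = cluster_greedy_modularity(g)
        assert len(comms) == 4 and q == 0.0

    def test_partition_beats_trivial_partitions(self):
        g = nx.planted_partition_graph(2, 20, 0.5, 0.05, seed=1)
        comms, q = cluster_greedy_modularity(g)
        q_single = nx.community.modularity(g, [set(g.nodes)])
        q_singletons = nx.community.modularity(g, [{n} for n in g.nodes])
        assert q >= q_single and q >= q_singletons

    def test_planted_two_block_recovery(self):
        g = nx.planted_partition_graph(2, 20, 0.5, 0.05, seed=1)
        comms, _ = cluster_greedy_modularity(g)
        pred = {}
        for k, comm in enumerate(comms):
            for node in comm:
                pred[node] = k
        truth = [0 if n < 20 else 1 for n in g.nodes]
        ari = adjusted_rand_score(truth, [pred[n] for n in g.nodes])
        assert ari >= 0.9


class TestRewiringNull:
    def test_rewiring_preserves_every_degree(self, rng):
        g = nx.gnp_random_graph(30, 0.2, seed=4)
        h = _rewire(g, 1000, rng)
        assert dict(h.degree()) == dict(g.degree())
        assert h.number_of_edges() == g.number_of_edges()
        assert not any(u == v for u, v in h.edges)

    def test_rewiring_actually_moves_edges(self, rng):
        g = nx.gnp_random_graph(30, 0.2, seed=4)
        h = _rewire(g, 1000, rng)
        assert set(h.edges) != set(g.edges)

    def test_single_edge_graph_p_one(self):
        g = nx.Graph([(0, 1)])
        with pytest.warns(UserWarning):
            assert modularity_significance(g, n_perm=10, seed=0) == 1.0

    def test_modular_graph_significant(self):
        g = nx.planted_partition_graph(4, 10, 0.8, 0.02, seed=2)
        p = modularity_significance(g, n_perm=50, rewiring_iters=500, seed=0)
        assert p == 0.0

    def test_seed_reproducible(self):
        g = nx.gnp_random_graph(20, 0.2, seed=3)
        a = modularity_significance(g, n_perm=20, rewiring_iters=200, seed=5)
        b = modularity_significance(g, n_perm=20, rewiring_iters=200, seed=5)
        assert a == b


class TestExtractCohorts:
    def test_threshold_at_six(self):
        comms = [set(range(10)), set(range(10, 16)), set(range(16, 21))]
        cohort_of = extract_cohorts(comms)
        assert {cohort_of[n] for n in range(10)} == {"cohort_1"}
        assert {cohort_of[n] for n in range(10, 16)} == {"cohort_2"}
        assert {cohort_of[n] for n in range(16, 21)} == {"background"}

    def test_all_small_communities(self):
        cohort_of = extract_cohorts([{1, 2}, {3, 4, 5}])
        assert set(cohort_of.values()) == {"background"}

    def test_matches_brute_force_size_filter(self, rng):
        nodes = list(range(50))
        labels = rng.integers(0, 8, size=50)
        comms = [set(np.flatnonzero(labels == k)) for k in range(8) if (labels == k).any()]
        cohort_of = extract_cohorts(comms)
        for comm in comms:
            expect_cohort = len(comm) >= 6
            got = {cohort_of[n] for n in comm}
            assert (got != {"background"}) == expect_cohort


class TestDegreeWithinCohort:
    def test_cross_cohort_edges_excluded(self):
        g = nx.Graph([(0, 1), (0, 2), (0, 3), (0, 10), (0, 11)])
        cohort_of = {n: "cohort_1" for n in [0, 1, 2, 3]}
        cohort_of.update({n: "cohort_2" for n in [10, 11]})
        cohort_of[10] = "cohort_2"
        deg = degree_within_cohort(g, cohort_of)
        assert deg[0] == 3  # the two cross-cohort edges do not count

    def test_isolated_in_cohort(self):
        g = nx.Graph([(0, 10)])
        deg = degree_within_cohort(g, {0: "cohort_1", 10: "cohort_2"})
        assert deg[0] == 0 and deg[10] == 0

    def test_matches_adjacency_mask_recomputation(self, rng):
        g = nx.gnp_random_graph(30, 0.2, seed=8)
        labels = rng.integers(0, 3, size=30)
        cohort_of = {n: f"cohort_{labels[n] + 1}" for n in g.nodes}
        deg = degree_within_cohort(g, cohort_of)
        a = nx.to_numpy_array(g, nodelist=sorted(g.nodes))
        for n in g.nodes:
            same = np.array([labels[m] == labels[n] for m in sorted(g.nodes)])
            assert deg[n] == int(a[n] @ same)


class TestEnvironmentalPreference:
    def test_uniform_weights_give_zero(self):
        ab = pd.DataFrame(np.full((2, 10), 0.05), columns=[f"s{i}" for i in range(10)])
        params = pd.DataFrame({"temp": np.arange(10.0)}, index=ab.columns)
        pref = environmental_preference(
            AbundanceMatrix(ab), {0: "cohort_1", 1: "cohort_1"}, params
        )
        assert pref.loc["cohort_1", "temp"] == pytest.approx(0.0, abs=1e-12)

    def test_high_oxygen_cohort_positive_sign_and_matches_brute_force(self, rng):
        n = 20
        oxy = np.sort(rng.uniform(0, 15, size=n))
        ab = np.zeros((3, n))
        ab[0, n // 2 :] = rng.uniform(0.1, 0.2, size=n // 2)  # abundant at high oxygen
        ab[1] = rng.uniform(0.01, 0.05, size=n)
        ab[2] = rng.uniform(0.01, 0.05, size=n)
        cols = [f"s{i}" for i in range(n)]
        matrix = AbundanceMatrix(pd.DataFrame(ab, index=["a", "b", "c"], columns=cols))
        params = pd.DataFrame({"oxygen": oxy}, index=cols)
        cohort_of = {"a": "cohort_1", "b": "cohort_2", "c": "cohort_2"}
        pref = environmental_preference(matrix, cohort_of, params)
        assert pref.loc["cohort_1", "oxygen"] > 0
        # brute-force weighted mean of z-scores
        z = (oxy - oxy.mean()) / oxy.std(ddof=1)
        w = ab[0]
        assert pref.loc["cohort_1", "oxygen"] == pytest.approx((w * z).sum() / w.sum())
        # convex combination bounds
        assert z.min() <= pref.loc["cohort_1", "oxygen"] <= z.max()

    def test_constant_parameter_undefined(self):
        ab = pd.DataFrame(np.full((1, 5), 0.1), columns=[f"s{i}" for i in range(5)])
        params = pd.DataFrame({"flat": np.ones(5)}, index=ab.columns)
        with pytest.warns(UserWarning):
            pref = environmental_preference(AbundanceMatrix(ab), {0: "cohort_1"}, params)
        assert np.isnan(pref.loc["cohort_1", "flat"])

    def test_missing_values_dropped_per_parameter(self):
        ab = pd.DataFrame([[0.2, 0.1, 0.3]], columns=["s0", "s1", "s2"])
        params = pd.DataFrame(
            {"oxygen": [1.0, np.nan, 3.0], "temp": [5.0, 6.0, 7.0]}, index=ab.columns
        )
        pref = environmental_preference(AbundanceMatrix(ab), {0: "cohort_1"}, params)
        x = np.array([1.0, 3.0])
        z = (x - x.mean()) / x.std(ddof=1)
        w = np.array([0.2, 0.3])
        assert pref.loc["cohort_1", "oxygen"] == pytest.approx((w * z).sum() / w.sum())


class TestGraphFromEdges:
    def test_builds_simple_graph(self):
        edges = pd.DataFrame({"source": ["a", "a"], "target": ["b", "c"]})
        g = graph_from_edges(edges, nodes=["a", "b", "c", "d"])
        assert g.number_of_nodes() == 4 and g.number_of_edges() == 2

    def test_graphml_round_trip_keeps_cohort_attribute(self, tmp_path):
        from lakecohorts.cohorts import export_graphml

        g = two_triangles()
        cohort_of = {n: "cohort_1" for n in (0, 1, 2)}
        export_graphml(g, cohort_of, tmp_path / "net.graphml")
        back = nx.read_graphml(tmp_path / "net.graphml")
        assert back.nodes["0"]["cohort"] == "cohort_1"
        assert back.nodes["3"]["cohort"] == "background"
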