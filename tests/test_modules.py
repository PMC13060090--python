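import itertools

import networkx as nx
import numpy as np
import pytest

from metamod.modules import (
    AnchorCluster,
    build_modules,
    cluster_anchors,
    discover_modules,
    steiner_complete,
)
from metamod.network import MetabolicNetwork, NodeType
from metamod.sampling import CoMembershipMatrix, SamplingConfig
from metamod.scores import AnnotatedNetwork
from metamod.synthetic import generate_network, plant_signal
from metamod.scores import fit_bum

from conftest import make_fit


def _matrix(ids, pairs):
    n = len(ids)
    vals = np.zeros((n, n))
    np.fill_diagonal(vals, 1.0)
    idx = {v: i for i, v in enumerate(ids)}
    for (u, v), m in pairs.items():
        vals[idx[u], idx[v]] = vals[idx[v], idx[u]] = m
    return CoMembershipMatrix(list(ids), vals, n_iter=1000)


class TestClusterAnchors:
    def test_two_clean_blocks(self):
        M = _matrix(
            ["A", "B", "C", "D"],
            {("A", "B"): 1.0, ("C", "D"): 1.0},
        )
        clusters = cluster_anchors(M, cut=0.8, cut_mode="similarity")
        assert sorted(c.anchors for c in clusters) == [
            frozenset({"A", "B"}),
            frozenset({"C", "D"}),
        ]

    def test_no_comembership_gives_singletons(self):
        M = _matrix(["A", "B", "C"], {})
        clusters = cluster_anchors(M, cut=0.8)
        assert all(c.is_singleton for c in clusters)
        assert len(clusters) == 3

    def test_average_linkage_hand_example(self):
        """Merge AB at distance 0.1, then C at average distance 0.125 <= 0.2."""
        M = _matrix(["A", "B", "C"], {("A", "B"): 0.9, ("A", "C"): 0.9, ("B", "C"): 0.85})
        clusters = cluster_anchors(M, cut=0.8, cut_mode="similarity")
        assert len(clusters) == 1
        assert clusters[0].anchors == frozenset({"A", "B", "C"})

    def test_distance_cut_is_more_permissive(self):
        M = _matrix(["A", "B"], {("A", "B"): 0.3})
        assert len(cluster_anchors(M, cut=0.8, cut_mode="similarity")) == 2
        assert len(cluster_anchors(M, cut=0.8, cut_mode="distance")) == 1

    def test_empty_and_singleton_inputs(self):
        empty = CoMembershipMatrix([], np.zeros((0, 0)), 10)
        assert cluster_anchors(empty) == []
        single = CoMembershipMatrix(["A"], np.ones((1, 1)), 10)
        (c,) = cluster_anchors(single)
        assert c.is_singleton

    def test_clusters_partition_anchors(self):
        rng = np.random.default_rng(0)
        ids = [f"A{i}" for i in range(12)]
        vals = rng.random((12, 12))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        clusters = cluster_anchors(CoMembershipMatrix(ids, vals, 100), cut=0.5)
        seen = [a for c in clusters for a in c.anchors]
        assert sorted(seen) == sorted(ids)


class TestSteinerComplete:
    def test_adjacent_pair(self, toy_net, rng):
        mod = steiner_complete(toy_net, {"E1", "M1"}, rng)
        assert mod.nodes == {"E1", "M1"}
        assert mod.edges == {("E1", "M1")}

    def test_path_endpoints_pull_in_whole_path(self, rng):
        net = MetabolicNetwork.from_edges([("E1", "M1"), ("E2", "M1"), ("E2", "M2"), ("E3", "M2")])
        mod = steiner_complete(net, {"E1", "E3"}, rng)
        assert mod.nodes == {"E1", "M1", "E2", "M2", "E3"}

    def test_disconnected_anchors_rejected(self, rng):
        net = MetabolicNetwork.from_edges([("E1", "M1"), ("E2", "M2")])
        with pytest.raises(ValueError, match="component"):
            steiner_complete(net, {"E1", "E2"}, rng)

    @staticmethod
    def brute_optimum(graph: nx.Graph, terminals: set[str]) -> int:
        """Minimum Steiner cost (edges of a spanning tree of the smallest
        connected superset), by subset enumeration."""
        others = sorted(set(graph.nodes) - terminals)
        for r in range(len(others) + 1):
            for extra in itertools.combinations(others, r):
                s = terminals | set(extra)
                if nx.is_connected(graph.subgraph(s)):
                    return len(s) - 1
        raise AssertionError("terminals not connectable")

    @pytest.mark.parametrize("trial", range(60))
    def test_within_twice_optimal_on_small_graphs(self, trial):
        rng = np.random.default_rng(trial)
        net = generate_network(
            int(rng.integers(3, 7)), int(rng.integers(3, 7)), mean_met_degree=1.0, seed=trial
        )
        comp = max(nx.connected_components(net.graph), key=len)
        if len(comp) < 3:
            return
        comp = sorted(comp)
        n_term = int(rng.integers(2, min(4, len(comp)) + 1))
        terminals = {comp[i] for i in rng.choice(len(comp), n_term, replace=False)}
        mod = steiner_complete(net, terminals, np.random.default_rng(1000 + trial))
        assert terminals <= mod.nodes
        assert nx.is_connected(net.graph.subgraph(mod.nodes))
        cost = len(mod.nodes) - 1
        opt = self.brute_optimum(net.graph, terminals)
        assert cost <= 2 * max(opt, 1)


class TestBuildModules:
    @pytest.fixture
    def annotated(self, toy_net):
        return AnnotatedNetwork(toy_net, {"E1": 0.01, "E2": 0.02, "E3": 0.03, "M1": 0.5})

    def test_singleton_cluster_invalid(self, toy_net, annotated, rng):
        mods = build_modules(toy_net, [AnchorCluster(frozenset({"E1"}))], annotated, rng=rng)
        assert not mods[0].valid

    def test_p_hat_is_anchor_mean(self, toy_net, annotated, rng):
        cluster = AnchorCluster(frozenset({"E1", "E2", "E3"}))
        (mod,) = build_modules(toy_net, [cluster], annotated, rng=rng)
        assert mod.p_hat == pytest.approx(0.02)
        assert mod.valid

    def test_sorted_by_p_hat(self, toy_net, annotated, rng):
        clusters = [
            AnchorCluster(frozenset({"E2", "E3"})),
            AnchorCluster(frozenset({"E1", "M1"})),
        ]
        mods = build_modules(toy_net, clusters, annotated, rng=rng)
        assert [m.module_id for m in mods] == [1, 2]
        assert mods[0].p_hat <= mods[1].p_hat

    def test_anchor_type_split(self, toy_net, annotated, rng):
        cluster = AnchorCluster(frozenset({"E1", "M1"}))
        (mod,) = build_modules(toy_net, [cluster], annotated, rng=rng)
        assert mod.anchors_ec == {"E1"}
        assert mod.anchors_met == {"M1"}
        assert mod.n_ec == 1 and mod.n_met == 1


class TestDiscovery:
    def _dataset(self, seed=0):
        net = generate_network(60, 60, seed=seed)
        ec, met, truth = plant_signal(net, module_size=8, seed=seed)
        from metamod.scores import project_scores

        an = project_scores(net, ec, met)
        fits = {
            t: fit_bum([an.p[v] for v in an.p if an.node_type(v) is t], min_n=5)
            for t in NodeType
        }
        return an, fits

    def test_modules_connected_and_anchor_complete(self):
        an, fits = self._dataset(seed=4)
        res = discover_modules(an, fits, SamplingConfig(n_iter=200, seed=4))
        for mod in res.modules:
            assert nx.is_connected(an.network.graph.subgraph(mod.nodes))
            assert mod.anchors <= mod.nodes
        assert set().union(*(c.anchors for c in res.clusters)) == res.anchors if res.clusters else True

    def test_bitwise_reproducible(self):
        an, fits = self._dataset(seed=5)
        cfg = SamplingConfig(n_iter=150, seed=11)
        r1 = discover_modules(an, fits, cfg)
        r2 = discover_modules(an, fits, cfg)
        assert [m.nodes for m in r1.modules] == [m.nodes for m in r2.modules]
        assert [m.p_hat for m in r1.modules] == [m.p_hat for m in r2.modules]
        assert np.array_equal(r1.matrix.values, r2.matrix.values)
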