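"""Consensus networks, specificity labels, hubs, and modularity."""

import networkx as nx
import numpy as np
import pytest

from ppicohort import (
    ConsensusNetwork,
    build_consensus,
    hub_proteins,
    label_specificity,
    louvain_modularity,
    newman_girvan_q,
)
from tests.conftest import make_interactome, make_sample_graph


def consensus_of(*node_sets, min_count=1, mode="union_count", itx=None):
    members = [make_sample_graph(f"s{i}", ns) for i, ns in enumerate(node_sets)]
    return build_consensus(members, mode=mode, min_count=min_count, interactome=itx)


class TestBuildConsensus:
    def test_single_member_identity(self):
        sg = make_sample_graph("s0", ["a", "b", "c"])
        cons = build_consensus([sg], min_count=1)
        assert cons.node_set == sg.node_set
        assert set(map(frozenset, cons.graph.edges)) == set(map(frozenset, sg.graph.edges))
        assert all(d == 1 for _, d in cons.graph.nodes(data="occurrence_count"))

    def test_counting_rule(self):
        cons = consensus_of({"n1", "n2"}, {"n1", "n3"}, min_count=2)
        assert cons.node_set == {"n1"}
        assert cons.n_edges == 0

    def test_min_count_one_equals_graph_union(self):
        sets = [{"a", "b"}, {"b", "c"}, {"c", "d"}]
        members = [make_sample_graph(f"s{i}", ns) for i, ns in enumerate(sets)]
        cons = build_consensus(members, min_count=1)
        union_nodes = set().union(*sets)
        union_edges = {
            frozenset(e) for m in members for e in m.graph.edges
        }
        assert cons.node_set == union_nodes
        assert {frozenset(e) for e in cons.graph.edges} == union_edges

    def test_occurrence_counts(self):
        cons = consensus_of({"a", "b"}, {"a", "b"}, {"a", "c"}, min_count=1)
        assert cons.graph.nodes["a"]["occurrence_count"] == 3
        assert cons.graph.nodes["b"]["occurrence_count"] == 2
        assert cons.graph.edges["a", "b"]["occurrence_count"] == 2

    def test_min_count_above_members_gives_empty(self):
        cons = consensus_of({"a", "b"}, min_count=3)
        assert cons.n_nodes == 0

    def test_pooled_seeds_mode(self):
        itx = make_interactome([("X", "Y", 0.9), ("Y", "Z", 0.8)])
        g1 = make_sample_graph("s0", ["X", "Y"], edges=[("X", "Y")])
        g2 = make_sample_graph("s1", ["Y", "Z"], edges=[("Y", "Z")])
        cons = build_consensus([g1, g2], mode="pooled_seeds", interactome=itx)
        assert cons.node_set == {"X", "Y", "Z"}
        assert cons.n_edges == 2

    def test_imputed_role_iff_never_seed(self):
        g1 = make_sample_graph("s0", ["a", "b"])
        g1.graph.add_node("w", role="imputed")
        g1.graph.add_edge("a", "w", confidence=1.0)
        g1.graph.add_edge("w", "b", confidence=1.0)
        g2 = make_sample_graph("s1", ["a", "w"])  # w is a seed here
        cons = build_consensus([g1, g2], min_count=1)
        assert cons.graph.nodes["w"]["role"] == "seed"
        assert cons.graph.nodes["b"]["role"] == "seed"

    def test_rejects_empty_members(self):
        with pytest.raises(ValueError):
            build_consensus([])


class TestSpecificity:
    def test_partial_overlap(self):
        a = consensus_of({"p", "q"})
        b = consensus_of({"q", "r"})
        labels = label_specificity(a, b)
        assert labels == {"p": "unique_to_A", "q": "shared", "r": "unique_to_B"}

    def test_identical_sets_all_shared(self):
        a = consensus_of({"x", "y"})
        b = consensus_of({"x", "y"})
        assert set(label_specificity(a, b).values()) == {"shared"}

    def test_disjoint_sets_no_shared(self):
        a = consensus_of({"x"})
        b = consensus_of({"y"})
        assert "shared" not in label_specificity(a, b).values()

    def test_labels_partition_union(self):
        a = consensus_of({"a", "b", "c"})
        b = consensus_of({"c", "d"})
        labels = label_specificity(a, b)
        assert set(labels) == a.node_set | b.node_set


def net_from(graph):
    nx.set_edge_attributes(graph, 1, "occurrence_count")
    nx.set_edge_attributes(graph, 1.0, "confidence")
    return ConsensusNetwork(group="t", graph=graph)


class TestHubProteins:
    def test_star_graph(self):
        net = net_from(nx.star_graph(["c", "l1", "l2", "l3", "l4", "l5"]))
        hubs = hub_proteins(net, k=1)
        assert hubs.entries == [("c", 5)]
        assert not hubs.tie_straddles_k

    def test_straddling_tie_returns_whole_group(self):
        net = net_from(nx.cycle_graph(["a", "b", "c"]))
        hubs = hub_proteins(net, k=1)
        assert hubs.entries == [("a", 2), ("b", 2), ("c", 2)]
        assert hubs.tie_straddles_k

    def test_k_at_least_n_gives_full_list(self):
        net = net_from(nx.path_graph(["a", "b", "c"]))
        hubs = hub_proteins(net, k=10)
        assert hubs.entries == [("b", 2), ("a", 1), ("c", 1)]

    def test_empty_network(self):
        assert hub_proteins(ConsensusNetwork(group="t"), k=3).entries == []


def two_cliques(bridge=False):
    g = nx.Graph()
    for offset, names in ((0, "abcd"), (1, "wxyz")):
        for i, u in enumerate(names):
            for v in names[i + 1:]:
                g.add_edge(u, v)
    if bridge:
        g.add_edge("a", "w")
    return net_from(g)


class TestModularity:
    def test_q_of_two_disjoint_cliques(self):
        net = two_cliques()
        result = louvain_modularity(net, rng_seed=1)
        assert result.q == pytest.approx(0.5)
        assert result.n_modules == 2

    def test_q_of_bridged_cliques(self):
        # m=13; clique partition Q = 2*(6/13 - (13/26)^2) ~ 0.4231
        net = two_cliques(bridge=True)
        result = louvain_modularity(net, rng_seed=1)
        assert result.q == pytest.approx(2 * (6 / 13 - 0.25), abs=1e-9)

    def test_single_edge_single_module_q_zero(self):
        g = nx.Graph([("a", "b")])
        q = newman_girvan_q(g, {"a": 0, "b": 0})
        assert q == pytest.approx(0.0)

    def test_no_edge_graph_singletons(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b"])
        result = louvain_modularity(net_from(g), rng_seed=0)
        assert result.q == 0.0
        assert result.n_modules == 2

    def test_q_matches_networkx_on_random_graphs(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            g = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            labels = {node: int(rng.integers(0, 4)) for node in g.nodes}
            ours = newman_girvan_q(g, labels)
            comms = {}
            for node, c in labels.items():
                comms.setdefault(c, set()).add(node)
            theirs = nx.community.modularity(g, comms.values())
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_louvain_beats_trivial_partitions(self):
        rng = np.random.default_rng(29)
        for _ in range(10):
            g = nx.gnp_random_graph(15, 0.3, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            net = net_from(g)
            result = louvain_modularity(net, rng_seed=7)
            singletons = {node: i for i, node in enumerate(g.nodes)}
            one_module = {node: 0 for node in g.nodes}
            assert result.q >= newman_girvan_q(g, singletons) - 1e-12
            assert result.q >= newman_girvan_q(g, one_module) - 1e-12

    def test_deterministic_given_seed(self):
        net = two_cliques(bridge=True)
        r1 = louvain_modularity(net, rng_seed=42)
        r2 = louvain_modularity(net, rng_seed=42)
        assert r1.partition == r2.partition and r1.q == r2.q

    def test_partition_must_cover_graph(self):
        g = nx.Graph([("a", "b")])
        with pytest.raises(ValueError):
            newman_girvan_q(g, {"a": 0})
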