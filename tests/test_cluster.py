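"""Jaccard distances, UPGMA, cophenetic correlation, Fisher cluster tests."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ppicohort import (
    DistanceMatrix,
    PhenotypeLabels,
    cophenetic_correlation,
    fisher_cluster_test,
    jaccard_distance,
    pairwise_distances,
    significant_clusters,
    upgma,
)
from tests.conftest import make_sample_graph


def dmatrix(ids, pairs):
    n = len(ids)
    values = np.zeros((n, n))
    for (i, j), d in pairs.items():
        values[i, j] = values[j, i] = d
    return DistanceMatrix(samples=list(ids), values=values)


# ---------------------------------------------------------------- Jaccard

class TestJaccard:
    def test_identical_graphs(self):
        g = make_sample_graph("a", ["x", "y", "z"])
        h = make_sample_graph("b", ["x", "y", "z"])
        assert jaccard_distance(g, h) == 0.0

    def test_disjoint_graphs(self):
        g = make_sample_graph("a", ["x", "y"])
        h = make_sample_graph("b", ["u", "v"])
        assert jaccard_distance(g, h) == 1.0

    def test_partial_overlap(self):
        g = make_sample_graph("a", ["a", "b", "c"])
        h = make_sample_graph("b", ["b", "c", "d"])
        assert jaccard_distance(g, h) == pytest.approx(0.5)

    def test_both_empty(self):
        g = make_sample_graph("a", [])
        h = make_sample_graph("b", [])
        assert jaccard_distance(g, h) == 0.0

    def test_edge_mode_differs_from_node_mode(self):
        g = make_sample_graph("a", ["x", "y", "z"], edges=[("x", "y"), ("y", "z")])
        h = make_sample_graph("b", ["x", "y", "z"], edges=[("x", "y")])
        assert jaccard_distance(g, h, mode="nodes") == 0.0
        assert jaccard_distance(g, h, mode="edges") == pytest.approx(0.5)


@given(
    sets=st.tuples(
        st.sets(st.integers(0, 12), max_size=8),
        st.sets(st.integers(0, 12), max_size=8),
        st.sets(st.integers(0, 12), max_size=8),
    )
)
def test_jaccard_is_a_metric(sets):
    """Symmetry, identity of indiscernibles (node sets), triangle
    inequality on random set triples."""
    graphs = [make_sample_graph(f"s{i}", [f"n{x}" for x in s]) for i, s in enumerate(sets)]
    a, b, c = graphs
    dab, dba = jaccard_distance(a, b), jaccard_distance(b, a)
    assert dab == dba
    if sets[0] == sets[1]:
        assert dab == 0.0
    dac, dbc = jaccard_distance(a, c), jaccard_distance(b, c)
    assert dab <= dac + dbc + 1e-12


def test_pairwise_matches_bruteforce_and_is_symmetric():
    node_sets = [{"a", "b", "c"}, {"b", "c", "d"}, {"x"}]
    graphs = [make_sample_graph(f"s{i}", ns) for i, ns in enumerate(node_sets)]
    dist = pairwise_distances(graphs)
    for i, j in combinations(range(3), 2):
        inter = len(node_sets[i] & node_sets[j])
        union = len(node_sets[i] | node_sets[j])
        assert dist.values[i, j] == pytest.approx(1 - inter / union)
    assert np.array_equal(dist.values, dist.values.T)


def test_pairwise_rejects_duplicate_ids():
    graphs = [make_sample_graph("same", ["a"]), make_sample_graph("same", ["b"])]
    with pytest.raises(ValueError):
        pairwise_distances(graphs)


def test_single_graph_matrix():
    dist = pairwise_distances([make_sample_graph("only", ["a", "b"])])
    assert dist.values.shape == (1, 1) and dist.values[0, 0] == 0.0


# ------------------------------------------------------------------ UPGMA

def naive_upgma_heights(values):
    """Independent O(n^3) average linkage: cluster distance = mean of
    all original leaf-pair distances; returns sorted merge heights."""
    clusters = [{i} for i in range(len(values))]
    heights = []
    while len(clusters) > 1:
        best = None
        for x, y in combinations(range(len(clusters)), 2):
            d = np.mean([values[i][j] for i in clusters[x] for j in clusters[y]])
            if best is None or d < best[0]:
                best = (d, x, y)
        d, x, y = best
        heights.append(d)
        merged = clusters[x] | clusters[y]
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)] + [merged]
    return sorted(heights)


class TestUpgma:
    def test_three_leaf_worked_example(self):
        dist = dmatrix(["1", "2", "3"], {(0, 1): 0.2, (0, 2): 0.6, (1, 2): 0.8})
        dendro = upgma(dist)
        heights = sorted(n.height for n in dendro.internal_nodes())
        assert heights == pytest.approx([0.2, 0.7])

    def test_equal_distances_all_merges_at_c(self):
        c = 0.4
        dist = dmatrix(["a", "b", "c", "d"],
                       {p: c for p in combinations(range(4), 2)})
        dendro = upgma(dist)
        for node in dendro.internal_nodes():
            assert node.height == pytest.approx(c)

    def test_matches_naive_average_linkage(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            n = int(rng.integers(3, 8))
            m = rng.uniform(0.05, 1.0, size=(n, n))
            values = np.triu(m, 1)
            values = values + values.T
            dist = DistanceMatrix([f"s{i}" for i in range(n)], values)
            dendro = upgma(dist)
            got = sorted(node.height for node in dendro.internal_nodes())
            assert got == pytest.approx(naive_upgma_heights(values))

    def test_monotone_heights(self):
        rng = np.random.default_rng(3)
        m = rng.uniform(0.1, 1.0, size=(9, 9))
        values = np.triu(m, 1)
        values = values + values.T
        dendro = upgma(DistanceMatrix([f"s{i}" for i in range(9)], values))

        def check(node):
            for child in node.children:
                if not child.is_leaf:
                    assert child.height <= node.height + 1e-12
                    check(child)

        check(dendro.root)

    def test_permutation_invariance_of_cophenetic_distances(self):
        rng = np.random.default_rng(5)
        m = rng.uniform(0.1, 1.0, size=(6, 6))
        values = np.triu(m, 1)
        values = values + values.T
        ids = [f"s{i}" for i in range(6)]
        d1 = upgma(DistanceMatrix(ids, values)).cophenetic_distances()
        perm = rng.permutation(6)
        values2 = values[np.ix_(perm, perm)]
        ids2 = [ids[i] for i in perm]
        d2 = upgma(DistanceMatrix(ids2, values2)).cophenetic_distances()
        for pair, h in d1.items():
            assert d2[pair] == pytest.approx(h)

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            upgma(DistanceMatrix(["only"], np.zeros((1, 1))))


def test_newick_round_trip_preserves_cophenetic_distances():
    """Newick export re-parsed (dendropy) gives identical leaf-pair
    distances: patristic distance on an ultrametric tree = 2 x LCA height."""
    dendropy = pytest.importorskip("dendropy")
    rng = np.random.default_rng(8)
    m = rng.uniform(0.1, 1.0, size=(7, 7))
    values = np.triu(m, 1)
    values = values + values.T
    ids = [f"s{i}" for i in range(7)]
    dendro = upgma(DistanceMatrix(ids, values))
    tree = dendropy.Tree.get(data=dendro.to_newick(), schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    coph = dendro.cophenetic_distances()
    for a, b in combinations(ids, 2):
        expected = 2.0 * coph[frozenset((a, b))]
        assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(expected, abs=1e-4)


# ------------------------------------------------- cophenetic correlation

class TestCopheneticCorrelation:
    def test_worked_example(self):
        dist = dmatrix(["1", "2", "3"], {(0, 1): 0.2, (0, 2): 0.6, (1, 2): 0.8})
        dendro = upgma(dist)
        # inputs (0.2, 0.6, 0.8) vs cophenetic (0.2, 0.7, 0.7)
        assert cophenetic_correlation(dist, dendro) == pytest.approx(0.9449, abs=1e-4)

    def test_ultrametric_input_gives_one(self):
        dist = dmatrix(["a", "b", "c"], {(0, 1): 0.2, (0, 2): 0.5, (1, 2): 0.5})
        assert cophenetic_correlation(dist, upgma(dist)) == pytest.approx(1.0)

    def test_zero_variance_flagged_nan(self):
        dist = dmatrix(["a", "b", "c"],
                       {p: 0.3 for p in combinations(range(3), 2)})
        assert math.isnan(cophenetic_correlation(dist, upgma(dist)))


# ------------------------------------------------------------ Fisher test

def fisher_oracle(a, b, c, d):
    """Full hypergeometric enumeration: sum the probabilities of all
    tables with the observed margins that are no more probable."""
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def prob(x):
        return (
            math.comb(c1, x) * math.comb(n - c1, r1 - x) / math.comb(n, r1)
        )

    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


LABELS_5_5 = PhenotypeLabels(
    {f"p{i}": 1 for i in range(5)} | {f"q{i}": 2 for i in range(5)}
)


class TestFisherClusterTest:
    def test_perfectly_separated_table(self):
        t = fisher_cluster_test({f"p{i}" for i in range(5)}, LABELS_5_5)
        assert (t.a, t.b, t.c, t.d) == (5, 0, 0, 5)
        assert t.p == pytest.approx(2 / 252)

    def test_balanced_table_p_one(self):
        labels = PhenotypeLabels({"a": 1, "b": 1, "c": 2, "d": 2})
        t = fisher_cluster_test({"a", "c"}, labels)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)
        assert t.p == pytest.approx(1.0)

    def test_degenerate_margin_p_one(self):
        labels = PhenotypeLabels({"a": 1, "b": 1, "c": 2})
        t = fisher_cluster_test(set(), labels)
        assert t.p == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        # representative sweep; the exhaustive total<=30 sweep runs in
        # the acceptance suite
        labels_pool = [(3, 3), (4, 7), (6, 6), (10, 5)]
        for n1, n2 in labels_pool:
            labels = PhenotypeLabels(
                {f"x{i}": 1 for i in range(n1)} | {f"y{i}": 2 for i in range(n2)}
            )
            for a in range(n1 + 1):
                for b in range(n2 + 1):
                    members = {f"x{i}" for i in range(a)} | {f"y{i}" for i in range(b)}
                    t = fisher_cluster_test(members, labels)
                    assert t.p == pytest.approx(fisher_oracle(a, b, n1 - a, n2 - b))

    def test_requires_both_groups(self):
        with pytest.raises(ValueError):
            fisher_cluster_test({"a"}, PhenotypeLabels({"a": 1, "b": 1}))

    def test_members_must_be_labeled(self):
        with pytest.raises(ValueError):
            fisher_cluster_test({"zz"}, LABELS_5_5)


# ----------------------------------------------------- cluster selection

def two_block_matrix(n1, n2, within=0.1, between=0.9):
    ids = [f"p{i:02d}" for i in range(n1)] + [f"q{i:02d}" for i in range(n2)]
    n = n1 + n2
    values = np.full((n, n), between)
    values[:n1, :n1] = within
    values[n1:, n1:] = within
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(ids, values)


class TestSignificantClusters:
    LABELS = PhenotypeLabels(
        {f"p{i:02d}": 1 for i in range(10)} | {f"q{i:02d}": 2 for i in range(10)}
    )

    def test_pure_subtrees_found_with_exact_p(self):
        dist = two_block_matrix(10, 10)
        found = significant_clusters(upgma(dist), self.LABELS, alpha=0.001)
        assert len(found) == 2
        expected_p = 2 / math.comb(20, 10)
        for t in found:
            assert t.n == 10
            assert t.p == pytest.approx(expected_p)
        member_sets = {t.members for t in found}
        assert frozenset(f"p{i:02d}" for i in range(10)) in member_sets

    def test_maximality_no_nested_clusters(self):
        dist = two_block_matrix(10, 10)
        found = significant_clusters(upgma(dist), self.LABELS, alpha=0.05)
        for s, t in combinations(found, 2):
            assert not s.members <= t.members
            assert not t.members <= s.members

    def test_min_size_larger_than_n(self):
        dist = two_block_matrix(10, 10)
        assert significant_clusters(upgma(dist), self.LABELS, min_size=50) == []

    def test_max_height_excludes_high_branches(self):
        dist = two_block_matrix(10, 10, within=0.85, between=0.99)
        found = significant_clusters(
            upgma(dist), self.LABELS, alpha=0.001, max_height=0.8
        )
        assert found == []

    def test_type_one_error_control_quick(self):
        """Labels shuffled independently of topology rarely produce a
        significant cluster at alpha=0.001 (full 200-shuffle check in
        the acceptance suite)."""
        rng = np.random.default_rng(17)
        n = 40
        m = rng.uniform(0.1, 1.0, size=(n, n))
        values = np.triu(m, 1)
        values = values + values.T
        ids = [f"s{i:02d}" for i in range(n)]
        dendro = upgma(DistanceMatrix(ids, values))
        hits = 0
        for _ in range(50):
            perm = rng.permutation(n)
            labels = PhenotypeLabels(
                {ids[i]: (1 if k < n // 2 else 2) for k, i in enumerate(perm)}
            )
            if significant_clusters(dendro, labels, alpha=0.001):
                hits += 1
        assert hits <= 3
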