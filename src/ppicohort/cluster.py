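"""Sample clustering: Jaccard graph distances, UPGMA, cluster enrichment.

Samples are compared by the Jaccard distance between their network node
sets (optionally edge sets), clustered by UPGMA (average linkage), and
each dendrogram branch is tested for phenotype enrichment with the
two-sided Fisher exact test on the 2x2 in-cluster/out-of-cluster by
group table. The cophenetic correlation — the Pearson correlation
between input distances and tree-implied distances — measures how
faithfully the dendrogram represents the distance matrix.

The UPGMA here is implemented directly rather than delegated, because
reproducible dendrograms on cohort data require a defined tie-break:
among equally close cluster pairs, the pair whose smallest member
sample ID is lexicographically least (then the other cluster's smallest
member) merges first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy.stats import fisher_exact

from .expression import PhenotypeLabels
from .networks import SampleGraph

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over ordered sample IDs."""

    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.samples)
        if len(set(self.samples)) != n:
            raise ValueError("duplicate sample IDs")
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match sample list")
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.values) != 0.0):
            raise ValueError("nonzero diagonal")
        if np.any(self.values < 0.0) or np.any(self.values > 1.0):
            raise ValueError("entries outside [0, 1]")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.samples.index(pair[0])
        j = self.samples.index(pair[1])
        return float(self.values[i, j])

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in pair order of :func:`sample_pairs`."""
        n = len(self.samples)
        return self.values[np.triu_indices(n, k=1)]

    def sample_pairs(self) -> Iterator[tuple[str, str]]:
        yield from combinations(self.samples, 2)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\t" + "\t".join(self.samples) + "\n")
            for i, s in enumerate(self.samples):
                row = "\t".join(f"{v:.6f}" for v in self.values[i])
                fh.write(f"{s}\t{row}\n")


@dataclass
class DendroNode:
    """A dendrogram node; leaves have height 0 and no children."""

    id: str
    height: float
    children: tuple["DendroNode", ...] = ()
    leaves: frozenset[str] = frozenset()

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Dendrogram:
    """Rooted binary UPGMA tree over samples.

    Internal-node heights are the average inter-cluster distances at
    merge time and are non-decreasing toward the root (ultrametric).
    """

    root: DendroNode
    samples: list[str]

    def internal_nodes(self) -> list[DendroNode]:
        out: list[DendroNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.append(node)
                stack.extend(node.children)
        return out

    def cophenetic_distances(self) -> dict[frozenset[str], float]:
        """Leaf-pair -> height of the lowest common ancestor."""
        coph: dict[frozenset[str], float] = {}
        for node in self.internal_nodes():
            left, right = node.children
            for a in left.leaves:
                for b in right.leaves:
                    coph[frozenset((a, b))] = node.height
        return coph

    def to_newick(self) -> str:
        def render(node: DendroNode, parent_height: float) -> str:
            length = parent_height - node.height
            if node.is_leaf:
                return f"'{node.id}':{length:.6f}"
            inner = ",".join(render(c, node.height) for c in node.children)
            return f"({inner}):{length:.6f}"

        left, right = self.root.children
        inner = ",".join(render(c, self.root.height) for c in (left, right))
        return f"({inner});"

    def write_newick(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


def jaccard_distance(g1: SampleGraph, g2: SampleGraph, mode: str = "nodes") -> float:
    """Jaccard distance 1 - |X1 n X2| / |X1 u X2| between two sample
    graphs, over node sets (default; seeds and imputed alike) or edge
    sets (``mode="edges"``). Two empty sets give 0 with a warning."""
    if mode == "nodes":
        s1, s2 = g1.node_set, g2.node_set
    elif mode == "edges":
        s1 = {frozenset(e) for e in g1.graph.edges}
        s2 = {frozenset(e) for e in g2.graph.edges}
    else:
        raise ValueError(f"mode must be 'nodes' or 'edges', got {mode!r}")
    union = s1 | s2
    if not union:
        logger.warning(
            "jaccard_distance: both graphs empty (%s, %s)", g1.sample, g2.sample
        )
        return 0.0
    return 1.0 - len(s1 & s2) / len(union)


def pairwise_distances(
    graphs: Sequence[SampleGraph], mode: str = "nodes"
) -> DistanceMatrix:
    """All-pairs Jaccard distance matrix over the given sample graphs."""
    ids = [g.sample for g in graphs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample IDs among graphs")
    n = len(graphs)
    values = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d = jaccard_distance(graphs[i], graphs[j], mode=mode)
        values[i, j] = values[j, i] = d
    return DistanceMatrix(samples=ids, values=values)


def upgma(dist: DistanceMatrix) -> Dendrogram:
    """Classic UPGMA (average linkage) with deterministic tie-breaking.

    Repeatedly merges the pair of clusters with the smallest average
    inter-cluster distance; the new node's height is that distance, and
    distances to other clusters update as size-weighted arithmetic
    means. Ties break toward the pair whose smallest member sample ID is
    lexicographically least, then the other cluster's smallest member.
    """
    n = len(dist.samples)
    if n < 2:
        raise ValueError("UPGMA requires at least 2 samples")

    nodes: dict[int, DendroNode] = {}
    sizes: dict[int, int] = {}
    mins: dict[int, str] = {}
    for i, s in enumerate(dist.samples):
        nodes[i] = DendroNode(id=s, height=0.0, leaves=frozenset((s,)))
        sizes[i] = 1
        mins[i] = s
    d: dict[tuple[int, int], float] = {}
    for i, j in combinations(range(n), 2):
        d[(i, j)] = float(dist.values[i, j])

    active = set(range(n))
    next_id = n
    while len(active) > 1:
        best: tuple[float, str, str] | None = None
        best_pair: tuple[int, int] | None = None
        for i, j in combinations(sorted(active), 2):
            dij = d[(i, j)]
            tie = tuple(sorted((mins[i], mins[j])))
            key = (dij, tie[0], tie[1])
            if best is None or key < best:
                best = key
                best_pair = (i, j)
        assert best_pair is not None and best is not None
        i, j = best_pair
        height = best[0]
        merged = DendroNode(
            id=f"N{next_id - n + 1}",
            height=height,
            children=(nodes[i], nodes[j]),
            leaves=nodes[i].leaves | nodes[j].leaves,
        )
        si, sj = sizes[i], sizes[j]
        for k in active - {i, j}:
            dik = d[tuple(sorted((i, k)))]
            djk = d[tuple(sorted((j, k)))]
            d[tuple(sorted((next_id, k)))] = (si * dik + sj * djk) / (si + sj)
        active -= {i, j}
        active.add(next_id)
        nodes[next_id] = merged
        sizes[next_id] = si + sj
        mins[next_id] = min(mins[i], mins[j])
        next_id += 1

    root = nodes[next_id - 1]
    return Dendrogram(root=root, samples=list(dist.samples))


def cophenetic_correlation(dist: DistanceMatrix, dendro: Dendrogram) -> float:
    """Pearson correlation between the n(n-1)/2 input distances and the
    dendrogram's cophenetic distances. Returns NaN (with a warning) if
    either vector has zero variance."""
    if set(dendro.samples) != set(dist.samples):
        raise ValueError("dendrogram leaves differ from matrix samples")
    coph = dendro.cophenetic_distances()
    x = dist.condensed()
    y = np.array([coph[frozenset(p)] for p in dist.sample_pairs()])
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        logger.warning("cophenetic_correlation: zero variance, undefined")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class ClusterTest:
    """Fisher exact enrichment of one dendrogram branch.

    The 2x2 table is (in-cluster, out-of-cluster) x (group1, group2):
    a,b in-cluster counts, c,d out-of-cluster counts. ``p`` is the
    two-sided Fisher exact p-value; ``p_bonferroni`` an optional
    correction over the number of branches tested alongside.
    """

    node_id: str
    members: frozenset[str]
    a: int
    b: int
    c: int
    d: int
    p: float
    height: float = float("nan")
    p_bonferroni: float | None = None

    @property
    def n(self) -> int:
        return self.a + self.b

    @property
    def majority_group(self) -> int:
        return 1 if self.a >= self.b else 2


def fisher_cluster_test(
    members: frozenset[str] | set[str],
    labels: PhenotypeLabels,
    node_id: str = "",
    height: float = float("nan"),
) -> ClusterTest:
    """Two-sided Fisher exact test of group composition inside vs
    outside the cluster (sum over tables with the same margins of
    hypergeometric probabilities not exceeding the observed one)."""
    labels.require_two_groups()
    labeled = set(labels.assignment)
    members = frozenset(members)
    if not members <= labeled:
        raise ValueError("cluster members must all carry phenotype labels")
    g1, g2 = labels.members(1), labels.members(2)
    a = len(members & g1)
    b = len(members & g2)
    c = len(g1) - a
    d = len(g2) - b
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return ClusterTest(
        node_id=node_id, members=members, a=a, b=b, c=c, d=d, p=float(p), height=height
    )


def significant_clusters(
    dendro: Dendrogram,
    labels: PhenotypeLabels,
    alpha: float = 0.001,
    min_size: int = 2,
    max_height: float = 0.8,
) -> list[ClusterTest]:
    """Significant, maximal dendrogram branches by Fisher enrichment.

    Candidates are the leaf sets of internal nodes with at least
    ``min_size`` leaves and height at most ``max_height`` (the
    meta-cluster threshold, a tree cut). Each candidate is Fisher
    tested; branches with p < alpha are returned restricted to maximal
    ones (no returned cluster is a subset of another), sorted by p
    ascending. Raw p-values are primary; a Bonferroni-corrected value
    over the number of tested branches is attached for reference.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    candidates = [
        node
        for node in dendro.internal_nodes()
        if len(node.leaves) >= min_size and node.height <= max_height
    ]
    tests = [
        fisher_cluster_test(node.leaves, labels, node_id=node.id, height=node.height)
        for node in candidates
    ]
    n_tested = len(tests)
    tests = [replace(t, p_bonferroni=min(1.0, t.p * n_tested)) for t in tests]
    hits = [t for t in tests if t.p < alpha]
    hits.sort(key=lambda t: (-len(t.members), t.p, t.node_id))
    maximal: list[ClusterTest] = []
    for t in hits:
        if not any(t.members <= kept.members for kept in maximal):
            maximal.append(t)
    maximal.sort(key=lambda t: (t.p, -len(t.members), t.node_id))
    return maximal


def write_cluster_report(
    tests: Sequence[ClusterTest], path: str | Path, alpha: float
) -> None:
    """Cluster report TSV: node ID, n, 2x2 counts, p, Bonferroni p
    (reference only), significance flag."""
    with open(path, "w") as fh:
        fh.write("node_id\tn\ta\tb\tc\td\tp\tp_bonferroni\tsignificant\n")
        for t in tests:
            bonf = "" if t.p_bonferroni is None else f"{t.p_bonferroni:.6g}"
            fh.write(
                f"{t.node_id}\t{t.n}\t{t.a}\t{t.b}\t{t.c}\t{t.d}\t"
                f"{t.p:.6g}\t{bonf}\t{int(t.p < alpha)}\n"
            )
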