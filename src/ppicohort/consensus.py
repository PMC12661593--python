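"""Group-level consensus networks, hub ranking, and modularity.

The member sample graphs of a significant cluster, split by phenotype
group, are merged into one consensus network per group: by default the
union of member graphs keeping nodes recurring in at least ``min_count``
members (suppressing private noise), or alternatively a rebuild from the
pooled seed genes of all members. Consensus nodes are annotated with
occurrence counts, seed/imputed role, and group specificity; hubs are
the most-connected (highest-degree) consensus nodes; community
structure is found with the Louvain greedy modularity optimisation and
scored with the Newman-Girvan modularity Q.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx

from .expression import SeedSet
from .interactome import Interactome
from .networks import SampleGraph, build_sample_network

logger = logging.getLogger(__name__)


@dataclass
class ConsensusNetwork:
    """Merged network of one phenotype group's member sample graphs.

    Node attributes: ``occurrence_count`` (member samples containing the
    node), ``role`` ("seed" if a seed in >= 1 member, else "imputed").
    Edge attributes: ``occurrence_count``, ``confidence``.
    """

    group: str
    graph: nx.Graph = field(default_factory=nx.Graph)
    n_members: int = 0
    mode: str = "union_count"

    @property
    def node_set(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, symbol: str) -> int:
        return self.graph.degree(symbol)


@dataclass
class HubReport:
    """Top-k hub proteins; the full tie group at rank k is included and
    ``tie_straddles_k`` flags when it extends the list beyond k."""

    entries: list[tuple[str, int]]
    k: int
    tie_straddles_k: bool = False

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def symbols(self) -> list[str]:
        return [s for s, _ in self.entries]


@dataclass
class ModularityResult:
    """Louvain partition and its Newman-Girvan modularity Q."""

    partition: dict[str, int]
    q: float

    @property
    def n_modules(self) -> int:
        return len(set(self.partition.values()))


def build_consensus(
    member_graphs: Sequence[SampleGraph],
    mode: str = "union_count",
    min_count: int = 1,
    interactome: Interactome | None = None,
    group: str = "",
    max_path_length: int = 2,
    connector_mode: str = "best",
) -> ConsensusNetwork:
    """Merge member sample graphs into one consensus network.

    mode="union_count": keep nodes appearing in >= ``min_count`` member
    graphs and the member edges whose endpoints both survive, with
    occurrence counts. mode="pooled_seeds": pool every member's seed
    genes and rebuild a single network with
    :func:`~ppicohort.networks.build_sample_network` (requires the
    interactome).
    """
    if not member_graphs:
        raise ValueError("member_graphs must be non-empty")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    n_members = len(member_graphs)

    if mode == "pooled_seeds":
        if interactome is None:
            raise ValueError("pooled_seeds mode requires the interactome")
        pooled = sorted({s for g in member_graphs for s in g.seed_nodes})
        seeds = SeedSet(
            sample=f"pooled:{group}", direction="up", n_requested=max(len(pooled), 1),
            genes=pooled,
        )
        built = build_sample_network(
            seeds, interactome, max_path_length=max_path_length,
            connector_mode=connector_mode,
        )
        g = built.graph.copy()
        for n in g.nodes:
            g.nodes[n]["occurrence_count"] = sum(
                1 for m in member_graphs if n in m.graph
            ) or 1
        for u, v in g.edges:
            g.edges[u, v]["occurrence_count"] = sum(
                1 for m in member_graphs if m.graph.has_edge(u, v)
            ) or 1
        return ConsensusNetwork(group=group, graph=g, n_members=n_members, mode=mode)

    if mode != "union_count":
        raise ValueError(f"mode must be 'union_count' or 'pooled_seeds', got {mode!r}")
    if min_count > n_members:
        logger.warning(
            "build_consensus: min_count %d exceeds member count %d; empty consensus",
            min_count,
            n_members,
        )
        return ConsensusNetwork(group=group, n_members=n_members, mode=mode)

    node_count: dict[str, int] = {}
    node_seed: dict[str, bool] = {}
    edge_count: dict[frozenset[str], int] = {}
    edge_conf: dict[frozenset[str], float] = {}
    for m in member_graphs:
        for n, role in m.graph.nodes(data="role"):
            node_count[n] = node_count.get(n, 0) + 1
            node_seed[n] = node_seed.get(n, False) or role == "seed"
        for u, v, conf in m.graph.edges(data="confidence"):
            e = frozenset((u, v))
            edge_count[e] = edge_count.get(e, 0) + 1
            edge_conf[e] = conf

    g = nx.Graph()
    for n, count in node_count.items():
        if count >= min_count:
            g.add_node(
                n,
                occurrence_count=count,
                role="seed" if node_seed[n] else "imputed",
            )
    for e, count in edge_count.items():
        u, v = tuple(e)
        if u in g and v in g:
            g.add_edge(u, v, occurrence_count=count, confidence=edge_conf[e])
    return ConsensusNetwork(group=group, graph=g, n_members=n_members, mode=mode)


def label_specificity(
    cons_a: ConsensusNetwork, cons_b: ConsensusNetwork
) -> dict[str, str]:
    """Partition the union of two consensus node sets into
    unique_to_A / unique_to_B / shared."""
    a, b = cons_a.node_set, cons_b.node_set
    out: dict[str, str] = {}
    for n in a - b:
        out[n] = "unique_to_A"
    for n in b - a:
        out[n] = "unique_to_B"
    for n in a & b:
        out[n] = "shared"
    return out


def hub_proteins(network: ConsensusNetwork, k: int = 5) -> HubReport:
    """Top-k nodes by consensus degree (ties lexicographic); a tie group
    straddling rank k is returned whole and flagged."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(
        ((n, network.graph.degree(n)) for n in network.graph.nodes),
        key=lambda nd: (-nd[1], nd[0]),
    )
    if len(ranked) <= k:
        return HubReport(entries=ranked, k=k)
    cutoff = ranked[k - 1][1]
    end = k
    while end < len(ranked) and ranked[end][1] == cutoff:
        end += 1
    straddle = end > k
    if straddle:
        logger.warning(
            "hub_proteins: degree tie at rank %d extends hub list to %d entries",
            k,
            end,
        )
    return HubReport(entries=ranked[:end], k=k, tie_straddles_k=straddle)


def newman_girvan_q(
    graph: nx.Graph, partition: dict[str, int], weighted: bool = False
) -> float:
    """Newman-Girvan modularity Q = sum_c [l_c/m - (d_c/2m)^2] of a node
    partition: excess intra-module edge density over the degree-matched
    random expectation. ``weighted`` uses edge occurrence counts."""
    if set(partition) != set(graph.nodes):
        raise ValueError("partition must cover every node exactly once")

    def w(u: str, v: str) -> float:
        return graph.edges[u, v].get("occurrence_count", 1) if weighted else 1.0

    m = sum(w(u, v) for u, v in graph.edges)
    if m == 0:
        return 0.0
    intra: dict[int, float] = {}
    deg: dict[int, float] = {}
    for u, v in graph.edges:
        wu = w(u, v)
        if partition[u] == partition[v]:
            intra[partition[u]] = intra.get(partition[u], 0.0) + wu
        deg[partition[u]] = deg.get(partition[u], 0.0) + wu
        deg[partition[v]] = deg.get(partition[v], 0.0) + wu
    q = 0.0
    for c in set(partition.values()):
        q += intra.get(c, 0.0) / m - (deg.get(c, 0.0) / (2 * m)) ** 2
    return q


def louvain_modularity(
    network: ConsensusNetwork,
    resolution: float = 1.0,
    rng_seed: int = 0,
    weighted: bool = False,
) -> ModularityResult:
    """Community structure by the Louvain greedy modularity optimisation
    (seeded, hence deterministic) scored with Newman-Girvan Q.

    Edges are unweighted by default; ``weighted`` switches to edge
    occurrence counts. A graph with no edges yields singleton modules
    and Q = 0.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("network is empty")
    if g.number_of_edges() == 0:
        partition = {n: i for i, n in enumerate(sorted(g.nodes))}
        return ModularityResult(partition=partition, q=0.0)
    weight = "occurrence_count" if weighted else None
    communities = nx.community.louvain_communities(
        g, weight=weight, resolution=resolution, seed=rng_seed
    )
    communities = sorted(communities, key=lambda c: min(c))
    partition = {n: i for i, comm in enumerate(communities) for n in comm}
    q = newman_girvan_q(g, partition, weighted=weighted)
    return ModularityResult(partition=partition, q=q)


def write_graphml(
    network: ConsensusNetwork,
    path: str | Path,
    specificity: dict[str, str] | None = None,
    modules: dict[str, int] | None = None,
    max_vertices: int | None = 50,
) -> None:
    """GraphML export with node attributes (role, specificity,
    occurrence_count, degree, module ID), suitable for GEPHI import.

    ``max_vertices`` is a rendering truncation only: the export keeps
    the top nodes by degree (ties lexicographic); analysis is never
    truncated.
    """
    g = network.graph.copy()
    for n in g.nodes:
        g.nodes[n]["degree"] = network.graph.degree(n)
        if specificity is not None:
            g.nodes[n]["specificity"] = specificity.get(n, "")
        if modules is not None:
            g.nodes[n]["module"] = modules.get(n, -1)
    if max_vertices is not None and g.number_of_nodes() > max_vertices:
        keep = sorted(g.nodes, key=lambda n: (-g.nodes[n]["degree"], n))[:max_vertices]
        g = g.subgraph(keep).copy()
    nx.write_graphml(g, path)


def write_hub_report(hubs: HubReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tsymbol\tdegree\ttie_straddles_k\n")
        for rank, (symbol, degree) in enumerate(hubs.entries, start=1):
            fh.write(f"{rank}\t{symbol}\t{degree}\t{int(hubs.tie_straddles_k)}\n")


def write_consensus_edge_tsv(network: ConsensusNetwork, path: str | Path) -> None:
    rows = sorted(
        (min(u, v), max(u, v), d["confidence"], d["occurrence_count"])
        for u, v, d in network.graph.edges(data=True)
    )
    with open(path, "w") as fh:
        fh.write("symbolA\tsymbolB\tconfidence\toccurrence_count\n")
        for a, b, conf, count in rows:
            fh.write(f"{a}\t{b}\t{conf:.4f}\t{count}\n")
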