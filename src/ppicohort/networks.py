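"""Per-sample PPI network construction.

Each sample's network is grown from its seed genes under a maximum path
length of 1 or 2 on the background interactome: seeds directly
interacting are linked; with path length 2, seed pairs without a direct
interaction may be joined through a single intermediary ("imputed")
protein, a common interactome neighbour of both. Every edge in a sample
graph exists in the interactome with identical confidence; isolated
nodes are removed so the graph reflects connected interaction content
only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx

from .expression import SeedSet
from .interactome import Interactome

logger = logging.getLogger(__name__)


@dataclass
class SampleGraph:
    """One sample's PPI network.

    Nodes carry a ``role`` attribute ("seed" or "imputed"); edges carry
    the interactome ``confidence``. ``dropped_seeds`` records seeds
    absent from the interactome or left with degree 0.
    """

    sample: str
    graph: nx.Graph = field(default_factory=nx.Graph)
    dropped_seeds: list[str] = field(default_factory=list)

    @property
    def node_set(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def role(self, symbol: str) -> str:
        return self.graph.nodes[symbol]["role"]

    @property
    def seed_nodes(self) -> set[str]:
        return {n for n, r in self.graph.nodes(data="role") if r == "seed"}

    @property
    def imputed_nodes(self) -> set[str]:
        return {n for n, r in self.graph.nodes(data="role") if r == "imputed"}


def build_sample_network(
    seeds: SeedSet,
    interactome: Interactome,
    max_path_length: int = 2,
    connector_mode: str = "best",
) -> SampleGraph:
    """Build a sample's network from its seed set.

    Construction: (i) seeds absent from the interactome are dropped;
    (ii) every interactome edge between two retained seeds is added;
    (iii) with ``max_path_length=2``, each retained seed pair with no
    direct edge but at least one common interactome neighbour gains
    connector(s): mode "best" adds the single common neighbour w
    maximising min(conf(u,w), conf(w,v)) — ties broken by larger
    conf(u,w)+conf(w,v), then lexicographically smallest w — while mode
    "all" adds every common neighbour; (iv) degree-0 nodes are removed.
    Connector nodes that were not seeds are tagged "imputed".
    """
    if max_path_length not in (1, 2):
        raise ValueError(f"max_path_length must be 1 or 2, got {max_path_length}")
    if connector_mode not in ("best", "all"):
        raise ValueError(f"connector_mode must be 'best' or 'all', got {connector_mode!r}")

    g = nx.Graph()
    if not seeds.genes:
        logger.warning("sample %s: empty seed list", seeds.sample)
        return SampleGraph(sample=seeds.sample, graph=g, dropped_seeds=[])

    retained = [s for s in seeds.genes if interactome.has_node(s)]
    absent = [s for s in seeds.genes if not interactome.has_node(s)]
    if absent:
        logger.info(
            "sample %s: %d seed(s) absent from interactome", seeds.sample, len(absent)
        )
    retained_set = set(retained)
    g.add_nodes_from(retained, role="seed")

    for u, v in combinations(retained, 2):
        if interactome.has_edge(u, v):
            g.add_edge(u, v, confidence=interactome.confidence(u, v))

    if max_path_length == 2:
        nbrs = {s: interactome.neighbors(s) for s in retained}
        for u, v in combinations(retained, 2):
            if interactome.has_edge(u, v):
                continue
            common = nbrs[u] & nbrs[v]
            if not common:
                continue
            if connector_mode == "all":
                chosen = common
            else:
                chosen = {
                    min(
                        common,
                        key=lambda w: (
                            -min(interactome.confidence(u, w), interactome.confidence(w, v)),
                            -(interactome.confidence(u, w) + interactome.confidence(w, v)),
                            w,
                        ),
                    )
                }
            for w in chosen:
                if w not in g:
                    g.add_node(w, role="seed" if w in retained_set else "imputed")
                g.add_edge(u, w, confidence=interactome.confidence(u, w))
                g.add_edge(w, v, confidence=interactome.confidence(w, v))

    isolated = [n for n in g.nodes if g.degree(n) == 0]
    g.remove_nodes_from(isolated)
    dropped = absent + sorted(n for n in isolated)
    if isolated:
        logger.info(
            "sample %s: removed %d degree-0 seed(s)", seeds.sample, len(isolated)
        )
    return SampleGraph(sample=seeds.sample, graph=g, dropped_seeds=dropped)


def write_sif(sg: SampleGraph, path: str | Path, interaction: str = "pp") -> None:
    """Write the network as SIF (node<TAB>interaction<TAB>node)."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in sg.graph.edges):
            fh.write(f"{u}\t{interaction}\t{v}\n")


def write_edge_tsv(sg: SampleGraph, path: str | Path) -> None:
    """Write a 3-column edge TSV (symbolA, symbolB, confidence)."""
    rows = sorted(
        (min(u, v), max(u, v), c) for u, v, c in sg.graph.edges(data="confidence")
    )
    with open(path, "w") as fh:
        for a, b, conf in rows:
            fh.write(f"{a}\t{b}\t{conf:.4f}\n")


def write_node_attributes(sg: SampleGraph, path: str | Path) -> None:
    """Write a node-attribute TSV (symbol, role)."""
    with open(path, "w") as fh:
        fh.write("symbol\trole\n")
        for n in sorted(sg.graph.nodes):
            fh.write(f"{n}\t{sg.graph.nodes[n]['role']}\n")
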