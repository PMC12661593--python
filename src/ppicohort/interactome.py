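"""Background interactome: reading, validation, filtering.

The interactome is the fixed graph of known protein-protein interactions
on which every sample network is built and every distance is measured.
Two input dialects are supported: STRING ``protein.links`` records
(``protein1 protein2 combined_score`` with integer scores 0-1000) and a
generic 2-3 column edge TSV. Confidences are stored normalised to [0, 1]
regardless of dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .errors import InputFormatError

logger = logging.getLogger(__name__)


@dataclass
class Interactome:
    """Undirected confidence-weighted protein graph.

    Wraps a :class:`networkx.Graph` whose edges carry a ``confidence``
    attribute in [0, 1]. Node labels are opaque protein/gene symbols.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def has_node(self, symbol: str) -> bool:
        return self.graph.has_node(symbol)

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def confidence(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["confidence"]

    def neighbors(self, symbol: str) -> set[str]:
        return set(self.graph.neighbors(symbol))

    def edges(self) -> Iterable[tuple[str, str, float]]:
        """Iterate edges as (a, b, confidence) with a < b."""
        for u, v, conf in self.graph.edges(data="confidence"):
            a, b = sorted((u, v))
            yield a, b, conf

    def validate(self) -> None:
        """Raise if structural invariants are violated."""
        for u, v, conf in self.graph.edges(data="confidence"):
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if conf is None or not (0.0 <= conf <= 1.0):
                raise ValueError(f"confidence of {u!r}-{v!r} outside [0,1]: {conf!r}")
            if not u or not v:
                raise ValueError("empty node symbol")


def _add_edge_max(g: nx.Graph, a: str, b: str, conf: float) -> None:
    # duplicate unordered pairs collapse to the max-confidence record
    if g.has_edge(a, b):
        if conf > g.edges[a, b]["confidence"]:
            g.edges[a, b]["confidence"] = conf
    else:
        g.add_edge(a, b, confidence=conf)


def read_string_links(
    path: str | Path,
    min_score: int = 900,
    alias: Mapping[str, str] | None = None,
) -> Interactome:
    """Read a STRING-style links file into an :class:`Interactome`.

    Parameters
    ----------
    path
        Whitespace- or tab-separated records ``protein1 protein2
        combined_score`` with integer scores in 0-1000. An optional
        header line beginning ``protein1`` is skipped.
    min_score
        Edges with ``combined_score`` below this threshold are dropped.
        The default of 900 keeps only high-confidence interactions.
    alias
        Optional symbol mapping (e.g. ENSP identifier -> gene symbol)
        applied to both endpoints at read time; symbols missing from the
        mapping pass through unchanged.

    Confidence is stored as ``combined_score / 1000``. Duplicate pairs
    collapse to the maximum-confidence record; self-pairs are dropped
    with a logged warning.
    """
    g = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if lineno == 1 and fields[0].lower().startswith("protein1"):
                continue
            if len(fields) != 3:
                raise InputFormatError(
                    f"{path}: line {lineno}: expected 3 fields, got {len(fields)}"
                )
            a, b, raw = fields
            try:
                score = int(raw)
            except ValueError:
                raise InputFormatError(
                    f"{path}: line {lineno}: non-integer score {raw!r}"
                ) from None
            if not 0 <= score <= 1000:
                raise InputFormatError(
                    f"{path}: line {lineno}: score {score} outside 0-1000"
                )
            if alias is not None:
                a = alias.get(a, a)
                b = alias.get(b, b)
            if a == b:
                n_self += 1
                continue
            if score >= min_score:
                _add_edge_max(g, a, b, score / 1000.0)
    if n_self:
        logger.warning("%s: dropped %d self-pair record(s)", path, n_self)
    return Interactome(g)


def read_edge_tsv(path: str | Path, default_confidence: float = 1.0) -> Interactome:
    """Read a generic 2-3 column edge TSV (symbolA, symbolB[, confidence]).

    A missing confidence column is filled with ``default_confidence``.
    Duplicate pairs collapse to the maximum confidence; self-pairs are
    dropped with a warning.
    """
    g = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise InputFormatError(
                    f"{path}: line {lineno}: expected 2 or 3 columns, got {len(fields)}"
                )
            a, b = fields[0].strip(), fields[1].strip()
            if len(fields) == 3:
                try:
                    conf = float(fields[2])
                except ValueError:
                    raise InputFormatError(
                        f"{path}: line {lineno}: non-numeric confidence {fields[2]!r}"
                    ) from None
                if not 0.0 <= conf <= 1.0:
                    raise InputFormatError(
                        f"{path}: line {lineno}: confidence {conf} outside [0,1]"
                    )
            else:
                conf = default_confidence
            if a == b:
                n_self += 1
                continue
            _add_edge_max(g, a, b, conf)
    if n_self:
        logger.warning("%s: dropped %d self-loop row(s)", path, n_self)
    return Interactome(g)


def write_edge_tsv(itx: Interactome, path: str | Path) -> None:
    """Write a 3-column edge TSV sorted by (symbolA, symbolB), symbolA <
    symbolB, confidences with 4 decimal places (round-trip exact)."""
    rows = sorted(itx.edges())
    with open(path, "w") as fh:
        for a, b, conf in rows:
            fh.write(f"{a}\t{b}\t{conf:.4f}\n")


def largest_connected_component(itx: Interactome) -> Interactome:
    """Induced subgraph on the largest connected component.

    Size ties are broken by the lexicographically smallest member
    symbol; an empty graph passes through unchanged. Logs the number of
    nodes removed.
    """
    if itx.n_nodes == 0:
        return Interactome(nx.Graph())
    comps = list(nx.connected_components(itx.graph))
    comps.sort(key=lambda c: (-len(c), min(c)))
    keep = comps[0]
    removed = itx.n_nodes - len(keep)
    if removed:
        logger.info("largest_connected_component: removed %d node(s)", removed)
    return Interactome(itx.graph.subgraph(keep).copy())


def read_alias_tsv(path: str | Path) -> dict[str, str]:
    """Read an optional two-column alias TSV (identifier -> symbol)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise InputFormatError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
                )
            mapping[fields[0].strip()] = fields[1].strip()
    return mapping
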