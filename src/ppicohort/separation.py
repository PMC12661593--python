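"""Interactome-based network separation score s_AB.

Given two protein sets A and B on a background interactome, the
separation score is

    s_AB = <d_AB> - (<d_AA> + <d_BB>) / 2

where <d_AA> (and <d_BB>) is the mean over the set's members of the
shortest-path hop distance to the nearest *other* member of the same
set, and <d_AB> is the mean over all members of both sets of the
distance to the nearest member of the other set (zero for a protein in
both sets). s_AB > 0 indicates the two sets occupy topologically
separated interactome neighbourhoods and can be regarded as distinct
molecular entities; s_AB < 0 indicates they overlap.

Distances are unweighted hop counts; set members absent from the
interactome or unreachable from every relevant target are excluded from
the means and reported in the exclusion count.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from pathlib import Path

from .interactome import Interactome

logger = logging.getLogger(__name__)


@dataclass
class SeparationResult:
    """s_AB and its components (all distances in hops)."""

    mean_daa: float
    mean_dbb: float
    mean_dab: float
    s_ab: float
    n_a_used: int
    n_b_used: int
    n_excluded: int

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("mean_dAA\tmean_dBB\tmean_dAB\ts_AB\tn_A_used\tn_B_used\tn_excluded\n")
            fh.write(
                f"{self.mean_daa:.6f}\t{self.mean_dbb:.6f}\t{self.mean_dab:.6f}\t"
                f"{self.s_ab:.6f}\t{self.n_a_used}\t{self.n_b_used}\t{self.n_excluded}\n"
            )


def _nearest_distance(
    itx: Interactome, source: str, targets: set[str], min_dist: int = 0
) -> int | None:
    """BFS hop distance from ``source`` to the nearest member of
    ``targets`` at distance >= ``min_dist``; None if unreachable."""
    if min_dist == 0 and source in targets:
        return 0
    g = itx.graph
    seen = {source}
    frontier = deque([(source, 0)])
    while frontier:
        node, dist = frontier.popleft()
        for nbr in g.neighbors(node):
            if nbr in seen:
                continue
            if nbr in targets and dist + 1 >= min_dist:
                return dist + 1
            seen.add(nbr)
            frontier.append((nbr, dist + 1))
    return None


def mean_within_distance(itx: Interactome, s: set[str]) -> tuple[float, int, int]:
    """Mean nearest-other-member hop distance within the set.

    Returns (mean, n_used, n_excluded); members absent from the
    interactome or unreachable from every other member are excluded.
    Raises if fewer than two members are present in the interactome.
    """
    present = sorted(s & itx.nodes)
    if len(present) < 2:
        raise ValueError(
            f"need >= 2 set members present in the interactome, got {len(present)}"
        )
    present_set = set(present)
    dists: list[int] = []
    excluded = len(s) - len(present)
    for node in present:
        d = _nearest_distance(itx, node, present_set - {node})
        if d is None:
            excluded += 1
        else:
            dists.append(d)
    if not dists:
        raise ValueError("no set member can reach another member")
    return sum(dists) / len(dists), len(dists), excluded


def mean_cross_distance(
    itx: Interactome, a: set[str], b: set[str]
) -> tuple[float, int, int, int]:
    """Mean nearest-other-set hop distance across two sets.

    For every member of A present in the interactome, the distance to
    the nearest member of B (zero if it is itself in B), and vice
    versa; the mean is over all such values. Returns
    (mean, n_a_used, n_b_used, n_excluded).
    """
    a_present = sorted(a & itx.nodes)
    b_present = sorted(b & itx.nodes)
    if not a_present or not b_present:
        raise ValueError("both sets must intersect the interactome")
    a_set, b_set = set(a_present), set(b_present)
    dists: list[int] = []
    excluded = (len(a) - len(a_present)) + (len(b) - len(b_present))
    n_a_used = n_b_used = 0
    for node in a_present:
        d = _nearest_distance(itx, node, b_set)
        if d is None:
            excluded += 1
        else:
            dists.append(d)
            n_a_used += 1
    for node in b_present:
        d = _nearest_distance(itx, node, a_set)
        if d is None:
            excluded += 1
        else:
            dists.append(d)
            n_b_used += 1
    if not dists:
        raise ValueError("no member of either set can reach the other set")
    return sum(dists) / len(dists), n_a_used, n_b_used, excluded


def separation_sab(itx: Interactome, a: set[str], b: set[str]) -> SeparationResult:
    """Network separation s_AB = <d_AB> - (<d_AA> + <d_BB>) / 2.

    Symmetric in A and B. Identical sets give s_AB = -<d_AA> < 0 (full
    overlap); disjoint sets in distant interactome neighbourhoods give
    s_AB > 0.
    """
    mean_daa, _, excl_a = mean_within_distance(itx, a)
    mean_dbb, _, excl_b = mean_within_distance(itx, b)
    mean_dab, n_a_used, n_b_used, excl_ab = mean_cross_distance(itx, a, b)
    s_ab = mean_dab - (mean_daa + mean_dbb) / 2.0
    return SeparationResult(
        mean_daa=mean_daa,
        mean_dbb=mean_dbb,
        mean_dab=mean_dab,
        s_ab=s_ab,
        n_a_used=n_a_used,
        n_b_used=n_b_used,
        n_excluded=excl_ab,
    )


def read_node_list(path: str | Path) -> set[str]:
    """Read a node-list file, one symbol per line."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym:
                out.add(sym)
    return out
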