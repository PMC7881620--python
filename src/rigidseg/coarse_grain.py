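"""Louvain coarse-graining of the protein graph.

Rigid domains show up as densely connected regions of the contact graph, so
the graph is first reduced with Louvain community detection.  The
coarse-grained graph links two communities whenever at least one residue
pair between them is a contact, and annotates every community pair with the
mean variance xi: the average, over all cross pairs of residues, of the
sample variance of the pair distance across conformations.  xi is the
motion signal the later labeling stage works with — residue pairs that move
relative to each other inflate it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .protein_graph import ProteinGraph

logger = logging.getLogger(__name__)

DEFAULT_TARGET_COMMUNITIES = 20


@dataclass
class CoarseGraph:
    """Communities of residues with inter-community mean variances.

    ``communities[i]`` is the sorted tuple of residue indices of community
    i; ``graph`` is the community-level adjacency; ``xi`` is a dense K x K
    symmetric matrix of mean variances (Å²), defined for *all* community
    pairs, not only adjacent ones — line-graph edges need xi of
    non-adjacent pairs too.
    """

    communities: list[tuple[int, ...]]
    graph: nx.Graph
    xi: np.ndarray

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    def residues(self, community_indices: Sequence[int] | None = None) -> list[int]:
        idx = (range(self.n_communities) if community_indices is None
               else community_indices)
        out: list[int] = []
        for i in idx:
            out.extend(self.communities[i])
        return sorted(out)

    def induced(self, community_indices: Sequence[int]) -> "CoarseGraph":
        """Subgraph on a subset of communities, reindexed to 0..k-1."""
        kept = sorted(community_indices)
        sub = nx.Graph()
        sub.add_nodes_from(range(len(kept)))
        relabel = {old: new for new, old in enumerate(kept)}
        for a, b in self.graph.subgraph(kept).edges:
            sub.add_edge(relabel[a], relabel[b])
        xi = self.xi[np.ix_(kept, kept)]
        return CoarseGraph([self.communities[i] for i in kept], sub, xi)

    def to_partition_tsv(self, path: str | Path) -> None:
        rows = [(r, i) for i, members in enumerate(self.communities)
                for r in members]
        rows.sort()
        lines = ["residue\tcommunity"] + [f"{r}\t{i}" for r, i in rows]
        Path(path).write_text("\n".join(lines) + "\n")


def louvain_partition(
    graph: ProteinGraph, resolution: float = 1.0, seed: int = 0
) -> list[set[int]]:
    """Louvain communities of the protein graph (weighted modularity).

    Deterministic for a fixed seed.  Vertices with no edges come back as
    singleton communities; communities never span connected components.
    """
    if graph.n_vertices == 0:
        raise ValueError("cannot partition an empty graph")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    parts = nx.community.louvain_communities(
        graph.graph, weight="weight", resolution=resolution, seed=seed
    )
    return [set(p) for p in sorted(parts, key=min)]


def tune_resolution(
    graph: ProteinGraph,
    target: int = DEFAULT_TARGET_COMMUNITIES,
    band: tuple[int, int] | None = None,
    seed: int = 0,
    max_iter: int = 30,
) -> tuple[float, list[set[int]]]:
    """Bisect the Louvain resolution until the community count hits a band.

    The band defaults to [target - 5, target + 5].  Higher resolution gives
    more, smaller communities; the search brackets the target and bisects,
    returning the partition whose count is closest to the target if the
    band is never hit within ``max_iter`` evaluations.
    """
    if target < 2:
        raise ValueError("target must be at least 2")
    lo_band, hi_band = band if band is not None else (target - 5, target + 5)
    n = graph.n_vertices

    best: tuple[int, float, list[set[int]]] | None = None

    def evaluate(res: float) -> int:
        nonlocal best
        parts = louvain_partition(graph, resolution=res, seed=seed)
        gap = abs(len(parts) - target)
        if best is None or gap < best[0]:
            best = (gap, res, parts)
        return len(parts)

    lo, hi = 1e-3, 1.0
    count = evaluate(hi)
    iters = 1
    # grow the upper bracket until enough communities appear
    while count < target and hi < 1e4 and iters < max_iter:
        lo, hi = hi, hi * 4.0
        count = evaluate(hi)
        iters += 1
    # geometric bisection on the resolution
    while iters < max_iter and not lo_band <= len(best[2]) <= hi_band:
        mid = math.sqrt(lo * hi)
        count = evaluate(mid)
        iters += 1
        if count < target:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1.001:
            break

    _, resolution, partition = best
    largest = max(len(p) for p in partition)
    if largest > math.ceil(n / 4):
        logger.warning(
            "largest community has %d of %d residues; consider a higher "
            "resolution or target", largest, n,
        )
    if not lo_band <= len(partition) <= hi_band:
        logger.info(
            "resolution tuning stopped at %d communities (target %d)",
            len(partition), target,
        )
    return resolution, partition


def build_coarse_graph(
    graph: ProteinGraph,
    tensor: np.ndarray,
    partition: Sequence[set[int] | Sequence[int]],
) -> CoarseGraph:
    """Community-level graph plus the dense xi matrix.

    Two communities are adjacent iff some residue pair between them is an
    edge of the protein graph.  xi(c1, c2) averages the per-pair distance
    variance (denominator M - 1) over *all* cross pairs of residues,
    adjacent or not.
    """
    communities = [tuple(sorted(p)) for p in partition]
    covered = sorted(r for c in communities for r in c)
    if covered != sorted(graph.graph.nodes):
        raise ValueError("partition does not cover the graph's vertices")

    k = len(communities)
    member_of = {}
    for i, members in enumerate(communities):
        for r in members:
            member_of[r] = i

    cg = nx.Graph()
    cg.add_nodes_from(range(k))
    for a, b in graph.graph.edges:
        ca, cb = member_of[a], member_of[b]
        if ca != cb:
            cg.add_edge(ca, cb)

    variance = np.asarray(tensor, dtype=float).var(axis=0, ddof=1)
    xi = np.zeros((k, k))
    for i in range(k):
        rows = np.fromiter(communities[i], dtype=int)
        for j in range(i + 1, k):
            cols = np.fromiter(communities[j], dtype=int)
            xi[i, j] = xi[j, i] = variance[np.ix_(rows, cols)].mean()
    return CoarseGraph(communities, cg, xi)
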