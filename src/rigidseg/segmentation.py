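"""Recursive rigid-domain segmentation and domain merging.

The driver ties the stages together: contact graph -> Louvain communities
-> coarse graph -> recursive splitting.  At each recursion level the line
graph of the current coarse (sub)graph is labeled by exact MAP inference;
coarse edges labeled -1 are removed and the connected components become
candidate domains.  A component is accepted once its residues are rigid
(ensemble RMSD below theta), it consists of a single community, or the
recursion cap is reached.  Outlier indicators are recomputed from each
subgraph's own xi arrays, so the medians reflect the subproblem.

A final merging pass absorbs fragments smaller than ``min_domain_size``
into the neighboring domain that keeps the merged RMSD lowest, then
greedily merges adjacent domain pairs while the merged ensemble RMSD stays
below theta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .coarse_grain import (CoarseGraph, build_coarse_graph, tune_resolution,
                           DEFAULT_TARGET_COMMUNITIES)
from .line_crf import compute_gammas, line_graph, map_labeling
from .protein_graph import (DEFAULT_DELTA, DEFAULT_THETA, ProteinGraph,
                            Segmentation, apply_prior, build_protein_graph,
                            distance_tensor, ensemble_rmsd)
from .structures_io import ConformationEnsemble

logger = logging.getLogger(__name__)


@dataclass
class SegmentationConfig:
    """Tunable parameters of the pipeline (distances in Å)."""

    delta: float = DEFAULT_DELTA            # contact cutoff
    theta: float = DEFAULT_THETA            # rigidity threshold
    target_communities: int = DEFAULT_TARGET_COMMUNITIES
    mad_threshold: float = 3.0
    outlier_expansion: float = 0.0
    max_recursion: int = 10
    min_domain_size: int = 10               # residues
    seed: int = 0
    graph_rule: str = "all-conformations"

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.theta <= 0:
            raise ValueError("delta and theta must be positive")
        if self.min_domain_size < 1:
            raise ValueError("min_domain_size must be at least 1")
        if self.max_recursion < 1:
            raise ValueError("max_recursion must be at least 1")
        if self.outlier_expansion < 0:
            raise ValueError("outlier_expansion must be non-negative")


@dataclass
class SegmentNode:
    """One recursion step (diagnostic record)."""

    depth: int
    communities: list[int]
    n_residues: int
    rmsd: float | None
    action: str                  # split / leaf-rigid / leaf-single / ...
    n_children: int = 0


@dataclass
class SegmentTree:
    """Trace of the recursive splitting, for reports and debugging."""

    nodes: list[SegmentNode] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "n_steps": len(self.nodes),
            "max_depth": max((n.depth for n in self.nodes), default=0),
            "n_splits": sum(1 for n in self.nodes if n.action == "split"),
            "warnings": list(self.warnings),
        }

    @property
    def leaves(self) -> list[SegmentNode]:
        return [n for n in self.nodes if n.action != "split"]


def split_once(
    coarse: CoarseGraph,
    config: SegmentationConfig | None = None,
    expansion: float | None = None,
) -> list[CoarseGraph]:
    """One labeling round: cut the -1 coarse edges, return the components.

    Builds the line graph of ``coarse``, computes the outlier indicators
    from its own xi arrays, runs MAP inference, deletes every coarse edge
    whose line vertex came out -1, and returns the connected components as
    induced coarse subgraphs.
    """
    config = config or SegmentationConfig()
    if coarse.n_communities == 0:
        raise ValueError("empty coarse graph")
    lg = line_graph(coarse)
    if lg.n_vertices == 0:
        comps = _graph_components(coarse)
        return [coarse.induced(c) for c in comps]
    compute_gammas(lg, threshold=config.mad_threshold,
                   expansion=config.outlier_expansion
                   if expansion is None else expansion)
    y = map_labeling(lg, backend="exact")
    pruned = coarse.graph.copy()
    for i, (a, b) in enumerate(lg.vertices):
        if y[i] == -1:
            pruned.remove_edge(a, b)
    comps = _graph_components_of(pruned)
    return [coarse.induced(c) for c in comps]


def _graph_components(coarse: CoarseGraph) -> list[list[int]]:
    return _graph_components_of(coarse.graph)


def _graph_components_of(g: nx.Graph) -> list[list[int]]:
    return sorted((sorted(c) for c in nx.connected_components(g)), key=min)


def merge_segments(
    segments: Sequence[Sequence[int]],
    ensemble: ConformationEnsemble,
    config: SegmentationConfig,
    pgraph: ProteinGraph,
) -> list[list[int]]:
    """Two-phase merging of candidate domains.

    Phase 1 absorbs every segment smaller than ``min_domain_size`` into
    the candidate minimizing the merged ensemble RMSD, preferring segments
    adjacent in the protein graph (falling back to all segments).  Phase 2
    repeatedly merges the protein-graph-adjacent pair with the smallest
    merged RMSD, as long as that RMSD stays below theta.  Deterministic:
    ties go to the smallest segment index.
    """
    segs: list[list[int]] = [sorted(s) for s in segments]

    def merged_rmsd(s1: Sequence[int], s2: Sequence[int]) -> float:
        union = sorted(set(s1) | set(s2))
        if len(union) < 3:
            return 0.0
        return ensemble_rmsd(ensemble, union)

    def adjacent(s1: Sequence[int], s2: Sequence[int]) -> bool:
        set2 = set(s2)
        return any(nb in set2 for r in s1 for nb in pgraph.graph[r])

    # phase 1: absorb small fragments
    while len(segs) > 1:
        small = [(len(s), min(s), i) for i, s in enumerate(segs)
                 if len(s) < config.min_domain_size]
        if not small:
            break
        _, _, i = min(small)
        candidates = [j for j in range(len(segs))
                      if j != i and adjacent(segs[i], segs[j])]
        if not candidates:
            candidates = [j for j in range(len(segs)) if j != i]
        j = min(candidates, key=lambda j: (merged_rmsd(segs[i], segs[j]), j))
        lo, hi = min(i, j), max(i, j)
        segs[lo] = sorted(set(segs[i]) | set(segs[j]))
        del segs[hi]

    # phase 2: greedy rigid merging of adjacent pairs
    while len(segs) > 1:
        best = None
        for i in range(len(segs)):
            for j in range(i + 1, len(segs)):
                if not adjacent(segs[i], segs[j]):
                    continue
                r = merged_rmsd(segs[i], segs[j])
                if r < config.theta and (best is None or (r, i, j) < best):
                    best = (r, i, j)
        if best is None:
            break
        _, i, j = best
        segs[i] = sorted(set(segs[i]) | set(segs[j]))
        del segs[j]
    return segs


def backmap(
    components: Sequence[Sequence[int]],
    partition: Sequence[Sequence[int]],
    ensemble: ConformationEnsemble | None = None,
    theta: float = DEFAULT_THETA,
) -> Segmentation:
    """Map community-level components back to a per-residue segmentation.

    Each residue inherits the domain of its community's component; domain
    ids are assigned contiguously in order of the first residue.  With an
    ensemble given, per-domain ensemble RMSDs are computed and domains at
    or above theta are flagged non-rigid.
    """
    residue_sets = []
    for comp in components:
        residues: list[int] = []
        for c in comp:
            residues.extend(partition[c])
        residue_sets.append(sorted(residues))
    return segmentation_from_residue_sets(residue_sets, ensemble, theta)


def segmentation_from_residue_sets(
    residue_sets: Sequence[Sequence[int]],
    ensemble: ConformationEnsemble | None = None,
    theta: float = DEFAULT_THETA,
) -> Segmentation:
    ordered = sorted((sorted(s) for s in residue_sets), key=lambda s: s[0])
    n = sum(len(s) for s in ordered)
    labels = np.full(n, -1, dtype=int)
    for d, s in enumerate(ordered):
        labels[np.asarray(s, dtype=int)] = d
    if (labels < 0).any():
        raise ValueError("residue sets do not partition 0..N-1")
    rmsds: dict[int, float] = {}
    non_rigid: set[int] = set()
    if ensemble is not None:
        for d, s in enumerate(ordered):
            if len(s) >= 3:
                r = ensemble_rmsd(ensemble, s)
            else:
                r = float("nan")
            rmsds[d] = r
            if not r < theta:
                non_rigid.add(d)
        residue_ids = ensemble.residue_ids
    else:
        residue_ids = None
    return Segmentation(labels, rmsds, residue_ids, frozenset(non_rigid))


def segment(
    ensemble: ConformationEnsemble,
    config: SegmentationConfig | None = None,
    prior: Segmentation | None = None,
    alpha: float = 0.75,
) -> tuple[Segmentation, SegmentTree]:
    """Full rigid-domain segmentation of a conformational ensemble.

    Returns the per-residue segmentation (after merging) and the recursion
    trace.  ``prior`` optionally reweights cross-boundary contacts by
    ``alpha`` before coarse-graining.
    """
    config = config or SegmentationConfig()
    tensor = distance_tensor(ensemble)
    pgraph = build_protein_graph(tensor, delta=config.delta,
                                 rule=config.graph_rule,
                                 residue_ids=ensemble.residue_ids)
    if prior is not None:
        pgraph = apply_prior(pgraph, prior, alpha)
    _, partition = tune_resolution(pgraph, target=config.target_communities,
                                   seed=config.seed)
    coarse = build_coarse_graph(pgraph, tensor, partition)

    tree = SegmentTree()
    leaves: list[CoarseGraph] = []

    def recurse(sub: CoarseGraph, depth: int) -> None:
        residues = sub.residues()
        rmsd = (ensemble_rmsd(ensemble, residues)
                if len(residues) >= 3 else None)
        rigid = rmsd is None or rmsd < config.theta
        node = SegmentNode(depth, list(range(sub.n_communities)),
                           len(residues), rmsd, "")
        if rigid:
            node.action = "leaf-rigid"
        elif sub.n_communities == 1:
            node.action = "leaf-single"
            tree.warnings.append(
                f"non-rigid leaf: single community of {len(residues)} "
                f"residues, RMSD {rmsd:.2f} Å")
        elif depth >= config.max_recursion:
            node.action = "leaf-depth"
            tree.warnings.append("recursion cap reached on a non-rigid "
                                 "component")
        else:
            comps = [sub]
            for step in range(3):  # base try + at most two expansions
                comps = split_once(sub, config,
                                   expansion=config.outlier_expansion
                                   + 0.1 * step)
                if len(comps) > 1:
                    break
            if len(comps) == 1:
                node.action = "leaf-unsplit"
                tree.warnings.append(
                    f"non-rigid leaf: {len(residues)} residues "
                    f"(RMSD {rmsd:.2f} Å) could not be split")
            else:
                node.action = "split"
                node.n_children = len(comps)
                tree.nodes.append(node)
                for comp in comps:
                    recurse(comp, depth + 1)
                return
        tree.nodes.append(node)
        leaves.append(sub)

    recurse(coarse, 0)

    segments = [leaf.residues() for leaf in leaves]
    merged = merge_segments(segments, ensemble, config, pgraph)
    result = segmentation_from_residue_sets(merged, ensemble, config.theta)
    if result.non_rigid_domains:
        logger.warning("%d domain(s) remain above the rigidity threshold",
                       len(result.non_rigid_domains))
    return result, tree
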