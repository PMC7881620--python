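"""The residue-level protein graph and ensemble rigidity.

Residues are vertices; an edge links residues k, l when they stay within a
cutoff distance delta of each other.  Under the default rule the pair must
be close in *every* conformation and the edge is weighted by
``exp(-Var)``, the reciprocal exponentiated variance of the pair distance
across conformations, so conformationally stable contacts carry weight
near one and variable contacts are down-weighted.  A subset of residues is
rigid when its ensemble RMSD — the mean pairwise superposed RMSD over all
conformation pairs — falls below the rigidity threshold theta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal

import networkx as nx
import numpy as np

from .structures_io import ConformationEnsemble, ResidueId

GraphRule = Literal["all-conformations", "any-conformation"]

#: default contact cutoff (Å); 10.5 and 13.5 are the usual alternatives
DEFAULT_DELTA = 7.5
#: default rigidity threshold (Å)
DEFAULT_THETA = 3.5


def distance_tensor(ensemble: ConformationEnsemble) -> np.ndarray:
    """Per-conformation Euclidean distance matrices, shape (M, N, N)."""
    diff = ensemble.coords[:, :, None, :] - ensemble.coords[:, None, :, :]
    return np.linalg.norm(diff, axis=-1)


@dataclass
class ProteinGraph:
    """Weighted contact graph over residues 0..N-1.

    ``graph`` carries per-edge attributes ``weight`` (in (0, 1]) and
    ``variance`` (sample variance of the pair distance across
    conformations, Å²).
    """

    graph: nx.Graph
    cutoff_delta: float
    rule: GraphRule = "all-conformations"
    residue_ids: list[ResidueId] | None = None

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    def edge_weight(self, k: int, l: int) -> float:
        return self.graph.edges[k, l]["weight"]

    def edge_variance(self, k: int, l: int) -> float:
        return self.graph.edges[k, l]["variance"]

    def copy(self) -> "ProteinGraph":
        return ProteinGraph(self.graph.copy(), self.cutoff_delta, self.rule,
                            self.residue_ids)

    def to_edge_tsv(self, path: str | Path) -> None:
        lines = ["vertex_k\tvertex_l\tweight\tvariance"]
        for k, l, data in sorted(self.graph.edges(data=True)):
            lines.append(
                f"{k}\t{l}\t{data['weight']:.10g}\t{data['variance']:.10g}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def exp_neg_variance(var: np.ndarray) -> np.ndarray:
    """Default edge-weight function w = exp(-Var)."""
    return np.exp(-var)


def build_protein_graph(
    tensor: np.ndarray,
    delta: float = DEFAULT_DELTA,
    rule: GraphRule = "all-conformations",
    weight_fn: Callable[[np.ndarray], np.ndarray] = exp_neg_variance,
    residue_ids: list[ResidueId] | None = None,
) -> ProteinGraph:
    """Build the contact graph from a distance tensor.

    rule="all-conformations" (default): edge iff max_m d <= delta, weighted
    by ``weight_fn`` of the sample variance (denominator M-1).
    rule="any-conformation": edge iff min_m d <= delta, weighted by the
    fraction of conformations in which the pair is within the cutoff.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    tensor = np.asarray(tensor, dtype=float)
    M, N, _ = tensor.shape
    g = nx.Graph()
    g.add_nodes_from(range(N))

    variance = tensor.var(axis=0, ddof=1)
    if rule == "all-conformations":
        adjacency = tensor.max(axis=0) <= delta
        weights = weight_fn(variance)
    elif rule == "any-conformation":
        adjacency = tensor.min(axis=0) <= delta
        weights = (tensor <= delta).sum(axis=0) / M
    else:
        raise ValueError(f"unknown rule {rule!r}")

    ks, ls = np.nonzero(np.triu(adjacency, k=1))
    for k, l in zip(ks.tolist(), ls.tolist()):
        g.add_edge(k, l, weight=float(weights[k, l]),
                   variance=float(variance[k, l]))
    return ProteinGraph(g, delta, rule, residue_ids)


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimal RMSD between two point sets after optimal superposition.

    Standard Kabsch procedure: center both sets, take the SVD of the
    covariance, correct the sign of the last singular vector so the optimal
    transform is a proper rotation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = ac.T @ bc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    # residual sum of squares via singular values avoids building the rotation
    s[-1] *= d
    rss = (ac * ac).sum() + (bc * bc).sum() - 2.0 * s.sum()
    return math.sqrt(max(rss, 0.0) / len(a))


def ensemble_rmsd(
    ensemble: ConformationEnsemble, subset: Iterable[int] | None = None
) -> float:
    """Ensemble RMSD of a residue subset (Å).

    Mean over all M(M-1)/2 conformation pairs of the Kabsch-superposed RMSD
    restricted to the subset.
    """
    coords = ensemble.coords
    if subset is not None:
        idx = np.fromiter(subset, dtype=int)
        if idx.size < 3:
            raise ValueError("subset must contain at least 3 residues")
        coords = coords[:, idx]
    M = coords.shape[0]
    total = 0.0
    for m in range(M - 1):
        for mp in range(m + 1, M):
            total += kabsch_rmsd(coords[m], coords[mp])
    return 2.0 * total / (M * (M - 1))


def is_rigid(
    ensemble: ConformationEnsemble,
    subset: Iterable[int] | None = None,
    theta: float = DEFAULT_THETA,
) -> bool:
    """Whether a residue subset is rigid: ensemble RMSD strictly below theta."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    return ensemble_rmsd(ensemble, subset) < theta


@dataclass
class Segmentation:
    """Per-residue rigid-domain labels, ids contiguous from 0."""

    labels: np.ndarray
    domain_rmsd: dict[int, float] = field(default_factory=dict)
    residue_ids: list[ResidueId] | None = None
    non_rigid_domains: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_domains(self) -> int:
        return len(np.unique(self.labels))

    def to_tsv(self, path: str | Path) -> None:
        lines = ["chain\tresidue\tdomain"]
        for n, label in enumerate(self.labels):
            if self.residue_ids is not None:
                chain, num, icode = self.residue_ids[n]
                lines.append(f"{chain}\t{num}{icode}\t{label}")
            else:
                lines.append(f"-\t{n}\t{label}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Segmentation":
        labels = []
        residue_ids: list[ResidueId] = []
        for line in Path(path).read_text().splitlines()[1:]:
            chain, res, label = line.split("\t")
            num = "".join(ch for ch in res if ch.isdigit() or ch == "-")
            icode = res[len(num):]
            residue_ids.append((chain, int(num), icode))
            labels.append(int(label))
        return cls(np.array(labels), residue_ids=residue_ids)


def apply_prior(
    graph: ProteinGraph, prior: Segmentation, alpha: float
) -> ProteinGraph:
    """Down-weight edges crossing a prior segmentation's boundaries.

    Edges whose endpoints carry different prior labels have their weight
    multiplied by ``alpha`` (0 < alpha < 1, typically 0.75); all other
    weights are untouched.  Returns a new graph.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    labels = prior.labels
    if len(labels) < graph.n_vertices:
        raise ValueError("prior does not label every vertex")
    out = graph.copy()
    for k, l in out.graph.edges:
        if labels[k] != labels[l]:
            out.graph.edges[k, l]["weight"] *= alpha
    return out
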