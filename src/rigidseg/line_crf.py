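"""Line-graph CRF: outlier features, labeling score, and exact MAP inference.

The edges of the coarse-grained graph become the vertices of a (modified)
line graph; inferring a ±1 label per line vertex is therefore inferring a
label per coarse edge.  A label of -1 marks an edge as *inter-domain*: such
edges are cut, splitting the coarse graph into candidate rigid domains.

Features come from the mean-variance signal xi.  Within one rigid domain
the inter-community distances barely change across conformations, so large
xi values are treated as outliers of the intra-domain distribution
(one-sided MAD rule).  The outlier indicators gamma (±1) enter a pairwise
conditional random field whose unnormalized log-probability is

    score(y) = sum_v gamma_v * y_v + sum_e Psi2(e, y)

with the edge feature Psi2 rewarding labelings consistent with the outlier
pattern and, when the shared community may sit in a hinge, using the xi
ordering of the two line vertices to decide which side the hinge belongs
to.  The MAP labeling is computed exactly by bucket elimination.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .coarse_grain import CoarseGraph

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826          # consistency constant for normal data
DEFAULT_MAD_THRESHOLD = 3.0
XI_EQUAL_TOL = 1e-9
BRUTE_FORCE_LIMIT = 22
MAX_BOUNDARY = 25


class CapacityError(RuntimeError):
    """Exact inference would exceed the boundary-size cap.

    Raised instead of silently approximating; the remedy is a coarser
    community structure (fewer, larger communities)."""


@dataclass
class LabeledLineGraph:
    """Modified line graph of a coarse-grained graph.

    ``vertices[i]`` is the coarse community pair the i-th line vertex
    stands for; ``edges`` are index pairs (i < j).  ``xi_vertex[i]`` /
    ``xi_edge[j]`` carry the mean variances; the gamma arrays are filled by
    :func:`compute_gammas`.
    """

    vertices: list[tuple[int, int]]
    edges: list[tuple[int, int]]
    xi_vertex: np.ndarray
    xi_edge: np.ndarray
    gamma_vertex: np.ndarray | None = None
    gamma_edge: np.ndarray | None = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def require_gamma(self) -> None:
        if self.gamma_vertex is None or self.gamma_edge is None:
            raise RuntimeError("outlier indicators not computed yet; "
                               "call compute_gammas first")

    def to_tsv(self, path: str | Path) -> None:
        lines = ["# vertices: community_pair\txi\tgamma"]
        gv = self.gamma_vertex
        for i, (a, b) in enumerate(self.vertices):
            g = "" if gv is None else f"\t{gv[i]:+d}"
            lines.append(f"({a},{b})\t{self.xi_vertex[i]:.10g}{g}")
        lines.append("# edges: vertex_pair\txi\tgamma")
        ge = self.gamma_edge
        for j, (i1, i2) in enumerate(self.edges):
            g = "" if ge is None else f"\t{ge[j]:+d}"
            lines.append(f"({i1},{i2})\t{self.xi_edge[j]:.10g}{g}")
        Path(path).write_text("\n".join(lines) + "\n")


def line_graph(coarse: CoarseGraph) -> LabeledLineGraph:
    """Modified line-graph transformation of the coarse-grained graph.

    Vertices are the coarse edges.  Two line vertices (c0,c1), (c0,c2) are
    linked iff they share the community c0 *and* the end communities c1, c2
    are not adjacent in the coarse graph — incident edge pairs whose ends
    are themselves connected would duplicate the information carried by the
    third edge, so they are discarded.
    """
    cg = coarse.graph
    vertices = sorted(tuple(sorted(e)) for e in cg.edges)
    if not vertices:
        logger.warning("coarse graph has no edges; empty line graph "
                       "(single-community case)")
        return LabeledLineGraph([], [], np.empty(0), np.empty(0))
    index = {v: i for i, v in enumerate(vertices)}
    xi_vertex = np.array([coarse.xi[a, b] for a, b in vertices])

    edges: list[tuple[int, int]] = []
    xi_edge: list[float] = []
    for c0 in cg.nodes:
        incident = sorted(index[tuple(sorted((c0, nb)))] for nb in cg[c0])
        for i1, i2 in itertools.combinations(incident, 2):
            ends = (set(vertices[i1]) | set(vertices[i2])) - {c0}
            e1, e2 = sorted(ends)
            if cg.has_edge(e1, e2):
                continue
            assert not cg.has_edge(e1, e2)
            edges.append((i1, i2))
            xi_edge.append(coarse.xi[e1, e2])
    order = sorted(range(len(edges)), key=lambda j: edges[j])
    edges = [edges[j] for j in order]
    xi_edge_arr = np.array([xi_edge[j] for j in order]) if edges else np.empty(0)
    return LabeledLineGraph(vertices, edges, xi_vertex, xi_edge_arr)


def mad_outliers(values: Sequence[float],
                 threshold: float = DEFAULT_MAD_THRESHOLD) -> np.ndarray:
    """One-sided MAD outlier flags over an ascending array.

    Entry i is flagged -1 iff it exceeds the median and its distance from
    the median, normalized by 1.4826 * MAD, exceeds the threshold.  Only
    large values can be outliers (inter-domain mean variances are larger
    than intra-domain ones), so flags always form a suffix of the
    ascending array.  A zero MAD falls back to the mean absolute
    deviation; if that is zero too, nothing is flagged.
    """
    values = np.asarray(values, dtype=float)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if np.any(np.diff(values) < 0):
        raise ValueError("values must be sorted ascending")
    if values.size == 0:
        return np.empty(0, dtype=int)
    med = float(np.median(values))
    spread = float(np.median(np.abs(values - med)))
    if spread == 0.0:
        spread = float(np.mean(np.abs(values - med)))
    gamma = np.ones(values.size, dtype=int)
    if spread == 0.0:
        return gamma
    z = (values - med) / (MAD_SCALE * spread)
    gamma[(values > med) & (z > threshold)] = -1
    return gamma


def expand_outliers(gamma: np.ndarray, values: Sequence[float],
                    fraction: float = 0.0) -> np.ndarray:
    """Enlarge the outlier set with the largest non-flagged entries.

    Marks -1 the floor(fraction * len) largest entries not already
    flagged; the flagged set stays a suffix of the ascending array.
    """
    if fraction < 0:
        raise ValueError("fraction must be non-negative")
    gamma = np.asarray(gamma, dtype=int).copy()
    values = np.asarray(values, dtype=float)
    if np.any(np.diff(values) < 0):
        raise ValueError("values must be sorted ascending")
    flagged = np.flatnonzero(gamma == -1)
    if flagged.size and (np.diff(flagged) != 1).any() or \
       (flagged.size and flagged[-1] != gamma.size - 1):
        raise ValueError("gamma flags must form a suffix of the array")
    extra = int(fraction * gamma.size)
    if extra:
        start = (flagged[0] if flagged.size else gamma.size) - extra
        gamma[max(start, 0):] = -1
    return gamma


def compute_gammas(
    lg: LabeledLineGraph,
    threshold: float = DEFAULT_MAD_THRESHOLD,
    expansion: float = 0.0,
) -> LabeledLineGraph:
    """Fill the outlier indicators of a line graph (in place, returned).

    The vertex and edge xi arrays are each sorted ascending, run through
    the one-sided MAD rule (optionally expanded), and unsorted back.
    """
    for attr_xi, attr_gamma in (("xi_vertex", "gamma_vertex"),
                                ("xi_edge", "gamma_edge")):
        xi = getattr(lg, attr_xi)
        order = np.argsort(xi, kind="stable")
        gamma_sorted = mad_outliers(xi[order], threshold)
        gamma_sorted = expand_outliers(gamma_sorted, xi[order], expansion)
        gamma = np.empty_like(gamma_sorted)
        gamma[order] = gamma_sorted
        setattr(lg, attr_gamma, gamma)
    return lg


def _psi2(gamma_e: int, g1: int, g2: int, xi1: float, xi2: float,
          y1: int, y2: int) -> int:
    """Edge feature of the pairwise CRF (the three-case definition)."""
    if g1 == 1 and g2 == 1:
        # shared community may be a hinge; xi ordering decides the side
        xi_equal = abs(xi1 - xi2) <= XI_EQUAL_TOL
        if y1 == -1 and y2 == 1 and gamma_e == -1 and not xi_equal and xi1 > xi2:
            return 1
        if y1 == 1 and y2 == -1 and gamma_e == -1 and not xi_equal and xi1 < xi2:
            return 1
        if y1 == 1 and y2 == 1 and gamma_e == 1:
            return 1
        if y1 * y2 == -1 and gamma_e == -1 and xi_equal:
            return 0
        return -1
    if (gamma_e == -1) + (g1 == -1) + (g2 == -1) >= 2:
        # agreement with the outlier indicators is rewarded
        return 1 if y1 * g1 + y2 * g2 == 2 else -1
    return 0


def score_labeling(lg: LabeledLineGraph, y: Sequence[int]) -> float:
    """Unnormalized log-probability of a ±1 labeling."""
    lg.require_gamma()
    y = np.asarray(y, dtype=int)
    if y.shape != (lg.n_vertices,) or not np.all(np.abs(y) == 1):
        raise ValueError("y must assign ±1 to every line vertex")
    score = float(np.dot(lg.gamma_vertex, y))
    for j, (i1, i2) in enumerate(lg.edges):
        score += _psi2(int(lg.gamma_edge[j]),
                       int(lg.gamma_vertex[i1]), int(lg.gamma_vertex[i2]),
                       float(lg.xi_vertex[i1]), float(lg.xi_vertex[i2]),
                       int(y[i1]), int(y[i2]))
    return score


# ---------------------------------------------------------------------------
# exact MAP inference (bucket elimination + lexicographic self-reduction)

_LABELS = (1, -1)  # axis index 0 <-> +1, 1 <-> -1; +1 sorts first


def _min_fill_order(adj: dict[int, set[int]]) -> tuple[list[int], int]:
    """Min-fill elimination order and the resulting boundary size."""
    adj = {v: set(ns) for v, ns in adj.items()}
    order: list[int] = []
    width = 0
    while adj:
        best_v, best_fill = -1, None
        for v in sorted(adj):
            ns = adj[v]
            fill = sum(1 for a, b in itertools.combinations(sorted(ns), 2)
                       if b not in adj[a])
            if best_fill is None or fill < best_fill:
                best_v, best_fill = v, fill
        ns = adj.pop(best_v)
        order.append(best_v)
        width = max(width, len(ns) + 1)
        for a in ns:
            adj[a].discard(best_v)
            adj[a] |= ns - {a}
    return order, width


def _align(fvars: tuple[int, ...], arr: np.ndarray,
           uvars: tuple[int, ...]) -> np.ndarray:
    perm = sorted(range(len(fvars)), key=lambda i: uvars.index(fvars[i]))
    arr = np.transpose(arr, perm)
    shape = tuple(2 if u in fvars else 1 for u in uvars)
    return arr.reshape(shape)


def _eliminate_max(factors: list[tuple[tuple[int, ...], np.ndarray]],
                   order: list[int]) -> float:
    """Max of the factor sum over all assignments, by bucket elimination."""
    pool = list(factors)
    for v in order:
        involved = [f for f in pool if v in f[0]]
        pool = [f for f in pool if v not in f[0]]
        uvars = tuple(sorted(set().union(*(set(f[0]) for f in involved))))
        acc = np.zeros((2,) * len(uvars))
        for fv, fa in involved:
            acc = acc + _align(fv, fa, uvars)
        axis = uvars.index(v)
        pool.append((tuple(u for u in uvars if u != v), acc.max(axis=axis)))
    return sum(float(fa) for _, fa in pool)


def _component_factors(lg: LabeledLineGraph, comp: list[int]):
    in_comp = set(comp)
    factors: list[tuple[tuple[int, ...], np.ndarray]] = []
    for v in comp:
        g = int(lg.gamma_vertex[v])
        factors.append(((v,), np.array([g * 1.0, -g * 1.0])))
    for j, (i1, i2) in enumerate(lg.edges):
        if i1 not in in_comp:
            continue
        table = np.empty((2, 2))
        for a1, y1 in enumerate(_LABELS):
            for a2, y2 in enumerate(_LABELS):
                table[a1, a2] = _psi2(
                    int(lg.gamma_edge[j]),
                    int(lg.gamma_vertex[i1]), int(lg.gamma_vertex[i2]),
                    float(lg.xi_vertex[i1]), float(lg.xi_vertex[i2]),
                    y1, y2)
        factors.append(((i1, i2), table))
    return factors


def _components(lg: LabeledLineGraph) -> list[list[int]]:
    parent = list(range(lg.n_vertices))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i1, i2 in lg.edges:
        parent[find(i1)] = find(i2)
    comps: dict[int, list[int]] = {}
    for v in range(lg.n_vertices):
        comps.setdefault(find(v), []).append(v)
    return [sorted(c) for c in comps.values()]


def _map_component_exact(lg: LabeledLineGraph, comp: list[int]) -> dict[int, int]:
    adj: dict[int, set[int]] = {v: set() for v in comp}
    in_comp = set(comp)
    for i1, i2 in lg.edges:
        if i1 in in_comp:
            adj[i1].add(i2)
            adj[i2].add(i1)
    order, width = _min_fill_order(adj)
    if width > MAX_BOUNDARY:
        raise CapacityError(
            f"induced boundary size {width} exceeds {MAX_BOUNDARY}; "
            "re-run with fewer, larger communities "
            "(lower target_communities)")
    factors = _component_factors(lg, comp)
    best = _eliminate_max(factors, order)

    # lexicographic self-reduction: fix vertices in index order, preferring
    # +1; the constrained max tells us whether +1 is still optimal
    assignment: dict[int, int] = {}
    clamps: list[tuple[tuple[int, ...], np.ndarray]] = []
    for v in comp:
        trial = clamps + [((v,), np.array([0.0, -np.inf]))]
        if _eliminate_max(factors + trial, order) == best:
            assignment[v] = 1
            clamps = trial
        else:
            assignment[v] = -1
            clamps = clamps + [((v,), np.array([-np.inf, 0.0]))]
    return assignment


def _map_component_brute(lg: LabeledLineGraph, comp: list[int]) -> dict[int, int]:
    factors = _component_factors(lg, comp)
    best_score = -np.inf
    best_y: tuple[int, ...] | None = None
    pos = {v: i for i, v in enumerate(comp)}
    for y in itertools.product(_LABELS, repeat=len(comp)):
        s = 0.0
        for fv, fa in factors:
            idx = tuple(0 if y[pos[v]] == 1 else 1 for v in fv)
            s += fa[idx]
        if s > best_score:  # strict: keeps the lexicographically first
            best_score = s
            best_y = y
    return {v: best_y[pos[v]] for v in comp}


def map_labeling(
    lg: LabeledLineGraph,
    backend: Literal["exact", "brute-force"] = "exact",
) -> np.ndarray:
    """MAP ±1 labeling of the line graph.

    The score decomposes over connected components, so each component is
    solved independently.  Ties break toward the lexicographically
    smallest labeling in vertex order with +1 before -1 — both backends
    implement the same rule, which makes them comparable labelwise.
    """
    lg.require_gamma()
    if lg.n_vertices == 0:
        return np.empty(0, dtype=int)
    if backend == "brute-force" and lg.n_vertices > BRUTE_FORCE_LIMIT:
        raise ValueError(
            f"brute force is limited to {BRUTE_FORCE_LIMIT} line vertices")
    y = np.empty(lg.n_vertices, dtype=int)
    for comp in _components(lg):
        solver = (_map_component_brute if backend == "brute-force"
                  else _map_component_exact)
        for v, label in solver(lg, comp).items():
            y[v] = label
    return y
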