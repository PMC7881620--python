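"""Independent reference implementations used as test oracles.

Everything here is written from the definitions, deliberately on a
different code path from the package (explicit loops, scipy routines),
so that agreement is evidence of correctness rather than shared bugs.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def brute_distance_tensor(coords: np.ndarray) -> np.ndarray:
    m, n, _ = coords.shape
    out = np.zeros((m, n, n))
    for mm in range(m):
        for k in range(n):
            for l in range(n):
                out[mm, k, l] = float(np.sqrt(
                    ((coords[mm, k] - coords[mm, l]) ** 2).sum()))
    return out


def brute_contact_graph(tensor, delta, rule):
    """Edge dict {(k,l): (weight, variance)} by per-pair loops."""
    m, n, _ = tensor.shape
    edges = {}
    for k in range(n):
        for l in range(k + 1, n):
            d = tensor[:, k, l]
            var = float(np.var(d, ddof=1))
            if rule == "all-conformations":
                if d.max() <= delta:
                    edges[(k, l)] = (float(np.exp(-var)), var)
            else:
                if d.min() <= delta:
                    edges[(k, l)] = (float((d <= delta).sum() / m), var)
    return edges


def scipy_pair_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(ac, bc)
    return rssd / np.sqrt(len(a))


def scipy_ensemble_rmsd(coords: np.ndarray, subset=None) -> float:
    if subset is not None:
        coords = coords[:, np.asarray(sorted(subset))]
    m = coords.shape[0]
    vals = [scipy_pair_rmsd(coords[i], coords[j])
            for i in range(m) for j in range(i + 1, m)]
    return 2.0 * float(np.sum(vals)) / (m * (m - 1))


def reference_mad_flags(values, threshold=3.0):
    values = np.asarray(values, dtype=float)
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    spread = mad if mad > 0 else float(np.mean(np.abs(values - med)))
    flags = np.ones(values.size, dtype=int)
    if spread > 0:
        for i, v in enumerate(values):
            if v > med and (v - med) / (1.4826 * spread) > threshold:
                flags[i] = -1
    return flags


def reference_psi2(gamma_e, g1, g2, xi1, xi2, y1, y2, tol=1e-9):
    """Edge feature, transcribed case by case from the definition."""
    if g1 == 1 and g2 == 1:
        if (y1, y2) == (-1, 1) and gamma_e == -1 and xi1 - xi2 > tol:
            return 1
        if (y1, y2) == (1, -1) and gamma_e == -1 and xi2 - xi1 > tol:
            return 1
        if (y1, y2) == (1, 1) and gamma_e == 1:
            return 1
        if y1 != y2 and gamma_e == -1 and abs(xi1 - xi2) <= tol:
            return 0
        return -1
    n_neg = [gamma_e, g1, g2].count(-1)
    if n_neg >= 2:
        return 1 if (y1 * g1 + y2 * g2) == 2 else -1
    return 0


def reference_score(lg, y):
    """Total CRF score by direct summation over vertices and edges."""
    total = 0.0
    for v in range(lg.n_vertices):
        total += int(lg.gamma_vertex[v]) * int(y[v])
    for j, (i1, i2) in enumerate(lg.edges):
        total += reference_psi2(
            int(lg.gamma_edge[j]),
            int(lg.gamma_vertex[i1]), int(lg.gamma_vertex[i2]),
            float(lg.xi_vertex[i1]), float(lg.xi_vertex[i2]),
            int(y[i1]), int(y[i2]))
    return total


def brute_overlap(a, b):
    """Best matched fraction over all injective id assignments (small K)."""
    import itertools
    a = np.asarray(a)
    b = np.asarray(b)
    ua, ub = np.unique(a), np.unique(b)
    small, big, x, yv = (ua, ub, a, b) if len(ua) <= len(ub) else (ub, ua, b, a)
    best = 0
    for perm in itertools.permutations(big, len(small)):
        matched = sum(int(np.sum((x == s) & (yv == t)))
                      for s, t in zip(small, perm))
        best = max(best, matched)
    return best / a.size


def brute_pair_error(a, b):
    a = np.asarray(a)
    b = np.asarray(b)
    n = a.size
    bad = 0
    for i in range(n):
        for j in range(i + 1, n):
            if (a[i] == a[j]) != (b[i] == b[j]):
                bad += 1
    return bad / (n * (n - 1) / 2)


def brute_inconsistency(partition, truth):
    truth = np.asarray(truth)
    n = truth.size
    total = 0.0
    for cluster in partition:
        members = sorted(cluster)
        k = len(members)
        if k < 2:
            continue
        mism = sum(1 for x in range(k) for yy in range(x + 1, k)
                   if truth[members[x]] != truth[members[yy]])
        total += 2.0 * (k / n) * mism / (k * (k - 1))
    return total
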