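"""Agreement metrics for segmentations and clusterings.

``overlap`` matches two segmentations' domain ids with a linear assignment
(Hungarian method on the contingency table) and reports the matched-residue
fraction; ``pair_error`` reports how often the two disagree on whether a
residue pair shares a domain.  ``inconsistency_error`` scores a clustering
against ground-truth labels: the size-weighted within-cluster mismatch
rate, used to judge how well graph construction and coarse-graining respect
the true domain boundaries.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment


def _labels(x) -> np.ndarray:
    arr = np.asarray(getattr(x, "labels", x))
    if arr.ndim != 1:
        raise ValueError("expected a 1-D label array or a Segmentation")
    return arr


def _contingency(a: np.ndarray, b: np.ndarray):
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    table = np.zeros((len(ua), len(ub)), dtype=int)
    np.add.at(table, (ia, ib), 1)
    return table


def overlap(a, b) -> float:
    """Matched-residue fraction under the best domain-id assignment.

    Invariant to relabeling either segmentation; 1.0 iff the two are
    identical up to a permutation of domain ids.
    """
    a, b = _labels(a), _labels(b)
    if a.shape != b.shape:
        raise ValueError("segmentations cover different residue sets")
    table = _contingency(a, b)
    rows, cols = linear_sum_assignment(table, maximize=True)
    return float(table[rows, cols].sum()) / a.size


def assignment(a, b) -> dict[int, int]:
    """The maximizing domain-id correspondence behind :func:`overlap`."""
    a, b = _labels(a), _labels(b)
    table = _contingency(a, b)
    ua, ub = np.unique(a), np.unique(b)
    rows, cols = linear_sum_assignment(table, maximize=True)
    return {int(ua[r]): int(ub[c]) for r, c in zip(rows, cols)}


def pair_error(a, b) -> float:
    """Fraction of residue pairs whose same-domain status differs."""
    a, b = _labels(a), _labels(b)
    if a.shape != b.shape:
        raise ValueError("segmentations cover different residue sets")
    n = a.size
    if n < 2:
        raise ValueError("need at least two residues")
    # number of agreeing pairs, via the contingency table:
    # same-same pairs = sum over cells of C(n_ij, 2); both 'different' pairs
    # follow from the marginals by inclusion-exclusion
    table = _contingency(a, b)
    total = n * (n - 1) // 2

    def pairs2(x):
        return int((x.astype(np.int64) * (x - 1) // 2).sum())

    both_same = pairs2(table)
    same_a = pairs2(table.sum(axis=1))
    same_b = pairs2(table.sum(axis=0))
    disagreements = (same_a - both_same) + (same_b - both_same)
    return disagreements / total


def inconsistency_error(partition: Sequence[Sequence[int]],
                        truth: Sequence[int]) -> float:
    """Size-weighted within-cluster label-mismatch rate.

        error = 2 * sum_k (|C_k| / N) * (# mismatched pairs in C_k)
                                        / (|C_k| (|C_k| - 1))

    Zero iff every cluster is label-pure; singleton clusters contribute
    nothing.
    """
    truth = np.asarray(truth)
    n = truth.size
    total = 0.0
    for cluster in partition:
        idx = np.asarray(sorted(cluster), dtype=int)
        k = idx.size
        if k < 2:
            continue
        labels = truth[idx]
        mismatches = 0
        for u, lab in zip(*np.unique(labels, return_counts=True)):
            mismatches += lab * (k - lab)
        mismatches //= 2
        total += 2.0 * (k / n) * mismatches / (k * (k - 1))
    return total
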