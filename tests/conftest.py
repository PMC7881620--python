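from __future__ import annotations

import numpy as np
import pytest

from rigidseg import FixtureSpec, make_ensemble
from rigidseg.line_crf import LabeledLineGraph

PDB_3RES = """\
ATOM      1  N   ALA A   1      -1.000   0.500   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      4  CA  ALA A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""

PDB_MISSING_CA = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  N   ALA A   2       3.800   0.000   0.000  1.00  0.00           N
ATOM      3  CA  ALA A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def pdb_3res(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(PDB_3RES)
    return path


@pytest.fixture
def pdb_missing_ca(tmp_path):
    path = tmp_path / "gap.pdb"
    path.write_text(PDB_MISSING_CA)
    return path


@pytest.fixture(scope="session")
def two_domain():
    """60+60 residues, 60 deg hinge, 0.3 Å noise, M=2 — with ground truth."""
    return make_ensemble(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def three_domain():
    return make_ensemble(FixtureSpec(domain_sizes=(50, 40, 60),
                                     hinge_angles=(30.0, 45.0), seed=7))


def random_line_graph(rng: np.random.Generator, n: int | None = None,
                      p: float = 0.35) -> LabeledLineGraph:
    """Random labeled line graph with outlier flags on the xi suffix.

    The structural invariant (gamma = -1 only for the largest xi values)
    is respected; community pairs are dummies, the CRF never reads them.
    """
    if n is None:
        n = int(rng.integers(1, 13))
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)
             if rng.random() < p]
    xi_v = rng.gamma(2.0, 1.0, size=n)
    xi_e = rng.gamma(2.0, 1.0, size=len(edges))

    def suffix_flags(values, k):
        flags = np.ones(len(values), dtype=int)
        if k:
            top = np.argsort(values, kind="stable")[len(values) - k:]
            flags[top] = -1
        return flags

    gv = suffix_flags(xi_v, int(rng.integers(0, max(n // 3, 1) + 1)))
    ge = suffix_flags(xi_e, int(rng.integers(0, max(len(edges) // 3, 1) + 1))) \
        if edges else np.empty(0, dtype=int)
    return LabeledLineGraph(
        vertices=[(i, 1000 + i) for i in range(n)],
        edges=edges,
        xi_vertex=xi_v,
        xi_edge=np.asarray(xi_e, dtype=float),
        gamma_vertex=gv,
        gamma_edge=ge,
    )
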