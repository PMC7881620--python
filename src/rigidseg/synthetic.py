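"""Synthetic multi-conformation ensembles with known rigid domains.

The generator emulates hinge motion, the classic large-scale
conformational change: a chain of consecutive rigid domains connected by
hinges, each conformation bending the hinges by a fraction of the full
hinge angle (conformation m uses angle * m / (M - 1), a linear morph) with
isotropic Gaussian coordinate noise on top.  The backbone is an ideal
helical curve with consecutive-residue spacing equal to
``backbone_spacing`` — self-avoiding by construction and locally dense, so
the default 7.5 Å cutoff yields a connected, banded contact graph like a
real protein chain's.

Ground-truth domain labels come back alongside the coordinates, so every
pipeline stage can be scored against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .protein_graph import Segmentation
from .structures_io import ConformationEnsemble, write_multimodel_pdb

_CLASH_DISTANCE = 3.0   # Å, between residues more than 4 apart in sequence
_RETRY_BUDGET = 100


class GenerationError(RuntimeError):
    """Raised when no clash-free geometry is found within the retry budget."""


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic hinge-motion ensemble."""

    domain_sizes: tuple[int, ...] = (60, 60)
    hinge_angles: tuple[float, ...] = (60.0,)   # degrees, one per hinge
    noise_sd: float = 0.3                       # Å
    n_conformations: int = 2
    seed: int = 0
    backbone_spacing: float = 3.8               # Å between consecutive CA

    def __post_init__(self) -> None:
        if len(self.domain_sizes) < 1 or any(s < 10 for s in self.domain_sizes):
            raise ValueError("every domain needs at least 10 residues")
        if len(self.hinge_angles) != len(self.domain_sizes) - 1:
            raise ValueError("need one hinge angle per adjacent domain pair")
        if any(not 0.0 <= a <= 180.0 for a in self.hinge_angles):
            raise ValueError("hinge angles must lie in [0, 180] degrees")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_conformations < 2:
            raise ValueError("need at least two conformations")
        if self.backbone_spacing <= 0:
            raise ValueError("backbone_spacing must be positive")

    @property
    def n_residues(self) -> int:
        return sum(self.domain_sizes)


def _helix_backbone(n: int, spacing: float) -> np.ndarray:
    # ideal alpha-helix CA geometry (r=2.3 Å, 100 deg/residue, 1.5 Å rise),
    # uniformly rescaled so consecutive CA-CA distance equals `spacing`
    radius, twist, rise = 2.3, np.deg2rad(100.0), 1.5
    i = np.arange(n)
    coords = np.stack([radius * np.cos(twist * i),
                       radius * np.sin(twist * i),
                       rise * i], axis=1)
    step = np.linalg.norm(coords[1] - coords[0])
    return coords * (spacing / step)


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return (np.eye(3) + np.sin(angle_rad) * k
            + (1 - np.cos(angle_rad)) * (k @ k))


def _has_clash(coords: np.ndarray) -> bool:
    n = len(coords)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    ii, jj = np.triu_indices(n, k=5)   # ignore near-sequence neighbours
    return bool((dist[ii, jj] < _CLASH_DISTANCE).any())


def make_ensemble(spec: FixtureSpec) -> tuple[ConformationEnsemble,
                                              Segmentation]:
    """Generate a hinge-motion ensemble and its ground-truth segmentation.

    Deterministic for a fixed seed.  Hinge axes are drawn at random
    (perpendicular components dominate so the chain bends rather than
    twists); axis sets producing steric clashes are rejected and redrawn,
    up to a retry budget.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    m = spec.n_conformations
    base = _helix_backbone(n, spec.backbone_spacing)
    boundaries = np.cumsum(spec.domain_sizes)[:-1]   # first residue of next domain
    chain_axis = np.array([0.0, 0.0, 1.0])           # helix axis of the backbone

    for _ in range(_RETRY_BUDGET):
        # hinge axes perpendicular to the chain direction, so the arm bends
        # (an axis along the chain would merely twist the helix in place)
        axes = rng.normal(size=(len(boundaries), 3))
        axes -= np.outer(axes @ chain_axis, chain_axis)
        norms = np.linalg.norm(axes, axis=1)
        if (norms < 1e-6).any():
            continue
        axes /= norms[:, None]

        conformations = np.empty((m, n, 3))
        ok = True
        for conf in range(m):
            frac = conf / (m - 1)
            coords = base.copy()
            cumulative = np.eye(3)
            for h, boundary in enumerate(boundaries):
                angle = np.deg2rad(spec.hinge_angles[h]) * frac
                if angle == 0.0:
                    continue
                pivot = coords[boundary - 1]
                # the arm past this hinge has been rotated by earlier hinges;
                # bend about the correspondingly rotated axis
                rot = _rotation_matrix(cumulative @ axes[h], angle)
                coords[boundary:] = (coords[boundary:] - pivot) @ rot.T + pivot
                cumulative = rot @ cumulative
            if frac > 0 and any(a > 0 for a in spec.hinge_angles) \
                    and _has_clash(coords):
                ok = False
                break
            conformations[conf] = coords
        if ok:
            break
    else:
        raise GenerationError(
            f"no clash-free hinge geometry in {_RETRY_BUDGET} attempts; "
            "reduce the hinge angles or domain count")

    conformations += rng.normal(scale=spec.noise_sd,
                                size=conformations.shape)
    residue_ids = [("A", i + 1, "") for i in range(n)]
    labels = np.repeat(np.arange(len(spec.domain_sizes)),
                       spec.domain_sizes)
    ensemble = ConformationEnsemble(
        conformations, residue_ids,
        [f"synthetic#{spec.seed}m{i}" for i in range(m)])
    truth = Segmentation(labels, residue_ids=residue_ids)
    return ensemble, truth


def write_fixture(spec: FixtureSpec, pdb_path: str | Path,
                  truth_path: str | Path) -> tuple[ConformationEnsemble,
                                                   Segmentation]:
    """Write the fixture as a multi-model PDB plus a ground-truth TSV."""
    ensemble, truth = make_ensemble(spec)
    write_multimodel_pdb(pdb_path, ensemble)
    truth.to_tsv(truth_path)
    return ensemble, truth
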