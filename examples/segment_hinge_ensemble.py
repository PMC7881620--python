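"""Segment a synthetic two-domain hinge ensemble and score the result.

Generates 120 residues in two 60-residue rigid domains related by a 60
degree hinge bend (two conformations, 0.3 Å coordinate noise), runs the
full pipeline, and compares the recovered domains with the planted truth.
"""

from rigidseg import (FixtureSpec, SegmentationConfig, make_ensemble,
                      overlap, segment)

ensemble, truth = make_ensemble(FixtureSpec(
    domain_sizes=(60, 60), hinge_angles=(60.0,), noise_sd=0.3,
    n_conformations=2, seed=11))

segmentation, tree = segment(ensemble, SegmentationConfig(seed=11))

print(f"residues: {ensemble.n_residues}, "
      f"conformations: {ensemble.n_conformations}")
print(f"domains found: {segmentation.n_domains}")
for d, rmsd in segmentation.domain_rmsd.items():
    size = int((segmentation.labels == d).sum())
    print(f"  domain {d}: {size} residues, ensemble RMSD {rmsd:.2f} Å")
print(f"overlap with ground truth: {overlap(segmentation, truth):.3f}")
print(f"recursion steps: {tree.summary()['n_steps']}")
# Each domain's RMSD is far below the 3.5 Å rigidity threshold while the
# whole chain is not rigid, so the hinge was found; overlap near 1 means
# almost every residue landed in the right domain.
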