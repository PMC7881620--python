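"""Agreement metrics on a worked example, and prior-guided reweighting.

First scores two small hand-written segmentations against each other, then
shows how a prior segmentation can steer the contact graph: edges crossing
prior boundaries are down-weighted by alpha = 0.75 before coarse-graining.
"""

import numpy as np

from rigidseg import (FixtureSpec, SegmentationConfig, Segmentation,
                      make_ensemble, overlap, pair_error, segment)

a = np.array([1, 1, 1, 2, 2])
b = np.array([1, 1, 2, 2, 2])
print(f"overlap(a, b)    = {overlap(a, b):.2f}  "
      "(4 of 5 residues match under the best domain pairing)")
print(f"pair_error(a, b) = {pair_error(a, b):.2f}  "
      "(4 of 10 residue pairs disagree on same-domain status)")

ensemble, truth = make_ensemble(FixtureSpec(seed=5))
prior = Segmentation(truth.labels)   # a (here: perfect) prior labeling
plain, _ = segment(ensemble, SegmentationConfig(seed=5))
guided, _ = segment(ensemble, SegmentationConfig(seed=5),
                    prior=prior, alpha=0.75)
print(f"overlap without prior: {overlap(plain, truth):.3f}")
print(f"overlap with prior:    {overlap(guided, truth):.3f}")
# The prior cannot hurt a case the pipeline already solves; on harder
# inputs the down-weighted cross-boundary contacts keep Louvain
# communities from mixing residues of different domains.
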