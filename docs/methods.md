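# Methods

This note documents the model behind `rigidseg`, the parameters that
matter, the numerical conventions, and what the synthetic benchmark does
and does not establish.

## Model and assumptions

A *rigid domain* is a residue subset S whose internal geometry is
conserved across the M input conformations: the ensemble RMSD

    RMSD(S) = 2/(M(M−1)) · Σ_{m<m'} RMSD_S(X^(m), X^(m'))

(mean over all conformation pairs of the Kabsch-superposed RMSD restricted
to S) is strictly below the rigidity threshold θ. The method assumes

- a common residue index across conformations (externally aligned if the
  sequences differ; a TSV mapping table is the supported input for that),
- that relative domain motion shows up as variance in inter-residue
  distances, which is true for hinge and shear motions but degrades for
  intrinsically disordered regions, where everything is variable and the
  outlier signal washes out (such components end as flagged non-rigid
  leaves rather than looping),
- one representative atom per residue (Cα default; configurable, e.g. C1'
  for nucleic acids).

## Pipeline stages and their parameters

**Contact graph** (`protein_graph`). Edge iff the pair distance stays ≤ δ
in *every* conformation; δ = 7.5 Å by default (10.5/13.5 Å are sensible
alternatives — larger cutoffs densify the graph and the line graph, at
computational cost). Edge weight w = exp(−Var), with the sample variance
(denominator M−1) of the pair distance; the weight function is pluggable.
The weights influence only the Louvain step — everything downstream reads
the ξ statistics, not the weights. The alternative any-conformation rule
(edge iff close in ≥ 1 conformation, weight = fraction of close
conformations) is implemented for comparison and is measurably worse on
the synthetic benchmark (size-weighted inconsistency error of the Louvain
clusters), consistent with variance weighting being the default.

**Coarse-graining** (`coarse_grain`). The Louvain resolution is tuned by
geometric bisection until the community count falls in
[target−5, target+5] (target 20, cap 30 evaluations, best-effort with a
log record otherwise). ~20 communities balances two failure modes:
communities large enough to swallow hinge residues raise the
inconsistency error, while very small communities weaken the ξ signal and
blow up the line graph (its size grows quadratically in coarse degree).
ξ is computed over **all** cross pairs of residues from the distance
tensor, not only over contact-graph edges — the defining sum runs over
a1 ∈ c1, a2 ∈ c2 without restriction. Disconnected graphs are handled
natively (communities never span components).

**Line graph + CRF** (`line_crf`). The line graph is modified: incident
coarse-edge pairs are linked only when their end communities are
non-adjacent, so edge features add information not already carried by a
third coarse edge. Outliers of the ascending ξ arrays (vertices and edges
separately) are flagged one-sided — only values above the median can be
outliers, since inter-domain mean variances are larger than intra-domain
ones — using the robust z-score (x − median)/(1.4826·MAD) > 3.0. The
MAD consistency constant and threshold are the standard choices and are
configurable; a zero MAD falls back to the mean absolute deviation. The
edge feature Ψ² follows a three-case definition; the case triggers are
disambiguated as: (i) both vertex indicators +1 → the five hinge
sub-cases, with ξ equality decided at tolerance 1e-9; (ii) at least two
of {γ_e, γ_v1, γ_v2} equal −1 → reward iff both labels match their vertex
indicators; (iii) anything else contributes 0. The full truth table is
exercised against an independent transcription in the tests.

**Exact MAP inference.** The score decomposes over connected components.
Per component, max-sum bucket elimination along a min-fill ordering gives
the optimum; the labeling itself is recovered by clamping vertices in
index order (prefer +1, keep the clamp iff the constrained maximum is
unchanged), which realizes a deterministic lexicographic tie-break
(+1 < −1) exactly — all factor values are integers, so the equality test
is exact. Inference is exact whenever the induced boundary size is ≤ 25;
beyond that a `CapacityError` advises fewer, larger communities instead
of silently approximating. A brute-force backend (≤ 22 vertices)
implements the same tie rule and serves as the oracle in tests.

**Recursion** (`segmentation`). A component is final when it is rigid
(RMSD < θ, strict), consists of a single community, or the depth cap
(default 10) is reached. Non-rigid components are re-split on their
induced coarse subgraph; γ is recomputed from that subgraph's own ξ
arrays, because local medians reflect the subproblem better than
indicators inherited from the full graph. If a non-rigid component comes
back unsplit (MAP all +1), the outlier set is expanded by 0.1 of the
array length, at most twice, before the component is accepted as a
flagged non-rigid leaf — intrinsically flexible regions should not loop.

**Merging.** Two phases, both deterministic (ties to the smallest segment
index): (1) every segment below `min_domain_size` (default 10 residues)
is absorbed into the protein-graph-adjacent segment minimizing the merged
RMSD (all segments as fallback when none is adjacent); (2) among adjacent
pairs whose merged RMSD < θ, the smallest-RMSD pair is merged repeatedly
until none qualifies. Merging is idempotent; segments whose union has
fewer than 3 residues are treated as trivially rigid (superposition is
underdetermined below 3 points).

## Synthetic benchmark

The generator (`synthetic`) emulates hinge motion between consecutive
rigid domains: an ideal helical backbone (consecutive-residue spacing
3.8 Å — self-avoiding by construction, locally dense, so δ = 7.5 Å gives
a connected, banded contact graph), hinge axes drawn perpendicular to the
chain direction (an axis along the chain would twist in place rather than
bend), conformation m bent by fraction m/(M−1) of each hinge angle (a
linear morph), and isotropic Gaussian noise (default 0.3 Å) on every
coordinate. Axis draws leading to steric clashes (< 3 Å between residues
≥ 5 apart in sequence) are rejected, up to 100 retries. Defaults: two
60-residue domains, one 60° hinge, M = 2 — a regime where each true
domain stays sub-Å rigid while the whole chain moves by > 5 Å.

What passing on these fixtures shows: the pipeline recovers planted
hinge-domain structure from distance-variance signal alone, at realistic
noise. What it does not show: robustness to shear (small-amplitude)
motions, missing residues, flexible linkers longer than one residue,
domains that are non-contiguous in sequence (the method itself never uses
sequence contiguity, but the generator only plants contiguous domains),
or crystallographic artifacts. Problem sizes in the tests and the
acceptance script (120–150 residues, 2–5 conformations, 10 seeds) were
chosen as the smallest at which the hinge-vs-noise contrast is
unambiguous.

## Numerical conventions

- Sample variances use denominator M−1 throughout (matching the ξ
  normalization).
- Rigidity comparisons are strict (<); RMSD of < 3 points is undefined
  (error for user-facing calls, trivially rigid inside merging).
- Kabsch superposition corrects the sign of the last singular vector, so
  reflections are never used; the RMSD is evaluated from singular values.
- Louvain is seeded; with a fixed seed and fixed inputs the whole
  pipeline is bit-reproducible (the segmentation TSV is byte-identical
  across runs).
- Altloc resolution: highest occupancy, ties to the first altloc id;
  residues missing the representative atom are dropped with a warning.

## Known limitations

- Exact inference on very dense coarse graphs can exceed the boundary
  cap; the remedy (coarser communities) trades boundary size against
  hinge-resolution granularity.
- The overlap metric normalizes by N; with wildly different domain
  counts the linear assignment leaves surplus domains unmatched, which is
  intended but worth knowing when comparing against references that
  normalize differently.
- No hinge-residue localization beyond domain boundaries, no motion
  classification (hinge vs shear), and no all-atom RMSD.
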