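# rigidseg

Rigid-domain detection from multiple conformations of a protein.

Proteins carry out large-scale conformational changes — hinge and shear
motions between nearly-rigid domains. Given two or more structures of the
same protein (open/closed crystal forms, NMR models, morph snapshots),
`rigidseg` partitions the residues into rigid domains **without being told
how many domains to look for**. It is aimed at structural biologists and
method developers who want a dependency-light, scriptable alternative to
domain-motion web servers, with every intermediate object inspectable from
Python.

## Method

One representative atom per residue (Cα by default) gives, for each
conformation *m*, coordinates `X^(m) ∈ R^(N×3)` and a distance matrix
`D^(m)`. The pipeline is:

1. **Protein graph.** Residues *k, l* are connected iff
   `max_m D^(m)_kl ≤ δ` (default δ = 7.5 Å, elastic-network-style cutoff);
   the edge weight is `exp(−Var_m D^(m)_kl)`, so conformationally stable
   contacts weigh ~1 and variable ones are suppressed.
2. **Coarse-graining.** Louvain communities (resolution auto-tuned to
   ≈ 20 communities) become the vertices of a coarse graph; every
   community pair carries the *mean variance*
   `ξ(c1,c2) = (1/(|c1||c2|(M−1))) Σ_{a1∈c1} Σ_{a2∈c2} Σ_m (D^(m)_{a1a2} − mean_m D_{a1a2})²`,
   the motion signal: pairs moving relative to each other inflate ξ.
3. **Line-graph CRF.** Coarse edges become vertices of a modified line
   graph (incident edge pairs are linked only if their end communities are
   *not* adjacent). One-sided MAD outlier detection on the ascending ξ
   arrays yields indicators γ ∈ {−1,+1}; a pairwise conditional random
   field `score(y) = Σ_v γ_v y_v + Σ_e Ψ²(e, y)` is maximized exactly
   (bucket elimination — a generalized Viterbi algorithm for arbitrary
   graphs). Vertices labeled −1 are inter-domain edges and are cut.
4. **Recursion + merging.** Components whose ensemble RMSD
   (`(2/(M(M−1))) Σ_{m<m'} RMSD_S(X^(m), X^(m'))`, Kabsch-superposed) is
   below θ = 3.5 Å are accepted as rigid; others are re-split. A final
   pass absorbs fragments of < 10 residues and merges adjacent domains
   whose union is still rigid.

A prior segmentation can be supplied: contacts crossing its boundaries
are down-weighted by α (default 0.75) before coarse-graining.

## Worked example

```sh
python examples/segment_hinge_ensemble.py
```

generates a 120-residue, two-conformation ensemble whose halves are
related by a 60° hinge bend (0.3 Å noise) and prints:

```
residues: 120, conformations: 2
domains found: 2
  domain 0: 59 residues, ensemble RMSD 0.65 Å
  domain 1: 61 residues, ensemble RMSD 0.75 Å
overlap with ground truth: 0.992
recursion steps: 3
```

Both recovered domains are far below the 3.5 Å rigidity threshold while
the whole chain is not rigid, so the hinge was localized; overlap 0.992
means 119 of 120 residues landed in the planted domain (the stray is at
the ambiguous hinge boundary). `examples/line_graph_inference.py` exposes
the intermediate ξ/γ/MAP objects, and `examples/compare_and_prior.py`
shows the agreement metrics and prior reweighting.

The same pipeline is available from the shell:

```sh
rigidseg fixture --sizes 60,60 --angles 60 --out-prefix fx
rigidseg segment --structure fx.pdb:A --out-prefix run   # multi-model PDB
rigidseg compare run.segments.tsv fx.truth.tsv
```

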