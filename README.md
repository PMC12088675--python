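# morphorank

Morphometric ranking of microglia from binarized single-cell masks.

Microglia — the resident immune cells of the central nervous system —
shift continuously between *ramified* (small soma, many fine branched
processes), *rod-like* (bipolar, elongated) and *amoeboid* (round,
few processes) shapes depending on age, region and pathology.  Because
these shapes form a continuum rather than discrete classes, `morphorank`
**orders** cells along a single morphology axis instead of clustering
them: every cell gets a scalar score, and two experimental conditions can
be compared by the overlap of their score distributions.

## Method

The pipeline has two stages.

**Measurement.**  Each input mask (one cell per image, foreground = cell)
is standardized to 0.5 µm/pixel on a 300×300 field, cleaned (largest
8-connected component, interior holes filled) and reduced to 20
dimensionless descriptors: circularity `2√(πA)/P` and its reciprocal
ramification index, perimeter²/area, density on the fixed field, a
soma/processes partition obtained by erosion-to-extinction followed by a
surface-matched cross-shaped reconstruction (giving area ratios and a
polarization index), skeleton statistics from topology-preserving
thinning (skeleton length², branch/end-point ratio), a Sholl-profile
branching index, box-counting fractal dimension, gliding-box lacunarity,
convex-hull ratios (solidity, convexity, hull circularity, span and radii
ratios), and coordinate-PCA elongation (linearity `VarMax/VarMin`,
inertia = axis-length ratio).

**Ranking.**  Five descriptors whose natural direction opposes the
ramification axis (lacunarity, roundness factor, hull radii ratio,
processes/cell areas ratio, skeleton/processes ratio) are sign-inverted;
all columns are z-scored.  A PCA of the resulting correlation structure
projects each parameter onto PC1/PC2 (correlation-circle convention,
loading × √eigenvalue).  Parameters are ranked by |PC1 projection| and
the shortest prefix whose cumulative share reaches a threshold (default
0.8) is kept, with weights `W_n = |w_n|/|w_0|` and phases
`φ_n = arctan(y_n/W_n)`.  Each cell *j* then becomes an Andrews curve

    S_j(t) = Σ_n  F_jn · W_n · cos(2πnt + φ_n),   t ∈ [0, 1)

sampled at 360 angles.  At the angle θ\* where the across-cell variance
of the curves is maximal, `S_j(θ*)` is the cell's **Andrews score**; cells
are ranked by it, most amoeboid first.

A seeded synthetic-cell generator (soma disk + branching persistent
random walks, complexity knob c ∈ [0,1] from bare disk to hyper-ramified)
provides cohorts with known ground-truth ordering, so the whole pipeline
is testable without microscopy data.

## Worked example

```
$ morphorank synth --n 30 --seed 42 --out demo/masks
wrote 30 masks + ground_truth.csv -> demo/masks
$ morphorank run --masks demo/masks --out demo/out
ranked 30 cells (0 excluded) -> demo/out
$ head -4 demo/out/ranking.csv
rank,cell_id,andrews_score,group_label
1,cell_0000,10.047523579349539,
2,cell_0001,9.606210900271048,
3,cell_0002,8.801197550752397,
```

The cohort spans the complexity gradient (cell_0000 is a bare disk,
cell_0029 is hyper-ramified), and the ranking recovers it: rank 1 is the
most amoeboid cell, with scores descending toward the ramified end.
`demo/out/report.json` records the machine-readable diagnostics: on this
cohort 14 of the 20 parameters are selected at the 0.8 threshold (led by
`ramification_index`), the first two principal components carry 81% of
the total variance, and the maximum curve variance sits at θ\* = 111°.

Other subcommands: `measure` (masks → 20-column feature CSV), `rank`
(feature CSV → ranking, for pre-computed tables), `compare` (Spearman ρ
and rank-difference histogram between two rankings), `overlap`
(score-distribution overlap between two labelled groups).  All are thin
wrappers over the `morphorank` library API (`compute_features`,
`prepare_matrix`, `pca_select`, `andrews_rank`, ...).

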