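# fishmorph

3D landmark geometric morphometrics of fish body shape: Generalized
Procrustes Analysis (GPA), PCA morphospace construction, per-landmark
eigenvector-contribution analysis, anatomical-axis variance decomposition,
clade-wise morphospace occupancy, and a synthetic fauna generator with
ground truth for parameter-recovery testing.

The package targets faunal-scale body-shape studies of the kind performed
on the Lower Mississippi Basin (LMB) ichthyofauna: each specimen is
digitized as 11 homologous 3D landmarks (tip of snout, eyes, pectoral and
pelvic fin insertions, dorsal- and anal-fin anterior insertions, hypural
margins) in 3D Slicer and exported as `.fcsv` fiducial files; species are
nested in family and clade groups; and the questions are where shape
variance lives — which landmarks, which anatomical axes, which clades.

## The model

Each specimen is a configuration $X_i \in \mathbb{R}^{p\times 3}$ of
$p=11$ landmarks. GPA removes location, scale and orientation: every
configuration is centered, scaled to unit centroid size
$\mathrm{CS}(X)=\sqrt{\sum_l \lVert x_l-\bar x\rVert^2}$, and iteratively
rotated (proper rotations only, via SVD) to minimize
$\sum_i \lVert X_i - \bar X \rVert^2$ against the unit-size consensus
$\bar X$, which is re-estimated each pass. PCA of the covariance of the
flattened aligned coordinates yields eigenvalues $\lambda_k$ (variance
fractions $w_k=\lambda_k/\sum\lambda$) and unit eigenvectors $e_k$, each a
$p \times 3$ deformation field of the mean shape.

On top of this standard machinery sit the study-specific summaries:

- **Weighted landmark magnitudes** — $m_{lk} = w_k\,\lVert e_k[l,:]\rVert$,
  with row sums $S_l$, normalized percentages
  $N_l = 100\,S_l/\sum_l S_l$, and per-PC column fractions for landmark
  subsets (e.g. the share of PC1 carried by fin-insertion landmarks).
- **Axis decomposition** — summing per-landmark coordinate variances
  separately over the anteroposterior, dorsoventral and mediolateral axes
  splits total Procrustes disparity into length, depth and width;
  identically $V_d = \sum_k \lambda_k \sum_l e_k[l,d]^2$.
- **Centroid outlier score** — $\sum_k w_k\,\lvert s_{ik}\rvert$ flags
  species far from the faunal mean.
- **Morphospace occupancy** — minimum convex hulls of species-mean scores
  per nested clade group.

The synthetic generator inverts the analysis: species-level amplitudes on
orthogonal "growth-field" deformation modes, landmark noise, and nuisance
similarity transforms, with full ground truth for recovery tests.

## Worked example

`examples/landmark_contributions.py` runs a simulated fauna end to end and
then feeds the published LMB weighted-magnitude table through the same
arithmetic:

```
published LMB summary, recomputed totals:
  DF anterior insertion: Sum=0.515  Norm=18.44%
  Left P2: Sum=0.326  Norm=11.67%
  Left eye: Sum=0.132  Norm=4.73%
  fin landmarks on PC1: 62.9% of that component
  fin landmarks on PC2: 56.6% of that component
  fin landmarks on PC3: 58.4% of that component
```

The `Sum` column totals each landmark's variance-weighted eigenvector
magnitude over the top six PCs; `Norm` rescales those totals to
percentages of the fauna-wide sum — the dorsal-fin insertion alone carries
18.44% of the weighted eigenvector magnitude. The per-PC lines give the
fraction of one component's total magnitude carried by the median- and
paired-fin insertion landmarks, matching the published 62.8 / 56.6 /
58.5% to the rounding of the printed inputs.

Other examples (each a short, runnable narrative): `simulate_fauna.py`,
`align_and_morphospace.py`, `axis_decomposition.py`, `full_pipeline.py`.

A thin CLI wraps the pipeline for shell use:

```sh
fishmorph simulate --seed 1 -o fauna/
fishmorph run-all --input fauna/manifest.csv -o run/
fishmorph report run/
```

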