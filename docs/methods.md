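# Methods

## Procrustes superimposition

Configurations are centered, scaled to unit centroid size, and rotated
iteratively onto the running consensus: the initial consensus is the first
configuration (deterministic), every configuration is rotated to it by the
SVD solution of the orthogonal Procrustes problem restricted to proper
rotations (determinant +1 — left and right landmarks are digitized
explicitly, so mirror alignments are anatomically wrong), and the
consensus is replaced by the unit-size-rescaled arithmetic mean of the
rotated set. Iteration stops when the Procrustes distance between
successive consensus estimates falls below `tolerance` (default 1e-8,
cap 100 iterations; convergence is typically reached in 3–6 iterations).
The GPA objective Σᵢ‖Xᵢ − consensus‖² is recorded each pass and is
non-increasing by construction of each step.

Scale is removed once per specimen and the consensus is rescaled to unit
size every iteration — the standard full-Procrustes convention, which
guarantees that all aligned configurations and the consensus have unit
centroid size exactly. Projection of the aligned shapes onto the tangent
space at the consensus is available (`project_to_tangent=True`) but off by
default: the downstream contribution analysis operates on plain Procrustes
coordinates.

**Frame anchoring.** GPA fixes shape but not the global orientation of
shape space: the output frame follows the first specimen. For real data
digitized in a consistent anatomical orientation this is what one wants;
for simulated data whose specimens carry random nuisance rotations the
frame is arbitrary, so `align_to_reference` rotates a whole alignment so
its consensus matches a reference configuration (the generator template).
The pipeline does this automatically in simulate mode. Eigenvalues,
scores, per-landmark magnitude norms and Procrustes distances are
frame-invariant; the axis decomposition and eigenvector *components* are
not, which is why the recovery tests re-anchor before comparing.

## Morphospace

PCA is performed on the covariance (not correlation) matrix of the
flattened aligned coordinates: Procrustes coordinates share one scale, and
covariance PCA keeps the morphospace metric — distances in score space are
Procrustes distances. Sample covariance uses denominator n−1 throughout,
so the eigenvalue sum equals the total sample variance exactly and the
raw-coordinate and eigen-route axis decompositions agree to machine
precision. Components below 1e-12 of the leading eigenvalue are dropped
(GPA leaves at most 3p−7 nonzero directions). Each eigenvector is oriented
so its largest-magnitude entry is positive (ties to the lowest index),
making reports independent of the numerical backend. The retained
dimension K defaults to the smallest K reaching 95% cumulative variance,
mirroring common reporting practice for this kind of fauna (top six PCs ≈
95%); it is configurable everywhere it matters.

The model's `mean_shape` is the arithmetic mean of the aligned
configurations — the PCA centering — so that reconstruction
(mean + Σ scoreₖ·eₖ) and the `shape_at_pc` score round-trip are exact. The
unit-size rescaled version of the same mean is the GPA consensus
(`mean_shape(alignment)`); the two differ by a scalar factor within
O(total variance) of 1.

The centroid outlier score is Σₖ wₖ|scoreₖ| over all retained components
by default (configurable `K_use`): a variance-weighted L1 eccentricity
that flags long-rostrum outliers and similar extreme shapes. Convex hulls
for clade occupancy are computed on species-mean scores (means of member
specimens' scores; equivalent to means of aligned coordinates by
linearity) via Qhull, with explicit degenerate handling (single point,
collinear set → point/segment of area zero).

## Landmark contribution analysis

m[l,k] = wₖ·‖eₖ[l,:]‖ with wₖ the variance *proportion* (0.511, not
51.1) over all nonzero components — the weight is a property of the full
decomposition, not of the K displayed columns. On the proportion scale the
per-column sums necessarily lie in [wₖ, wₖ√p] (Cauchy–Schwarz for a unit
vector split into p 3-blocks), which fails on the percent scale; this is
asserted in tests. The normalization denominator of Norm (%) uses the K
displayed columns. Reports round magnitudes to 3 decimals and percentages
to 2, ranked by row sum descending.

The axis decomposition is computed from raw aligned coordinates (all
components) by default; a `top_k` flag restricts to leading components via
the eigen route when a truncated summary is wanted.

## Synthetic fauna generator

The generator emulates the structure of a faunal landmark dataset: a
fusiform 11-landmark template (standard length 1.0; dorsal-fin insertion
0.25 SL above the midline, vertically aligned with the pelvic fins; head
≈ 0.3 SL; bilateral pairs mirrored), species nested in the four clade
groups, per-species amplitudes aₛₘ ~ Normal(offset(g), σₘ) on additive
deformation modes, iid per-coordinate landmark noise (σ_ε, default
0.005 SL), and per-specimen nuisance transforms: uniform random proper
rotation, Normal(0, 0.5) translation per axis, and log-uniform scale in
[0.5, 2] (bounded away from degenerate centroid sizes).

Defaults emulate a 166-species, 4-group fauna with 2 specimens per
species (332 configurations; the real deposit has 232 specimens in 166
species — one to several per species — and 2 is the smallest count that
exercises species-mean machinery). Mode amplitude spreads are proportional
to the square roots of leading variance fractions typical of fish faunas
(0.511 : 0.159 : 0.134 : 0.064) scaled to 0.1 SL overall; group offsets
place clades apart chiefly along the elongation mode, echoing the
elongate-to-deep-bodied PC1 clade structure of real faunas. Normal
amplitude distributions are used for analytic tractability of the
recovery checks.

**Tangent-space modes.** All four default modes (elongation, deepening,
widening, head size) are constructed to be *exactly* orthogonal to the
seven similarity directions at the template (translations, rotation
generators, scale), by solving a small nullspace problem on a tied,
mirror-symmetric landmark support; residual overlaps between modes are
removed by Gram–Schmidt. A mode with a net translation/rotation/scale
component would be partially absorbed by the superimposition and could
never be recovered cleanly; tangent modes survive alignment to first
order. The deepening mode is purely dorsoventral and the widening mode
purely mediolateral by construction, which makes the axis-decomposition
recovery checks sharp.

Random streams are split per species and per specimen via seed-sequence
spawn keys, and within a specimen between shape noise and nuisance
transforms — so changing `specimens_per_species` never perturbs species
draws, and toggling nuisance never changes the shapes.

**What the generator does not emulate**, hence what passing recovery
tests do not show about real data: photogrammetric measurement error
structure (noise here is iid and isotropic), preservation artifacts
(bending), allometry and other size–shape covariance, tree-based
phylogenetic trait evolution (clade structure is mean offsets only), and
cross-axis deformation modes. Because the default modes are axis-pure,
mode variance shares map one-to-one onto axis variance shares, which real
faunas — where depth variance is spread across several mixed-axis PCs —
do not obey.

## Numerical behavior worth knowing

- Shape-space curvature makes eigenvector recovery second-order biased at
  finite amplitude: with a single generating mode of spread σ, the
  recovered first eigenvector deviates from the mode by O(σ) in
  per-landmark norms (≈ 0.2σ empirically). The exact-recovery tests
  therefore run in a small-amplitude regime, with a companion assertion at
  realistic amplitude and looser tolerance.
- The spec of fiducial files follows 3D Slicer: `# CoordinateSystem`
  values `RAS`/`0` pass through, `LPS`/`1` negate the first two columns;
  landmarks are matched by label, never row order; missing or duplicated
  labels are hard errors (taxa lacking homologous landmarks are excluded,
  not imputed).
- Degenerate inputs: all-coincident landmarks (centroid size 0) raise at
  scaling; a rank-deficient rotation cross-product matrix emits a warning
  and returns one of the minimizers; ties in nearest-to-mean are broken by
  dataset order with a warning.
- Reported problem sizes in the acceptance script (50–2000 synthetic
  specimens) were chosen as the smallest that make each check statistically
  sharp; the whole script runs in seconds.
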