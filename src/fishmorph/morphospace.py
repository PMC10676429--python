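"""PCA morphospace of Procrustes-aligned shapes.

The covariance matrix of the flattened aligned coordinates is
eigendecomposed; each eigenvector is a ``p x 3`` per-landmark displacement
field (a deformation of the mean shape) and each eigenvalue the Procrustes
variance it explains.  Covariance (not correlation) PCA is used throughout:
Procrustes coordinates share a single scale, so the morphospace stays
metric — distances in score space are Procrustes shape distances.

Specimen scores, species mean scores, centroid-outlier scores, PC endpoint
shapes and per-clade convex-hull occupancy are all derived from the fitted
model here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .gpa import AlignmentResult, center_scale


@dataclass
class MorphospaceModel:
    """A fitted PCA morphospace.

    Attributes
    ----------
    mean_shape
        ``p x 3`` arithmetic mean of the aligned configurations — the PCA
        centering.  (The unit-size rescaled version is the GPA consensus;
        the two agree up to a scalar factor very close to 1.)
    eigenvalues
        Non-increasing sample variances of the components (all numerically
        nonzero components are kept, so their sum equals the total
        Procrustes variance).
    variance_fractions
        ``eigenvalues / eigenvalues.sum()`` — the weights w_k used in the
        landmark contribution analysis.
    eigenvectors
        ``K x 3p`` matrix; row k is the unit displacement field of PC k+1,
        oriented so its largest-magnitude entry is positive.
    scores
        ``n x K`` specimen scores (zero column means).
    K_retained
        Smallest K whose cumulative variance fraction reaches the retention
        threshold (default 0.95).
    """

    mean_shape: np.ndarray
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    eigenvectors: np.ndarray
    scores: np.ndarray
    K_retained: int
    specimen_ids: list[str]
    species: list[str]
    groups: list[str]
    retention_threshold: float = 0.95

    @property
    def n_components(self) -> int:
        return self.eigenvalues.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.mean_shape.shape[0]

    def eigenvector_field(self, k: int) -> np.ndarray:
        """Eigenvector of PC ``k`` (1-based) reshaped to ``p x 3``."""
        if not 1 <= k <= self.n_components:
            raise ValueError(f"PC index {k} out of range 1..{self.n_components}")
        return self.eigenvectors[k - 1].reshape(self.n_landmarks, 3)

    def project(self, shape: np.ndarray) -> np.ndarray:
        """Score vector of an aligned ``p x 3`` shape."""
        flat = np.asarray(shape, dtype=float).reshape(-1) - self.mean_shape.reshape(-1)
        return self.eigenvectors @ flat


@dataclass
class SpeciesSummary:
    """Per-species morphospace summary: mean score and sample size."""

    species: str
    mean_scores: np.ndarray
    n_specimens: int
    group: str = ""


def fit_pca(alignment: AlignmentResult,
            retention_threshold: float = 0.95) -> MorphospaceModel:
    """Fit the PCA morphospace to an alignment.

    Eigendecomposition of the sample covariance (denominator ``n - 1``) of
    the flattened aligned coordinates, components sorted by decreasing
    eigenvalue.  Numerically zero components (below ``1e-12`` of the
    leading eigenvalue) are dropped; at most ``3p - 7`` survive because GPA
    removes seven similarity degrees of freedom.

    Sign convention: each eigenvector is oriented so that its
    largest-magnitude entry is positive (ties resolved to the lowest
    index), making reports reproducible across numerical backends.
    """
    n = alignment.n_specimens
    if n < 3:
        raise ValueError(f"PCA needs at least 3 specimens, got {n}")
    X = alignment.flattened()
    center = X.mean(axis=0)
    Xc = X - center

    # SVD route: eigenvalues of the covariance are s^2 / (n - 1)
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    keep = eigenvalues > eigenvalues[0] * 1e-12 if eigenvalues[0] > 0 else slice(0, 1)
    eigenvalues = eigenvalues[keep]
    vectors = Vt[keep]

    # deterministic orientation
    for row in vectors:
        idx = int(np.argmax(np.abs(row)))
        if row[idx] < 0:
            row *= -1.0

    scores = Xc @ vectors.T
    fractions = eigenvalues / eigenvalues.sum()
    cumulative = np.cumsum(fractions)
    K_retained = int(np.searchsorted(cumulative, retention_threshold - 1e-12) + 1)
    K_retained = min(K_retained, len(eigenvalues))

    return MorphospaceModel(
        mean_shape=center.reshape(alignment.n_landmarks, 3),
        eigenvalues=eigenvalues,
        variance_fractions=fractions,
        eigenvectors=vectors,
        scores=scores,
        K_retained=K_retained,
        specimen_ids=list(alignment.specimen_ids),
        species=list(alignment.species),
        groups=list(alignment.groups),
        retention_threshold=retention_threshold,
    )


def mean_shape(alignment: AlignmentResult, rescale: bool = True) -> np.ndarray:
    """Arithmetic mean of the aligned configurations (the 'mshape').

    With ``rescale`` (default) the mean is rescaled to unit centroid size,
    matching the GPA consensus exactly.
    """
    mean = alignment.aligned.mean(axis=0)
    return center_scale(mean) if rescale else mean


def species_means(model: MorphospaceModel) -> list[SpeciesSummary]:
    """Per-species mean score vectors (mean over member specimens)."""
    summaries: list[SpeciesSummary] = []
    seen: dict[str, int] = {}
    for sp in model.species:
        key = sp or "<unknown>"
        if key not in seen:
            seen[key] = len(summaries)
            summaries.append(SpeciesSummary(key, np.zeros(model.n_components), 0))
    for sp, grp, row in zip(model.species, model.groups, model.scores):
        summary = summaries[seen[sp or "<unknown>"]]
        summary.mean_scores = summary.mean_scores + row
        summary.n_specimens += 1
        summary.group = summary.group or grp
    for summary in summaries:
        summary.mean_scores = summary.mean_scores / summary.n_specimens
    return summaries


def nearest_to_mean(model: MorphospaceModel, level: str = "specimen",
                    K_use: int | None = None) -> str:
    """Identifier closest to the morphospace origin (the mean shape).

    Distance is the Euclidean norm in the first ``K_use`` (default: all
    retained) score dimensions; at ``level='species'`` species mean scores
    are used.  Ties are broken by dataset order with a warning.
    """
    K = model.K_retained if K_use is None else K_use
    if level == "specimen":
        labels = model.specimen_ids
        points = model.scores[:, :K]
    elif level == "species":
        summaries = species_means(model)
        labels = [s.species for s in summaries]
        points = np.stack([s.mean_scores[:K] for s in summaries])
    else:
        raise ValueError(f"level must be 'specimen' or 'species', got {level!r}")
    if len(labels) == 0:
        raise ValueError("empty dataset")
    norms = np.linalg.norm(points, axis=1)
    best = int(np.argmin(norms))
    if np.sum(np.isclose(norms, norms[best], rtol=0, atol=1e-12)) > 1:
        warnings.warn("tie in distance to mean; returning the first by dataset "
                      "order", RuntimeWarning, stacklevel=2)
    return labels[best]


def centroid_outlier_score(scores: np.ndarray, w: np.ndarray,
                           K_use: int | None = None) -> float:
    """Variance-weighted L1 eccentricity of one specimen in the morphospace.

    The sum over components of the absolute score weighted by that
    component's variance fraction: ``sum_k w_k * |score_k|``.  Large values
    flag shapes far from the faunal mean (e.g. long-rostrum outliers).
    """
    scores = np.asarray(scores, dtype=float)
    w = np.asarray(w, dtype=float)
    if scores.shape != w.shape:
        raise ValueError(f"scores and weights length mismatch: "
                         f"{scores.shape} vs {w.shape}")
    K = scores.shape[0] if K_use is None else K_use
    if K > scores.shape[0]:
        raise ValueError(f"K_use={K} exceeds available components {scores.shape[0]}")
    return float(np.sum(w[:K] * np.abs(scores[:K])))


def shape_at_pc(model: MorphospaceModel, k: int, t: float | None = None,
                sd_units: float | None = None) -> np.ndarray:
    """Shape at displacement ``t`` along PC ``k`` (1-based) from the mean.

    ``t`` is in Procrustes units; alternatively ``sd_units=c`` places the
    shape at ``c * sqrt(lambda_k)``.  ``t=0`` returns the mean shape.
    """
    if not 1 <= k <= model.n_components:
        raise ValueError(f"PC index {k} out of range 1..{model.n_components}")
    if (t is None) == (sd_units is None):
        raise ValueError("provide exactly one of t or sd_units")
    if t is None:
        t = float(sd_units) * float(np.sqrt(model.eigenvalues[k - 1]))
    return model.mean_shape + t * model.eigenvector_field(k)


def convex_hull_2d(points: np.ndarray) -> np.ndarray:
    """Vertices of the minimum convex hull, in counter-clockwise order.

    Degenerate inputs degrade gracefully: a single point returns that
    point, collinear sets return the extreme segment endpoints.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("empty point set")
    if pts.shape[1] != 2:
        raise ValueError("expected 2D points")
    unique = np.unique(pts, axis=0)
    if unique.shape[0] == 1:
        return unique
    try:
        hull = ConvexHull(pts)
    except QhullError:
        # collinear: return the two extreme points along the spread direction
        direction = unique[-1] - unique[0]
        order = np.argsort(pts @ direction)
        return pts[[order[0], order[-1]]]
    return pts[hull.vertices]  # Qhull returns 2D hull vertices CCW


def hull_area(vertices: np.ndarray) -> float:
    """Polygon area by the shoelace formula (0 for points and segments)."""
    v = np.atleast_2d(np.asarray(vertices, dtype=float))
    if v.shape[0] < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def group_occupancy(model: MorphospaceModel,
                    pc_pair: tuple[int, int] = (1, 2)) -> dict[str, dict]:
    """Convex-hull morphospace occupancy per clade group.

    Species mean scores (not individual specimens) are projected onto the
    chosen PC plane (1-based pair) and a minimum convex hull is computed
    for each group.  Groups with no species are omitted with a warning.

    Returns a mapping ``group -> {'hull': vertices, 'area': float,
    'n_species': int, 'points': species-mean coordinates}``.
    """
    ki, kj = pc_pair
    for k in (ki, kj):
        if not 1 <= k <= model.n_components:
            raise ValueError(f"PC index {k} out of range 1..{model.n_components}")
    summaries = species_means(model)
    result: dict[str, dict] = {}
    for group in dict.fromkeys(s.group for s in summaries):
        pts = np.array([[s.mean_scores[ki - 1], s.mean_scores[kj - 1]]
                        for s in summaries if s.group == group])
        if pts.shape[0] == 0:
            warnings.warn(f"group {group!r} has no species; omitted",
                          RuntimeWarning, stacklevel=2)
            continue
        hull = convex_hull_2d(pts)
        result[group] = {"hull": hull, "area": hull_area(hull),
                         "n_species": pts.shape[0], "points": pts}
    return result
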