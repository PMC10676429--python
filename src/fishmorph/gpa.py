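"""Generalized Procrustes Analysis (GPA).

GPA places all landmark configurations in a common shape space by
(1) translating each configuration so its centroid sits at the origin,
(2) scaling each to unit centroid size (the root summed squared distance
of the landmarks from their centroid), and (3) iteratively rotating each
configuration to minimize its summed squared difference from the sample
average, re-estimating that average until it stops moving.  The removed
similarity transforms (3 translations, 3 rotations, 1 scale) leave the
aligned data on a ``3p - 7``-dimensional manifold.

Rotations are restricted to proper rotations (determinant +1): left and
right landmarks are digitized explicitly, so a mirror alignment would be
anatomically wrong.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .io import Dataset


@dataclass
class AlignmentResult:
    """Output of :func:`gpa`.

    Attributes
    ----------
    aligned
        ``n x p x 3`` array of dimensionless Procrustes coordinates; every
        slice has centroid at the origin and unit centroid size.
    consensus
        The ``p x 3`` consensus (mean) shape, rescaled to unit centroid size.
    centroid_sizes
        Per-specimen centroid sizes in the original units (mm for raw data).
    specimen_ids, species, groups
        Metadata of the aligned specimens, in alignment order.
    iterations, final_change
        Convergence record: number of consensus updates performed and the
        Procrustes distance between the last two consensus estimates.
    objective_history
        Value of the GPA objective sum_i ||X_i - consensus||^2 after each
        iteration; non-increasing.
    """

    aligned: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    specimen_ids: list[str]
    species: list[str]
    groups: list[str]
    iterations: int
    final_change: float
    tolerance: float
    max_iterations: int
    objective_history: list[float]
    tangent_projected: bool = False

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]

    def flattened(self) -> np.ndarray:
        """Aligned coordinates as an ``n x 3p`` matrix (row-major per landmark)."""
        n = self.aligned.shape[0]
        return self.aligned.reshape(n, -1)


def centroid_size(config: np.ndarray) -> float:
    """Root summed squared distance of the landmarks from their centroid.

    This is the size measure removed by Procrustes scaling; it is invariant
    to rotation and translation and scales linearly with the configuration.
    """
    config = np.asarray(config, dtype=float)
    if config.ndim != 2 or config.shape[0] < 1:
        raise ValueError("expected a p x k coordinate matrix with p >= 1")
    if not np.all(np.isfinite(config)):
        raise ValueError("non-finite coordinates")
    centered = config - config.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


def center_scale(config: np.ndarray) -> np.ndarray:
    """Translate the centroid to the origin and rescale to unit centroid size."""
    config = np.asarray(config, dtype=float)
    size = centroid_size(config)
    if size <= 0.0:
        raise ValueError("degenerate configuration: all landmarks coincident "
                         "(centroid size 0)")
    return (config - config.mean(axis=0)) / size


def optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||A @ R - B|| over rotations.

    Both inputs must be centered.  The minimizer is obtained from the SVD
    of ``A.T @ B``: with ``U s V^T = A.T @ B``, the optimal proper rotation
    is ``U diag(1, 1, det(UV^T)) V^T`` — the sign correction on the
    smallest singular direction excludes reflections.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    M = A.T @ B
    U, s, Vt = np.linalg.svd(M)
    if s[-1] <= 1e-12 * max(s[0], 1e-300):
        warnings.warn("rank-deficient cross-product matrix: rotation optimum "
                      "may be ambiguous", RuntimeWarning, stacklevel=2)
    d = np.sign(np.linalg.det(U @ Vt))
    if d == 0.0:
        d = 1.0
    D = np.ones(M.shape[0])
    D[-1] = d
    return (U * D) @ Vt


def procrustes_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Euclidean distance between two aligned configurations.

    The square root of the summed squared coordinate differences — the
    metric of the Procrustes shape space in which the morphospace lives.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    return float(np.sqrt(np.sum((A - B) ** 2)))


def _rescale_unit(shape: np.ndarray) -> np.ndarray:
    return center_scale(shape)


def gpa(
    dataset: Dataset | np.ndarray,
    tolerance: float = 1e-8,
    max_iterations: int = 100,
    project_to_tangent: bool = False,
) -> AlignmentResult:
    """Run Generalized Procrustes Analysis on a dataset.

    Parameters
    ----------
    dataset
        A :class:`~fishmorph.io.Dataset` (only analyzable specimens enter
        the alignment) or a raw ``n x p x 3`` array.
    tolerance
        Convergence threshold on the Procrustes distance between successive
        consensus estimates.
    max_iterations
        Iteration cap; hitting it leaves ``final_change`` above tolerance.
    project_to_tangent
        If True, orthogonally project the aligned shapes onto the tangent
        space at the consensus (removing the radial component).  Off by
        default: plain Procrustes coordinates.

    Notes
    -----
    The iteration is the standard scheme: center and scale everything, take
    the first configuration as the initial consensus, rotate every
    configuration onto the consensus, replace the consensus by the unit-size
    rescaled arithmetic mean of the rotated set, and repeat until the
    consensus stops moving.
    """
    if isinstance(dataset, Dataset):
        configs = dataset.analyzable
        if len(configs) < 2:
            raise ValueError(f"GPA needs at least 2 analyzable configurations, "
                             f"got {len(configs)}")
        raw = np.stack([c.coords for c in configs])
        ids = [c.specimen_id for c in configs]
        species = [c.species for c in configs]
        groups = [c.group for c in configs]
    else:
        raw = np.asarray(dataset, dtype=float)
        if raw.ndim != 3 or raw.shape[0] < 2:
            raise ValueError("expected an n x p x 3 array with n >= 2")
        ids = [f"config_{i}" for i in range(raw.shape[0])]
        species = [""] * raw.shape[0]
        groups = ["synthetic"] * raw.shape[0]

    sizes = np.array([centroid_size(x) for x in raw])
    aligned = np.stack([center_scale(x) for x in raw])

    consensus = aligned[0].copy()
    history: list[float] = []
    change = np.inf
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        for i in range(aligned.shape[0]):
            aligned[i] = aligned[i] @ optimal_rotation(aligned[i], consensus)
        new_consensus = _rescale_unit(aligned.mean(axis=0))
        history.append(float(np.sum((aligned - new_consensus) ** 2)))
        change = procrustes_distance(new_consensus, consensus)
        consensus = new_consensus
        if change < tolerance:
            break

    if project_to_tangent:
        v = consensus.ravel()
        v = v / np.linalg.norm(v)
        flat = aligned.reshape(aligned.shape[0], -1)
        flat = flat - np.outer(flat @ v - 1.0, v)  # keep the consensus component
        aligned = flat.reshape(aligned.shape)

    return AlignmentResult(
        aligned=aligned,
        consensus=consensus,
        centroid_sizes=sizes,
        specimen_ids=ids,
        species=species,
        groups=groups,
        iterations=iterations,
        final_change=float(change),
        tolerance=tolerance,
        max_iterations=max_iterations,
        objective_history=history,
        tangent_projected=project_to_tangent,
    )


def align_to_reference(result: AlignmentResult,
                       reference: np.ndarray) -> AlignmentResult:
    """Rotate a whole alignment so its consensus matches a reference orientation.

    GPA fixes shape but leaves one global rotation free (the output sits in
    the frame of the initial consensus, i.e. the first specimen).  When the
    anatomical axes matter — e.g. for the length/depth/width variance
    decomposition on simulated data whose specimens carry random nuisance
    rotations — the alignment must first be re-anchored: the consensus is
    rotated onto the (center-scaled) reference configuration and the same
    rotation is applied to every aligned specimen.  Eigenvalues, scores and
    Procrustes distances are unaffected; only the frame changes.
    """
    ref = center_scale(np.asarray(reference, dtype=float))
    R = optimal_rotation(result.consensus, ref)
    return replace(
        result,
        aligned=result.aligned @ R,
        consensus=result.consensus @ R,
    )
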