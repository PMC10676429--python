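"""Per-landmark contribution analysis and anatomical-axis decomposition.

Two complementary summaries of where shape variance lives:

* **Weighted eigenvector magnitudes.** For each landmark l and component k
  the 3D norm of the landmark's block of the unit eigenvector,
  ``sqrt(e_k[l,x]^2 + e_k[l,y]^2 + e_k[l,z]^2)``, weighted by the variance
  fraction w_k of that component:  ``m[l,k] = w_k * ||e_k[l,:]||``.
  Row sums S_l rank landmarks by their total contribution across the top
  components, and ``N_l = 100 * S_l / sum(S)`` normalizes the ranking to
  percentages.  Column fractions ``m[l,k] / sum_l m[l,k]`` say how much of
  one component a subset of landmarks carries (e.g. the fin-insertion
  landmarks on PC1).

* **Axis variance decomposition.** Summing the per-landmark sample
  variance of the aligned coordinates separately over the three anatomical
  axes splits total body-shape disparity into length (anteroposterior),
  depth (dorsoventral) and width (mediolateral) components.  The same
  quantity is available through the eigendecomposition as
  ``sum_k lambda_k sum_l e_k[l,d]^2`` — an exact identity when all
  components are used.

The weights w_k are variance *proportions* (0.511, not 51.1): per-landmark
magnitudes of a unit eigenvector are at most 1, so column sums of m lie in
``[w_k, w_k * sqrt(p)]``, which only holds on the proportion scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gpa import AlignmentResult
from .morphospace import MorphospaceModel
from .scheme import AXIS_ROLES, LandmarkScheme


@dataclass
class ContributionTable:
    """Per-landmark x per-PC weighted eigenvector magnitudes.

    ``magnitudes`` is ``p x K`` with rows in scheme order; ``weights`` are
    the variance fractions used (may be ``None`` when the table was built
    from already-weighted published values).
    """

    landmark_names: tuple[str, ...]
    landmark_numbers: tuple[int, ...]
    magnitudes: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if self.magnitudes.ndim != 2:
            raise ValueError("magnitudes must be a p x K matrix")
        if self.magnitudes.shape[0] != len(self.landmark_names):
            raise ValueError("one magnitude row per landmark required")
        if np.any(self.magnitudes < 0):
            raise ValueError("magnitudes are norms and cannot be negative")

    @property
    def n_landmarks(self) -> int:
        return self.magnitudes.shape[0]

    @property
    def K(self) -> int:
        return self.magnitudes.shape[1]

    @property
    def row_sums(self) -> np.ndarray:
        """S_l: each landmark's total weighted magnitude across the K PCs."""
        return self.magnitudes.sum(axis=1)

    @property
    def norm_pct(self) -> np.ndarray:
        """N_l: row sums normalized to percentages (sums to 100)."""
        S = self.row_sums
        total = S.sum()
        if total <= 0:
            raise ValueError("all-zero contribution table")
        return 100.0 * S / total

    @property
    def column_fractions(self) -> np.ndarray:
        """f[l,k]: landmark l's fraction of PC k's total magnitude."""
        col = self.magnitudes.sum(axis=0)
        return self.magnitudes / col

    def index_of(self, landmark: str) -> int:
        try:
            return self.landmark_names.index(landmark)
        except ValueError:
            raise KeyError(f"landmark {landmark!r} not in table") from None

    def to_frame(self, rank_by_sum: bool = True) -> pd.DataFrame:
        """Report frame: Landmark, L#, PC1..PCK, Sum, Norm (%)."""
        frame = pd.DataFrame(self.magnitudes,
                             columns=[f"PC{k}" for k in range(1, self.K + 1)])
        frame.insert(0, "L#", self.landmark_numbers)
        frame.insert(0, "Landmark", self.landmark_names)
        frame["Sum"] = self.row_sums
        frame["Norm (%)"] = self.norm_pct
        if rank_by_sum:
            frame = frame.sort_values("Sum", ascending=False, kind="stable")
        return frame.reset_index(drop=True)


@dataclass
class AxisDecomposition:
    """Total aligned-shape variance split over the three anatomical axes."""

    variances: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.variances) != set(AXIS_ROLES):
            raise ValueError("variances must cover the three anatomical roles")
        if any(v < 0 for v in self.variances.values()):
            raise ValueError("variances cannot be negative")

    @property
    def fractions(self) -> dict[str, float]:
        total = sum(self.variances.values())
        if total <= 0:
            raise ValueError("zero total variance")
        return {role: v / total for role, v in self.variances.items()}

    def as_percentages(self) -> dict[str, float]:
        return {role: 100.0 * f for role, f in self.fractions.items()}


def weighted_landmark_magnitudes(model: MorphospaceModel,
                                 scheme: LandmarkScheme,
                                 K: int | None = None) -> ContributionTable:
    """Variance-weighted 3D eigenvector magnitudes per landmark and PC.

    ``m[l,k] = w_k * sqrt(e_k[l,x]^2 + e_k[l,y]^2 + e_k[l,z]^2)`` where
    w_k is the variance fraction of PC k taken over *all* nonzero
    components (the weight is a property of the full decomposition, not of
    the K displayed columns).
    """
    K = model.K_retained if K is None else K
    if K > model.n_components:
        raise ValueError(f"K={K} exceeds available components "
                         f"{model.n_components}")
    p = model.n_landmarks
    mags = np.empty((p, K))
    for k in range(K):
        field = model.eigenvectors[k].reshape(p, 3)
        mags[:, k] = model.variance_fractions[k] * np.linalg.norm(field, axis=1)
    return ContributionTable(scheme.landmark_names, scheme.landmark_numbers,
                             mags, weights=model.variance_fractions[:K].copy())


def landmark_totals(table: ContributionTable) -> tuple[np.ndarray, np.ndarray]:
    """Row sums S_l and normalized percentages N_l = 100 S_l / sum(S)."""
    return table.row_sums, table.norm_pct


def group_fraction(table: ContributionTable, k: int,
                   landmarks: list[str] | list[int]) -> float:
    """Percentage of PC ``k`` (1-based) carried by a set of landmarks.

    ``100 * sum_{l in set} m[l,k] / sum_l m[l,k]``; the set may be given
    as landmark names or row indices.
    """
    if not 1 <= k <= table.K:
        raise ValueError(f"PC index {k} out of range 1..{table.K}")
    if len(landmarks) == 0:
        raise ValueError("empty landmark set")
    idx = [table.index_of(l) if isinstance(l, str) else int(l) for l in landmarks]
    if any(not 0 <= i < table.n_landmarks for i in idx):
        raise ValueError(f"landmark index out of range: {idx}")
    col = table.magnitudes[:, k - 1]
    return float(100.0 * col[idx].sum() / col.sum())


def axis_variance_decomposition(
    alignment: AlignmentResult,
    scheme: LandmarkScheme,
    model: MorphospaceModel | None = None,
    top_k: int | None = None,
) -> AxisDecomposition:
    """Split total shape variance over the three anatomical axes.

    Default route: for each internal axis d, sum over landmarks the sample
    variance (denominator ``n - 1``) of the aligned coordinate ``(l, d)``
    across specimens — i.e. all components contribute.  With ``model`` and
    ``top_k`` given, the eigen-route restricted to the leading components
    is used instead: ``V_d = sum_{k<=K} lambda_k sum_l e_k[l,d]^2``.
    """
    if alignment.n_specimens < 2:
        raise ValueError("axis decomposition needs at least 2 specimens")
    p = alignment.n_landmarks
    if top_k is not None:
        if model is None:
            raise ValueError("top_k requires a fitted model")
        fields = model.eigenvectors[:top_k].reshape(top_k, p, 3)
        V = np.einsum("k,kld->d", model.eigenvalues[:top_k], fields**2)
    else:
        V = alignment.aligned.var(axis=0, ddof=1).sum(axis=0)
    return AxisDecomposition({scheme.axis_roles[d]: float(V[d]) for d in range(3)})


def axis_decomposition_from_model(model: MorphospaceModel,
                                  scheme: LandmarkScheme) -> AxisDecomposition:
    """Eigen-route axis decomposition over all components.

    ``V_d = sum_k lambda_k sum_l e_k[l,d]^2``; identical to the raw-
    coordinate route because the eigenvectors are an orthonormal basis of
    the centered data.
    """
    p = model.n_landmarks
    fields = model.eigenvectors.reshape(model.n_components, p, 3)
    V = np.einsum("k,kld->d", model.eigenvalues, fields**2)
    return AxisDecomposition({scheme.axis_roles[d]: float(V[d]) for d in range(3)})


def render_contribution_report(table: ContributionTable,
                               decomposition: AxisDecomposition,
                               directory: str | Path,
                               table_name: str = "contribution_table.csv",
                               axes_name: str = "axis_decomposition.json",
                               ) -> tuple[Path, Path]:
    """Write the ranked contribution table (CSV) and axis fractions (JSON).

    Magnitudes and sums are rounded to 3 decimals and percentages to 2,
    rows ranked by total (summed) magnitude descending.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    frame = table.to_frame(rank_by_sum=True)
    pc_cols = [c for c in frame.columns if c.startswith("PC")] + ["Sum"]
    frame[pc_cols] = frame[pc_cols].round(3)
    frame["Norm (%)"] = frame["Norm (%)"].round(2)
    table_path = directory / table_name
    frame.to_csv(table_path, index=False)

    axes_path = directory / axes_name
    with open(axes_path, "w") as fh:
        json.dump({"variances": decomposition.variances,
                   "fractions": decomposition.fractions,
                   "percentages": decomposition.as_percentages()}, fh, indent=2)
    return table_path, axes_path
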