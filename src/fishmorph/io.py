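"""Reading and writing landmark data.

Two on-disk formats are supported:

* 3D Slicer markups fiducial files (``.fcsv``, header-comment CSV, one file
  per specimen), the format produced by Slicer's fiducial tool.  The
  ``# CoordinateSystem`` header is honored: Slicer writes either RAS
  (right/anterior/superior, code ``0``) or LPS (left/posterior/superior,
  code ``1``); LPS coordinates are converted to RAS by negating the first
  two columns.  Landmarks are matched to the scheme by *label*, never by
  row order, because fiducial order in Slicer is placement order.
* a flat matrix CSV with one row per specimen and ``<landmark>_<axis>``
  coordinate columns, convenient for spreadsheet inspection.

A manifest CSV (columns ``specimen_id, path, species, family, group``)
assembles per-specimen fcsv files into an analysis-ready :class:`Dataset`.
Missing or mislabeled landmarks are hard errors — specimens without the
full homologous landmark set are excluded from analysis, not imputed.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scheme import AXIS_ROLES, LandmarkScheme, default_scheme

#: recognized clade groups for specimens (the four nested analysis groups,
#: plus bookkeeping categories)
GROUPS = (
    "non-teleost",
    "non-acanthomorph teleost",
    "non-ovalentarian acanthomorph",
    "ovalentarian acanthomorph",
    "excluded",
    "synthetic",
)

_AXIS_SUFFIX = ("x", "y", "z")  # internal axes 0, 1, 2 in flat CSV columns


class LandmarkError(ValueError):
    """A structured landmark-data error carrying specimen context."""

    def __init__(self, message: str, specimen: str | None = None,
                 labels: Sequence[str] | None = None):
        self.specimen = specimen
        self.labels = list(labels) if labels else []
        ctx = f" [specimen {specimen!r}]" if specimen else ""
        lab = f" (labels: {', '.join(self.labels)})" if self.labels else ""
        super().__init__(message + ctx + lab)


@dataclass(frozen=True)
class AxisMap:
    """Mapping from RAS file axes onto internal anatomical axes.

    ``ras_axis_of_role[role]`` gives the RAS column (0=R, 1=A, 2=S) holding
    that anatomical role, with an optional per-role sign.  The default —
    R→mediolateral, A→anteroposterior, S→dorsoventral, all positive —
    matches a fish digitized upright, facing anterior.
    """

    ras_axis_of_role: dict[str, int] = field(
        default_factory=lambda: {
            "anteroposterior": 1, "dorsoventral": 2, "mediolateral": 0,
        }
    )
    signs: dict[str, float] = field(
        default_factory=lambda: {
            "anteroposterior": 1.0, "dorsoventral": 1.0, "mediolateral": 1.0,
        }
    )

    def __post_init__(self) -> None:
        if sorted(self.ras_axis_of_role.values()) != [0, 1, 2]:
            raise ValueError("axis map must use each RAS axis exactly once")
        if set(self.ras_axis_of_role) != set(AXIS_ROLES):
            raise ValueError("axis map must cover the three anatomical roles")

    def to_internal(self, ras: np.ndarray, scheme: LandmarkScheme) -> np.ndarray:
        out = np.empty_like(ras, dtype=float)
        for axis, role in scheme.axis_roles.items():
            out[:, axis] = self.signs[role] * ras[:, self.ras_axis_of_role[role]]
        return out

    def to_ras(self, internal: np.ndarray, scheme: LandmarkScheme) -> np.ndarray:
        out = np.empty_like(internal, dtype=float)
        for axis, role in scheme.axis_roles.items():
            out[:, self.ras_axis_of_role[role]] = internal[:, axis] / self.signs[role]
        return out


@dataclass
class LandmarkConfiguration:
    """One specimen's landmark coordinates plus identity metadata.

    ``coords`` is a ``p x 3`` matrix in internal axis order (AP, DV, ML),
    millimetres when raw and dimensionless after Procrustes alignment.
    Row order follows the scheme.
    """

    specimen_id: str
    coords: np.ndarray
    scheme: LandmarkScheme
    species: str = ""
    family: str = ""
    group: str = "synthetic"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        p = self.scheme.n_landmarks
        if self.coords.shape != (p, 3):
            raise LandmarkError(
                f"expected a {p}x3 coordinate matrix, got {self.coords.shape}",
                specimen=self.specimen_id,
            )
        if not np.all(np.isfinite(self.coords)):
            bad = [self.scheme.landmark_names[i]
                   for i in np.where(~np.isfinite(self.coords).all(axis=1))[0]]
            raise LandmarkError("non-finite coordinates",
                                specimen=self.specimen_id, labels=bad)
        if self.group not in GROUPS:
            raise LandmarkError(f"unknown group {self.group!r}",
                                specimen=self.specimen_id)

    @property
    def is_analyzable(self) -> bool:
        return self.group != "excluded"


@dataclass
class Dataset:
    """A collection of configurations sharing one landmark scheme."""

    scheme: LandmarkScheme
    configurations: list[LandmarkConfiguration]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [c.specimen_id for c in self.configurations]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise LandmarkError(f"duplicate specimen ids: {dup}")
        for c in self.configurations:
            if c.scheme != self.scheme:
                raise LandmarkError("configuration scheme differs from dataset scheme",
                                    specimen=c.specimen_id)

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self):
        return iter(self.configurations)

    @property
    def analyzable(self) -> list[LandmarkConfiguration]:
        """Configurations entering alignment (group != 'excluded')."""
        return [c for c in self.configurations if c.is_analyzable]

    def coords_array(self, analyzable_only: bool = True) -> np.ndarray:
        """Stack coordinates into an ``n x p x 3`` array."""
        configs = self.analyzable if analyzable_only else self.configurations
        return np.stack([c.coords for c in configs])


# ---------------------------------------------------------------------------
# fcsv


def _parse_coordinate_system(lines: Iterable[str]) -> str:
    for line in lines:
        m = re.match(r"#\s*CoordinateSystem\s*=\s*(\S+)", line)
        if m:
            token = m.group(1).strip().upper()
            if token in ("LPS", "1"):
                return "LPS"
            if token in ("RAS", "0"):
                return "RAS"
            raise LandmarkError(f"unrecognized CoordinateSystem {token!r}")
    return "RAS"  # Slicer default when the header is absent


def read_fcsv(
    path: str | Path,
    scheme: LandmarkScheme | None = None,
    axis_map: AxisMap | None = None,
    specimen_id: str | None = None,
    species: str = "",
    family: str = "",
    group: str = "synthetic",
) -> LandmarkConfiguration:
    """Read one Slicer markups fiducial file into a configuration.

    Rows are reordered to scheme order by matching the ``label`` column
    against the scheme's landmark names (whitespace-trimmed exact match).
    LPS files are converted to RAS (x and y negated) before the axis map
    places RAS axes onto anatomical roles.
    """
    path = Path(path)
    scheme = scheme or default_scheme()
    axis_map = axis_map or AxisMap()
    sid = specimen_id or path.stem

    header: list[str] = []
    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        for line in fh:
            if line.startswith("#"):
                header.append(line)
            elif line.strip():
                rows.append(next(csv.reader([line])))

    system = _parse_coordinate_system(header)

    seen: dict[str, np.ndarray] = {}
    for row in rows:
        if len(row) < 12:
            raise LandmarkError(f"malformed fiducial row: {row!r}", specimen=sid)
        label = row[11].strip()
        if label in seen:
            raise LandmarkError("duplicate landmark label", specimen=sid,
                                labels=[label])
        try:
            seen[label] = np.array([float(v) for v in row[1:4]])
        except ValueError:
            raise LandmarkError("non-numeric coordinate", specimen=sid,
                                labels=[label]) from None

    missing = [n for n in scheme.landmark_names if n not in seen]
    if missing:
        raise LandmarkError("missing landmark labels", specimen=sid, labels=missing)
    extra = [n for n in seen if n not in scheme.landmark_names]
    if extra:
        raise LandmarkError("labels not in scheme", specimen=sid, labels=extra)

    ras = np.stack([seen[n] for n in scheme.landmark_names])
    if system == "LPS":
        ras[:, 0] *= -1.0
        ras[:, 1] *= -1.0
    coords = axis_map.to_internal(ras, scheme)
    return LandmarkConfiguration(sid, coords, scheme, species=species,
                                 family=family, group=group)


def write_fcsv(
    config: LandmarkConfiguration,
    path: str | Path,
    coordinate_system: str = "RAS",
    axis_map: AxisMap | None = None,
) -> None:
    """Write a configuration as a Slicer 4.x markups fiducial file.

    Round-trip guarantee: re-reading the file (with the same axis map)
    reproduces the coordinates to better than 1e-9.
    """
    if config.scheme.n_landmarks == 0 or config.coords.size == 0:
        raise LandmarkError("cannot write an empty configuration",
                            specimen=config.specimen_id)
    coordinate_system = coordinate_system.upper()
    if coordinate_system not in ("RAS", "LPS"):
        raise LandmarkError(f"unknown coordinate system {coordinate_system!r}")
    axis_map = axis_map or AxisMap()
    ras = axis_map.to_ras(config.coords, config.scheme)
    if coordinate_system == "LPS":
        ras = ras.copy()
        ras[:, 0] *= -1.0
        ras[:, 1] *= -1.0

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write("# Markups fiducial file version = 4.11\n")
        fh.write(f"# CoordinateSystem = {coordinate_system}\n")
        fh.write("# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,"
                 "associatedNodeID\n")
        writer = csv.writer(fh)
        for i, name in enumerate(config.scheme.landmark_names):
            x, y, z = (f"{v:.17g}" for v in ras[i])
            writer.writerow(
                [f"vtkMRMLMarkupsFiducialNode_{i}", x, y, z,
                 0, 0, 0, 1, 1, 1, 0, name, "", ""]
            )


# ---------------------------------------------------------------------------
# manifest / dataset


def read_dataset(
    manifest: str | Path,
    scheme: LandmarkScheme | None = None,
    axis_map: AxisMap | None = None,
) -> Dataset:
    """Assemble a dataset from a manifest CSV.

    The manifest has columns ``specimen_id, path, species, family, group``;
    fcsv paths are resolved relative to the manifest's directory.  Rows
    whose group is ``excluded`` are loaded and kept for bookkeeping but are
    omitted from alignment by default (``Dataset.analyzable``).
    """
    manifest = Path(manifest)
    scheme = scheme or default_scheme()
    table = pd.read_csv(manifest, dtype=str).fillna("")
    required = {"specimen_id", "path", "species", "family", "group"}
    if not required.issubset(table.columns):
        raise LandmarkError(
            f"manifest missing columns: {sorted(required - set(table.columns))}")

    configs = []
    for _, row in table.iterrows():
        fpath = Path(row["path"])
        if not fpath.is_absolute():
            fpath = manifest.parent / fpath
        if not fpath.exists():
            raise LandmarkError(f"fcsv file not found: {fpath}",
                                specimen=row["specimen_id"])
        configs.append(
            read_fcsv(fpath, scheme, axis_map,
                      specimen_id=row["specimen_id"], species=row["species"],
                      family=row["family"], group=row["group"] or "synthetic")
        )
    return Dataset(scheme, configs, provenance=f"manifest: {manifest}")


def write_manifest(dataset: Dataset, directory: str | Path,
                   manifest_name: str = "manifest.csv") -> Path:
    """Write one fcsv per specimen plus a manifest CSV into *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for config in dataset.configurations:
        fname = re.sub(r"[^A-Za-z0-9_.-]", "_", config.specimen_id) + ".fcsv"
        write_fcsv(config, directory / fname)
        rows.append({"specimen_id": config.specimen_id, "path": fname,
                     "species": config.species, "family": config.family,
                     "group": config.group})
    manifest = directory / manifest_name
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


# ---------------------------------------------------------------------------
# flat matrix CSV


def flat_columns(scheme: LandmarkScheme) -> list[str]:
    """Coordinate column names of the flat dialect: ``<landmark>_<axis>``."""
    return [f"{name}_{ax}" for name in scheme.landmark_names for ax in _AXIS_SUFFIX]


def dataset_to_frame(dataset: Dataset) -> pd.DataFrame:
    """Flatten a dataset to one row per specimen (metadata + coordinates)."""
    cols = flat_columns(dataset.scheme)
    records = []
    for c in dataset.configurations:
        rec = {"specimen_id": c.specimen_id, "species": c.species,
               "family": c.family, "group": c.group}
        rec.update(dict(zip(cols, c.coords.ravel())))
        records.append(rec)
    return pd.DataFrame.from_records(records)


def write_flat_csv(dataset: Dataset, path: str | Path) -> None:
    dataset_to_frame(dataset).to_csv(path, index=False, float_format="%.17g")


def read_flat_csv(path: str | Path, scheme: LandmarkScheme | None = None) -> Dataset:
    """Read the flat one-row-per-specimen dialect back into a dataset."""
    scheme = scheme or default_scheme()
    table = pd.read_csv(path)
    cols = flat_columns(scheme)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise LandmarkError(f"flat CSV missing coordinate columns: {missing[:4]}...")
    configs = []
    for _, row in table.iterrows():
        coords = row[cols].to_numpy(dtype=float).reshape(scheme.n_landmarks, 3)
        configs.append(LandmarkConfiguration(
            str(row["specimen_id"]), coords, scheme,
            species=str(row.get("species", "") or ""),
            family=str(row.get("family", "") or ""),
            group=str(row.get("group", "synthetic") or "synthetic")))
    return Dataset(scheme, configs, provenance=f"flat csv: {path}")
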