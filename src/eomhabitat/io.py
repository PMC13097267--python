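"""NIfTI volume / mask I/O, grid-geometry validation, and cohort manifests.

Water and fat signal-intensity images and the extraocular-muscle (EOM)
masks are exchanged as NIfTI-1 files. A cohort is described by a CSV
manifest with one row per patient pointing at the pre-/post-therapy
volumes and masks, plus the treatment-response label.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GEOMETRY_TOL_MM",
    "MANIFEST_COLUMNS",
    "RESPONSE_LABELS",
    "Geometry",
    "ScalarVolume",
    "SegmentationMask",
    "CohortManifest",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "validate_aligned",
    "read_manifest",
    "write_manifest",
]

#: Tolerance (mm) when comparing voxel spacings and origins: NIfTI headers
#: store float32, so independently written headers differ at machine precision.
GEOMETRY_TOL_MM = 1e-4

#: Required manifest columns, in canonical order.
MANIFEST_COLUMNS = (
    "patient_id",
    "response",
    "pre_water",
    "pre_fat",
    "post_water",
    "post_fat",
    "mask_pre",
    "mask_post",
)

RESPONSE_LABELS = ("responsive", "unresponsive")


class VolumeValidationError(ValueError):
    """Raised when a loaded image violates a container invariant."""


@dataclass(frozen=True)
class Geometry:
    """Grid geometry of a 3D volume: voxel spacing, origin, axis directions.

    ``direction`` is the 3x3 matrix whose columns are the unit vectors of
    the voxel axes in physical space; together with ``spacing`` and
    ``origin`` it determines the affine index -> mm mapping.
    """

    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeValidationError(f"spacing must be 3 positive values, got {self.spacing}")
        if len(self.direction) != 9:
            raise VolumeValidationError("direction must be a flattened 3x3 matrix")

    @property
    def direction_matrix(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float).reshape(3, 3)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def affine(self) -> np.ndarray:
        """4x4 NIfTI affine (index -> mm)."""
        aff = np.eye(4)
        aff[:3, :3] = self.direction_matrix @ np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    @classmethod
    def from_affine(cls, affine: np.ndarray) -> "Geometry":
        m = np.asarray(affine, dtype=float)[:3, :3]
        spacing = np.linalg.norm(m, axis=0)
        if np.any(spacing <= 0):
            raise VolumeValidationError("degenerate affine: zero-length axis")
        direction = m / spacing
        origin = np.asarray(affine, dtype=float)[:3, 3]
        return cls(tuple(spacing), tuple(origin), tuple(direction.ravel()))

    def matches(self, other: "Geometry", tol: float = GEOMETRY_TOL_MM) -> bool:
        return (
            np.allclose(self.spacing, other.spacing, atol=tol, rtol=0.0)
            and np.allclose(self.origin, other.origin, atol=tol, rtol=0.0)
            and np.allclose(self.direction_matrix, other.direction_matrix, atol=1e-6, rtol=0.0)
        )


def _check_3d(data: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(data)
    if arr.ndim != 3 or min(arr.shape) < 1:
        raise VolumeValidationError(f"{what} must be a 3D array with all dimensions >= 1, got shape {arr.shape}")
    return arr


@dataclass
class ScalarVolume:
    """One channel (water or fat signal intensity) at one time point."""

    data: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        self.data = _check_3d(self.data, "ScalarVolume").astype(np.float64, copy=False)
        n_neg = int(np.count_nonzero(self.data < 0))
        if n_neg:
            raise VolumeValidationError(f"signal intensities must be non-negative; {n_neg} negative voxel(s) found")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.geometry.spacing


@dataclass
class SegmentationMask:
    """Binary {0,1} volume-of-interest mask on the same grid as its channel."""

    data: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        arr = _check_3d(self.data, "SegmentationMask")
        values = np.unique(arr)
        if not np.all(np.isin(values, (0, 1))):
            raise VolumeValidationError(f"mask values must be in {{0,1}}, found {values[:10]}")
        self.data = arr.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())

    def require_nonempty(self) -> "SegmentationMask":
        if self.n_foreground == 0:
            raise VolumeValidationError("muscle mask has no foreground voxels")
        return self


def read_volume(path: str | os.PathLike) -> ScalarVolume:
    """Load a NIfTI scalar volume, validating dimensionality and sign."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 else data
    if data.ndim != 3:
        raise VolumeValidationError(f"{path}: expected a 3D image, got {data.ndim} dimensions")
    return ScalarVolume(np.asarray(data, dtype=np.float64), Geometry.from_affine(img.affine))


def write_volume(vol: ScalarVolume, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float64), vol.geometry.affine())
    nib.save(img, str(path))


def read_mask(path: str | os.PathLike) -> SegmentationMask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeValidationError(f"{path}: expected a 3D mask, got {data.ndim} dimensions")
    return SegmentationMask(np.rint(data).astype(np.uint8), Geometry.from_affine(img.affine))


def write_mask(mask: SegmentationMask, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.geometry.affine())
    nib.save(img, str(path))


def validate_aligned(
    a: ScalarVolume | SegmentationMask,
    b: ScalarVolume | SegmentationMask,
    tol: float = GEOMETRY_TOL_MM,
) -> bool:
    """True iff the two grids coincide: same shape, spacing and geometry."""
    return a.data.shape == b.data.shape and a.geometry.matches(b.geometry, tol=tol)


class ManifestError(ValueError):
    """Raised when a cohort manifest violates its contract."""


@dataclass
class CohortManifest:
    """Validated cohort table; file paths are resolved against ``root``."""

    table: pd.DataFrame
    root: Path = field(default_factory=Path)

    PATH_COLUMNS = ("pre_water", "pre_fat", "post_water", "post_fat", "mask_pre", "mask_post")

    def __len__(self) -> int:
        return len(self.table)

    def resolve(self, patient_id: str, column: str) -> Path:
        row = self.table.loc[self.table["patient_id"] == patient_id]
        if row.empty:
            raise ManifestError(f"unknown patient_id {patient_id!r}")
        p = Path(str(row.iloc[0][column]))
        return p if p.is_absolute() else self.root / p

    def patients(self) -> Iterable[tuple[str, str, dict[str, Path]]]:
        """Yield (patient_id, response, {column: resolved path})."""
        for _, row in self.table.iterrows():
            paths = {
                col: (Path(str(row[col])) if Path(str(row[col])).is_absolute() else self.root / str(row[col]))
                for col in self.PATH_COLUMNS
            }
            yield str(row["patient_id"]), str(row["response"]), paths


def _validate_manifest_table(table: pd.DataFrame, root: Path, check_paths: bool = True) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise ManifestError(f"manifest is missing required column(s): {missing}")
    dup = table["patient_id"][table["patient_id"].duplicated()]
    if len(dup):
        rows = (table.index[table["patient_id"].isin(dup)] + 1).tolist()
        raise ManifestError(f"duplicate patient_id {sorted(set(dup))} at row(s) {rows}")
    bad = table.index[~table["response"].isin(RESPONSE_LABELS)]
    if len(bad):
        label = table.loc[bad[0], "response"]
        raise ManifestError(
            f"row {bad[0] + 1}: response label {label!r} not in {set(RESPONSE_LABELS)}"
        )
    if check_paths:
        for idx, row in table.iterrows():
            for col in CohortManifest.PATH_COLUMNS:
                p = Path(str(row[col]))
                if not p.is_absolute():
                    p = root / p
                if not p.exists():
                    raise ManifestError(f"row {idx + 1}: {col} path does not exist: {p}")


def read_manifest(path: str | os.PathLike, check_paths: bool = True) -> CohortManifest:
    """Load and validate a cohort manifest CSV.

    Relative file paths are interpreted relative to the manifest's own
    directory, so a generated cohort directory is relocatable.
    """
    path = Path(path)
    table = pd.read_csv(path, dtype=str)
    root = path.parent
    _validate_manifest_table(table, root, check_paths=check_paths)
    return CohortManifest(table.reset_index(drop=True), root)


def write_manifest(table: pd.DataFrame, path: str | os.PathLike) -> None:
    path = Path(path)
    _validate_manifest_table(table, path.parent, check_paths=False)
    table.loc[:, list(MANIFEST_COLUMNS) + [c for c in table.columns if c not in MANIFEST_COLUMNS]].to_csv(
        path, index=False
    )
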