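"""Volume, surface and record I/O plus the core domain types.

Coordinate convention
---------------------
All in-memory arrays are indexed ``(x, y, z)`` with ``z`` the A-scan (depth)
axis.  Voxel indices are 0-based; voxel ``(i, j, k)`` occupies the half-open
physical box ``[i*sx, (i+1)*sx) x ... `` and its center sits at
``((i+0.5)*sx, (j+0.5)*sy, (k+0.5)*sz)`` in micrometers.  On disk,
multi-page TIFF stores ``z`` as the page axis and each page as ``(y, x)``;
the reader/writer pair is the identity on masks.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VoxelSpacing",
    "LabeledVolume",
    "SurfaceMap",
    "SkeletonVoxelRecord",
    "VolumeIOError",
    "DimensionalityError",
    "GeometryError",
    "DEFAULT_SPACING",
    "load_labeled_volume",
    "write_labeled_volume",
    "load_surface_map",
    "write_surface_map",
    "write_records",
    "read_records",
    "records_to_frame",
]


class VolumeIOError(OSError):
    """Raised when a volume/surface file cannot be read or written."""


class DimensionalityError(ValueError):
    """Raised when an input array does not have the expected rank."""


class GeometryError(ValueError):
    """Raised on geometrically inconsistent inputs (crossing surfaces,
    out-of-volume tubes, ...)."""


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical voxel edge lengths in micrometers.

    ``sz`` is the spacing along the A-scan (depth) axis.  The defaults are
    the Optovue Avanti grid: 9.87 um laterally, 12.54 um axially.  The
    lateral/axial anisotropy is what makes shape ratios meaningless until
    converted to physical units, so spacing travels with every volume.
    """

    sx: float = 9.87
    sy: float = 9.87
    sz: float = 12.54

    def __post_init__(self) -> None:
        for name in ("sx", "sy", "sz"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"spacing {name}={v!r} must be finite and > 0")

    @property
    def lateral(self) -> float:
        """Single lateral spacing used for width conversions.

        OCTA grids are laterally isotropic (sx == sy); if they differ the
        arithmetic mean is used.
        """
        return 0.5 * (self.sx + self.sy)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.sx, self.sy, self.sz)


DEFAULT_SPACING = VoxelSpacing()


@dataclass
class LabeledVolume:
    """A binary vessel label volume with its physical spacing."""

    mask: np.ndarray
    spacing: VoxelSpacing = DEFAULT_SPACING
    name: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3:
            raise DimensionalityError(
                f"LabeledVolume expects a 3D mask, got ndim={self.mask.ndim}"
            )
        if min(self.mask.shape) < 1:
            raise ValueError("mask dimensions must be positive")
        if self.mask.dtype != bool:
            self.mask = self.mask != 0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.mask.sum())


@dataclass
class SurfaceMap:
    """Per-(x, y) z-height (in voxel units) of a retinal surface.

    Used for the ILM and ONL boundaries that delimit the region of
    interest.  Heights are float voxel coordinates; z increases with depth.
    """

    height: np.ndarray
    spacing: VoxelSpacing = DEFAULT_SPACING

    def __post_init__(self) -> None:
        self.height = np.asarray(self.height, dtype=float)
        if self.height.ndim != 2:
            raise DimensionalityError(
                f"SurfaceMap expects a 2D height grid, got ndim={self.height.ndim}"
            )
        if not np.all(np.isfinite(self.height)):
            raise ValueError("surface heights must be finite everywhere")

    @property
    def shape(self) -> tuple[int, int]:
        return self.height.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class SkeletonVoxelRecord:
    """One measurement site on the vessel centerline.

    Attributes
    ----------
    position:
        (x, y, z) integer voxel indices of the skeleton voxel.
    n:
        Connected labeled voxel count inside the sphere neighborhood.
    area_vx:
        Cross-section area estimate ``A_c = n / d_sphere`` in voxel^2.
    depth_vx:
        Contiguous labeled run length along z through the site, voxels.
    width_vx:
        Elliptical width ``4*A_c / (pi*depth)`` in voxels.
    width_um, depth_um, area_um2:
        Physical conversions (lateral spacing, axial spacing, their product).
    eq:
        Elliptical quotient: physical depth / physical width.
    boundary_flag:
        True when the sphere neighborhood was clipped by the volume border
        (n is then biased low).
    """

    position: tuple[int, int, int]
    n: int
    area_vx: float
    depth_vx: int
    width_vx: float
    width_um: float
    depth_um: float
    area_um2: float
    eq: float
    boundary_flag: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("overlap count n must be >= 1")
        if self.depth_vx < 1:
            raise ValueError("depth_vx must be >= 1 (one-voxel floor)")
        if self.width_vx <= 0 or self.eq <= 0:
            raise ValueError("width and elliptical quotient must be positive")


RECORD_COLUMNS = [
    "x", "y", "z", "n", "area_vx", "depth_vx", "width_vx",
    "width_um", "depth_um", "area_um2", "eq", "boundary_flag",
]


# ---------------------------------------------------------------------------
# volumes

def _is_nifti(path: str) -> bool:
    p = str(path).lower()
    return p.endswith(".nii") or p.endswith(".nii.gz")


def load_labeled_volume(path, spacing: VoxelSpacing | None = None,
                        name: str | None = None) -> LabeledVolume:
    """Read a binary label volume from multi-page TIFF or NIfTI-1.

    Nonzero voxels mark vessel.  For TIFF the page axis is z and pages are
    (y, x); the array is normalized to (x, y, z).  For NIfTI the data array
    is taken as (x, y, z) directly and the header voxel sizes, when present
    and nonzero, override the ``spacing`` argument.
    """
    spacing = spacing or DEFAULT_SPACING
    if not os.path.exists(path):
        raise VolumeIOError(f"cannot read volume: no such file {path!r}")
    try:
        if _is_nifti(path):
            img = nib.load(str(path))
            arr = np.asanyarray(img.dataobj)
            zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
            if len(zooms) == 3 and all(np.isfinite(z) and z > 0 for z in zooms):
                spacing = VoxelSpacing(*zooms)
        else:
            arr = tifffile.imread(str(path))
            if arr.ndim == 3:
                arr = np.transpose(arr, (2, 1, 0))  # (z, y, x) -> (x, y, z)
    except VolumeIOError:
        raise
    except Exception as exc:  # pragma: no cover - format-specific messages
        raise VolumeIOError(f"cannot read volume {path!r}: {exc}") from exc
    if arr.ndim == 2:
        raise DimensionalityError(
            f"{path!r} holds a 2D image; a 3D volume is required"
        )
    if arr.ndim != 3:
        raise DimensionalityError(
            f"{path!r} has rank {arr.ndim}; a 3D volume is required"
        )
    return LabeledVolume(arr != 0, spacing, name or os.path.basename(str(path)))


def write_labeled_volume(volume: LabeledVolume, path) -> None:
    """Write a label volume as multi-page TIFF (pages = z) or NIfTI-1."""
    try:
        if _is_nifti(path):
            affine = np.diag([*volume.spacing.as_tuple(), 1.0])
            img = nib.Nifti1Image(volume.mask.astype(np.uint8), affine)
            img.header.set_zooms(volume.spacing.as_tuple())
            nib.save(img, str(path))
        else:
            pages = np.transpose(volume.mask.astype(np.uint8), (2, 1, 0))
            tifffile.imwrite(str(path), pages)
    except Exception as exc:
        raise VolumeIOError(f"cannot write volume {path!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# surfaces

def load_surface_map(path, spacing: VoxelSpacing | None = None) -> SurfaceMap:
    """Read a surface height map from single-page TIFF or a CSV matrix.

    CSV rows correspond to x, columns to y (the same (x, y) layout as the
    in-memory array); TIFF pages are (y, x) as for volumes.
    """
    spacing = spacing or DEFAULT_SPACING
    if not os.path.exists(path):
        raise VolumeIOError(f"cannot read surface map: no such file {path!r}")
    p = str(path).lower()
    try:
        if p.endswith(".csv") or p.endswith(".txt"):
            arr = np.loadtxt(str(path), delimiter=",", ndmin=2)
        else:
            arr = tifffile.imread(str(path))
            if arr.ndim != 2:
                raise DimensionalityError(
                    f"{path!r}: surface TIFF must be single-page 2D"
                )
            arr = arr.T  # (y, x) -> (x, y)
    except (VolumeIOError, DimensionalityError):
        raise
    except Exception as exc:
        raise VolumeIOError(f"cannot read surface map {path!r}: {exc}") from exc
    return SurfaceMap(arr, spacing)


def write_surface_map(surface: SurfaceMap, path) -> None:
    p = str(path).lower()
    try:
        if p.endswith(".csv") or p.endswith(".txt"):
            np.savetxt(str(path), surface.height, delimiter=",")
        else:
            tifffile.imwrite(str(path), surface.height.T.astype(np.float32))
    except Exception as exc:
        raise VolumeIOError(f"cannot write surface map {path!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# record tables

def records_to_frame(records: Sequence[SkeletonVoxelRecord]) -> pd.DataFrame:
    """Tabulate records with one row per skeleton voxel."""
    rows = [
        {
            "x": r.position[0], "y": r.position[1], "z": r.position[2],
            "n": r.n, "area_vx": r.area_vx, "depth_vx": r.depth_vx,
            "width_vx": r.width_vx, "width_um": r.width_um,
            "depth_um": r.depth_um, "area_um2": r.area_um2, "eq": r.eq,
            "boundary_flag": bool(r.boundary_flag),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def _frame_to_records(frame: pd.DataFrame) -> list[SkeletonVoxelRecord]:
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            SkeletonVoxelRecord(
                position=(int(row.x), int(row.y), int(row.z)),
                n=int(row.n),
                area_vx=float(row.area_vx),
                depth_vx=int(row.depth_vx),
                width_vx=float(row.width_vx),
                width_um=float(row.width_um),
                depth_um=float(row.depth_um),
                area_um2=float(row.area_um2),
                eq=float(row.eq),
                boundary_flag=bool(row.boundary_flag),
            )
        )
    return records


def write_records(records: Sequence[SkeletonVoxelRecord], path) -> None:
    """Write measurement records as CSV (comma, header row, UTF-8).

    Positions are integers; physical values are written at full float
    precision so that a write/read round trip is exact.
    """
    frame = records_to_frame(records)
    try:
        # %.17g guarantees the write/read round trip is float-exact
        frame.to_csv(path, index=False, encoding="utf-8", float_format="%.17g")
    except OSError as exc:
        raise VolumeIOError(f"cannot write records {path!r}: {exc}") from exc


def read_records(path) -> list[SkeletonVoxelRecord]:
    if not os.path.exists(path):
        raise VolumeIOError(f"cannot read records: no such file {path!r}")
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise VolumeIOError(f"records file {path!r} lacks columns {missing}")
    return _frame_to_records(frame)
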