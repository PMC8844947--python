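"""Depth, width, eccentricity and the elliptical quotient per skeleton voxel.

Model
-----
A vessel cross-section is modeled as an ellipse with one axis in the
lateral (x/y) plane and one along the A-scan (z) axis; vessels course
nearly parallel to the retinal surfaces, so the axial axis of the ellipse
aligns with the image z axis.  Per skeleton voxel:

* ``d_depth`` — the contiguous labeled run along z through the voxel
  (voxels above plus below plus the voxel itself), floored at 1 voxel.
* ``A_c``   — the sphere-neighborhood cross-section area (see
  :mod:`octastretch.cross_section`).
* ``d_width`` — from the ellipse area identity
  ``A = pi * a * b = (pi/4) * d_width * d_depth``:
  ``d_width = 4 * A_c / (pi * d_depth)``.
* elliptical quotient ``eq = (d_depth * sz) / (d_width * s_lateral)`` —
  the physical axial-to-lateral axis ratio.  1 for a circular vessel,
  > 1 when the vessel is stretched along the A-scan.

The quotient is the practical replacement for the eccentricity
``eps = sqrt(1 - (b_/a_)^2)`` of the ellipse: eccentricity is blind to
*which* axis is the long one (the semi-major/semi-minor labels swap when a
vessel flips from axially stretched to laterally stretched), while
``eq = b/a = sqrt(1 - eps^2)`` keeps the orientation sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import pi, sqrt

import numpy as np

from .cross_section import (
    SphereParams,
    connected_overlap_count,
    cross_section_area,
    is_boundary_site,
)
from .skeleton import skeleton_points, skeletonize_3d
from .volio import LabeledVolume, SkeletonVoxelRecord, VoxelSpacing

__all__ = [
    "EllipseShape",
    "depth_at",
    "width_from_area",
    "eccentricity",
    "elliptical_quotient",
    "build_record",
    "analyze_network",
]

log = logging.getLogger("octastretch")


@dataclass(frozen=True)
class EllipseShape:
    """A vessel cross-section ellipse in physical units (um).

    ``a`` is the lateral semi-axis, ``b`` the axial (z) semi-axis;
    ``a_bar``/``b_bar`` are the same two lengths relabeled as
    semi-major/semi-minor.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("semi-axes must be positive")

    @property
    def a_bar(self) -> float:
        return max(self.a, self.b)

    @property
    def b_bar(self) -> float:
        return min(self.a, self.b)

    @property
    def area(self) -> float:
        return pi * self.a * self.b

    @property
    def eccentricity(self) -> float:
        return eccentricity(self.a_bar, self.b_bar)

    @property
    def quotient(self) -> float:
        """Axial over lateral axis ratio b/a (> 1: stretched along z)."""
        return self.b / self.a


def depth_at(volume: LabeledVolume | np.ndarray, voxel: tuple[int, int, int]) -> int:
    """Length of the maximal contiguous labeled run along z through ``voxel``.

    Counts the labeled voxels directly above and below the site plus the
    site itself — the connected vertical extent of *this* vessel.  Runs
    belonging to other vessels in the same (x, y) column (e.g. an
    overlapping plexus layer, separated by a gap) are not counted.  Always
    >= 1: a depth below one voxel cannot be labeled or measured.
    """
    mask = volume.mask if isinstance(volume, LabeledVolume) else np.asarray(volume) != 0
    x, y, z = (int(v) for v in voxel)
    if not mask[x, y, z]:
        raise ValueError(f"voxel {(x, y, z)} is not labeled")
    column = mask[x, y, :]
    lo = z
    while lo > 0 and column[lo - 1]:
        lo -= 1
    hi = z
    while hi + 1 < column.size and column[hi + 1]:
        hi += 1
    return hi - lo + 1


def width_from_area(area: float, d_depth: float) -> float:
    """Elliptical width from cross-section area: 4*A_c / (pi * d_depth)."""
    if area <= 0:
        raise ValueError("area must be positive")
    if d_depth < 1:
        raise ValueError("d_depth must be >= 1 voxel")
    return 4.0 * area / (pi * d_depth)


def eccentricity(a_bar: float, b_bar: float) -> float:
    """Ellipse eccentricity sqrt(1 - (b_bar/a_bar)^2), in [0, 1).

    ``a_bar`` must be the semi-major axis; callers holding an unordered
    axis pair swap first (the semi-major/semi-minor labels swap whenever
    the stretching flips axis).
    """
    if b_bar <= 0:
        raise ValueError("semi-minor axis must be positive")
    if b_bar > a_bar:
        raise ValueError("a_bar must be the semi-major axis (a_bar >= b_bar); swap")
    return sqrt(1.0 - (b_bar / a_bar) ** 2)


def elliptical_quotient(width_vx: float, depth_vx: float,
                        spacing: VoxelSpacing) -> float:
    """Physical axial extent over physical lateral extent.

    ``eq = (depth_vx * sz) / (width_vx * s_lateral)``.  The voxel
    anisotropy (9.87 um lateral vs 12.54 um axial on the reference device)
    is factored in here; a physically circular vessel has eq = 1 even
    though its voxel-space footprint is elliptical.
    """
    if width_vx <= 0:
        raise ValueError("width must be positive")
    if depth_vx < 1:
        raise ValueError("depth is floored at 1 voxel")
    return (depth_vx * spacing.sz) / (width_vx * spacing.lateral)


def build_record(position: tuple[int, int, int], n: int, depth_vx: int,
                 params: SphereParams, spacing: VoxelSpacing,
                 boundary_flag: bool = False) -> SkeletonVoxelRecord:
    """Assemble one consistent measurement record from raw counts.

    Physical fields satisfy ``area_um2 = (pi/4) * width_um * depth_um``
    exactly, by construction of the ellipse identity.
    """
    area_vx = cross_section_area(n, params.d_sphere)
    width_vx = width_from_area(area_vx, depth_vx)
    width_um = width_vx * spacing.lateral
    depth_um = depth_vx * spacing.sz
    return SkeletonVoxelRecord(
        position=tuple(int(p) for p in position),  # type: ignore[arg-type]
        n=int(n),
        area_vx=area_vx,
        depth_vx=int(depth_vx),
        width_vx=width_vx,
        width_um=width_um,
        depth_um=depth_um,
        area_um2=area_vx * spacing.lateral * spacing.sz,
        eq=elliptical_quotient(width_vx, depth_vx, spacing),
        boundary_flag=boundary_flag,
    )


def analyze_network(volume: LabeledVolume, roi: np.ndarray | None = None,
                    params: SphereParams | None = None) -> list[SkeletonVoxelRecord]:
    """Run the full per-voxel pipeline on a labeled vessel volume.

    Skeletonizes the mask, optionally restricts measurement sites to an
    ROI slab, and produces one :class:`SkeletonVoxelRecord` per skeleton
    voxel.  Sites whose sphere neighborhood is clipped by the volume
    border are boundary-flagged (their n biases low); they are kept in the
    output and excluded from headline aggregates downstream by default.
    """
    params = params or SphereParams()
    skel = skeletonize_3d(volume)
    if roi is not None:
        if roi.shape != volume.mask.shape:
            raise ValueError(
                f"ROI shape {roi.shape} does not match volume {volume.mask.shape}"
            )
        skel &= roi
    points = skeleton_points(skel)
    if points.size == 0:
        log.warning("empty skeleton for volume %r: no records produced",
                    volume.name)
        return []
    records = []
    for p in points:
        pos = (int(p[0]), int(p[1]), int(p[2]))
        n = connected_overlap_count(volume.mask, pos, params)
        depth = depth_at(volume.mask, pos)
        records.append(
            build_record(pos, n, depth, params, volume.spacing,
                         boundary_flag=is_boundary_site(pos, volume.mask.shape,
                                                        params.d_sphere))
        )
    log.info("analyzed %r: %d skeleton voxels (d_sphere=%d, connectivity=%d)",
             volume.name, len(records), params.d_sphere, params.connectivity)
    return records
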