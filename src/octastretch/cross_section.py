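"""Sphere-neighborhood estimation of vessel cross-section area.

The estimator: around a skeleton voxel, take the spherical neighborhood of
diameter ``d_sphere`` (in voxel index units), count the labeled voxels
inside the sphere that are connected to the skeleton voxel, and divide the
count by the sphere diameter:

    A_c = n / d_sphere        (voxel^2)

For a straight tube threading the sphere, the labeled-and-connected set is
a chord of length ~d_sphere times the cross-section, so the division
recovers the per-plane area.  The sphere is used because it is rotation
invariant: the estimate does not depend on vessel orientation.  The same
construction with a circle in 2D yields a vessel *width* instead of an
area.

Validity: the cross-section must fit well inside the sphere.  Slices of
the chord near the sphere poles have a reduced in-sphere radius
(sqrt((d/2)^2 - offset^2)), so cross-sections whose radius approaches the
sphere radius are clipped there and A_c biases low; choose d_sphere
comfortably larger than the largest expected vessel extent in voxels (and,
per the tortuosity caveat, smaller than the vessel's curve radius).

Note the sphere lives in voxel *index* space.  On anisotropic grids the
physical neighborhood is therefore an ellipsoid; this matches applying a
9-voxel sphere directly to the native grid, and the anisotropy is factored
in later when voxel measures are converted to micrometers.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi, sqrt

import numpy as np
from scipy import ndimage

from .volio import LabeledVolume

__all__ = [
    "SphereParams",
    "sphere_offsets",
    "circle_offsets",
    "connected_overlap_count",
    "cross_section_area",
    "circular_equivalent_diameter",
    "vessel_width_2d",
    "is_boundary_site",
]


@dataclass(frozen=True)
class SphereParams:
    """Neighborhood parameters: sphere diameter (voxels) and connectivity.

    ``d_sphere`` defaults to 9 voxels, sized for retinal-plexus vessels on
    the Optovue grid.  ``connectivity`` is the voxel adjacency used for the
    "connected to the skeleton voxel" restriction: 26 (vertex), 18 (edge)
    or 6 (face) in 3D; in 2D, 8 or 4.
    """

    d_sphere: int = 9
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.d_sphere < 3 or self.d_sphere % 2 == 0:
            raise ValueError("d_sphere must be an odd integer >= 3")
        if self.connectivity not in (6, 18, 26, 4, 8):
            raise ValueError("connectivity must be one of 4, 8 (2D), 6, 18, 26 (3D)")

    @property
    def radius_vx(self) -> float:
        return self.d_sphere / 2.0

    @property
    def max_offset(self) -> int:
        """Largest per-axis integer offset inside the sphere."""
        return int(self.d_sphere // 2)


def _offsets(d: int, ndim: int) -> np.ndarray:
    if d < 1:
        raise ValueError("diameter must be positive")
    r = d / 2.0
    m = int(np.floor(r))
    axes = [np.arange(-m, m + 1)] * ndim
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, ndim)
    keep = (grid.astype(float) ** 2).sum(axis=1) <= r * r + 1e-12
    return grid[keep]


def sphere_offsets(d_sphere: int) -> np.ndarray:
    """Integer offsets (dx, dy, dz) with Euclidean norm <= d_sphere/2.

    Includes (0, 0, 0); symmetric under axis negation and permutation, the
    lattice form of rotation invariance.
    """
    return _offsets(d_sphere, 3)


def circle_offsets(d_circle: int) -> np.ndarray:
    """2D analogue of :func:`sphere_offsets`."""
    return _offsets(d_circle, 2)


def _structure(ndim: int, connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3, 4: 1, 8: 2}[connectivity]
    return ndimage.generate_binary_structure(ndim, rank)


def connected_overlap_count(mask: np.ndarray | LabeledVolume,
                            center: tuple[int, ...],
                            params: SphereParams | None = None) -> int:
    """Count labeled voxels inside the sphere connected to the center voxel.

    Connectivity is evaluated within the sphere-restricted voxel set, so a
    second vessel that crosses the sphere without touching the center's
    component is not counted.  At volume borders the count runs over the
    in-bounds portion of the sphere (callers flag such sites via
    :func:`is_boundary_site`).
    """
    if isinstance(mask, LabeledVolume):
        mask = mask.mask
    params = params or SphereParams()
    center = tuple(int(c) for c in center)
    if not mask[center]:
        raise ValueError(f"center {center} is not a labeled vessel voxel")

    m = params.max_offset
    r2 = params.radius_vx ** 2 + 1e-12
    lo = [max(0, c - m) for c in center]
    hi = [min(s, c + m + 1) for c, s in zip(center, mask.shape)]
    window = mask[tuple(slice(a, b) for a, b in zip(lo, hi))]

    coords = np.meshgrid(
        *[np.arange(a, b) - c for a, b, c in zip(lo, hi, center)], indexing="ij"
    )
    in_sphere = sum(g.astype(float) ** 2 for g in coords) <= r2
    restricted = window & in_sphere
    labels, _ = ndimage.label(restricted, structure=_structure(mask.ndim,
                                                               params.connectivity))
    center_label = labels[tuple(c - a for c, a in zip(center, lo))]
    return int((labels == center_label).sum())


def cross_section_area(n: int, d_sphere: int) -> float:
    """A_c = n / d_sphere, in voxel^2 (or voxels, in the 2D width reading)."""
    if n < 1:
        raise ValueError("overlap count n must be >= 1")
    if d_sphere < 1:
        raise ValueError("d_sphere must be >= 1")
    return n / d_sphere


def circular_equivalent_diameter(area: float) -> float:
    """Diameter of the circle with area ``A_c``: d_v = 2*sqrt(A_c/pi).

    The isotropic single-number summary of vessel caliber, valid under the
    assumption of a circular cross-section.
    """
    if area <= 0:
        raise ValueError("area must be positive")
    return 2.0 * sqrt(area / pi)


def vessel_width_2d(mask: np.ndarray, center: tuple[int, int],
                    d_circle: int = 11, connectivity: int = 8) -> float:
    """2D vessel width at a skeleton pixel: n / d_circle.

    The worked reference case: 37 overlapping pixels in a circle of
    diameter 11 give a width of 3.36 px.
    """
    params = SphereParams(d_sphere=d_circle, connectivity=connectivity)
    n = connected_overlap_count(np.asarray(mask) != 0, center, params)
    return cross_section_area(n, d_circle)


def is_boundary_site(center: tuple[int, ...], shape: tuple[int, ...],
                     d_sphere: int) -> bool:
    """True when the sphere at ``center`` would be clipped by the border."""
    m = d_sphere // 2
    return any(c - m < 0 or c + m >= s for c, s in zip(center, shape))
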