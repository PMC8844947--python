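"""Synthetic tubular phantoms with known axial stretch, and the
double-reflection artifact model.

The generator emulates the geometry of hand-labeled retinal OCTA vessel
volumes: sparse networks of near-horizontal tubes occupying a few percent
of a thin slab between two retinal surfaces, on an anisotropic voxel grid.
Each tube has a known lateral radius and a known axial stretch factor —
the ground-truth elliptical quotient — so the whole measurement pipeline
can be validated by parameter recovery.

Rasterization model: a tube is a straight segment in physical space with
an *elliptical* cross-section aligned to the z axis — lateral semi-axis
``r``, axial semi-axis ``r * stretch`` — regardless of course direction.
This is valid for the near-horizontal courses generated here (slopes are
capped at 15%, matching the slope statistics of the inner limiting
membrane).  A voxel is labeled iff its physical center lies inside some
tube.

The reflection model formalizes the proposed physical cause of axial
stretching: if the probe beam is reflected twice inside a vessel (extra
in-vessel path of length h), the instrument registers a virtual
penetration depth h/2 beyond the true one, stretching the apparent
cross-section along z.  When the second bounce stays in the same lateral
cross-section, h cannot exceed the vessel diameter, so the implied
elliptical quotient is capped at 1.5; observed quotients beyond that
require longitudinal reflections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .surfaces import roi_mask, surface_gradient
from .volio import (
    DEFAULT_SPACING,
    GeometryError,
    LabeledVolume,
    SurfaceMap,
    VoxelSpacing,
)

__all__ = [
    "TubeSpec",
    "PhantomTruth",
    "ReflectionGeometry",
    "rasterize_tubes",
    "make_surface",
    "make_network_phantom",
    "apparent_depth_reflection",
]


@dataclass(frozen=True)
class TubeSpec:
    """One straight synthetic vessel.

    ``start``/``end`` are physical endpoints in micrometers; ``radius_lateral``
    is the lateral (x/y-plane) radius in micrometers; ``stretch`` is the
    axial-to-lateral axis ratio of the cross-section — the ground-truth
    elliptical quotient of the tube.
    """

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius_lateral: float
    stretch: float = 1.0
    id: str = "tube"

    def __post_init__(self) -> None:
        if self.radius_lateral <= 0:
            raise ValueError(f"tube {self.id!r}: radius must be positive")
        if self.stretch <= 0:
            raise ValueError(f"tube {self.id!r}: stretch must be positive")
        if np.allclose(self.start, self.end):
            raise ValueError(f"tube {self.id!r}: endpoints must be distinct")

    @property
    def true_area_um2(self) -> float:
        """Cross-section area pi * r * (r * stretch)."""
        return np.pi * self.radius_lateral**2 * self.stretch

    @property
    def true_eq(self) -> float:
        return self.stretch


@dataclass
class PhantomTruth:
    """Ground truth accompanying a rasterized phantom."""

    tubes: list[TubeSpec] = field(default_factory=list)

    @property
    def true_eq(self) -> dict[str, float]:
        return {t.id: t.true_eq for t in self.tubes}

    @property
    def true_area_um2(self) -> dict[str, float]:
        return {t.id: t.true_area_um2 for t in self.tubes}

    def centerline(self, tube_id: str, n_points: int = 100) -> np.ndarray:
        """Sampled physical centerline points (um) of one tube."""
        (t,) = [t for t in self.tubes if t.id == tube_id]
        frac = np.linspace(0.0, 1.0, n_points)[:, None]
        return np.asarray(t.start) + frac * (
            np.asarray(t.end) - np.asarray(t.start)
        )


@dataclass(frozen=True)
class ReflectionGeometry:
    """Geometry of a double reflection inside a vessel.

    ``h`` is the extra in-vessel path (distance between the two bounce
    points, um).  In ``lateral`` mode both bounces lie in one lateral
    cross-section, so 0 <= h <= vessel_diameter; ``longitudinal`` mode
    allows the second bounce further along the vessel and places no upper
    bound on h.
    """

    vessel_diameter: float
    reflection_mode: str = "lateral"
    h: float = 0.0

    def __post_init__(self) -> None:
        if self.vessel_diameter <= 0:
            raise ValueError("vessel diameter must be positive")
        if self.reflection_mode not in ("lateral", "longitudinal"):
            raise ValueError("reflection_mode must be 'lateral' or 'longitudinal'")
        if self.h < 0:
            raise ValueError("extra path h cannot be negative")
        if self.reflection_mode == "lateral" and self.h > self.vessel_diameter:
            raise GeometryError(
                f"lateral reflection requires h <= diameter "
                f"({self.h} > {self.vessel_diameter})"
            )


def apparent_depth_reflection(geom: ReflectionGeometry) -> tuple[float, float]:
    """Apparent axial extent (um) and implied elliptical quotient.

    The doubled path adds h/2 of virtual penetration depth, so

        apparent depth = d + h/2,   implied eq = 1 + h / (2 d).

    The implied quotient is affine in h with slope 1/(2d).  In lateral
    mode h <= d, so the supremum is eq = 1.5, attained at h = d; values
    beyond 1.5 require longitudinal reflections.
    """
    apparent = geom.vessel_diameter + geom.h / 2.0
    return apparent, apparent / geom.vessel_diameter


# ---------------------------------------------------------------------------
# rasterization

def rasterize_tubes(specs: list[TubeSpec], shape: tuple[int, int, int],
                    spacing: VoxelSpacing = DEFAULT_SPACING, seed: int = 0,
                    label_noise: float = 0.0,
                    name: str = "phantom") -> tuple[LabeledVolume, PhantomTruth]:
    """Rasterize straight elliptical tubes into a labeled volume.

    A voxel is labeled iff its physical center lies inside some tube's
    z-aligned elliptical cross-section, evaluated at the nearest point of
    the tube's centerline segment (clamping at the endpoints yields
    slightly rounded end caps).  ``label_noise`` flips each voxel
    independently with the given probability under ``seed``.

    Raises :class:`GeometryError`, naming the tube, if an endpoint lies
    outside the physical extent of the volume.
    """
    shape = tuple(int(s) for s in shape)
    extent = np.array(shape, dtype=float) * np.array(spacing.as_tuple())
    for t in specs:
        for label, p in (("start", t.start), ("end", t.end)):
            p = np.asarray(p, dtype=float)
            if np.any(p < 0) or np.any(p > extent):
                raise GeometryError(
                    f"tube {t.id!r}: {label} point {tuple(p)} lies outside "
                    f"the physical volume extent {tuple(extent)} um"
                )

    mask = np.zeros(shape, dtype=bool)
    s = np.array(spacing.as_tuple())
    for t in specs:
        p0 = np.asarray(t.start, dtype=float)
        p1 = np.asarray(t.end, dtype=float)
        r_lat = t.radius_lateral
        r_ax = t.radius_lateral * t.stretch

        # bounding box in voxel indices, padded by the semi-axes
        pad = np.array([r_lat, r_lat, r_ax])
        lo_um = np.minimum(p0, p1) - pad
        hi_um = np.maximum(p0, p1) + pad
        lo = np.maximum(np.floor(lo_um / s - 0.5).astype(int), 0)
        hi = np.minimum(np.ceil(hi_um / s - 0.5).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue

        axes_um = [
            (np.arange(a, b) + 0.5) * sp for a, b, sp in zip(lo, hi, s)
        ]
        cx, cy, cz = np.meshgrid(*axes_um, indexing="ij")
        centers = np.stack([cx, cy, cz], axis=-1)

        u = p1 - p0
        tt = np.clip(((centers - p0) @ u) / (u @ u), 0.0, 1.0)
        nearest = p0 + tt[..., None] * u
        delta = centers - nearest
        lat2 = delta[..., 0] ** 2 + delta[..., 1] ** 2
        inside = lat2 / r_lat**2 + delta[..., 2] ** 2 / r_ax**2 <= 1.0
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= inside

    if label_noise > 0.0:
        rng = np.random.default_rng(seed)
        flips = rng.random(shape) < label_noise
        mask ^= flips

    return LabeledVolume(mask, spacing, name), PhantomTruth(list(specs))


# ---------------------------------------------------------------------------
# surfaces and networks

def make_surface(shape_xy: tuple[int, int], spacing: VoxelSpacing = DEFAULT_SPACING,
                 mean_height_vx: float = 40.0, mean_gradient: float = 0.059,
                 seed: int = 0) -> SurfaceMap:
    """Smooth random surface with a prescribed mean slope.

    A sum of random low-frequency sinusoids is scaled so the mean physical
    gradient magnitude matches ``mean_gradient`` (default 5.9%, the
    average slope of the inner limiting membrane).
    """
    nx, ny = shape_xy
    rng = np.random.default_rng(seed)
    x = np.arange(nx)[:, None] / max(nx, 1)
    y = np.arange(ny)[None, :] / max(ny, 1)
    h = np.zeros((nx, ny))
    for _ in range(6):
        fx, fy = rng.uniform(0.5, 2.5, size=2)
        phx, phy = rng.uniform(0, 2 * np.pi, size=2)
        h += rng.uniform(0.3, 1.0) * np.sin(2 * np.pi * fx * x + phx) * np.sin(
            2 * np.pi * fy * y + phy
        )
    surf = SurfaceMap(h, spacing)
    g = surface_gradient(surf)
    gm = float(g.mean())
    if gm > 0 and mean_gradient > 0:
        h = h * (mean_gradient / gm)
    h = h - h.min() + mean_height_vx - float((h - h.min()).mean())
    return SurfaceMap(h, spacing)


def _sample_surface(surface: SurfaceMap, x_vx: float, y_vx: float) -> float:
    """Nearest-pixel surface height (voxel units) at fractional indices."""
    nx, ny = surface.shape
    i = int(np.clip(round(x_vx), 0, nx - 1))
    j = int(np.clip(round(y_vx), 0, ny - 1))
    return float(surface.height[i, j])


def make_network_phantom(
    density_target: float = 0.05,
    shape: tuple[int, int, int] = (304, 304, 160),
    spacing: VoxelSpacing = DEFAULT_SPACING,
    seed: int = 0,
    slab: tuple[SurfaceMap, SurfaceMap] | None = None,
    slab_thickness_vx: float = 15.0,
    n_tubes: int | None = None,
    radius_range_um: tuple[float, float] = (10.0, 35.0),
    stretch: float = 1.0,
    max_course_slope: float = 0.15,
    max_tubes: int = 400,
) -> tuple[LabeledVolume, tuple[SurfaceMap, SurfaceMap], PhantomTruth]:
    """Random vessel network inside a retinal-slab ROI.

    Tubes are laid approximately parallel to the upper (ILM-like) surface:
    each course follows the local surface height, with its z slope capped
    at ``max_course_slope``.  Tube diameters default to 20-70 um and are
    placed until the labeled fraction of the ROI reaches
    ``density_target`` (or exactly ``n_tubes`` tubes when given).  Fully
    reproducible under ``seed``.

    Returns the labeled volume, the (ilm, onl) surface pair, and the
    ground truth.  If the density target cannot be reached within the tube
    budget a warning is issued and the achieved density stands.
    """
    if not 0.0 < density_target <= 0.2:
        raise ValueError("density_target must lie in (0, 0.2]")
    nx, ny, nz = (int(v) for v in shape)
    rng = np.random.default_rng(seed)

    if slab is None:
        margin = slab_thickness_vx + 6.0
        ilm = make_surface(
            (nx, ny), spacing,
            mean_height_vx=min(40.0, max(2.0, nz - margin) / 2.0 + 2.0),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        h = np.clip(ilm.height, 1.0, nz - slab_thickness_vx - 2.0)
        ilm = SurfaceMap(h, spacing)
        onl = SurfaceMap(h + slab_thickness_vx, spacing)
    else:
        ilm, onl = slab
    roi, roi_count = roi_mask(ilm, onl, (nx, ny, nz))

    s = np.array(spacing.as_tuple())
    extent = np.array([nx, ny, nz], dtype=float) * s
    thickness = float((onl.height - ilm.height).mean())

    specs: list[TubeSpec] = []
    mask = np.zeros((nx, ny, nz), dtype=bool)
    target = n_tubes if n_tubes is not None else max_tubes
    for k in range(max_tubes):
        if n_tubes is None:
            density = mask[roi].sum() / roi_count if roi_count else 0.0
            if density >= density_target:
                break
        elif len(specs) >= target:
            break
        radius = float(rng.uniform(*radius_range_um))
        # lateral course spanning most of the field of view
        theta = float(rng.uniform(0, 2 * np.pi))
        d2 = np.array([np.cos(theta), np.sin(theta)])
        mid = np.array([rng.uniform(0.25, 0.75) * nx, rng.uniform(0.25, 0.75) * ny])
        half = 0.45 * min(nx, ny)
        a_xy = mid - half * d2
        b_xy = mid + half * d2
        a_xy = np.clip(a_xy, 2.0, [nx - 3.0, ny - 3.0])
        b_xy = np.clip(b_xy, 2.0, [nx - 3.0, ny - 3.0])
        if np.hypot(*(b_xy - a_xy)) < 10:
            continue

        # follow the surface: endpoint depths from the local ILM height,
        # with the course slope capped
        depth_off = float(rng.uniform(0.25, 0.75)) * thickness
        za = _sample_surface(ilm, *a_xy) + depth_off
        zb = _sample_surface(ilm, *b_xy) + depth_off
        run_um = float(np.hypot(*((b_xy - a_xy) * s[:2])))
        dz_um = (zb - za) * s[2]
        if run_um > 0 and abs(dz_um) / run_um > max_course_slope:
            dz_um = np.sign(dz_um) * max_course_slope * run_um
            zb = za + dz_um / s[2]
        za = float(np.clip(za, 1.0, nz - 2.0))
        zb = float(np.clip(zb, 1.0, nz - 2.0))

        start = ((a_xy[0] + 0.5) * s[0], (a_xy[1] + 0.5) * s[1], (za + 0.5) * s[2])
        end = ((b_xy[0] + 0.5) * s[0], (b_xy[1] + 0.5) * s[1], (zb + 0.5) * s[2])
        start = tuple(np.clip(start, 0.0, extent))
        end = tuple(np.clip(end, 0.0, extent))
        spec = TubeSpec(start, end, radius, stretch, id=f"tube{len(specs):03d}")
        vol_k, _ = rasterize_tubes([spec], (nx, ny, nz), spacing)
        mask |= vol_k.mask
        specs.append(spec)

    achieved = mask[roi].sum() / roi_count if roi_count else 0.0
    if n_tubes is None and achieved < density_target:
        import warnings

        warnings.warn(
            f"density target {density_target:.3f} unreachable within "
            f"{max_tubes} tubes; achieved {achieved:.3f}", stacklevel=2
        )
    volume = LabeledVolume(mask, spacing, name=f"network-seed{seed}")
    return volume, (ilm, onl), PhantomTruth(specs)
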