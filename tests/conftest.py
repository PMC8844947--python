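import numpy as np
import pytest

from octastretch import VoxelSpacing
from octastretch.phantom import TubeSpec, rasterize_tubes


@pytest.fixture(scope="session")
def device_spacing():
    """Spacing of the reference OCTA device grid (um)."""
    return VoxelSpacing(9.87, 9.87, 12.54)


@pytest.fixture(scope="session")
def iso_spacing():
    """Unit isotropic spacing: voxel units equal physical units."""
    return VoxelSpacing(1.0, 1.0, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def straight_tube(axis: str, radius: float, length: float = 60.0,
                  pad: float = 10.0, stretch: float = 1.0,
                  spacing: VoxelSpacing | None = None):
    """Digitized straight tube along a coordinate axis or the xy diagonal.

    Works in voxel units under unit spacing unless a spacing is given.
    Returns (LabeledVolume, axis unit vector, TubeSpec).
    """
    spacing = spacing or VoxelSpacing(1.0, 1.0, 1.0)
    if axis == "diag":
        n = int(length / np.sqrt(2)) + 2 * int(pad)
        shape = (n, n, 2 * int(np.ceil(radius * stretch)) + 2 * int(pad))
        zc = shape[2] / 2 * spacing.sz
        spec = TubeSpec(
            (pad * spacing.sx, pad * spacing.sy, zc),
            ((pad + length / np.sqrt(2)) * spacing.sx,
             (pad + length / np.sqrt(2)) * spacing.sy, zc),
            radius, stretch,
        )
        u = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
    else:
        i = "xyz".index(axis)
        shape = [2 * int(np.ceil(radius * stretch)) + 2 * int(pad)] * 3
        shape[i] = int(length) + 2 * int(pad)
        shape = tuple(shape)
        s = np.array(spacing.as_tuple())
        center = np.array(shape) / 2 * s
        start, end = center.copy(), center.copy()
        start[i] = pad * s[i]
        end[i] = (pad + length) * s[i]
        spec = TubeSpec(tuple(start), tuple(end), radius, stretch)
        u = np.eye(3)[i]
    volume, _ = rasterize_tubes([spec], shape, spacing)
    return volume, u, spec
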