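import numpy as np
import pytest

from octastretch.phantom import (
    PhantomTruth,
    ReflectionGeometry,
    TubeSpec,
    apparent_depth_reflection,
    make_network_phantom,
    make_surface,
    rasterize_tubes,
)
from octastretch.surfaces import roi_mask, slope_stats
from octastretch.volio import GeometryError, VoxelSpacing


class TestTubeSpec:
    def test_truth_formulas(self):
        t = TubeSpec((0, 0, 0), (100, 0, 0), radius_lateral=15.0, stretch=2.0)
        assert t.true_area_um2 == pytest.approx(np.pi * 225 * 2.0)
        assert t.true_eq == 2.0

    def test_degenerate_specs_rejected(self):
        with pytest.raises(ValueError):
            TubeSpec((0, 0, 0), (0, 0, 0), 10.0)
        with pytest.raises(ValueError):
            TubeSpec((0, 0, 0), (1, 0, 0), -1.0)


class TestRasterizeTubes:
    def test_per_plane_area_matches_analytic(self, device_spacing):
        # radius 15 um, stretch 1: analytic per-x-plane area
        # pi*15^2/(9.87*12.54) = 5.71 voxels; a slight lateral course
        # samples many sub-voxel phases so the mean approaches it
        sp = device_spacing
        spec = TubeSpec((8 * sp.sx, 18.2 * sp.sy, 20.37 * sp.sz),
                        (132 * sp.sx, 24.2 * sp.sy, 20.37 * sp.sz), 15.0, 1.0)
        vol, _ = rasterize_tubes([spec], (140, 44, 40), sp)
        per_plane = vol.mask[12:128].sum(axis=(1, 2))
        assert per_plane.mean() == pytest.approx(5.71, rel=0.15)

    def test_stretched_tube_extent_ratio(self, device_spacing):
        sp = device_spacing
        spec = TubeSpec((6 * sp.sx, 20.2 * sp.sy, 25.37 * sp.sz),
                        (114 * sp.sx, 20.2 * sp.sy, 25.37 * sp.sz), 30.0, 2.5)
        vol, _ = rasterize_tubes([spec], (120, 40, 52), sp)
        ratios = []
        for x in range(30, 90):
            plane = vol.mask[x]
            ys, zs = np.nonzero(plane)
            extent_um_z = (zs.max() - zs.min() + 1) * sp.sz
            extent_um_y = (ys.max() - ys.min() + 1) * sp.sy
            ratios.append(extent_um_z / extent_um_y)
        assert np.mean(ratios) == pytest.approx(2.5, rel=0.15)

    def test_zero_tubes_gives_empty_volume(self, iso_spacing):
        vol, truth = rasterize_tubes([], (10, 10, 10), iso_spacing)
        assert vol.count() == 0 and truth.tubes == []

    def test_out_of_volume_tube_names_id(self, iso_spacing):
        bad = TubeSpec((0, 5, 5), (500, 5, 5), 2.0, id="runaway")
        with pytest.raises(GeometryError, match="runaway"):
            rasterize_tubes([bad], (20, 10, 10), iso_spacing)

    def test_label_noise_flips_at_stated_rate(self, iso_spacing):
        vol0, _ = rasterize_tubes([], (40, 40, 40), iso_spacing)
        vol1, _ = rasterize_tubes([], (40, 40, 40), iso_spacing,
                                  seed=5, label_noise=0.05)
        rate = vol1.count() / vol1.mask.size
        assert rate == pytest.approx(0.05, rel=0.1)

    def test_determinism_under_seed(self, iso_spacing):
        spec = TubeSpec((5, 10, 10), (35, 10, 10), 3.0)
        a, _ = rasterize_tubes([spec], (40, 20, 20), iso_spacing,
                               seed=3, label_noise=0.02)
        b, _ = rasterize_tubes([spec], (40, 20, 20), iso_spacing,
                               seed=3, label_noise=0.02)
        c, _ = rasterize_tubes([spec], (40, 20, 20), iso_spacing,
                               seed=4, label_noise=0.02)
        assert np.array_equal(a.mask, b.mask)
        assert not np.array_equal(a.mask, c.mask)

    def test_truth_extent_ratio_consistency(self, device_spacing):
        # measured physical axial/lateral extent within 10% of the spec
        # stretch for radius >= 3 lateral voxels
        sp = device_spacing
        for stretch in (1.0, 2.0, 3.0):
            spec = TubeSpec((6 * sp.sx, 20.2 * sp.sy, 40.37 * sp.sz),
                            (114 * sp.sx, 20.2 * sp.sy, 40.37 * sp.sz),
                            35.0, stretch)
            vol, truth = rasterize_tubes([spec], (120, 40, 80), sp)
            ratios = []
            for x in range(30, 90):
                ys, zs = np.nonzero(vol.mask[x])
                ratios.append(((zs.max() - zs.min() + 1) * sp.sz)
                              / ((ys.max() - ys.min() + 1) * sp.sy))
            assert np.mean(ratios) == pytest.approx(stretch, rel=0.10)

    def test_centerline_endpoints(self):
        t = TubeSpec((0, 0, 0), (10, 0, 0), 1.0, id="a")
        line = PhantomTruth([t]).centerline("a", n_points=11)
        assert line.shape == (11, 3)
        np.testing.assert_allclose(line[0], (0, 0, 0))
        np.testing.assert_allclose(line[-1], (10, 0, 0))


class TestReflectionModel:
    def test_maximum_lateral_quotient_is_three_halves(self):
        d = 40.0
        _, eq = apparent_depth_reflection(ReflectionGeometry(d, "lateral", d))
        assert eq == 1.5

    def test_no_double_reflection_means_circular(self):
        _, eq = apparent_depth_reflection(ReflectionGeometry(40.0, "lateral", 0.0))
        assert eq == 1.0

    def test_sweep_attains_max_at_h_equals_d(self):
        d = 33.0
        hs = np.linspace(0, d, 1000)
        eqs = [apparent_depth_reflection(ReflectionGeometry(d, "lateral", h))[1]
               for h in hs]
        assert max(eqs) == pytest.approx(1.5, abs=1e-12)
        assert int(np.argmax(eqs)) == len(hs) - 1

    def test_quotient_affine_in_h_with_slope_half_over_d(self):
        d = 50.0
        hs = np.linspace(0, d, 11)
        eqs = np.array([
            apparent_depth_reflection(ReflectionGeometry(d, "lateral", h))[1]
            for h in hs
        ])
        slopes = np.diff(eqs) / np.diff(hs)
        np.testing.assert_allclose(slopes, 1 / (2 * d), rtol=1e-12)

    def test_lateral_mode_bounds_h_by_diameter(self):
        with pytest.raises(GeometryError):
            ReflectionGeometry(40.0, "lateral", 41.0)

    def test_longitudinal_mode_can_exceed_three_halves(self):
        _, eq = apparent_depth_reflection(
            ReflectionGeometry(40.0, "longitudinal", 120.0))
        assert eq == pytest.approx(2.5)


class TestNetworkPhantom:
    def test_density_on_study_sized_grid(self):
        vol, (ilm, onl), truth = make_network_phantom(
            density_target=0.05, seed=3)
        roi, count = roi_mask(ilm, onl, vol.shape)
        density = vol.mask[roi].sum() / count
        assert 0.035 <= density <= 0.065
        assert len(truth.tubes) > 1

    def test_same_seed_bit_identical(self):
        a, _, _ = make_network_phantom(0.04, shape=(80, 80, 40), seed=9)
        b, _, _ = make_network_phantom(0.04, shape=(80, 80, 40), seed=9)
        c, _, _ = make_network_phantom(0.04, shape=(80, 80, 40), seed=10)
        assert np.array_equal(a.mask, b.mask)
        assert not np.array_equal(a.mask, c.mask)

    def test_single_tube_is_one_component(self):
        from scipy import ndimage

        vol, _, truth = make_network_phantom(
            0.05, shape=(80, 80, 40), seed=2, n_tubes=1)
        assert len(truth.tubes) == 1
        assert ndimage.label(vol.mask, structure=np.ones((3, 3, 3)))[1] == 1

    def test_surface_slope_matches_target(self):
        surf = make_surface((120, 120), mean_gradient=0.059, seed=4)
        stats = slope_stats(surf)
        assert stats.mean_pct == pytest.approx(5.9, rel=0.05)

    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError):
            make_network_phantom(0.5, shape=(40, 40, 30), seed=1)
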