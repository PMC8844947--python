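import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octastretch.cross_section import (
    SphereParams,
    circle_offsets,
    circular_equivalent_diameter,
    connected_overlap_count,
    cross_section_area,
    is_boundary_site,
    sphere_offsets,
    vessel_width_2d,
)
from octastretch.skeleton import skeletonize_3d
from tests.conftest import straight_tube


class TestSphereOffsets:
    def test_diameter_one_is_center_only(self):
        assert sphere_offsets(1).tolist() == [[0, 0, 0]]

    def test_diameter_three_has_19_offsets(self):
        # center + 6 face + 12 edge neighbors; corners at norm sqrt(3) > 1.5
        offs = sphere_offsets(3)
        assert len(offs) == 19
        assert not any(np.abs(o).sum() == 3 for o in offs)

    @pytest.mark.parametrize("d", [5, 9, 11])
    def test_matches_brute_force_enumeration(self, d):
        offs = {tuple(o) for o in sphere_offsets(d)}
        m = d // 2
        brute = {
            (i, j, k)
            for i in range(-m, m + 1)
            for j in range(-m, m + 1)
            for k in range(-m, m + 1)
            if i * i + j * j + k * k <= (d / 2) ** 2
        }
        assert offs == brute

    @given(st.integers(min_value=1, max_value=15).filter(lambda d: d % 2 == 1))
    @settings(deadline=None, derandomize=True)
    def test_symmetric_under_negation_and_permutation(self, d):
        offs = {tuple(o) for o in sphere_offsets(d)}
        assert (0, 0, 0) in offs
        for o in offs:
            assert (-o[0], -o[1], -o[2]) in offs
            assert (o[1], o[2], o[0]) in offs

    def test_2d_circle_offsets(self):
        assert len(circle_offsets(1)) == 1
        assert len(circle_offsets(3)) == 9  # all 8 neighbors within 1.5


class TestConnectedOverlapCount:
    def test_isolated_voxel_counts_one(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[10, 10, 10] = True
        assert connected_overlap_count(mask, (10, 10, 10), SphereParams(9)) == 1

    def test_straight_line_counts_the_chord(self):
        # 1-voxel line through the center: the 9-voxel chord |offset| <= 4
        mask = np.zeros((30, 9, 9), bool)
        mask[:, 4, 4] = True
        assert connected_overlap_count(mask, (15, 4, 4), SphereParams(9)) == 9

    def test_disconnected_vessel_in_sphere_not_counted(self):
        single = np.zeros((20, 20, 20), bool)
        single[10, 10, :] = True            # center vessel along z
        both = single.copy()
        both[10, 13, :] = True              # second vessel, not 26-adjacent
        params = SphereParams(9)
        assert (connected_overlap_count(both, (10, 10, 10), params)
                == connected_overlap_count(single, (10, 10, 10), params))

    def test_unlabeled_center_rejected(self):
        mask = np.zeros((9, 9, 9), bool)
        with pytest.raises(ValueError):
            connected_overlap_count(mask, (4, 4, 4), SphereParams(9))

    def test_boundary_site_flagging(self):
        assert is_boundary_site((3, 10, 10), (20, 20, 20), 9)
        assert not is_boundary_site((4, 10, 10), (20, 20, 20), 9)
        assert is_boundary_site((10, 10, 16), (20, 20, 20), 9)


class TestAreaAndDiameter:
    def test_unit_line_has_unit_area(self):
        assert cross_section_area(9, 9) == 1.0

    def test_worked_2d_example(self):
        # 37 overlapping pixels, circle diameter 11 -> width 3.36 px
        assert cross_section_area(37, 11) == pytest.approx(3.36, abs=0.005)

    @pytest.mark.parametrize(
        "area,dv",
        [(np.pi, 2.0), (np.pi / 4, 1.0), (13.86, 4.2012)],
    )
    def test_circular_equivalent_diameter(self, area, dv):
        assert circular_equivalent_diameter(area) == pytest.approx(dv, abs=5e-4)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            circular_equivalent_diameter(0.0)


class TestVesselWidth2D:
    def test_isolated_pixel(self):
        mask = np.zeros((30, 30), bool)
        mask[15, 15] = True
        assert vessel_width_2d(mask, (15, 15), 11) == pytest.approx(1 / 11)

    def test_one_pixel_line_has_unit_width(self):
        mask = np.zeros((30, 30), bool)
        mask[:, 15] = True
        assert vessel_width_2d(mask, (15, 15), 11) == 1.0


class TestEstimatorProperties:
    def test_planar_oracle_equivalence_axis_aligned(self):
        # A_c within 15% of the mean digitized per-plane area, radius >= 2
        for rho in (2.0, 3.0):
            vol, u, spec = straight_tube("x", rho)
            sk = skeletonize_3d(vol)
            pts = np.argwhere(sk)
            t = pts @ u
            sel = (t >= t.min() + (np.ptp(t)) / 3) & (t <= t.max() - (np.ptp(t)) / 3)
            acs = [
                cross_section_area(
                    connected_overlap_count(vol.mask, tuple(p), SphereParams(9)), 9)
                for p in pts[sel]
            ]
            i0 = int(10 + 4)
            planes = [vol.mask[k].sum() for k in range(i0, vol.shape[0] - i0)]
            oracle = float(np.mean(planes))
            assert np.mean(acs) == pytest.approx(oracle, rel=0.15)

    def test_orientation_invariance_within_20_percent(self):
        means = {}
        for axis in ("x", "y", "z", "diag"):
            vol, u, spec = straight_tube(axis, 2.5)
            sk = skeletonize_3d(vol)
            pts = np.argwhere(sk)
            t = pts @ u
            sel = (t >= t.min() + np.ptp(t) / 3) & (t <= t.max() - np.ptp(t) / 3)
            acs = [
                cross_section_area(
                    connected_overlap_count(vol.mask, tuple(p), SphereParams(9)), 9)
                for p in pts[sel]
            ]
            means[axis] = float(np.mean(acs))
        vals = list(means.values())
        assert max(vals) / min(vals) <= 1.20

    def test_area_monotone_in_tube_radius(self):
        prev = 0.0
        for rho in (1.0, 1.5, 2.0, 2.5, 3.0):
            vol, u, spec = straight_tube("x", rho)
            c = tuple(np.array(vol.shape) // 2)
            center = (vol.shape[0] // 2, vol.shape[1] // 2, vol.shape[2] // 2)
            # snap to a labeled voxel near the center
            labeled = np.argwhere(vol.mask)
            site = labeled[np.linalg.norm(labeled - np.array(center), axis=1).argmin()]
            ac = cross_section_area(
                connected_overlap_count(vol.mask, tuple(site), SphereParams(9)), 9)
            assert ac >= prev
            prev = ac

    def test_end_of_vessel_underestimation(self, iso_spacing):
        # at the centerline terminal of a border-truncated tube the sphere
        # hangs half outside the vessel: A_c drops to ~50% of interior
        from octastretch.phantom import TubeSpec, rasterize_tubes

        vol, _ = rasterize_tubes(
            [TubeSpec((0.01, 8, 8), (59.99, 8, 8), 2.5, 1.0)], (60, 16, 16),
            iso_spacing)
        params = SphereParams(9)
        end = cross_section_area(
            connected_overlap_count(vol.mask, (0, 8, 8), params), 9)
        interior = np.mean([
            cross_section_area(
                connected_overlap_count(vol.mask, (x, 8, 8), params), 9)
            for x in range(25, 36)
        ])
        assert 0.35 <= end / interior <= 0.65

    def test_branch_point_overestimation(self, iso_spacing):
        from octastretch.phantom import TubeSpec, rasterize_tubes

        main = TubeSpec((10, 20, 8), (70, 20, 8), 2.5, 1.0, id="main")
        branch = TubeSpec((40, 20, 8), (68, 48, 8), 2.5, 1.0, id="branch")
        vol, _ = rasterize_tubes([main, branch], (80, 60, 16), iso_spacing)
        params = SphereParams(9)
        junction = cross_section_area(
            connected_overlap_count(vol.mask, (40, 20, 8), params), 9)
        interior = np.mean([
            cross_section_area(
                connected_overlap_count(vol.mask, (x, 20, 8), params), 9)
            for x in range(15, 31)
        ])
        assert junction > interior
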