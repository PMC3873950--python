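"""Geometric primitives: lengths, tapers, virtual slices, walls, angles."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_h

from rootarch import geometry as geo
from rootarch import synthetic as syn
from rootarch.model import Box, ValidationError

from conftest import seg, system


class TestAxisLength:
    def test_mother_radius_added(self):
        rs = system(
            seg("S1", None, "A1", 1, (0, 0, 0), (0, 0, -0.05), 0.01),
            seg("S2", "S1", "A2", 2, (0, 0, -0.05), (0.05, 0, -0.05), 0.002),
            seg("S3", "S2", "A2", 2, (0.05, 0, -0.05), (0.10, 0, -0.05), 0.002),
        )
        axes = rs.axes()
        # two collinear 5 cm segments + mother radius 0.5 cm -> 10.5 cm
        assert geo.axis_length(axes["A2"], rs.segments["S1"]) == pytest.approx(0.105)

    def test_order1_has_no_mother_radius(self):
        rs = system(
            seg("S1", None, "A1", 1, (0, 0, 0), (0, 0, -0.04), 0.005),
            seg("S2", "S1", "A1", 1, (0, 0, -0.04), (0, 0, -0.07), 0.004),
        )
        assert geo.axis_length(rs.axes()["A1"], None) == pytest.approx(0.07)

    def test_matches_polyline_oracle_on_generated_axis(self):
        rs = syn.generate(syn.GeneratorConfig(seed=3))
        for aid, segs in rs.axes().items():
            brute = sum(
                float(np.linalg.norm(s.tip_xyz - s.base_xyz)) for s in segs
            )
            assert geo.axis_length(segs, None) == pytest.approx(brute, abs=1e-9)


class TestMeanDiameter:
    @pytest.mark.parametrize(
        "volume_cm3,length_cm,expected_cm",
        [(math.pi, 1.0, 2.0), (math.pi / 4, 1.0, 1.0), (0.0, 1.0, 0.0)],
    )
    def test_cylinder_identity(self, volume_cm3, length_cm, expected_cm):
        d = geo.mean_diameter(volume_cm3 * 1e-6, length_cm * 1e-2)
        assert d == pytest.approx(expected_cm * 1e-2)

    def test_zero_length_raises(self):
        with pytest.raises(ValidationError):
            geo.mean_diameter(1e-6, 0.0)


class TestProximalTaper:
    def test_linear_taper_example(self):
        # d0 = 0.20 cm and 0.13 cm at 3.5 cm -> 10 %/cm
        rs = system(
            seg("S1", None, "A1", 1, (0, 0, 0), (0, 0, -0.035), 0.0020),
            seg("S2", "S1", "A1", 1, (0, 0, -0.035), (0, 0, -0.06), 0.0013),
        )
        t = geo.proximal_taper(rs, rs.axes()["A1"])
        assert t == pytest.approx(10.0)

    def test_constant_diameter_is_zero(self):
        rs = system(
            seg("S1", None, "A1", 1, (0, 0, 0), (0, 0, -0.05), 0.002),
            seg("S2", "S1", "A1", 1, (0, 0, -0.05), (0, 0, -0.09), 0.002),
        )
        assert geo.proximal_taper(rs, rs.axes()["A1"]) == pytest.approx(0.0)

    def test_short_axis_is_missing(self):
        rs = system(seg("S1", None, "A1", 1, (0, 0, 0), (0, 0, -0.02), 0.002))
        assert geo.proximal_taper(rs, rs.axes()["A1"]) is None

    def test_interpolation_between_knots(self):
        # diameter knots at 0, 2 and 5 cm: 3.0, 2.0, 1.0 mm
        rs = system(
            seg("S1", None, "A1", 1, (0, 0, 0), (0, 0, -0.02), 0.0030),
            seg("S2", "S1", "A1", 1, (0, 0, -0.02), (0, 0, -0.05), 0.0020),
            seg("S3", "S2", "A1", 1, (0, 0, -0.05), (0, 0, -0.08), 0.0010),
        )
        # d(3.5 cm) = 2.0 + (1.0-2.0)*(1.5/3.0) = 1.5 mm (hand interpolation)
        d35 = geo.diameter_at(rs, rs.axes()["A1"], 0.035)
        assert d35 == pytest.approx(0.0015)
        t = geo.proximal_taper(rs, rs.axes()["A1"])
        assert t == pytest.approx(100.0 * (3.0 - 1.5) / 3.0 / 3.5)


class TestVirtualize:
    def test_35mm_gives_four_slices(self):
        rs = system(seg("S1", None, "A1", 1, (0, 0, 0), (0.035, 0, 0), 0.002))
        vss = geo.virtualize(rs, rs.segments["S1"])
        assert [round(v.length_m, 6) for v in vss] == [0.01, 0.01, 0.01, 0.005]
        assert sum(v.length_m for v in vss) == pytest.approx(0.035)

    def test_10mm_single_slice(self):
        rs = system(seg("S1", None, "A1", 1, (0, 0, 0), (0.01, 0, 0), 0.002))
        assert len(geo.virtualize(rs, rs.segments["S1"])) == 1

    def test_frustum_volume_conserved(self):
        # d 4 -> 2 mm over 30 mm: slice volumes sum to the closed form
        rs = system(
            seg("S1", None, "A1", 1, (0, 0, 0), (0.03, 0, 0), 0.004),
            seg("S2", "S1", "A1", 1, (0.03, 0, 0), (0.05, 0, 0), 0.002),
        )
        vss = geo.virtualize(rs, rs.segments["S1"])
        expected = geo.frustum_volume(0.004, 0.002, 0.03)
        assert abs(sum(v.volume_m3 for v in vss) - expected) < 1e-12

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st_h.integers(min_value=0, max_value=10_000))
    def test_system_conservation_property(self, seed):
        """Virtualization conserves length and volume for any generated system."""
        rs = syn.generate(syn.GeneratorConfig(seed=seed, n_laterals=6))
        vss = geo.virtualize_system(rs)
        tot_len = sum(s.length_m for s in rs.segments.values())
        tot_vol = sum(geo.segment_volume(rs, s) for s in rs.segments.values())
        assert sum(v.length_m for v in vss) == pytest.approx(tot_len, rel=1e-9)
        assert sum(v.volume_m3 for v in vss) == pytest.approx(tot_vol, rel=1e-9)


class TestWallExtension:
    def _deflected_system(self, seed=5, n=8, length=0.25):
        cfg = syn.GeneratorConfig(
            seed=seed,
            n_laterals=n,
            azimuth_mode="stratified",
            tips_per_lateral=1,
            dir_jitter_deg=0.0,
            lateral_angle_sd_deg=0.0,
            lateral_angle_mean_deg=-5.0,
            lateral_mean_length_m=length,
            lateral_length_sd_m=0.0,
            taproot_jitter_deg=0.0,
            taproot_gravitropism=0.0,
            fine_root_rate_per_cm=0.0,
            branch_azimuth_sd_deg=0.0,
        )
        return syn.generate(cfg)

    def test_direction_restored_lengths_preserved(self):
        rs = self._deflected_system()
        gt = rs.ground_truth
        assert gt.deflected_axes  # the 25 cm laterals must hit the walls
        rc = geo.extend_wall_roots(rs)
        axes0, axes1 = rs.axes(), rc.axes()
        for aid in gt.deflected_axes:
            for s0, s1 in zip(axes0[aid], axes1[aid]):
                assert s1.length_m == pytest.approx(s0.length_m, abs=1e-9)
            # corrected distal vertices are collinear with the pre-contact direction
            tip = axes1[aid][-1].tip_xyz
            err = np.linalg.norm(tip - gt.true_tips[aid])
            assert err < 1e-3

    def test_untouched_system_is_identical(self):
        rs = syn.generate(syn.even_lateral_config(6, seed=2))  # short laterals
        assert not rs.ground_truth.deflected_axes
        rc = geo.extend_wall_roots(rs)
        for sid, s in rs.segments.items():
            np.testing.assert_array_equal(s.base_xyz, rc.segments[sid].base_xyz)
            np.testing.assert_array_equal(s.tip_xyz, rc.segments[sid].tip_xyz)

    def test_idempotent(self):
        rs = self._deflected_system(seed=9)
        once = geo.extend_wall_roots(rs)
        twice = geo.extend_wall_roots(once)
        for sid in rs.segments:
            np.testing.assert_allclose(
                once.segments[sid].tip_xyz, twice.segments[sid].tip_xyz, atol=1e-12
            )

    def test_axis_starting_on_wall_warned_and_unchanged(self):
        rs = system(
            seg("S1", None, "A1", 1, (0, 0, 0), (0, 0, -0.05), 0.005),
            seg("S2", "S1", "A2", 2, (0.15, 0, -0.05), (0.15, 0.02, -0.05), 0.001),
            seg("S3", "S2", "A2", 2, (0.15, 0.02, -0.05), (0.15, 0.05, -0.05), 0.001),
        )
        with pytest.warns(UserWarning, match="first vertex"):
            rc = geo.extend_wall_roots(rs)
        np.testing.assert_array_equal(rc.segments["S3"].tip_xyz, rs.segments["S3"].tip_xyz)


class TestTaprootAngle:
    def test_vertical(self):
        rs = system(seg("S1", None, "A1", 1, (0, 0, 0), (0, 0, -0.09), 0.005))
        a, flag = geo.taproot_angle(rs)
        assert a == pytest.approx(-90.0)
        assert flag is None

    def test_unit_slope(self):
        rs = system(seg("S1", None, "A1", 1, (0, 0, 0), (0.09, 0, -0.09), 0.005))
        a, _ = geo.taproot_angle(rs)
        assert a == pytest.approx(-45.0)

    def test_crooked_taproot_uses_crossing_point_only(self):
        # 5-knot crooked path; the oracle is the two-point collar->crossing line
        pts = [(0, 0, 0), (0.01, 0, -0.02), (-0.01, 0.01, -0.04), (0.02, 0, -0.06), (0.03, 0.01, -0.08)]
        segs = []
        for i in range(len(pts) - 1):
            segs.append(
                seg(f"S{i+1}", None if i == 0 else f"S{i}", "A1", 1, pts[i], pts[i + 1], 0.004)
            )
        rs = system(*segs)
        a, flag = geo.taproot_angle(rs)
        # crossing of z = -0.07 between knots 4 and 5
        t = (-0.07 + 0.06) / (-0.08 + 0.06)
        p = np.array(pts[3]) + t * (np.array(pts[4]) - np.array(pts[3]))
        expected = math.degrees(math.atan2(p[2], math.hypot(p[0], p[1])))
        assert a == pytest.approx(expected)
        assert flag is None

    def test_shallow_taproot_flagged(self):
        rs = system(seg("S1", None, "A1", 1, (0, 0, 0), (0, 0, -0.05), 0.005))
        _a, flag = geo.taproot_angle(rs)
        assert flag == "taproot-shallower-than-deep-limit"


class TestAzimuthRddWinding:
    def test_azimuth_plus_x_is_zero(self):
        rs = system(seg("S1", None, "A1", 1, (0, 0, 0), (0.03, 0, 0), 0.001))
        a, flag = geo.axis_azimuth(rs.axes()["A1"])
        assert a == pytest.approx(0.0)

    def test_azimuth_minus_x_is_180(self):
        rs = system(seg("S1", None, "A1", 1, (0, 0, 0), (-0.03, 0, 0), 0.001))
        a, _ = geo.axis_azimuth(rs.axes()["A1"])
        assert a == pytest.approx(180.0)

    def test_azimuth_curved_matches_interpolation_oracle(self):
        # bend at 6 mm: the 1 cm point sits 4 mm into the second chord
        rs = system(
            seg("S1", None, "A1", 1, (0, 0, 0), (0.006, 0, 0), 0.001),
            seg("S2", "S1", "A1", 1, (0.006, 0, 0), (0.006, 0.008, 0), 0.001),
        )
        a, _ = geo.axis_azimuth(rs.axes()["A1"])
        expected = math.degrees(math.atan2(0.004, 0.006))
        assert a == pytest.approx(expected)

    def test_vertical_first_cm_flagged(self):
        rs = system(seg("S1", None, "A1", 1, (0, 0, 0), (0, 0, -0.03), 0.001))
        a, flag = geo.axis_azimuth(rs.axes()["A1"])
        assert a is None and flag == "undefined-azimuth-vertical"

    def test_straight_radial_root(self):
        rs = system(seg("S1", None, "A1", 1, (0, 0, 0), (0.05, 0, -0.002), 0.001))
        r, _ = geo.rdd(rs.axes()["A1"])
        assert r == pytest.approx(0.0, abs=1e-9)
        assert geo.winding(rs.axes()["A1"]) == pytest.approx(1.0)

    def test_rdd_folds_wraparound(self):
        # position azimuth 10 deg at the 10 mm point, 350 deg at the tip -> 20
        p10 = 0.010 * np.array([math.cos(math.radians(10)), math.sin(math.radians(10)), 0])
        tip = 0.050 * np.array([math.cos(math.radians(350)), math.sin(math.radians(350)), 0])
        rs = system(
            seg("S1", None, "A1", 1, (0, 0, 0), p10, 0.001),
            seg("S2", "S1", "A1", 1, p10, tip, 0.001),
        )
        r, _ = geo.rdd(rs.axes()["A1"])
        assert r == pytest.approx(20.0, abs=1e-9)

    def test_quarter_circle_winding(self):
        r = 0.05
        theta = np.linspace(0, math.pi / 2, 200)
        pts = np.c_[r * np.sin(theta), r * (1 - np.cos(theta)), np.zeros_like(theta)]
        segs = [
            seg(f"S{i+1:03d}", None if i == 0 else f"S{i:03d}", "A1", 1, pts[i], pts[i + 1], 0.001)
            for i in range(len(pts) - 1)
        ]
        rs = system(*segs)
        assert geo.winding(rs.axes()["A1"]) == pytest.approx(math.pi / (2 * math.sqrt(2)), abs=1e-3)


class TestBranchingAngle:
    @pytest.mark.parametrize(
        "v_child,v_mother,expected",
        [((0, 1, 0), (1, 0, 0), 90.0), ((1, 0, 0), (1, 0, 0), 0.0), ((1, 1, 0), (1, 0, 0), 45.0)],
    )
    def test_reference_angles(self, v_child, v_mother, expected):
        mother = seg("M", None, "A1", 1, (0, 0, 0), v_mother, 0.004)
        child = seg("C", "M", "A2", 2, v_mother, tuple(np.add(v_mother, v_child)), 0.001)
        assert geo.branching_angle([child], mother) == pytest.approx(expected)


class TestRotationInvariance:
    def test_angles_invariant_under_z_rotation(self):
        rs = syn.generate(syn.GeneratorConfig(seed=17, n_laterals=8))
        rot = syn.generate(syn.GeneratorConfig(seed=17, n_laterals=8))
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])  # +90 deg
        for s in rot.segments.values():
            s.base_xyz = R @ s.base_xyz
            s.tip_xyz = R @ s.tip_xyz
        a0, _ = geo.taproot_angle(rs)
        a1, _ = geo.taproot_angle(rot)
        assert a1 == pytest.approx(a0, abs=1e-9)
        for aid in rs.axes():
            g0 = geo.axis_geometry(rs, aid)
            g1 = geo.axis_geometry(rot, aid)
            assert g1.winding == pytest.approx(g0.winding, rel=1e-9)
            assert g1.angle_to_surface_deg == pytest.approx(g0.angle_to_surface_deg, abs=1e-9)
            if g0.azimuth_deg is not None:
                assert g1.azimuth_deg == pytest.approx((g0.azimuth_deg + 90.0) % 360.0, abs=1e-6)
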