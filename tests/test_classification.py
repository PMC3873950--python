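"""Compartment labeling, stump split, sectors and reinforcement."""
import numpy as np
import pytest

from rootarch import compartments as comp
from rootarch import geometry as geo
from rootarch import synthetic as syn

from conftest import seg, system


class TestSplitStump:
    def test_straddling_segment_split(self):
        rs = system(
            seg("S1", None, "A1", 1, (0, 0, 0), (0, 0, -0.030), 0.006),
            seg("S2", "S1", "A1", 1, (0, 0, -0.030), (0, 0, -0.060), 0.005),
        )
        stump, tap, flag = comp.split_stump(rs)
        assert flag is None
        assert stump == [("S1", 0.0, 1.0), ("S2", 0.0, pytest.approx(0.5))]
        assert tap == [("S2", pytest.approx(0.5), 1.0)]

    def test_short_order1_all_stump_flagged(self):
        rs = system(seg("S1", None, "A1", 1, (0, 0, 0), (0, 0, -0.040), 0.006))
        stump, tap, flag = comp.split_stump(rs)
        assert flag == "order1-shorter-than-stump"
        assert tap == [] and stump == [("S1", 0.0, 1.0)]

    def test_volume_conserved_across_split(self):
        rs = system(
            seg("S1", None, "A1", 1, (0, 0, 0), (0, 0, -0.030), 0.008),
            seg("S2", "S1", "A1", 1, (0, 0, -0.030), (0, 0, -0.090), 0.006),
            seg("S3", "S2", "A1", 1, (0, 0, -0.090), (0, 0, -0.100), 0.003),
        )
        total = sum(geo.segment_volume(rs, s) for s in rs.segments.values())
        stump_v = comp.stump_volume(rs)
        _, tap, _ = comp.split_stump(rs)
        tap_v = sum(
            comp._piece_volume(rs, rs.segments[sid], f0, f1, "frustum")
            for sid, f0, f1 in tap
        )
        assert stump_v + tap_v == pytest.approx(total, rel=1e-12)


class TestClassRules:
    @pytest.mark.parametrize(
        "depth_mm,expected",
        [(-20, "shallow"), (-35, "intermediate"), (-50, "intermediate"), (-70, "deep"), (-80, "deep")],
    )
    def test_depth_classes(self, depth_mm, expected):
        assert comp.classify_depth(depth_mm * 1e-3) == expected

    @pytest.mark.parametrize(
        "angle,expected",
        [(-10, "horizontal"), (-30, "oblique"), (-45, "oblique"), (-60, "vertical"), (-75, "vertical")],
    )
    def test_direction_classes(self, angle, expected):
        assert comp.classify_direction(angle) == expected

    @pytest.mark.parametrize(
        "azimuth,expected",
        [(0, "us"), (44.9, "us"), (45, "pp"), (90, "pp"), (135, "ds"), (170, "ds"), (225, "pp"), (315, "us")],
    )
    def test_sector_bins(self, azimuth, expected):
        assert comp.sector_of_azimuth(azimuth) == expected


def _lateral_system(origin_z, angle_deg, length=0.08, extra_depth=None):
    """Taproot to -0.10 m with one lateral from the given origin depth/angle."""
    import math

    o = abs(origin_z)
    tip = (
        length * math.cos(math.radians(angle_deg)),
        0.0,
        origin_z + length * math.sin(math.radians(angle_deg)),
    )
    return system(
        seg("S1", None, "A1", 1, (0, 0, 0), (0, 0, origin_z), 0.008),
        seg("S2", "S1", "A1", 1, (0, 0, origin_z), (0, 0, -0.10), 0.005),
        seg("S3", "S1", "A2", 2, (0, 0, origin_z), tip, 0.0015),
    )


class TestCompartments:
    def test_shallow_horizontal_near_taproot_is_zrt(self):
        rs = _lateral_system(-0.020, -5.0)
        labeled = comp.classify_system(rs)
        lat = [v for v in labeled if v.axis_id == "A2"]
        near = [v for v in lat if v.rrd_m <= comp.ZRT_LIMIT_M]
        far = [v for v in lat if v.rrd_m > comp.ZRT_LIMIT_M]
        assert all(v.compartment == 3 for v in near)
        assert all(v.compartment == 4 for v in far)
        assert near and far

    def test_deep_origin_is_deep(self):
        rs = _lateral_system(-0.080, -5.0)
        labeled = comp.classify_system(rs)
        assert all(v.compartment == 6 for v in labeled if v.axis_id == "A2")

    def test_oblique_pooled_to_intermediate(self):
        rs = _lateral_system(-0.020, -45.0)
        labeled = comp.classify_system(rs)
        lat = [v for v in labeled if v.axis_id == "A2"]
        assert all(v.compartment == 8 for v in lat)
        assert all(v.pooled == "intermediate" for v in lat)

    def test_vertical_shallow_lateral_is_sinker_pooled_to_taproot(self):
        rs = _lateral_system(-0.020, -80.0)
        labeled = comp.classify_system(rs)
        lat = [v for v in labeled if v.axis_id == "A2"]
        assert all(v.compartment == 5 for v in lat)
        assert all(v.pooled == "taproot" for v in lat)

    def test_partition_of_volume(self):
        rs = syn.generate(syn.GeneratorConfig(seed=21))
        labeled = comp.classify_system(rs)
        total = sum(geo.segment_volume(rs, s) for s in rs.segments.values())
        by_pool = {}
        for v in labeled:
            by_pool[v.pooled] = by_pool.get(v.pooled, 0.0) + v.volume_m3
        assert sum(by_pool.values()) == pytest.approx(total, rel=1e-9)
        # stump excluded, the five non-stump pools partition the remainder
        non_stump = sum(v for k, v in by_pool.items() if k != "stump")
        assert non_stump == pytest.approx(total - comp.stump_volume(rs), rel=1e-9)

    def test_every_generated_axis_classifiable(self):
        for s in (1, 5, 12):
            rs = syn.generate(syn.GeneratorConfig(seed=s))
            labeled = comp.classify_system(rs)
            assert all(v.compartment in comp.COMPARTMENT_NAMES for v in labeled)


class TestRelativeRadialDistanceAndSector:
    def test_distance_and_sector_about_bearing_point(self):
        rs = _lateral_system(-0.020, 0.0, length=0.03)
        labeled = comp.classify_system(rs)
        lat = sorted((v for v in labeled if v.axis_id == "A2"), key=lambda v: v.s0_m)
        # midpoint of first 10 mm slice: 5 mm along +X from the bearing point
        assert lat[0].rrd_m == pytest.approx(0.005, abs=1e-9)
        assert lat[0].sector == "us"
        assert lat[-1].rrd_m == pytest.approx(0.025, abs=1e-9)

    @pytest.mark.parametrize("azimuth,expected", [(90.0, "pp"), (170.0, "ds")])
    def test_sector_from_azimuth(self, azimuth, expected):
        import math

        a = math.radians(azimuth)
        tip = (0.03 * math.cos(a), 0.03 * math.sin(a), -0.020)
        rs = system(
            seg("S1", None, "A1", 1, (0, 0, 0), (0, 0, -0.020), 0.008),
            seg("S2", "S1", "A1", 1, (0, 0, -0.020), (0, 0, -0.10), 0.005),
            seg("S3", "S1", "A2", 2, (0, 0, -0.020), tip, 0.0015),
        )
        labeled = comp.classify_system(rs)
        assert all(v.sector == expected for v in labeled if v.axis_id == "A2")


class TestSectorShares:
    def test_even_eight_laterals(self):
        rs = syn.generate(syn.even_lateral_config(8, seed=0))
        labeled = comp.classify_system(rs)
        for qty in ("volume", "length"):
            shares = comp.sector_shares(labeled, quantity=qty)
            assert shares["us"] == pytest.approx(25.0, abs=1e-9)
            assert shares["pp"] == pytest.approx(50.0, abs=1e-9)
            assert shares["ds"] == pytest.approx(25.0, abs=1e-9)
        assert comp.reinforcement(25.0) == pytest.approx(0.0)

    def test_single_upslope_lateral_reinforcement(self):
        rs = _lateral_system(-0.020, -5.0, length=0.04)
        labeled = comp.classify_system(rs)
        shares = comp.sector_shares(labeled, quantity="volume")
        assert shares["us"] == pytest.approx(100.0)
        assert comp.reinforcement(shares["us"]) == pytest.approx(300.0)

    def test_shares_match_bruteforce_sum(self):
        rs = syn.generate(syn.GeneratorConfig(seed=33))
        labeled = comp.classify_system(rs)
        shares = comp.sector_shares(labeled, quantity="volume")
        brute = {"us": 0.0, "pp": 0.0, "ds": 0.0}
        for v in labeled:
            if v.sector is not None:
                brute[v.sector] += v.volume_m3
        tot = sum(brute.values())
        for s in brute:
            assert shares[s] == pytest.approx(100.0 * brute[s] / tot, rel=1e-12)
        assert sum(shares.values()) == pytest.approx(100.0)

    def test_empty_compartment_is_missing_not_zero(self):
        rs = _lateral_system(-0.020, -5.0)
        labeled = comp.classify_system(rs)
        assert comp.sector_shares(labeled, compartment="deep") is None

    def test_rotation_permutes_sectors(self):
        rs = syn.generate(syn.GeneratorConfig(seed=8, n_laterals=10))
        rot = syn.generate(syn.GeneratorConfig(seed=8, n_laterals=10))
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        for s in rot.segments.values():
            s.base_xyz = R @ s.base_xyz
            s.tip_xyz = R @ s.tip_xyz
        sh0 = comp.sector_shares(comp.classify_system(rs), quantity="volume")
        sh1 = comp.sector_shares(comp.classify_system(rot), quantity="volume")
        # a +90 deg rotation sends us into pp and ds into pp, while pp splits
        # into us and ds; totals must agree on the us+ds <-> pp exchange
        assert sh1["pp"] + sh1["us"] + sh1["ds"] == pytest.approx(100.0)
        assert sh0["us"] + sh0["ds"] == pytest.approx(sh1["pp"], abs=1e-6)


class TestSectorTable:
    def test_shares_sum_to_100_where_present(self):
        rs = syn.generate(syn.GeneratorConfig(seed=4))
        st = comp.sector_table(rs)
        for cname, sub in st.groupby("compartment"):
            tot = sub["volume_cm3"].sum()
            if tot > 0:
                assert sub["volume_cm3"].sum() / tot == pytest.approx(1.0)
        all_rows = st[st["compartment"] == "all"]
        assert len(all_rows) == 3
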