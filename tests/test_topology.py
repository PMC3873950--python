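"""Topological index qb, mean branching order and fractal parameters."""
import math

import numpy as np
import pytest

from rootarch import synthetic as syn
from rootarch import topology as topo
from rootarch.topology import BranchEvent

from conftest import seg, system


# ---------------------------------------------------------------- oracle
def enumerate_leaf_depths(n: int):
    """All ordered binary-tree leaf-depth lists with n exterior links."""
    if n == 1:
        return [(0,)]
    out = []
    for k in range(1, n):
        for l in enumerate_leaf_depths(k):
            for r in enumerate_leaf_depths(n - k):
                out.append(tuple(d + 1 for d in l) + tuple(d + 1 for d in r))
    return out


class TestQb:
    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_matches_exhaustive_enumeration(self, n):
        """qb normalization agrees with brute-force Pe extremes for all shapes."""
        shapes = enumerate_leaf_depths(n)
        pes = [sum(d) for d in shapes]
        assert min(pes) == topo.pe_min(n)
        assert max(pes) == topo.pe_max(n)
        for d, pe in zip(shapes, pes):
            expected = (pe - min(pes)) / (max(pes) - min(pes))
            assert topo.qb_from_depths(d) == pytest.approx(expected)
            assert 0.0 <= topo.qb_from_depths(d) <= 1.0

    def test_herringbone_scores_one(self):
        rs = syn.generate(
            syn.even_lateral_config(1, seed=0, tips_per_lateral=8, herringbone_weight=1.0)
        )
        arbo = [a for a in rs.axes() if a != rs.axis_of_root()]
        root2 = min(arbo)  # the order-2 axis heads the arborescence
        assert topo.qb(rs, scope_axis_id=root2) == pytest.approx(1.0)

    def test_balanced_scores_zero(self):
        rs = syn.generate(
            syn.even_lateral_config(1, seed=0, tips_per_lateral=8, herringbone_weight=0.0)
        )
        root2 = min(a for a in rs.axes() if a != rs.axis_of_root())
        assert topo.qb(rs, scope_axis_id=root2) == pytest.approx(0.0)

    def test_herringbonization_is_monotone(self):
        """Moving tips from balanced positions to the main chain never lowers qb."""
        n = 8
        rng = np.random.default_rng(0)

        def depths(k_chain):
            # k_chain leaves hang directly off the spine; the rest form a
            # balanced subtree attached at the end of the chain
            chain = list(range(1, k_chain + 1))
            m = n - k_chain
            bal = [d + k_chain for d in _balanced_depths(m)]
            return chain + bal

        def _balanced_depths(m):
            if m == 1:
                return [0]
            lo = m // 2
            return [d + 1 for d in _balanced_depths(lo)] + [
                d + 1 for d in _balanced_depths(m - lo)
            ]

        vals = [topo.qb_from_depths(depths(k)) for k in range(0, n - 1)]
        assert vals[0] == pytest.approx(0.0)
        assert vals[-1] == pytest.approx(1.0)
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_too_few_tips_is_missing(self):
        rs = syn.generate(syn.even_lateral_config(1, seed=0, tips_per_lateral=1))
        root2 = min(a for a in rs.axes() if a != rs.axis_of_root())
        assert math.isnan(topo.qb(rs, scope_axis_id=root2))


class TestMbo:
    def _axes_system(self, n2, n3, fine_on_axis=None, fine_count=0):
        segs = [seg("T1", None, "A1", 1, (0, 0, 0), (0, 0, -0.10), 0.006)]
        k = 0
        for i in range(n2):
            k += 1
            segs.append(
                seg(f"L{k}", "T1", f"B{k}", 2, (0, 0, -0.10), (0.03 + 0.001 * k, 0, -0.10), 0.002)
            )
        host = [s for s in segs if s.order == 2][0]
        for i in range(n3):
            k += 1
            segs.append(
                seg(
                    f"L{k}", host.segment_id, f"B{k}", 3,
                    tuple(host.tip_xyz), (float(host.tip_xyz[0]) + 0.01, 0.01 * (i + 1), -0.10), 0.001,
                )
            )
        rs = system(*segs)
        if fine_on_axis is not None:
            rs.segments[fine_on_axis].fine_root_count = fine_count
            rs.segments[fine_on_axis].fine_root_mean_length_m = 0.01
        return rs

    def test_only_second_order_gives_one(self):
        rs = self._axes_system(5, 0)
        assert topo.mbo(rs) == pytest.approx(1.0)

    def test_weighted_mean(self):
        rs = self._axes_system(7, 3)
        assert topo.mbo(rs) == pytest.approx((7 * 1 + 3 * 2) / 10)

    def test_fine_roots_raise_mbo(self):
        # 5 fine roots on a 2nd-order axis count as order-3 contributions
        rs = self._axes_system(5, 0, fine_on_axis="L1", fine_count=5)
        expected = (5 * 1 + 5 * 2) / 10
        assert topo.mbo(rs, include_fine_roots=True) == pytest.approx(expected)

    def test_empty_scope_missing(self):
        rs = system(seg("T1", None, "A1", 1, (0, 0, 0), (0, 0, -0.05), 0.005))
        assert math.isnan(topo.mbo(rs))


class TestFractalParams:
    def test_event_arithmetic(self):
        e = BranchEvent("A1", 0.05, "laterals", 2.0, [1.0, 0.5], True)
        assert e.p_branch == pytest.approx(4.0 / 3.0)
        assert e.q == pytest.approx(1.0 / 1.5)

    def test_equal_daughters_q_half(self):
        e = BranchEvent("A1", 0.05, "laterals", 2.0, [1.0, 1.0], False)
        assert e.q == pytest.approx(0.5)

    def test_single_daughter_q_one_and_conservation_p_one(self):
        e = BranchEvent("A1", 0.05, "laterals", 1.0, [1.0], False)
        assert e.q == pytest.approx(1.0)
        assert e.p_branch == pytest.approx(1.0)

    def _tapered_axis_with_branch(self):
        # axis knots: 0 cm 4 mm, 4 cm 3 mm, 7 cm 2 mm, tip 9 cm; branch at 4 cm
        return system(
            seg("S1", None, "A1", 1, (0, 0, 0), (0, 0, -0.04), 0.004),
            seg("S2", "S1", "A1", 1, (0, 0, -0.04), (0, 0, -0.07), 0.003),
            seg("S3", "S2", "A1", 1, (0, 0, -0.07), (0, 0, -0.09), 0.002),
            seg("B1", "S1", "A2", 2, (0, 0, -0.04), (0.03, 0, -0.04), 0.001),
        )

    def test_continuing_csa_interpolated_2cm_after_branch(self):
        rs = self._tapered_axis_with_branch()
        events, qc = topo.branch_events(rs)
        assert qc["skipped_zero_csa"] == 0
        (e,) = events
        assert e.csa_before_m2 == pytest.approx(math.pi / 4 * 0.004**2)
        # continuing segment is 3 cm > 2 cm: d at 6 cm = 3 + (2-3)*(2/3) mm
        d6 = 0.003 + (0.002 - 0.003) * (2.0 / 3.0)
        assert e.csa_after_m2[0] == pytest.approx(math.pi / 4 * d6**2)
        assert e.csa_after_m2[1] == pytest.approx(math.pi / 4 * 0.001**2)

    def test_scope_means_equal_direct_recomputation(self):
        rs = syn.generate(syn.GeneratorConfig(seed=6))
        res = topo.fractal_params(rs)
        events = res["events"]
        for sc in ("stump", "taproot", "laterals"):
            ev = [e for e in events if e.scope == sc]
            if ev:
                assert res[f"p_branch_{sc}"] == pytest.approx(
                    float(np.mean([e.p_branch for e in ev]))
                )
                assert res[f"q_{sc}"] == pytest.approx(float(np.mean([e.q for e in ev])))

    def test_generator_hits_p_branch_target_on_lateral_events(self):
        cfg = syn.GeneratorConfig(
            seed=2, n_laterals=10, extra_tips_mean=2.0, dir_jitter_deg=0.0,
            lateral_taper_pct_per_cm=0.5, fine_root_rate_per_cm=0.0,
        )
        rs = syn.generate(cfg)
        res = topo.fractal_params(rs)
        assert res["p_branch_laterals"] == pytest.approx(cfg.p_branch_target, rel=0.15)
        assert res["q_laterals"] == pytest.approx(cfg.q_target, rel=0.15)


class TestBranchingIntervals:
    def _axis_with_branches(self, at_cm, axis_len_cm=10.0, fine=None):
        segs = [seg("S1", None, "A1", 1, (0, 0, 0), (0, 0, -axis_len_cm / 100), 0.005)]
        verts = sorted(at_cm)
        # split the taproot at each branch position
        segs = []
        prev = 0.0
        pid = None
        for i, c in enumerate(verts + [axis_len_cm]):
            sid = f"S{i+1}"
            segs.append(
                seg(sid, pid, "A1", 1, (0, 0, -prev / 100), (0, 0, -c / 100), 0.005)
            )
            pid = sid
            prev = c
        for i, c in enumerate(verts):
            segs.append(
                seg(
                    f"B{i+1}", f"S{i+1}", f"X{i+1}", 2,
                    (0, 0, -c / 100), (0.02, 0, -c / 100), 0.001,
                )
            )
        rs = system(*segs)
        if fine:
            sid, count = fine
            rs.segments[sid].fine_root_count = count
            rs.segments[sid].fine_root_mean_length_m = 0.01
        return rs

    def test_mean_gap(self):
        rs = self._axis_with_branches([1.0, 2.0, 4.0])
        assert topo.inter_lateral_length(rs, "A1") == pytest.approx(0.015)

    def test_apical_unbranched(self):
        rs = self._axis_with_branches([1.0, 2.0, 4.0], axis_len_cm=10.0)
        assert topo.apical_unbranched_length(rs, "A1") == pytest.approx(0.06)

    def test_single_branch_gap_missing(self):
        rs = self._axis_with_branches([3.0])
        assert topo.inter_lateral_length(rs, "A1") is None

    def test_fine_roots_merge_into_position_sorted_list(self):
        # branches at 1 and 4 cm plus 1 fine root centred on the 1-4 cm segment
        rs = self._axis_with_branches([1.0, 4.0], fine=("S2", 1))
        # merged positions: 1.0, 2.5 (fine root mid-segment), 4.0 -> mean 1.5 cm
        got = topo.inter_lateral_length(rs, "A1", include_fine_roots=True)
        assert got == pytest.approx(0.015)


class TestCountsAndSpecifics:
    def test_srl_arithmetic(self):
        # one 10 cm lateral of 2 cm3 -> SRL 5 cm/cm3 (taproot volume removed)
        d = 2 * math.sqrt(2e-6 / (math.pi * 0.10))
        rs = system(
            seg("S1", None, "A1", 1, (0, 0, 0), (0, 0, -0.040), 0.0),
            seg("S2", "S1", "A2", 2, (0, 0, -0.040), (0.10, 0, -0.040), d),
        )
        res = topo.counts_and_specifics(rs)
        lat_len = 0.10  # mother radius 0 (taproot diameter 0)
        assert res["total_volume_m3"] == pytest.approx(2e-6, rel=1e-9)
        srl = (res["total_length_m"] * 100) / (res["total_volume_m3"] * 1e6)
        assert srl == pytest.approx((0.04 + lat_len) * 100 / 2.0, rel=1e-9)

    def test_fine_root_counts(self):
        rs = syn.generate(syn.GeneratorConfig(seed=10))
        res = topo.counts_and_specifics(rs)
        n_fine = rs.total_fine_root_count()
        assert res["root_number_iafr"] == res["root_number"] + n_fine

    def test_density_recovers_generator_tissue_density(self):
        cfg = syn.GeneratorConfig(seed=14, dry_weight_density_g_cm3=0.528)
        rs = syn.generate(cfg)
        res = topo.counts_and_specifics(rs)
        assert res["root_density_g_per_cm3"] == pytest.approx(0.528, rel=1e-9)
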