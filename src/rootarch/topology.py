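"""Topological indices and fractal branching parameters.

``qb`` places a branching topology between a wholly dichotomous pattern
(qb = 0) and a wholly herringbone pattern (qb = 1).  It normalizes the
sum of topological path lengths from the collar to the exterior links,
Pe, between the minimum (most balanced binary tree) and maximum
(herringbone chain) attainable for the same number of exterior links:

    qb = (Pe - Pe_min(n)) / (Pe_max(n) - Pe_min(n))

Multifurcations are resolved to binary by serial splitting (zero-length
internal links), which leaves Pe well defined.  Path lengths are counted
in links of the binary-resolved tree; any constant offset cancels in the
normalization.

The fractal branching parameters describe cross-sectional area (CSA)
scaling at and between branch points: ``p_branch`` = CSA before the
branch over the summed CSA after it (> 1 under tapering, 1 under CSA
conservation), ``q`` = the largest post-branch segment's share of the
summed post-branch CSA (0.5 for an equal dichotomy, near 1 for
herringbone), and ``p_within`` = % CSA decrease per cm between
consecutive branch points on an axis.  Because the diameter on the main
axis was digitized just before a branch but not directly after, the
continuing CSA is taken 2 cm after the branch point (by linear
interpolation) whenever the continuing segment is longer than 2 cm.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import RootSystem
from .compartments import STUMP_LENGTH_M, arborescence_info, split_stump
from .geometry import (
    axis_geometry,
    axis_length,
    axis_volume,
    diameter_at,
    polyline,
    segment_volume,
)

__all__ = [
    "pe_min",
    "pe_max",
    "qb_from_depths",
    "leaf_depths",
    "qb",
    "mbo",
    "BranchEvent",
    "branch_events",
    "fractal_params",
    "inter_lateral_length",
    "apical_unbranched_length",
    "counts_and_specifics",
]


# ------------------------------------------------------------------- qb
def pe_min(n: int) -> int:
    """Minimum external path length of a binary tree with n leaves."""
    d = int(math.floor(math.log2(n)))
    return n * d + 2 * (n - 2**d)


def pe_max(n: int) -> int:
    """External path length of the herringbone (caterpillar) tree."""
    return (n - 1) * (n + 2) // 2


def qb_from_depths(depths: Sequence[int]) -> float:
    """qb from the leaf depths of a binary-resolved topology.

    Undefined (NaN) below four exterior links: with two or three leaves
    there is a single binary shape, so the normalization degenerates.
    """
    n = len(depths)
    if n < 2:
        return float("nan")
    lo, hi = pe_min(n), pe_max(n)
    if hi == lo:
        return float("nan")
    return (sum(depths) - lo) / (hi - lo)


def _axis_events(
    rs: RootSystem,
    axes: dict,
    axis_id: str,
    include_fine_roots: bool,
    allowed: Optional[set],
):
    """Ordered (s, entries) along an axis; an entry is a child axis id or 'fr'."""
    segs = axes[axis_id]
    _, cum = polyline(segs)
    seg_index = {s.segment_id: i for i, s in enumerate(segs)}
    events: dict[float, list] = {}
    for other, osegs in axes.items():
        head = osegs[0]
        if other != axis_id and head.parent_id in seg_index:
            if allowed is not None and other not in allowed:
                continue
            s = float(cum[seg_index[head.parent_id] + 1])
            events.setdefault(s, []).append(("axis", other))
    if include_fine_roots:
        for i, seg in enumerate(segs):
            k = seg.fine_root_count
            for j in range(k):
                s = float(cum[i] + (j + 0.5) / k * seg.length_m)
                events.setdefault(s, []).append(("fr", f"{seg.segment_id}#fr{j}"))
    out = []
    for s in sorted(events):
        out.append((s, sorted(events[s], key=lambda e: e[1])))
    return out


def leaf_depths(
    rs: RootSystem,
    scope_axis_id: Optional[str] = None,
    include_fine_roots: bool = False,
    allowed_arborescences: Optional[set] = None,
) -> list[int]:
    """Leaf depths of the binary-resolved topology rooted at an axis.

    ``scope_axis_id`` defaults to the order-1 axis (whole system).  When
    ``allowed_arborescences`` restricts the scope to a subset of lateral
    arborescences, the order-1 axis serves only as the connecting spine:
    its own tip and fine roots are not exterior links of the scope.
    """
    axes = rs.axes()
    root_axis = rs.axis_of_root()
    if scope_axis_id is None:
        scope_axis_id = root_axis
    restricted = allowed_arborescences is not None

    allowed_axes: Optional[set] = None
    if restricted:
        infos = arborescence_info(rs)
        allowed_axes = {
            aid
            for aid, info in infos.items()
            if info.root_axis_id in allowed_arborescences
        }

    def recurse(axis_id: str, depth: int, spine_only: bool) -> list[int]:
        out: list[int] = []
        d = depth
        fr = include_fine_roots and not spine_only
        for _s, entries in _axis_events(rs, axes, axis_id, fr, allowed_axes):
            for kind, ident in entries:
                d += 1
                if kind == "fr":
                    out.append(d)
                else:
                    out.extend(recurse(ident, d, False))
        if not spine_only:
            out.append(d)  # the axis tip is an exterior link
        return out

    spine_only = restricted and scope_axis_id == root_axis
    return recurse(scope_axis_id, 0, spine_only)


def qb(
    rs: RootSystem,
    scope_axis_id: Optional[str] = None,
    include_fine_roots: bool = False,
    allowed_arborescences: Optional[set] = None,
) -> float:
    """Topological index qb for a whole system, arborescence or subset."""
    return qb_from_depths(
        leaf_depths(rs, scope_axis_id, include_fine_roots, allowed_arborescences)
    )


# ------------------------------------------------------------------ MBO
def mbo(
    rs: RootSystem,
    axis_ids: Optional[Iterable[str]] = None,
    include_fine_roots: bool = False,
) -> float:
    """Mean branching order: mean of (order - 1) over lateral axes.

    An axis bearing only second-order laterals scores exactly 1.  Fine
    roots count at order(bearing axis) + 1 with multiplicity.  NaN for an
    empty scope.
    """
    axes = rs.axes()
    root_axis = rs.axis_of_root()
    if axis_ids is None:
        axis_ids = [a for a in axes if a != root_axis]
    axis_ids = list(axis_ids)
    vals = [axes[a][0].order - 1 for a in axis_ids if a != root_axis]
    if include_fine_roots:
        in_scope = set(axis_ids) | {root_axis}
        for aid in in_scope:
            if aid not in axes:
                continue
            bearing_order = axes[aid][0].order
            k = sum(s.fine_root_count for s in axes[aid])
            vals.extend([bearing_order] * k)  # (order+1) - 1
    if not vals:
        return float("nan")
    return float(np.mean(vals))


# --------------------------------------------------------- branch events
@dataclass
class BranchEvent:
    """CSA bookkeeping at one branching point on a bearing axis."""

    axis_id: str
    s_m: float  # curvilinear position of the branch on the bearing axis
    scope: str  # stump | taproot | laterals
    csa_before_m2: float
    csa_after_m2: list[float]  # continuing segment first (if any), then daughters
    has_continuing: bool
    p_branch: float = field(init=False)
    q: float = field(init=False)

    def __post_init__(self):
        tot = sum(self.csa_after_m2)
        self.p_branch = self.csa_before_m2 / tot if tot > 0 else float("nan")
        self.q = max(self.csa_after_m2) / tot if tot > 0 else float("nan")


def _csa(d: float) -> float:
    return math.pi * d * d / 4.0


def branch_events(
    rs: RootSystem,
    interp_after_m: float = 0.020,
    stump_length_m: float = STUMP_LENGTH_M,
) -> tuple[list[BranchEvent], dict]:
    """All branch events with the 2 cm continuing-CSA interpolation rule.

    Returns the event list and a QC dict counting skipped events (zero
    CSA before the branch).
    """
    axes = rs.axes()
    root_axis = rs.axis_of_root()
    qc = {"skipped_zero_csa": 0}
    out: list[BranchEvent] = []
    for aid, segs in axes.items():
        _, cum = polyline(segs)
        seg_index = {s.segment_id: i for i, s in enumerate(segs)}
        groups: dict[int, list] = {}
        for other, osegs in axes.items():
            head = osegs[0]
            if other != aid and head.parent_id in seg_index:
                groups.setdefault(seg_index[head.parent_id], []).append(osegs[0])
        for i in sorted(groups):
            s = float(cum[i + 1])
            csa_before = _csa(segs[i].diameter_m)
            if csa_before <= 0:
                qc["skipped_zero_csa"] += 1
                continue
            after: list[float] = []
            has_cont = i + 1 < len(segs)
            if has_cont:
                cont = segs[i + 1]
                if cont.length_m > interp_after_m:
                    d_cont = diameter_at(rs, segs, s + interp_after_m)
                else:
                    d_cont = cont.diameter_m
                after.append(_csa(d_cont))
            after.extend(_csa(h.diameter_m) for h in sorted(groups[i], key=lambda x: x.segment_id))
            if aid == root_axis:
                scope = "stump" if s <= stump_length_m else "taproot"
            else:
                scope = "laterals"
            out.append(
                BranchEvent(
                    axis_id=aid,
                    s_m=s,
                    scope=scope,
                    csa_before_m2=csa_before,
                    csa_after_m2=after,
                    has_continuing=has_cont,
                )
            )
    return out, qc


def fractal_params(rs: RootSystem, interp_after_m: float = 0.020) -> dict:
    """Per-scope means of p_branch, p_within and q.

    Scopes are stump, taproot and laterals.  ``p_within`` is the % CSA
    decrease per cm between consecutive branch points on an axis,
    measured from the continuing CSA just after one branch to the CSA
    just before the next.  Missing scopes yield NaN.
    """
    events, qc = branch_events(rs, interp_after_m)
    scopes = ("stump", "taproot", "laterals")
    res = {"qc": qc, "events": events}
    for sc in scopes:
        ev = [e for e in events if e.scope == sc]
        res[f"p_branch_{sc}"] = float(np.mean([e.p_branch for e in ev])) if ev else float("nan")
        res[f"q_{sc}"] = float(np.mean([e.q for e in ev])) if ev else float("nan")
    # p_within per axis between consecutive events
    within = {sc: [] for sc in scopes}
    by_axis: dict[str, list[BranchEvent]] = {}
    for e in events:
        by_axis.setdefault(e.axis_id, []).append(e)
    for aid, evs in by_axis.items():
        evs.sort(key=lambda e: e.s_m)
        for e1, e2 in zip(evs[:-1], evs[1:]):
            if not e1.has_continuing:
                continue
            csa_start = e1.csa_after_m2[0]
            csa_end = e2.csa_before_m2
            gap_cm = (e2.s_m - e1.s_m) * 100.0
            if csa_start <= 0 or gap_cm <= 0:
                continue
            within[e2.scope].append(100.0 * (csa_start - csa_end) / csa_start / gap_cm)
    for sc in scopes:
        res[f"p_within_{sc}"] = float(np.mean(within[sc])) if within[sc] else float("nan")
    return res


# -------------------------------------------------- branching intervals
def _branch_positions(
    rs: RootSystem, axis_id: str, include_fine_roots: bool
) -> list[float]:
    axes = rs.axes()
    return [
        s
        for s, entries in _axis_events(rs, axes, axis_id, include_fine_roots, None)
        for _ in entries
    ]


def inter_lateral_length(
    rs: RootSystem, axis_id: str, include_fine_roots: bool = False
) -> Optional[float]:
    """Mean curvilinear gap (m) between successive branch points on an axis.

    Unmeasured fine roots, when included, are placed at even quantiles
    along their bearing segment.  None with fewer than two laterals.
    """
    pos = sorted(set(_branch_positions(rs, axis_id, include_fine_roots)))
    if len(pos) < 2:
        return None
    return float(np.mean(np.diff(pos)))


def apical_unbranched_length(rs: RootSystem, axis_id: str) -> Optional[float]:
    """Curvilinear distance (m) from the last branch point to the apex."""
    segs = rs.axes()[axis_id]
    _, cum = polyline(segs)
    pos = _branch_positions(rs, axis_id, include_fine_roots=False)
    if not pos:
        return None
    return float(cum[-1] - max(pos))


# ------------------------------------------------------ counts & ratios
def counts_and_specifics(rs: RootSystem, solid: str = "frustum") -> dict:
    """Whole-system counts, lengths, volumes and the derived specific traits.

    The stump is excluded from the total root volume (it is the passive
    bole, not an anchoring element); mass-based traits are missing when
    dry weights are absent, and zero-volume denominators yield missing
    values rather than zeros.
    """
    from .compartments import stump_volume as _stump_volume

    axes = rs.axes()
    root_axis = rs.axis_of_root()
    lateral_axes = [a for a in axes if a != root_axis]
    n_axes = len(lateral_axes)
    n_fine = rs.total_fine_root_count()
    fine_length = sum(
        s.fine_root_count * s.fine_root_mean_length_m for s in rs.segments.values()
    )
    length = sum(
        axis_length(axes[a], rs.axis_parent_segment(a)) for a in axes
    )
    vol_total = sum(segment_volume(rs, s, solid) for s in rs.segments.values())
    v_stump = _stump_volume(rs, solid=solid)
    vol = vol_total - v_stump  # study convention: stump excluded
    res = {
        "root_number": n_axes,
        "root_number_iafr": n_axes + n_fine,
        "total_length_m": length,
        "total_length_iafr_m": length + fine_length,
        "total_volume_m3": vol,
        "total_volume_incl_stump_m3": vol_total,
        "stump_volume_m3": v_stump,
    }
    vol_cm3 = vol * 1e6
    res["srl_cm_per_cm3"] = (length * 100.0) / vol_cm3 if vol_cm3 > 0 else float("nan")
    rdw, sdw = rs.root_dry_weight_g, rs.shoot_dry_weight_g
    res["root_density_g_per_cm3"] = (
        rdw / vol_cm3 if (rdw is not None and vol_cm3 > 0) else float("nan")
    )
    res["srn_per_g"] = rdw and (n_axes + n_fine) / rdw if rdw else float("nan")
    if rdw is not None and sdw is not None and (rdw + sdw) > 0:
        rpc = 100.0 * rdw / (rdw + sdw)
        res["rpc_biomass_pct"] = rpc
        o1_vol = axis_volume(rs, axes[root_axis], solid)
        res["rpc_excl_order1_pct"] = rpc * max(vol_total - o1_vol, 0.0) / vol_total if vol_total > 0 else float("nan")
        res["taproot_pc_pct"] = rpc * (o1_vol - v_stump) / vol_total if vol_total > 0 else float("nan")
        res["stump_pc_pct"] = rpc * v_stump / vol_total if vol_total > 0 else float("nan")
    else:
        res["rpc_biomass_pct"] = float("nan")
        res["rpc_excl_order1_pct"] = float("nan")
        res["taproot_pc_pct"] = float("nan")
        res["stump_pc_pct"] = float("nan")
    return res
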