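"""Architectural compartments and slope-oriented circular sectors.

Every virtual segment is assigned to one of eight compartments:

1. stump (first 45 mm of the order-1 path), 2. taproot (rest of order 1),
3. zone of rapid taper (ZRT: proximal part of shallow horizontal
laterals), 4. horizontal shallow roots beyond the ZRT, 5. sinkers
(near-vertical laterals from shallow origins), 6. deep roots, 7.
intermediate-depth roots, 8. oblique roots.  Sinkers and obliques are
rare and are pooled into the taproot and intermediate compartments for
the six-class tables.

Lateral arborescences are classified by their origin: the depth of the
initial branching point on the order-1 root (shallow above -35 mm,
intermediate to -70 mm, deep below) combined with the direction class of
the second-order axis (horizontal within 30 deg of the soil surface,
oblique to 60 deg, vertical beyond).  Boundaries are assigned to the
deeper / steeper class.  The ZRT / beyond-ZRT split is spatial, by the
relative radial distance of each virtual segment from the bearing point
on the order-1 root (default limit 50 mm; the study never printed this
value, so it is configurable and documented).

Sectors: upslope ``us`` = azimuth in [315, 45), downslope ``ds`` =
[135, 225), and ``pp`` the two remaining perpendicular quadrants.  The
stump and taproot are the centre of the system and carry no sector.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import Frame, RootSegment, RootSystem
from .geometry import (
    VirtualSegment,
    axis_angle_to_surface,
    axis_azimuth,
    axis_length,
    axis_volume,
    branching_angle,
    diameter_at,
    frustum_volume,
    mean_diameter,
    point_at,
    polyline,
    segment_end_diameter,
    virtualize,
)

__all__ = [
    "COMPARTMENT_NAMES",
    "POOLED",
    "ArborescenceInfo",
    "split_stump",
    "stump_volume",
    "classify_depth",
    "classify_direction",
    "sector_of_azimuth",
    "arborescence_info",
    "axis_compartment",
    "classify_system",
    "sector_shares",
    "reinforcement",
    "sector_table",
]

STUMP_LENGTH_M = 0.045
DEPTH_SHALLOW_M = -0.035
DEPTH_DEEP_M = -0.070
ANGLE_HORIZONTAL_DEG = 30.0
ANGLE_VERTICAL_DEG = 60.0
ZRT_LIMIT_M = 0.050

COMPARTMENT_NAMES = {
    1: "stump",
    2: "taproot",
    3: "zrt",
    4: "shallow_beyond_zrt",
    5: "sinker",
    6: "deep",
    7: "intermediate",
    8: "oblique",
}

#: pooling for the six-class tables: sinkers join the taproot, obliques
#: join the intermediate-depth roots
POOLED = {
    1: "stump",
    2: "taproot",
    3: "zrt",
    4: "shallow_beyond_zrt",
    5: "taproot",
    6: "deep",
    7: "intermediate",
    8: "intermediate",
}

SECTORS = ("us", "pp", "ds")


def classify_depth(depth_m: float) -> str:
    """shallow / intermediate / deep with boundaries assigned downward."""
    if depth_m > DEPTH_SHALLOW_M:
        return "shallow"
    if depth_m > DEPTH_DEEP_M:
        return "intermediate"
    return "deep"


def classify_direction(angle_to_surface_deg: float) -> str:
    """horizontal / oblique / vertical with boundaries assigned steeper."""
    a = abs(angle_to_surface_deg)
    if a < ANGLE_HORIZONTAL_DEG:
        return "horizontal"
    if a < ANGLE_VERTICAL_DEG:
        return "oblique"
    return "vertical"


def sector_of_azimuth(azimuth_deg: float) -> str:
    """us = 0 +/- 45 deg, ds = 180 +/- 45 deg, pp = the rest (half-open bins)."""
    a = azimuth_deg % 360.0
    if a >= 315.0 or a < 45.0:
        return "us"
    if 135.0 <= a < 225.0:
        return "ds"
    return "pp"


# ------------------------------------------------------------ stump split
def split_stump(rs: RootSystem, stump_length_m: float = STUMP_LENGTH_M):
    """Cut the order-1 path at 45 mm curvilinear length.

    Returns ``(stump_pieces, taproot_pieces, flag)`` where pieces are
    ``(segment_id, f0, f1)`` fraction ranges of each order-1 segment; a
    segment straddling the limit is split into two virtual parts.  An
    order-1 path shorter than the stump length is all stump and flagged.
    """
    segs = rs.axes()[rs.axis_of_root()]
    _, cum = polyline(segs)
    stump, tap = [], []
    flag = None
    if cum[-1] <= stump_length_m:
        stump = [(s.segment_id, 0.0, 1.0) for s in segs]
        flag = "order1-shorter-than-stump"
        return stump, tap, flag
    for i, seg in enumerate(segs):
        a, b = cum[i], cum[i + 1]
        if b <= stump_length_m:
            stump.append((seg.segment_id, 0.0, 1.0))
        elif a >= stump_length_m:
            tap.append((seg.segment_id, 0.0, 1.0))
        else:
            f = (stump_length_m - a) / (b - a)
            stump.append((seg.segment_id, 0.0, f))
            tap.append((seg.segment_id, f, 1.0))
    return stump, tap, flag


def _piece_volume(rs: RootSystem, seg: RootSegment, f0: float, f1: float, solid: str) -> float:
    d_base = seg.diameter_m
    d_tip = segment_end_diameter(rs, seg, solid)
    da = d_base + (d_tip - d_base) * f0
    db = d_base + (d_tip - d_base) * f1
    return frustum_volume(da, db, seg.length_m * (f1 - f0))


def stump_volume(rs: RootSystem, stump_length_m: float = STUMP_LENGTH_M, solid: str = "frustum") -> float:
    """Volume of the stump pieces (exact partial-frustum integral)."""
    stump, _, _ = split_stump(rs, stump_length_m)
    segs = rs.segments
    return sum(_piece_volume(rs, segs[sid], f0, f1, solid) for sid, f0, f1 in stump)


# ------------------------------------------------- arborescence structure
@dataclass
class ArborescenceInfo:
    """Origin-based classification shared by a whole lateral arborescence."""

    root_axis_id: str  # the order-2 axis
    bearing_point: np.ndarray  # its base on the order-1 root
    origin_s_on_order1_m: float
    origin_depth_m: float
    depth_class: str
    direction_class: str
    on_stump: bool
    compartment: int  # 3 means "shallow horizontal" (ZRT split is spatial)


def arborescence_info(rs: RootSystem, stump_length_m: float = STUMP_LENGTH_M) -> dict[str, ArborescenceInfo]:
    """Map every lateral axis id to its arborescence's origin record."""
    axes = rs.axes()
    root_axis = rs.axis_of_root()
    o1_segs = axes[root_axis]
    o1_ids = {s.segment_id: i for i, s in enumerate(o1_segs)}
    _, o1_cum = polyline(o1_segs)

    # order-2 axes: those whose head parent lies on the order-1 axis
    infos: dict[str, ArborescenceInfo] = {}
    arbo_root: dict[str, str] = {}

    def assign(axis_id: str, root2: str):
        arbo_root[axis_id] = root2
        head_ids = {s.segment_id for s in axes[axis_id]}
        for other, osegs in axes.items():
            if other not in arbo_root and osegs[0].parent_id in head_ids:
                assign(other, root2)

    for aid, segs in axes.items():
        if aid == root_axis:
            continue
        pid = segs[0].parent_id
        if pid in o1_ids:
            assign(aid, aid)
    # any axis not yet assigned hangs below another lateral; resolve by
    # walking up until an assigned axis is found (covers odd topologies)
    for aid in axes:
        if aid == root_axis or aid in arbo_root:
            continue
        cur = aid
        chain = [aid]
        while cur not in arbo_root:
            parent_seg = rs.axis_parent_segment(cur)
            if parent_seg is None:
                break
            cur = parent_seg.axis_id
            if cur == root_axis:
                break
            chain.append(cur)
        root2 = arbo_root.get(cur, chain[-1])
        for c in chain:
            arbo_root[c] = root2

    for aid, root2 in arbo_root.items():
        if root2 in infos:
            info = infos[root2]
        else:
            segs2 = axes[root2]
            bearing = segs2[0].base_xyz
            pidx = o1_ids[segs2[0].parent_id]
            origin_s = float(o1_cum[pidx + 1])  # attachment = bearing segment tip
            depth = float(bearing[2])
            dclass = classify_depth(depth)
            dirclass = classify_direction(axis_angle_to_surface(segs2))
            comp = _origin_compartment(dclass, dirclass)
            info = ArborescenceInfo(
                root_axis_id=root2,
                bearing_point=bearing,
                origin_s_on_order1_m=origin_s,
                origin_depth_m=depth,
                depth_class=dclass,
                direction_class=dirclass,
                on_stump=origin_s <= stump_length_m,
                compartment=comp,
            )
            infos[root2] = info
        infos[aid] = info
    return infos


def _origin_compartment(depth_class: str, direction_class: str) -> int:
    if depth_class == "deep":
        return 6
    if depth_class == "intermediate":
        return 7
    # shallow origins split by direction
    if direction_class == "horizontal":
        return 3  # ZRT vs beyond decided spatially per virtual segment
    if direction_class == "oblique":
        return 8
    return 5  # vertical shallow-origin laterals are sinkers


def axis_compartment(rs: RootSystem, axis_id: str, infos: Optional[dict] = None) -> int:
    """Origin-class compartment of a lateral axis (3 = shallow horizontal)."""
    if infos is None:
        infos = arborescence_info(rs)
    return infos[axis_id].compartment


# ---------------------------------------------------------- full labeling
def classify_system(
    rs: RootSystem,
    zrt_limit_m: float = ZRT_LIMIT_M,
    stump_length_m: float = STUMP_LENGTH_M,
    solid: str = "frustum",
) -> list[VirtualSegment]:
    """Virtualize and label every segment of a system (a total partition).

    Order-1 slices become stump or taproot (with a forced cut at 45 mm);
    lateral slices inherit their arborescence's origin compartment, with
    the shallow-horizontal ones split between ZRT and beyond by relative
    radial distance.  Lateral slices also get their azimuth, sector and
    relative radial distance about the bearing point on the order-1 root.
    """
    axes = rs.axes()
    root_axis = rs.axis_of_root()
    infos = arborescence_info(rs, stump_length_m)
    out: list[VirtualSegment] = []
    for aid, segs in axes.items():
        _, cum = polyline(segs)
        is_order1 = aid == root_axis
        info = None if is_order1 else infos[aid]
        for j, seg in enumerate(segs):
            cuts = ()
            if is_order1 and cum[j] < stump_length_m < cum[j + 1]:
                cuts = (stump_length_m - cum[j],)
            for vs in virtualize(rs, seg, cuts_m=cuts, solid=solid):
                vs.axis_s_mid_m = cum[j] + (vs.s0_m + vs.s1_m) / 2.0
                if is_order1:
                    vs.compartment = 1 if vs.axis_s_mid_m < stump_length_m else 2
                else:
                    comp = info.compartment
                    v = vs.midpoint_xyz - info.bearing_point
                    vs.rrd_m = float(math.hypot(v[0], v[1]))
                    if vs.rrd_m > 1e-12:
                        vs.azimuth_deg = Frame.azimuth_deg(v[0], v[1])
                        vs.sector = sector_of_azimuth(vs.azimuth_deg)
                    if comp == 3:
                        comp = 3 if vs.rrd_m <= zrt_limit_m else 4
                    vs.compartment = comp
                if vs.compartment is None:
                    raise AssertionError("unlabeled virtual segment")
                vs.pooled = POOLED[vs.compartment]
                out.append(vs)
    return out


# ------------------------------------------------------- sector statistics
def reinforcement(share_pct: float) -> float:
    """Excess of a 90-degree sector's share over the uniform 25 %, in %."""
    return (share_pct - 25.0) / 25.0 * 100.0


def axis_sector(rs: RootSystem, axis_id: str, infos: dict) -> Optional[str]:
    """Sector of a lateral axis: azimuth of bearing-point -> point-at-1-cm."""
    segs = rs.axes()[axis_id]
    verts, cum = polyline(segs)
    p = point_at(verts, cum, 0.010)
    v = p - infos[axis_id].bearing_point
    if math.hypot(v[0], v[1]) < 1e-12:
        return None
    return sector_of_azimuth(Frame.azimuth_deg(v[0], v[1]))


def sector_shares(
    labeled: Sequence[VirtualSegment],
    compartment: Optional[object] = None,
    quantity: str = "volume",
) -> Optional[dict[str, float]]:
    """Sector shares (%) of volume or length over labeled virtual segments.

    ``compartment`` may be an int (raw class), a pooled name, or None for
    all lateral slices.  Returns None when the scope has zero total (a
    missing value, never 0).
    """
    tot = {s: 0.0 for s in SECTORS}
    for vs in labeled:
        if vs.sector is None:
            continue
        if compartment is not None:
            if isinstance(compartment, int):
                if vs.compartment != compartment:
                    continue
            elif vs.pooled != compartment:
                continue
        tot[vs.sector] += vs.volume_m3 if quantity == "volume" else vs.length_m
    grand = sum(tot.values())
    if grand <= 0:
        return None
    return {s: 100.0 * tot[s] / grand for s in SECTORS}


def sector_table(
    rs: RootSystem,
    zrt_limit_m: float = ZRT_LIMIT_M,
    include_fine_roots: bool = False,
    solid: str = "frustum",
) -> pd.DataFrame:
    """Plant x compartment x sector aggregates for the sector mixed model.

    Rows: pooled lateral compartments (plus an ``all`` scope) by sector,
    with volume, length, axis count and mean axis traits.  Fine roots are
    excluded from sector analysis by default (their sector was not
    recorded in the study); when included they contribute count and
    length at their bearing axis's sector, never volume.
    """
    from .geometry import axis_geometry  # local imports to avoid cycles
    from .topology import mbo as _mbo

    labeled = classify_system(rs, zrt_limit_m=zrt_limit_m, solid=solid)
    infos = arborescence_info(rs)
    axes = rs.axes()
    root_axis = rs.axis_of_root()
    lateral_axes = [aid for aid in axes if aid != root_axis]
    geo = {aid: axis_geometry(rs, aid, solid=solid) for aid in lateral_axes}
    ax_sector = {aid: axis_sector(rs, aid, infos) for aid in lateral_axes}
    ax_comp = {aid: POOLED[infos[aid].compartment] if infos[aid].compartment != 3 else "shallow" for aid in lateral_axes}
    # virtual slices: pooled, with zrt+beyond also aggregated as "shallow"
    rows = []
    comp_scopes = ["all", "zrt", "shallow_beyond_zrt", "shallow", "intermediate", "deep", "taproot_pool"]
    for comp in comp_scopes:
        for sec in SECTORS:
            def in_comp(pooled_name):
                if comp == "all":
                    return True
                if comp == "shallow":
                    return pooled_name in ("zrt", "shallow_beyond_zrt")
                if comp == "taproot_pool":
                    return pooled_name == "taproot"
                return pooled_name == comp

            vol = sum(
                vs.volume_m3
                for vs in labeled
                if vs.sector == sec and vs.order > 1 and in_comp(vs.pooled)
            )
            length = sum(
                vs.length_m
                for vs in labeled
                if vs.sector == sec and vs.order > 1 and in_comp(vs.pooled)
            )
            ax_ids = [
                aid
                for aid in lateral_axes
                if ax_sector[aid] == sec and in_comp(ax_comp[aid])
            ]
            n_axes = len(ax_ids)
            n_fine = sum(geo[aid].n_fine_roots for aid in ax_ids)
            if include_fine_roots:
                length += sum(
                    s.fine_root_count * s.fine_root_mean_length_m
                    for aid in ax_ids
                    for s in axes[aid]
                )
            rows.append(
                {
                    "plant_id": rs.plant_id,
                    "compartment": comp,
                    "sector": sec,
                    "volume_cm3": vol * 1e6,
                    "length_cm": length * 100.0,
                    "n_axes": n_axes,
                    "n_axes_iafr": n_axes + (n_fine if include_fine_roots else 0),
                    "mean_diameter_cm": float(np.mean([geo[a].mean_diameter_m for a in ax_ids]) * 100.0) if ax_ids else np.nan,
                    "mean_length_cm": float(np.mean([geo[a].length_m for a in ax_ids]) * 100.0) if ax_ids else np.nan,
                    "mean_branching_angle_deg": float(np.nanmean([geo[a].branching_angle_deg for a in ax_ids])) if ax_ids else np.nan,
                    "mean_angle_to_surface_deg": float(np.mean([geo[a].angle_to_surface_deg for a in ax_ids])) if ax_ids else np.nan,
                    "srl_cm_cm3": (length * 100.0) / (vol * 1e6) if vol > 0 else np.nan,
                    "mbo_iafr": _mbo(rs, ax_ids, include_fine_roots=True) if ax_ids else np.nan,
                }
            )
    return pd.DataFrame(rows)
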