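"""Segment- and axis-level geometry.

Axes are digitized polylines with diameter knots at segment bases;
interpolation along an axis is linear in curvilinear distance for both
coordinates and diameters.  Two solid models are supported for volume:
``frustum`` (default; a segment tapers linearly from its basal diameter
to the next segment's basal diameter, the last segment of an axis being a
cylinder) and ``cylinder`` (constant basal diameter).

All angles are degrees; azimuths are compass-style about +Z with 0 = +X
(north/upslope) and 90 = +Y; angles to the soil surface are negative when
descending.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import Box, Frame, RootSegment, RootSystem, ValidationError

__all__ = [
    "VirtualSegment",
    "AxisGeometry",
    "frustum_volume",
    "polyline",
    "point_at",
    "diameter_knots",
    "diameter_at",
    "segment_end_diameter",
    "segment_volume",
    "axis_length",
    "axis_volume",
    "mean_diameter",
    "proximal_taper",
    "virtualize",
    "virtualize_system",
    "extend_wall_roots",
    "taproot_angle",
    "axis_azimuth",
    "rdd",
    "winding",
    "branching_angle",
    "axis_angle_to_surface",
    "fold_angle_deg",
    "axis_geometry",
]

VIRTUAL_LEN_M = 0.010  # 10 mm virtual segments for all spatial distributions


@dataclass
class VirtualSegment:
    """A <= 10 mm slice of a measured segment carrying apportioned volume."""

    segment_id: str
    axis_id: str
    order: int
    index: int
    s0_m: float  # curvilinear start within the segment
    s1_m: float
    length_m: float
    volume_m3: float
    midpoint_xyz: np.ndarray
    depth_m: float
    axis_s_mid_m: float = float("nan")  # curvilinear midpoint along the whole axis
    azimuth_deg: Optional[float] = None  # about the bearing point; set by classifier
    compartment: Optional[int] = None
    pooled: Optional[str] = None
    sector: Optional[str] = None
    rrd_m: Optional[float] = None


@dataclass
class AxisGeometry:
    """Per-axis trait record (reported units are converted downstream)."""

    axis_id: str
    order: int
    length_m: float
    mean_diameter_m: float
    volume_m3: float
    basal_diameter_m: float
    tip_diameter_m: float
    proximal_taper_pct_per_cm: Optional[float]
    branching_angle_deg: Optional[float]
    angle_to_surface_deg: float
    azimuth_deg: Optional[float]
    rdd_deg: Optional[float]
    winding: float
    apical_unbranched_length_m: Optional[float] = None
    n_fine_roots: int = 0
    flags: list = field(default_factory=list)


# ------------------------------------------------------------------ basics
def frustum_volume(d0: float, d1: float, length: float) -> float:
    """Exact volume of a conical frustum with end diameters d0, d1."""
    return math.pi * length / 12.0 * (d0 * d0 + d0 * d1 + d1 * d1)


def polyline(axis_segments: Sequence[RootSegment]):
    """Vertices (n+1, 3) and cumulative curvilinear distances (n+1,)."""
    verts = np.vstack([axis_segments[0].base_xyz] + [s.tip_xyz for s in axis_segments])
    d = np.linalg.norm(np.diff(verts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(d)])
    return verts, cum


def point_at(verts: np.ndarray, cum: np.ndarray, s: float) -> np.ndarray:
    """Point at curvilinear distance ``s`` (clamped to the axis ends)."""
    s = float(np.clip(s, 0.0, cum[-1]))
    i = int(np.searchsorted(cum, s, side="right")) - 1
    i = min(max(i, 0), len(cum) - 2)
    seg_len = cum[i + 1] - cum[i]
    t = 0.0 if seg_len == 0 else (s - cum[i]) / seg_len
    return verts[i] + t * (verts[i + 1] - verts[i])


def diameter_knots(rs: RootSystem, axis_segments: Sequence[RootSegment], solid: str = "frustum"):
    """Curvilinear knot positions and diameters along an axis.

    Knots sit at segment bases; the final knot at the axis tip carries the
    last segment's end diameter (its own basal diameter: cylinder tip).
    """
    _, cum = polyline(axis_segments)
    s_knots = list(cum[:-1]) + [cum[-1]]
    if solid == "frustum":
        d_knots = [s.diameter_m for s in axis_segments] + [axis_segments[-1].diameter_m]
    else:
        d_knots = [s.diameter_m for s in axis_segments] + [axis_segments[-1].diameter_m]
    return np.asarray(s_knots), np.asarray(d_knots)


def diameter_at(rs: RootSystem, axis_segments: Sequence[RootSegment], s: float, solid: str = "frustum") -> float:
    """Diameter at curvilinear distance ``s``, linearly interpolated."""
    s_knots, d_knots = diameter_knots(rs, axis_segments, solid)
    if solid == "cylinder":
        i = int(np.searchsorted(s_knots[1:-1], s, side="right"))
        return float(d_knots[min(i, len(axis_segments) - 1)])
    return float(np.interp(s, s_knots, d_knots))


def segment_end_diameter(rs: RootSystem, seg: RootSegment, solid: str = "frustum") -> float:
    """Apical diameter of a segment under the chosen solid model."""
    if solid == "cylinder":
        return seg.diameter_m
    for child in rs.children(seg.segment_id):
        if child.axis_id == seg.axis_id:
            return child.diameter_m
    return seg.diameter_m  # axis tip: cylinder


def segment_volume(rs: RootSystem, seg: RootSegment, solid: str = "frustum") -> float:
    d1 = segment_end_diameter(rs, seg, solid)
    return frustum_volume(seg.diameter_m, d1, seg.length_m)


def axis_length(axis_segments: Sequence[RootSegment], mother_segment: Optional[RootSegment] = None) -> float:
    """Axis length: sum of chord lengths plus the mother-root radius.

    Adding the bearing segment's radius accounts for the primary-growth
    path from the centre of the mother root to the branch base; the radius
    term is zero for the order-1 root.
    """
    total = sum(s.length_m for s in axis_segments)
    if mother_segment is not None:
        total += mother_segment.diameter_m / 2.0
    return total


def axis_volume(rs: RootSystem, axis_segments: Sequence[RootSegment], solid: str = "frustum") -> float:
    return sum(segment_volume(rs, s, solid) for s in axis_segments)


def mean_diameter(volume_m3: float, length_m: float) -> float:
    """Mean diameter of a root treated as a cylinder: 2*sqrt(V / (pi*L))."""
    if length_m <= 0:
        raise ValidationError("mean_diameter undefined for zero length")
    return 2.0 * math.sqrt(max(volume_m3, 0.0) / (math.pi * length_m))


def proximal_taper(
    rs: RootSystem,
    axis_segments: Sequence[RootSegment],
    window_m: float = 0.035,
    solid: str = "frustum",
) -> Optional[float]:
    """% diameter decrease per cm over the first 3.5 cm of the axis.

    Returns None (missing) when the axis is shorter than the window.
    """
    _, cum = polyline(axis_segments)
    if cum[-1] < window_m:
        return None
    d0 = diameter_at(rs, axis_segments, 0.0, solid)
    if d0 <= 0:
        raise ValidationError("proximal taper undefined: zero basal diameter")
    dw = diameter_at(rs, axis_segments, window_m, solid)
    return 100.0 * (d0 - dw) / d0 / (window_m * 100.0)


# ------------------------------------------------------------- virtualize
def virtualize(
    rs: RootSystem,
    seg: RootSegment,
    cuts_m: Sequence[float] = (),
    max_len_m: float = VIRTUAL_LEN_M,
    solid: str = "frustum",
) -> list[VirtualSegment]:
    """Split a segment into <= 10 mm virtual slices, conserving volume.

    ``cuts_m`` are extra forced boundaries (local curvilinear positions,
    e.g. the 45 mm stump limit crossing the segment).  Slice volumes come
    from the exact frustum integral, so they sum to the segment volume to
    machine precision.
    """
    L = seg.length_m
    if L <= 0:
        return []
    d0 = seg.diameter_m
    d1 = segment_end_diameter(rs, seg, solid)
    bounds = {0.0, L}
    for c in cuts_m:
        if 0.0 < c < L:
            bounds.add(float(c))
    bounds = sorted(bounds)
    # subdivide each inter-cut interval into 10 mm steps
    pts: list[float] = [0.0]
    for a, b in zip(bounds[:-1], bounds[1:]):
        n = max(1, math.ceil((b - a) / max_len_m - 1e-12))
        for k in range(1, n):
            pts.append(a + k * max_len_m)
        pts.append(b)
    u = seg.direction
    out = []
    for i, (a, b) in enumerate(zip(pts[:-1], pts[1:])):
        da = d0 + (d1 - d0) * a / L
        db = d0 + (d1 - d0) * b / L
        mid = seg.base_xyz + u * ((a + b) / 2.0)
        out.append(
            VirtualSegment(
                segment_id=seg.segment_id,
                axis_id=seg.axis_id,
                order=seg.order,
                index=i,
                s0_m=a,
                s1_m=b,
                length_m=b - a,
                volume_m3=frustum_volume(da, db, b - a),
                midpoint_xyz=mid,
                depth_m=float(mid[2]),
            )
        )
    return out


def virtualize_system(rs: RootSystem, solid: str = "frustum") -> list[VirtualSegment]:
    """All virtual segments of a system, with axis curvilinear midpoints."""
    out: list[VirtualSegment] = []
    for aid, segs in rs.axes().items():
        _, cum = polyline(segs)
        for j, seg in enumerate(segs):
            for vs in virtualize(rs, seg, solid=solid):
                vs.axis_s_mid_m = cum[j] + (vs.s0_m + vs.s1_m) / 2.0
                out.append(vs)
    return out


# ------------------------------------------------------- wall correction
def extend_wall_roots(
    rs: RootSystem,
    tol_m: float = 0.002,
    plane_angle_deg: float = 15.0,
    min_run: int = 2,
) -> RootSystem:
    """Undo the container-wall artefact by straightening wall-following axes.

    Potted roots that hit a wall or the bottom tend to grow along it; the
    digitized shape then reflects the pot, not the root's growth
    direction.  Each axis with a vertex within ``tol_m`` of a container
    face followed by at least ``min_run`` segments lying within
    ``plane_angle_deg`` of that face's plane is virtually re-aimed: every
    post-contact segment keeps its length but takes the last pre-contact
    direction.  Child arborescences attached to moved segments are
    translated rigidly.  Axes that never meet a wall are returned
    unchanged; an axis whose first vertex already lies on a wall is left
    alone with a warning.  The operation is idempotent.
    """
    out = rs.copy()
    faces = out.container.faces()
    sin_tol = math.sin(math.radians(plane_angle_deg))
    axes = out.axes()
    # parent-first order so subtree translations precede child processing
    order_sorted = sorted(axes, key=lambda aid: (axes[aid][0].order, aid))

    def subtree_segments(axis_id: str) -> list[RootSegment]:
        todo = [axis_id]
        segs: list[RootSegment] = []
        while todo:
            aid = todo.pop()
            segs.extend(axes[aid])
            ids = {s.segment_id for s in axes[aid]}
            for other, osegs in axes.items():
                if other != aid and osegs[0].parent_id in ids:
                    todo.append(other)
        return segs

    for aid in order_sorted:
        segs = axes[aid]
        verts, _ = polyline(segs)
        n = len(segs)

        def near_face(p):
            hits = []
            for ax, coord, normal in faces:
                if abs(p[ax] - coord) <= tol_m:
                    hits.append((ax, coord, normal))
            return hits

        if near_face(verts[0]):
            warnings.warn(
                f"axis {aid!r}: first vertex already on a container face; left unchanged",
                stacklevel=2,
            )
            continue
        contact = None
        for i in range(1, n):  # vertex i = tip of segment i-1
            for ax, coord, normal in near_face(verts[i]):
                run = 0
                for j in range(i, n):
                    d = segs[j].direction
                    if np.linalg.norm(d) == 0 or abs(float(d @ normal)) <= sin_tol:
                        run += 1
                    else:
                        break
                if run >= min_run:
                    contact = i
                    break
            if contact is not None:
                break
        if contact is None:
            continue
        u = verts[contact] - verts[contact - 1]
        nu = np.linalg.norm(u)
        if nu == 0:
            continue
        u = u / nu
        new_verts = verts.copy()
        for j in range(contact + 1, n + 1):
            new_verts[j] = new_verts[j - 1] + u * segs[j - 1].length_m
        # apply and propagate translations to attached arborescences
        for j in range(contact, n):
            seg = segs[j]
            delta_tip = new_verts[j + 1] - verts[j + 1]
            seg.base_xyz = new_verts[j].copy()
            seg.tip_xyz = new_verts[j + 1].copy()
            if np.linalg.norm(delta_tip) > 0:
                for other, osegs in axes.items():
                    if other != aid and osegs[0].parent_id == seg.segment_id:
                        for sub in subtree_segments(other):
                            sub.base_xyz = sub.base_xyz + delta_tip
                            sub.tip_xyz = sub.tip_xyz + delta_tip
    return out


# ---------------------------------------------------------------- angles
def fold_angle_deg(a: float) -> float:
    """Fold an azimuth difference into [0, 180]."""
    a = abs(a) % 360.0
    return 360.0 - a if a > 180.0 else a


def taproot_angle(rs: RootSystem, deep_limit_m: float = 0.070):
    """Angle to the soil surface of the collar -> deep-limit-crossing line.

    The crossing point is where the order-1 path first reaches 70 mm
    depth (linear interpolation between vertices).  If the taproot never
    gets that deep, its deepest point is used and the result is flagged.
    Negative angles descend; a vertical taproot scores -90.
    """
    segs = rs.axes()[rs.axis_of_root()]
    verts, _ = polyline(segs)
    collar = verts[0]
    z_target = collar[2] - deep_limit_m
    flag = None
    crossing = None
    for i in range(1, len(verts)):
        if verts[i][2] <= z_target:
            z0, z1 = verts[i - 1][2], verts[i][2]
            t = 0.0 if z1 == z0 else (z_target - z0) / (z1 - z0)
            crossing = verts[i - 1] + t * (verts[i] - verts[i - 1])
            break
    if crossing is None:
        k = int(np.argmin(verts[:, 2]))
        crossing = verts[k]
        flag = "taproot-shallower-than-deep-limit"
    v = crossing - collar
    return Frame.angle_to_surface_deg(v), flag


def axis_azimuth(axis_segments: Sequence[RootSegment], at_m: float = 0.010):
    """Azimuth of the axis base -> point-at-1-cm direction (soil-plane projection).

    Axes shorter than 1 cm fall back to the tip and are flagged; a
    perfectly vertical first centimetre has no azimuth (flagged, None).
    """
    verts, cum = polyline(axis_segments)
    flag = None
    if cum[-1] < at_m:
        p = verts[-1]
        flag = "axis-shorter-than-azimuth-window"
    else:
        p = point_at(verts, cum, at_m)
    v = p - verts[0]
    if math.hypot(v[0], v[1]) < 1e-12:
        return None, "undefined-azimuth-vertical"
    return Frame.azimuth_deg(v[0], v[1]), flag


def _position_azimuth(origin: np.ndarray, p: np.ndarray) -> Optional[float]:
    v = p - origin
    if math.hypot(v[0], v[1]) < 1e-12:
        return None
    return Frame.azimuth_deg(v[0], v[1])


def rdd(axis_segments: Sequence[RootSegment], from_m: float = 0.010):
    """Root directional deviation: |azimuth(tip) - azimuth(point at 10 mm)|.

    Azimuths are taken about the axis base (its origin on the mother
    root) and the difference is folded into [0, 180].  Axes of 10 mm or
    less use the tip for both ends (flagged; RDD 0).
    """
    verts, cum = polyline(axis_segments)
    origin = verts[0]
    flag = None
    if cum[-1] <= from_m:
        flag = "axis-shorter-than-rdd-window"
        p10 = verts[-1]
    else:
        p10 = point_at(verts, cum, from_m)
    a1 = _position_azimuth(origin, p10)
    a2 = _position_azimuth(origin, verts[-1])
    if a1 is None or a2 is None:
        return None, "undefined-azimuth-vertical"
    return fold_angle_deg(a2 - a1), flag


def winding(axis_segments: Sequence[RootSegment]) -> float:
    """Curvilinear length / straight base-to-tip distance (>= 1)."""
    verts, cum = polyline(axis_segments)
    chord = float(np.linalg.norm(verts[-1] - verts[0]))
    if chord == 0:
        return float("inf") if cum[-1] > 0 else 1.0
    return float(cum[-1] / chord)


def branching_angle(
    child_axis_segments: Sequence[RootSegment], mother_segment: RootSegment
) -> float:
    """3D angle between the child's first segment and the bearing segment."""
    v1 = child_axis_segments[0].direction
    v2 = mother_segment.direction
    if np.linalg.norm(v1) == 0 or np.linalg.norm(v2) == 0:
        raise ValidationError("branching angle undefined for zero-length segments")
    c = float(np.clip(v1 @ v2, -1.0, 1.0))
    return math.degrees(math.acos(c))


def axis_angle_to_surface(axis_segments: Sequence[RootSegment]) -> float:
    """Angle of the base->tip chord to the soil surface (negative down)."""
    verts, _ = polyline(axis_segments)
    v = verts[-1] - verts[0]
    if np.linalg.norm(v) == 0:
        return 0.0
    return Frame.angle_to_surface_deg(v)


def axis_geometry(rs: RootSystem, axis_id: str, solid: str = "frustum") -> AxisGeometry:
    """Assemble the per-axis geometric trait record."""
    segs = rs.axes()[axis_id]
    mother = rs.axis_parent_segment(axis_id)
    length = axis_length(segs, mother)
    vol = axis_volume(rs, segs, solid)
    az, az_flag = axis_azimuth(segs)
    rdd_v, rdd_flag = rdd(segs)
    flags = [f for f in (az_flag, rdd_flag) if f]
    return AxisGeometry(
        axis_id=axis_id,
        order=segs[0].order,
        length_m=length,
        mean_diameter_m=mean_diameter(vol, length) if length > 0 else 0.0,
        volume_m3=vol,
        basal_diameter_m=segs[0].diameter_m,
        tip_diameter_m=segment_end_diameter(rs, segs[-1], solid),
        proximal_taper_pct_per_cm=proximal_taper(rs, segs, solid=solid),
        branching_angle_deg=branching_angle(segs, mother) if mother is not None else None,
        angle_to_surface_deg=axis_angle_to_surface(segs),
        azimuth_deg=az,
        rdd_deg=rdd_v,
        winding=winding(segs),
        n_fine_roots=sum(s.fine_root_count for s in segs),
        flags=flags,
    )
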