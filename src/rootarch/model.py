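"""Domain model for 3D-digitized coarse root systems.

A digitized root system is a rooted tree of measured inter-node pieces
(:class:`RootSegment`), grouped into axes (an axis is one root: the
taproot, a second-order lateral, ...).  Segment ends were recorded during
excavation together with the root diameter at the segment base, plus a
count and mean length of the unmeasured "additional fine roots" (basal
diameter below 0.7 mm) borne by each segment.

Conventions
-----------
* SI units internally: coordinates and diameters in metres.
* Container frame: X points north/upslope (azimuth 0 deg), Y is parallel
  to the upper container border, Z is perpendicular to the soil surface
  and positive upward, so depths are negative.  The collar sits at the
  frame origin.
* Azimuths are compass-style about +Z: 0 deg = +X (upslope), 90 deg = +Y.
* ``order`` is the topological root order; the whole first-order path
  (stump + taproot) is order 1, its laterals order 2, and so on.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "Box",
    "Frame",
    "RootSegment",
    "RootSystem",
    "Violation",
    "validate",
    "MTGFormatError",
    "StructureError",
    "ValidationError",
]


class MTGFormatError(ValueError):
    """Malformed MTG-dialect header or body row."""


class StructureError(ValueError):
    """Topologically inconsistent segment set (orphans, cycles, no collar)."""


class ValidationError(ValueError):
    """Physically impossible field value (e.g. a negative diameter)."""


@dataclass(frozen=True)
class Box:
    """Container geometry: a rectangular pot centred on the collar.

    The soil surface is the plane z = 0; walls sit at x = +/- x_m / 2 and
    y = +/- y_m / 2, the bottom at z = -soil_depth_m.
    """

    x_m: float = 0.30
    y_m: float = 0.30
    soil_depth_m: float = 0.11

    def contains(self, p: np.ndarray, tol: float = 0.0) -> bool:
        return (
            abs(p[0]) <= self.x_m / 2 + tol
            and abs(p[1]) <= self.y_m / 2 + tol
            and -self.soil_depth_m - tol <= p[2]
        )

    def faces(self):
        """(axis index, plane coordinate, inward normal) for walls and bottom.

        The soil surface is not a face: roots never run along it from below
        in the way they follow walls, and the collar lies on it.
        """
        return [
            (0, self.x_m / 2, np.array([-1.0, 0.0, 0.0])),
            (0, -self.x_m / 2, np.array([1.0, 0.0, 0.0])),
            (1, self.y_m / 2, np.array([0.0, -1.0, 0.0])),
            (1, -self.y_m / 2, np.array([0.0, 1.0, 0.0])),
            (2, -self.soil_depth_m, np.array([0.0, 0.0, 1.0])),
        ]


class Frame:
    """The slope-oriented container frame (a documented convention).

    X = north = upslope (azimuth 0), Y parallel to the upper container
    border, Z perpendicular to the soil surface through the collar,
    positive upward.  Angles to the soil surface live in [-90, +90] deg
    and are negative when descending into the soil.
    """

    x_axis = np.array([1.0, 0.0, 0.0])
    y_axis = np.array([0.0, 1.0, 0.0])
    z_axis = np.array([0.0, 0.0, 1.0])

    @staticmethod
    def azimuth_deg(dx: float, dy: float) -> float:
        """Compass azimuth of a horizontal direction, in [0, 360)."""
        return math.degrees(math.atan2(dy, dx)) % 360.0

    @staticmethod
    def angle_to_surface_deg(v: np.ndarray) -> float:
        """Angle of a 3D direction to the soil-surface plane, negative downward."""
        h = math.hypot(v[0], v[1])
        return math.degrees(math.atan2(v[2], h))


@dataclass
class RootSegment:
    """One measured inter-node of a root axis.

    ``diameter_m`` is the basal (proximal) diameter as digitized; the
    apical diameter of a segment is the basal diameter of the next segment
    on the same axis (frustum solid model) or its own (cylinder model).
    """

    segment_id: str
    parent_id: Optional[str]
    axis_id: str
    order: int
    base_xyz: np.ndarray
    tip_xyz: np.ndarray
    diameter_m: float
    fine_root_count: int = 0
    fine_root_mean_length_m: float = 0.0

    def __post_init__(self):
        self.base_xyz = np.asarray(self.base_xyz, dtype=float)
        self.tip_xyz = np.asarray(self.tip_xyz, dtype=float)

    @property
    def length_m(self) -> float:
        return float(np.linalg.norm(self.tip_xyz - self.base_xyz))

    @property
    def direction(self) -> np.ndarray:
        """Unit chord direction; the zero vector for a zero-length segment."""
        d = self.tip_xyz - self.base_xyz
        n = np.linalg.norm(d)
        return d / n if n > 0 else np.zeros(3)


@dataclass
class RootSystem:
    """A rooted tree of segments plus plant metadata and container geometry."""

    segments: dict[str, RootSegment]
    plant_id: str = "P1"
    slope_deg: float = 0.0
    flexed: bool = False
    block: str = "B1"
    container: Box = field(default_factory=Box)
    shoot_dry_weight_g: Optional[float] = None
    root_dry_weight_g: Optional[float] = None
    #: set by the synthetic generator; carries generation-time ground truth
    ground_truth: object = None

    # ------------------------------------------------------------------ #
    def root(self) -> RootSegment:
        """The collar segment (the unique segment without a parent)."""
        roots = [s for s in self.segments.values() if s.parent_id is None]
        if len(roots) != 1:
            raise StructureError(
                f"expected exactly one collar segment, found {len(roots)}"
            )
        return roots[0]

    def children(self, segment_id: str) -> list[RootSegment]:
        return [s for s in self.segments.values() if s.parent_id == segment_id]

    def child_index(self) -> dict[str, list[RootSegment]]:
        idx: dict[str, list[RootSegment]] = {}
        for s in self.segments.values():
            if s.parent_id is not None:
                idx.setdefault(s.parent_id, []).append(s)
        return idx

    def axes(self) -> dict[str, list[RootSegment]]:
        """Axis id -> segments ordered base-to-tip along the axis."""
        groups: dict[str, list[RootSegment]] = {}
        for s in self.segments.values():
            groups.setdefault(s.axis_id, []).append(s)
        ordered: dict[str, list[RootSegment]] = {}
        for aid, segs in groups.items():
            by_id = {s.segment_id: s for s in segs}
            heads = [s for s in segs if s.parent_id not in by_id]
            if len(heads) != 1:
                raise StructureError(f"axis {aid!r} has {len(heads)} head segments")
            succ = {}
            for s in segs:
                if s.parent_id in by_id:
                    if s.parent_id in succ:
                        raise StructureError(
                            f"axis {aid!r} forks at segment {s.parent_id!r}"
                        )
                    succ[s.parent_id] = s
            chain = [heads[0]]
            while chain[-1].segment_id in succ:
                chain.append(succ[chain[-1].segment_id])
            if len(chain) != len(segs):
                raise StructureError(f"axis {aid!r} is not a single chain")
            ordered[aid] = chain
        return ordered

    def axis_of_root(self) -> str:
        return self.root().axis_id

    def axis_parent_segment(self, axis_id: str) -> Optional[RootSegment]:
        """The bearing (mother) segment of an axis, None for the order-1 axis."""
        head = self.axes()[axis_id][0]
        if head.parent_id is None:
            return None
        return self.segments[head.parent_id]

    def total_fine_root_count(self) -> int:
        return sum(s.fine_root_count for s in self.segments.values())

    def copy(self) -> "RootSystem":
        segs = {
            k: replace(v, base_xyz=v.base_xyz.copy(), tip_xyz=v.tip_xyz.copy())
            for k, v in self.segments.items()
        }
        return replace(self, segments=segs)


@dataclass(frozen=True)
class Violation:
    segment_id: str
    rule: str
    message: str


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return float(np.linalg.norm(p - a))
    t = float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab)))


def validate(rs: RootSystem, tol_m: float = 1e-6) -> list[Violation]:
    """Check all structural invariants; violations are data, not exceptions.

    Rules checked: a unique collar; acyclicity; known parents; order
    increments (same axis keeps the order, a branch adds exactly one);
    non-negative diameters; each segment base coinciding with its parent's
    tip or lying on the parent chord (within ``tol_m``).
    """
    v: list[Violation] = []
    segs = rs.segments
    roots = [s for s in segs.values() if s.parent_id is None]
    if len(roots) != 1:
        v.append(
            Violation("", "collar", f"expected exactly 1 collar segment, found {len(roots)}")
        )

    for s in segs.values():
        if s.diameter_m < 0:
            v.append(Violation(s.segment_id, "diameter", "negative diameter"))
        if not np.all(np.isfinite(s.base_xyz)) or not np.all(np.isfinite(s.tip_xyz)):
            v.append(Violation(s.segment_id, "coords", "non-finite coordinates"))
        if s.order < 1:
            v.append(Violation(s.segment_id, "order", "order must be >= 1"))
        if s.parent_id is not None:
            if s.parent_id not in segs:
                v.append(
                    Violation(s.segment_id, "orphan", f"unknown parent {s.parent_id!r}")
                )
                continue
            p = segs[s.parent_id]
            if s.order not in (p.order, p.order + 1):
                v.append(
                    Violation(
                        s.segment_id,
                        "order",
                        f"order jump parent {p.order} -> child {s.order}",
                    )
                )
            if s.axis_id == p.axis_id and s.order != p.order:
                v.append(
                    Violation(s.segment_id, "order", "order change within an axis")
                )
            if s.axis_id != p.axis_id and s.order != p.order + 1:
                v.append(
                    Violation(
                        s.segment_id, "order", "branch must increase order by one"
                    )
                )
            d_tip = float(np.linalg.norm(s.base_xyz - p.tip_xyz))
            if d_tip > tol_m:
                d_chord = _point_segment_distance(s.base_xyz, p.base_xyz, p.tip_xyz)
                if d_chord > tol_m:
                    v.append(
                        Violation(
                            s.segment_id,
                            "attachment",
                            "base neither at parent tip nor on parent chord "
                            f"(off by {min(d_tip, d_chord):.2e} m)",
                        )
                    )

    # acyclicity via parent walks with memoisation
    state: dict[str, int] = {}  # 0 visiting, 1 ok
    for s in segs.values():
        path = []
        cur = s.segment_id
        while cur is not None and cur in segs and state.get(cur) != 1:
            if state.get(cur) == 0:
                v.append(Violation(cur, "cycle", "parent chain contains a cycle"))
                break
            state[cur] = 0
            path.append(cur)
            cur = segs[cur].parent_id
        for pid in path:
            if state.get(pid) == 0:
                state[pid] = 1
    return v
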