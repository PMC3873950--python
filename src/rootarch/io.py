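"""Readers and writers: MTG-dialect text files and portable segment tables.

The full multiscale tree graph (MTG) grammar is large; digitized root
systems only ever use a small, flat corner of it (one scale for axes, one
for segments, coordinate/diameter/fine-root features).  This module
implements a documented dialect of exactly that corner — see
``docs/mtg_dialect.md`` for the grammar — and rejects anything else
explicitly.

Both formats round-trip losslessly to 1e-6 m.
"""
from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    Box,
    MTGFormatError,
    RootSegment,
    RootSystem,
    StructureError,
    ValidationError,
)

__all__ = [
    "read_mtg",
    "write_mtg",
    "read_segment_table",
    "write_segment_table",
]

_UNIT_SCALE = {"mm": 1e-3, "cm": 1e-2, "m": 1.0}
_FEATURES = ("XX", "YY", "ZZ", "Diameter", "FineRootN", "FineRootLen")

_META_KEYS = {
    "PLANT": ("plant_id", str),
    "SLOPE_DEG": ("slope_deg", float),
    "FLEXED": ("flexed", lambda s: s.strip().lower() in ("1", "true", "yes")),
    "BLOCK": ("block", str),
    "SHOOT_DW_G": ("shoot_dry_weight_g", float),
    "ROOT_DW_G": ("root_dry_weight_g", float),
}


def read_mtg(path) -> RootSystem:
    """Parse an MTG-dialect file into a validated :class:`RootSystem`.

    Raises :class:`MTGFormatError` (naming the offending line) for header
    or row syntax problems, :class:`StructureError` listing orphan ids for
    disconnected segments, and :class:`ValidationError` for negative
    diameters.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    scale = None
    collar = np.zeros(3)
    meta: dict = {}
    container = Box()
    rows: list[tuple[int, str, str, list[float]]] = []
    in_data = False
    saw_magic = False

    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not saw_magic:
            if not line.startswith("MTG-DIALECT"):
                raise MTGFormatError(f"line {ln}: expected 'MTG-DIALECT v1' header")
            saw_magic = True
            continue
        if not in_data:
            if line == "DATA:":
                in_data = True
                continue
            if ":" not in line:
                raise MTGFormatError(f"line {ln}: malformed header line {line!r}")
            key, _, val = line.partition(":")
            key, val = key.strip().upper(), val.strip()
            if key == "UNIT":
                if val not in _UNIT_SCALE:
                    raise MTGFormatError(f"line {ln}: unknown unit {val!r}")
                scale = _UNIT_SCALE[val]
            elif key == "COLLAR":
                try:
                    collar = np.array([float(x) for x in val.split()])
                except ValueError:
                    raise MTGFormatError(f"line {ln}: bad COLLAR coordinates") from None
                if collar.size != 3:
                    raise MTGFormatError(f"line {ln}: COLLAR needs 3 coordinates")
            elif key == "FEATURES":
                if tuple(val.split()) != _FEATURES:
                    raise MTGFormatError(
                        f"line {ln}: unsupported FEATURES; this dialect requires "
                        + " ".join(_FEATURES)
                    )
            elif key == "CONTAINER":
                try:
                    x, y, d = (float(t) for t in val.split())
                except ValueError:
                    raise MTGFormatError(f"line {ln}: bad CONTAINER dims") from None
                container = Box(x, y, d)
            elif key in _META_KEYS:
                attr, conv = _META_KEYS[key]
                meta[attr] = conv(val)
            else:
                raise MTGFormatError(f"line {ln}: unsupported header key {key!r}")
            continue
        # body row: <id> <topo> <6 feature values>
        parts = line.split()
        if len(parts) != 2 + len(_FEATURES):
            raise MTGFormatError(
                f"line {ln}: expected id, topology code and {len(_FEATURES)} features"
            )
        sid, topo = parts[0], parts[1]
        try:
            feats = [float(x) for x in parts[2:]]
        except ValueError:
            raise MTGFormatError(f"line {ln}: non-numeric feature value") from None
        rows.append((ln, sid, topo, feats))

    if not in_data:
        raise MTGFormatError("missing 'DATA:' section")
    if scale is None:
        scale = 1.0
    collar = collar * scale

    by_id: dict[str, tuple[int, str, list[float]]] = {}
    for ln, sid, topo, feats in rows:
        if sid in by_id:
            raise MTGFormatError(f"line {ln}: duplicate segment id {sid!r}")
        by_id[sid] = (ln, topo, feats)

    # resolve topology; forward references are fine (row order is irrelevant)
    parent: dict[str, Optional[str]] = {}
    kind: dict[str, str] = {}
    orphans = []
    root_ids = []
    for sid, (ln, topo, _f) in by_id.items():
        if topo == "-":
            parent[sid] = None
            kind[sid] = "root"
            root_ids.append(sid)
        elif topo[0] in "<+" and len(topo) > 1:
            pid = topo[1:]
            if pid not in by_id:
                orphans.append(sid)
            parent[sid] = pid
            kind[sid] = "succ" if topo[0] == "<" else "branch"
        else:
            raise MTGFormatError(f"line {ln}: bad topology code {topo!r}")
    if orphans:
        raise StructureError(
            "disconnected segments (unknown parent): " + ", ".join(sorted(orphans))
        )
    if len(root_ids) != 1:
        raise StructureError(
            f"expected exactly one collar row ('-'), found {len(root_ids)}"
        )

    # deterministic traversal (children sorted by id) assigns axis ids and
    # orders independently of row order
    children: dict[str, list[str]] = {}
    for sid, pid in parent.items():
        if pid is not None:
            children.setdefault(pid, []).append(sid)
    for v in children.values():
        v.sort()

    segments: dict[str, RootSegment] = {}
    axis_counter = 0

    def tip_of(sid: str) -> np.ndarray:
        f = by_id[sid][2]
        return np.array(f[:3]) * scale

    stack: list[tuple[str, Optional[str], int, Optional[int]]] = []
    # (segment id, axis id, order, _) seeded with the root
    axis_counter += 1
    stack.append((root_ids[0], f"A{axis_counter}", 1, None))
    seen = set()
    while stack:
        sid, axis_id, order, _ = stack.pop()
        if sid in seen:
            raise StructureError(f"cycle detected at segment {sid!r}")
        seen.add(sid)
        ln, topo, feats = by_id[sid]
        diam = feats[3] * scale
        if diam < 0:
            raise ValidationError(f"line {ln}: negative diameter for segment {sid!r}")
        base = collar if parent[sid] is None else tip_of(parent[sid])
        segments[sid] = RootSegment(
            segment_id=sid,
            parent_id=parent[sid],
            axis_id=axis_id,
            order=order,
            base_xyz=base,
            tip_xyz=tip_of(sid),
            diameter_m=diam,
            fine_root_count=int(round(feats[4])),
            fine_root_mean_length_m=feats[5] * scale,
        )
        kids = children.get(sid, [])
        succs = [k for k in kids if kind[k] == "succ"]
        if len(succs) > 1:
            raise StructureError(f"segment {sid!r} has multiple '<' successors")
        # push branches first so the successor continues depth-first next
        for k in kids:
            if kind[k] == "branch":
                axis_counter += 1
                stack.append((k, f"A{axis_counter}", order + 1, None))
        for k in succs:
            stack.append((k, axis_id, order, None))
    if len(seen) != len(by_id):
        missing = sorted(set(by_id) - seen)
        raise StructureError("unreachable segments: " + ", ".join(missing))

    # stable ordering: sorted ids for reproducibility across row orders
    segments = {k: segments[k] for k in sorted(segments)}
    rs = RootSystem(segments=segments, container=container, **meta)
    rs.root()  # asserts the single-collar invariant
    return rs


def write_mtg(rs: RootSystem, path, unit: str = "mm") -> None:
    """Serialize a RootSystem to the MTG dialect (default unit: mm)."""
    if unit not in _UNIT_SCALE:
        raise ValueError(f"unknown unit {unit!r}")
    s = 1.0 / _UNIT_SCALE[unit]
    root = rs.root()
    buf = _io.StringIO()
    buf.write("MTG-DIALECT v1\n")
    buf.write(f"UNIT: {unit}\n")
    c = root.base_xyz * s
    buf.write(f"COLLAR: {c[0]:.6f} {c[1]:.6f} {c[2]:.6f}\n")
    buf.write(f"PLANT: {rs.plant_id}\n")
    buf.write(f"SLOPE_DEG: {rs.slope_deg:g}\n")
    buf.write(f"FLEXED: {rs.flexed}\n")
    buf.write(f"BLOCK: {rs.block}\n")
    buf.write(
        f"CONTAINER: {rs.container.x_m:g} {rs.container.y_m:g} {rs.container.soil_depth_m:g}\n"
    )
    if rs.shoot_dry_weight_g is not None:
        buf.write(f"SHOOT_DW_G: {rs.shoot_dry_weight_g:.6g}\n")
    if rs.root_dry_weight_g is not None:
        buf.write(f"ROOT_DW_G: {rs.root_dry_weight_g:.6g}\n")
    buf.write("FEATURES: " + " ".join(_FEATURES) + "\n")
    buf.write("DATA:\n")
    axes = rs.axes()
    for aid in axes:
        prev = None
        for seg in axes[aid]:
            if seg.parent_id is None:
                topo = "-"
            elif prev is not None and seg.parent_id == prev.segment_id:
                topo = f"<{seg.parent_id}"
            else:
                topo = f"+{seg.parent_id}"
            t = seg.tip_xyz * s
            buf.write(
                f"{seg.segment_id}\t{topo}\t{t[0]:.6f} {t[1]:.6f} {t[2]:.6f}\t"
                f"{seg.diameter_m * s:.6f}\t{seg.fine_root_count}\t"
                f"{seg.fine_root_mean_length_m * s:.6f}\n"
            )
            prev = seg
    Path(path).write_text(buf.getvalue())


_TABLE_COLUMNS = [
    "segment_id",
    "parent_id",
    "axis_id",
    "order",
    "base_x_m",
    "base_y_m",
    "base_z_m",
    "tip_x_m",
    "tip_y_m",
    "tip_z_m",
    "diameter_m",
    "fine_root_count",
    "fine_root_mean_length_m",
]


def write_segment_table(rs: RootSystem, path) -> None:
    """Write the portable one-row-per-segment CSV (units: metres, SI frame)."""
    rows = []
    for seg in rs.segments.values():
        rows.append(
            {
                "segment_id": seg.segment_id,
                "parent_id": "" if seg.parent_id is None else seg.parent_id,
                "axis_id": seg.axis_id,
                "order": seg.order,
                "base_x_m": seg.base_xyz[0],
                "base_y_m": seg.base_xyz[1],
                "base_z_m": seg.base_xyz[2],
                "tip_x_m": seg.tip_xyz[0],
                "tip_y_m": seg.tip_xyz[1],
                "tip_z_m": seg.tip_xyz[2],
                "diameter_m": seg.diameter_m,
                "fine_root_count": seg.fine_root_count,
                "fine_root_mean_length_m": seg.fine_root_mean_length_m,
            }
        )
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    header = [
        "# rootarch segment table; units: metres; frame: X=north/upslope (azimuth 0),",
        "# Y parallel to upper container border, Z up (depths negative), collar at origin",
        f"# plant_id: {rs.plant_id}",
        f"# slope_deg: {rs.slope_deg:g}",
        f"# flexed: {rs.flexed}",
        f"# block: {rs.block}",
        f"# container_m: {rs.container.x_m:g} {rs.container.y_m:g} {rs.container.soil_depth_m:g}",
        f"# shoot_dry_weight_g: {'' if rs.shoot_dry_weight_g is None else format(rs.shoot_dry_weight_g, '.6g')}",
        f"# root_dry_weight_g: {'' if rs.root_dry_weight_g is None else format(rs.root_dry_weight_g, '.6g')}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_segment_table(path) -> RootSystem:
    """Read a portable segment-table CSV back into a RootSystem."""
    meta: dict = {}
    container = Box()
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        if ":" in line:
            key, _, val = line.lstrip("# ").partition(":")
            key, val = key.strip(), val.strip()
            if key == "plant_id":
                meta["plant_id"] = val
            elif key == "slope_deg":
                meta["slope_deg"] = float(val)
            elif key == "flexed":
                meta["flexed"] = val.lower() in ("true", "1", "yes")
            elif key == "block":
                meta["block"] = val
            elif key == "container_m":
                x, y, d = (float(t) for t in val.split())
                container = Box(x, y, d)
            elif key == "shoot_dry_weight_g" and val:
                meta["shoot_dry_weight_g"] = float(val)
            elif key == "root_dry_weight_g" and val:
                meta["root_dry_weight_g"] = float(val)
    df = pd.read_csv(_io.StringIO("".join(lines[body_start:])), dtype={"segment_id": str, "parent_id": str, "axis_id": str})
    segments: dict[str, RootSegment] = {}
    for _, r in df.iterrows():
        pid = r["parent_id"]
        pid = None if (pd.isna(pid) or pid == "") else str(pid)
        seg = RootSegment(
            segment_id=str(r["segment_id"]),
            parent_id=pid,
            axis_id=str(r["axis_id"]),
            order=int(r["order"]),
            base_xyz=np.array([r["base_x_m"], r["base_y_m"], r["base_z_m"]]),
            tip_xyz=np.array([r["tip_x_m"], r["tip_y_m"], r["tip_z_m"]]),
            diameter_m=float(r["diameter_m"]),
            fine_root_count=int(r["fine_root_count"]),
            fine_root_mean_length_m=float(r["fine_root_mean_length_m"]),
        )
        if seg.diameter_m < 0:
            raise ValidationError(f"negative diameter for segment {seg.segment_id!r}")
        segments[seg.segment_id] = seg
    segments = {k: segments[k] for k in sorted(segments)}
    rs = RootSystem(segments=segments, container=container, **meta)
    rs.root()
    return rs
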