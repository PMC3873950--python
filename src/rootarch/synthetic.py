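"""Synthetic container-grown seedling root systems.

The generator is phenomenological: it samples a final architecture
matching the measured growth habit of container-grown taprooted
seedlings — one thick, near-vertical gravitropic taproot tapering with
depth, shallow laterals running nearly parallel to the soil surface,
higher-order branching between herringbone and dichotomous extremes,
optional azimuthal anisotropy, and deflection along the 0.30 x 0.30 x
0.11 m container walls.  It is not a growth simulator.

Every stochastic choice flows from ``GeneratorConfig.seed``, and the
generation-time ground truth (true straight-growth tips of deflected
axes, the herringbone weight, the azimuth distribution parameters, the
ideal taproot direction) is attached to the returned system so that
downstream geometry, classification and topology code can be tested by
parameter recovery.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .model import Box, RootSegment, RootSystem, ValidationError, Frame

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate",
    "generate_cohort",
    "study_group_configs",
    "even_lateral_config",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the generator; defaults emulate the study's seedlings.

    Rates and lengths are SI; azimuths/angles in degrees.  ``herringbone_weight``
    is the probability that a new higher-order branch extends the main
    chain of its arborescence (1 = pure herringbone, 0 = maximally
    balanced insertion, giving qb = 0 for power-of-two tip counts).
    """

    seed: int = 0
    plant_id: str = "P1"
    slope_deg: float = 0.0
    flexed: bool = False
    block: str = "B1"
    container: Box = field(default_factory=Box)
    wall_behaviour: str = "deflect"  # deflect | clip

    n_laterals: int = 12
    azimuth_mode: str = "uniform"  # uniform | vonmises | stratified
    azimuth_mu_deg: float = 0.0
    azimuth_kappa: float = 0.0

    herringbone_weight: float = 0.8
    tips_per_lateral: Optional[int] = None  # fixed tip count; else 1 + Poisson
    extra_tips_mean: float = 0.5

    taproot_length_m: float = 0.10
    taproot_basal_diameter_m: float = 0.008
    taproot_taper_pct_per_cm: float = 6.0
    taproot_gravitropism: float = 0.5
    taproot_jitter_deg: float = 2.0

    lateral_mean_length_m: float = 0.12
    lateral_length_sd_m: float = 0.03
    lateral_taper_pct_per_cm: float = 3.0
    lateral_angle_mean_deg: float = -8.0
    lateral_angle_sd_deg: float = 6.0
    origin_depth_weights: tuple = (0.60, 0.28, 0.12)  # shallow/intermediate/deep
    child_length_frac: float = 0.45
    branch_azimuth_offset_deg: float = 70.0
    branch_azimuth_sd_deg: float = 15.0

    p_branch_target: float = 1.15
    q_target: float = 0.70

    segment_length_m: float = 0.02
    dir_jitter_deg: float = 5.0

    fine_root_rate_per_cm: float = 0.08
    fine_root_mean_length_m: float = 0.02

    dry_weight_density_g_cm3: float = 0.5
    shoot_root_ratio: float = 4.0


@dataclass
class GroundTruth:
    """What the generator knows that the measurement pipeline must recover."""

    config: GeneratorConfig
    taproot_ideal_direction: np.ndarray
    taproot_ideal_angle_deg: float
    lateral_azimuths_deg: list
    herringbone_weight: float
    azimuth_mode: str
    azimuth_mu_deg: float
    azimuth_kappa: float
    true_tips: dict  # axis_id -> straight-growth tip (no container walls)
    deflected_axes: list


# ----------------------------------------------------------- growth core
def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _dir_from(az_deg: float, angle_deg: float) -> np.ndarray:
    h = math.cos(math.radians(angle_deg))
    return np.array(
        [
            h * math.cos(math.radians(az_deg)),
            h * math.sin(math.radians(az_deg)),
            math.sin(math.radians(angle_deg)),
        ]
    )


def _jitter(rng: np.random.Generator, d: np.ndarray, sigma_deg: float) -> np.ndarray:
    if sigma_deg <= 0:
        return d
    r = rng.standard_normal(3)
    r -= (r @ d) * d
    n = np.linalg.norm(r)
    if n < 1e-12:
        return d
    r /= n
    a = math.radians(rng.normal(0.0, sigma_deg))
    return _unit(math.cos(a) * d + math.sin(a) * r)


def _constrained_dir(pos: np.ndarray, d: np.ndarray, box: Box) -> np.ndarray:
    """Project a direction onto any container face the point presses against."""
    out = d.copy()
    for ax, coord, inward in box.faces():
        if abs(pos[ax] - coord) < 1e-9 and float(out @ inward) < 0:
            out = out - (out @ -inward) * -inward
    n = np.linalg.norm(out)
    return out / n if n > 1e-9 else np.zeros(3)


def _first_exit(pos: np.ndarray, d: np.ndarray, L: float, box: Box) -> Optional[float]:
    """Fraction of the step at which the path first crosses a face, else None."""
    best = None
    for ax, coord, inward in box.faces():
        step = d[ax] * L
        if step * (-inward[ax]) <= 0:  # not moving toward this face
            continue
        t = (coord - pos[ax]) / step
        if 1e-9 < t < 1.0 - 1e-12:
            best = t if best is None else min(best, t)
    end = pos + d * L
    if best is None and not box.contains(end, tol=1e-9):
        return 1.0  # numerically grazing; treat the endpoint as the contact
    return best


def _grow(
    rng: np.random.Generator,
    base: np.ndarray,
    d0: np.ndarray,
    total_len: float,
    step: float,
    jitter_deg: float,
    box: Box,
    behaviour: str,
):
    """Grow a polyline of given curvilinear length inside the container.

    Returns (vertices, true straight-growth tip, deflected?).  On hitting
    a face the path is split exactly at the intersection and, for
    ``deflect``, slides within the face; for ``clip`` it stops there.
    The true tip integrates the intended (unconstrained) directions.
    """
    pos = base.astype(float).copy()
    free = _unit(d0.astype(float))
    verts = [pos.copy()]
    true_pos = pos.copy()
    remaining = total_len
    deflected = False
    while remaining > 1e-9:
        L = min(step, remaining)
        free = _jitter(rng, free, jitter_deg)
        true_pos = true_pos + free * L
        seg_rem = L
        guard = 0
        while seg_rem > 1e-9 and guard < 8:
            guard += 1
            d = _constrained_dir(pos, free, box)
            if np.linalg.norm(d) < 1e-9:
                return np.array(verts), true_pos, deflected
            t = _first_exit(pos, d, seg_rem, box)
            if t is None:
                pos = pos + d * seg_rem
                verts.append(pos.copy())
                seg_rem = 0.0
            else:
                contact = pos + d * (t * seg_rem)
                # snap exactly onto the face for robust downstream detection
                for ax, coord, _n in box.faces():
                    if abs(contact[ax] - coord) < 1e-7:
                        contact[ax] = coord
                if np.linalg.norm(contact - pos) > 1e-9:
                    verts.append(contact.copy())
                pos = contact
                seg_rem -= t * seg_rem
                deflected = True
                if behaviour == "clip":
                    return np.array(verts), true_pos, deflected
        remaining -= L
    return np.array(verts), true_pos, deflected


# ------------------------------------------------------- topology shapes
class _Node:
    __slots__ = ("left", "right")

    def __init__(self):
        self.left = None
        self.right = None

    @property
    def is_leaf(self):
        return self.left is None


def _build_topology(n_tips: int, h: float, rng: np.random.Generator) -> _Node:
    """Binary branching shape with n_tips exterior links.

    Each added tip splits either the current main-chain tip (probability
    ``h``; pure herringbone at h = 1) or a leaf of minimal depth
    (balanced insertion; a complete tree for power-of-two tip counts at
    h = 0).
    """
    root = _Node()
    for _ in range(n_tips - 1):
        if h >= 1.0 or (h > 0.0 and rng.random() < h):
            target = root
            while not target.is_leaf:
                target = target.right
        else:
            # breadth-first search for the shallowest leaf
            queue = [root]
            target = None
            while queue:
                node = queue.pop(0)
                if node.is_leaf:
                    target = node
                    break
                queue.extend([node.left, node.right])
        target.left = _Node()
        target.right = _Node()
    return root


def _spine(node: _Node) -> list[_Node]:
    """Internal nodes along the rightmost path (the axis's own branches)."""
    out = []
    cur = node
    while not cur.is_leaf:
        out.append(cur)
        cur = cur.right
    return out


# -------------------------------------------------------------- generate
class _Builder:
    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.segments: dict[str, RootSegment] = {}
        self.true_tips: dict[str, np.ndarray] = {}
        self.deflected: list[str] = []
        self._seg_n = 0
        self._axis_n = 0

    def new_axis(self) -> str:
        self._axis_n += 1
        return f"A{self._axis_n}"

    def add_segment(self, **kw) -> RootSegment:
        self._seg_n += 1
        seg = RootSegment(segment_id=f"S{self._seg_n:04d}", **kw)
        self.segments[seg.segment_id] = seg
        return seg

    def chain(
        self,
        axis_id: str,
        order: int,
        verts: np.ndarray,
        diam_at,
        first_parent: Optional[str],
    ) -> list[RootSegment]:
        cum = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(verts, axis=0), axis=1))]
        )
        segs = []
        parent = first_parent
        for i in range(len(verts) - 1):
            d = diam_at(cum[i])
            if d <= 0:
                raise ValidationError(
                    "configuration implies a non-positive diameter "
                    f"(axis {axis_id}, s = {cum[i]:.3f} m)"
                )
            seg = self.add_segment(
                parent_id=parent,
                axis_id=axis_id,
                order=order,
                base_xyz=verts[i],
                tip_xyz=verts[i + 1],
                diameter_m=float(d),
            )
            segs.append(seg)
            parent = seg.segment_id
        return segs


def _insert_s(verts: np.ndarray, targets: list[float]) -> np.ndarray:
    """Refine a polyline so each curvilinear target has an exact vertex."""
    for s in sorted(targets):
        cum = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(verts, axis=0), axis=1))]
        )
        if any(abs(cum - s) < 5e-4):
            continue
        i = int(np.searchsorted(cum, s)) - 1
        if i < 0 or i >= len(verts) - 1:
            continue
        t = (s - cum[i]) / (cum[i + 1] - cum[i])
        p = verts[i] + t * (verts[i + 1] - verts[i])
        verts = np.vstack([verts[: i + 1], p, verts[i + 1 :]])
    return verts


def generate(cfg: GeneratorConfig) -> RootSystem:
    """Generate one container-grown root system (deterministic per seed)."""
    rng = np.random.default_rng(cfg.seed)
    b = _Builder(cfg, rng)
    box = cfg.container

    # ---- order-1 root: gravitropic taproot -------------------------------
    s_rad = math.radians(cfg.slope_deg)
    gravity = np.array([-math.sin(s_rad), 0.0, -math.cos(s_rad)])
    ideal = _unit(
        cfg.taproot_gravitropism * gravity
        + (1 - cfg.taproot_gravitropism) * np.array([0.0, 0.0, -1.0])
    )
    collar = np.zeros(3)
    verts, true_tip, defl = _grow(
        rng,
        collar,
        ideal,
        cfg.taproot_length_m,
        cfg.segment_length_m,
        cfg.taproot_jitter_deg,
        box,
        cfg.wall_behaviour,
    )
    cum = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(verts, axis=0), axis=1))])
    o1_len = float(cum[-1])

    # lateral origin positions along the taproot, by depth class of origin
    def s_for_depth_class(cls: str) -> float:
        z = np.interp(np.linspace(0, o1_len, 200), cum, verts[:, 2])
        s_grid = np.linspace(0, o1_len, 200)
        if cls == "shallow":
            mask = z > -0.035
        elif cls == "intermediate":
            mask = (z <= -0.035) & (z > -0.070)
        else:
            mask = z <= -0.070
        mask &= (s_grid > 0.008) & (s_grid < o1_len - 0.005)
        cand = s_grid[mask]
        if cand.size == 0:  # class unreachable on this taproot: go shallow
            cand = s_grid[(s_grid > 0.008) & (s_grid < o1_len - 0.005)]
        return float(rng.uniform(cand.min(), cand.max()))

    if cfg.azimuth_mode == "stratified":
        # identical laterals: one shared shallow origin so every lateral has
        # the same basal diameter, length and shape up to rotation
        s0 = round(min(0.020, o1_len / 3.0), 4)
        origins = [s0] * cfg.n_laterals
    else:
        classes = rng.choice(
            ["shallow", "intermediate", "deep"],
            size=cfg.n_laterals,
            p=np.asarray(cfg.origin_depth_weights) / sum(cfg.origin_depth_weights),
        )
        origins = sorted(round(s_for_depth_class(c), 4) for c in classes)
    verts = _insert_s(verts, origins)
    cum = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(verts, axis=0), axis=1))])

    d0 = cfg.taproot_basal_diameter_m
    t1 = cfg.taproot_taper_pct_per_cm

    def tap_diam(s: float) -> float:
        return d0 * (1.0 - t1 * (s * 100.0) / 100.0)

    if tap_diam(o1_len) <= 0:
        raise ValidationError("taproot taper and length imply a negative diameter")
    o1_axis = b.new_axis()
    o1_segs = b.chain(o1_axis, 1, verts, tap_diam, None)
    b.true_tips[o1_axis] = true_tip
    if defl:
        b.deflected.append(o1_axis)

    # azimuths
    n = cfg.n_laterals
    if cfg.azimuth_mode == "stratified":
        azimuths = [(180.0 / n + k * 360.0 / n) % 360.0 for k in range(n)]
    elif cfg.azimuth_mode == "vonmises":
        azimuths = [
            math.degrees(rng.vonmises(math.radians(cfg.azimuth_mu_deg), cfg.azimuth_kappa))
            % 360.0
            for _ in range(n)
        ]
    else:
        azimuths = [float(rng.uniform(0.0, 360.0)) for _ in range(n)]

    # ---- lateral arborescences -------------------------------------------
    def find_parent_seg(s_origin: float) -> RootSegment:
        c = 0.0
        for seg in o1_segs:
            c += seg.length_m
            if c >= s_origin - 5e-4:
                return seg
        return o1_segs[-1]

    def realize(node: _Node, base, parent_id, order, az, angle, length, d_basal):
        axis_id = b.new_axis()
        vv, tt, dd = _grow(
            rng,
            np.asarray(base, dtype=float),
            _dir_from(az, angle),
            length,
            cfg.segment_length_m,
            cfg.dir_jitter_deg,
            box,
            cfg.wall_behaviour,
        )
        cc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(vv, axis=0), axis=1))])
        actual_len = float(cc[-1])
        spine = _spine(node)
        k = len(spine)
        s_branch = [actual_len * (j + 1) / (k + 1) for j in range(k)] if k else []
        vv = _insert_s(vv, s_branch)
        cc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(vv, axis=0), axis=1))])

        tw = cfg.lateral_taper_pct_per_cm
        p_t, q_t = cfg.p_branch_target, cfg.q_target
        # piecewise diameter: within-taper between events, CSA jumps at events
        ev = sorted(zip(s_branch, spine), key=lambda x: x[0])

        def diam_profile(s: float, pre_event: bool = False) -> float:
            # pre_event=True returns the diameter just before the CSA drop of
            # an event located exactly at s
            d = d_basal
            last = 0.0
            for s_e, _node_e in ev:
                passed = (s > s_e + 5e-4) if pre_event else (s >= s_e - 5e-4)
                if passed:
                    d = d * (1.0 - tw * (s_e - last) * 100.0 / 100.0)
                    d = d * math.sqrt(q_t / p_t)
                    last = s_e
                else:
                    break
            d = d * (1.0 - tw * (max(s - last, 0.0)) * 100.0 / 100.0)
            return d

        segs = b.chain(axis_id, order, vv, diam_profile, parent_id)
        b.true_tips[axis_id] = tt
        if dd:
            b.deflected.append(axis_id)
        # children at branch vertices
        ccum = 0.0
        vert_s = cc
        for s_e, node_e in ev:
            i = int(np.argmin(np.abs(vert_s - s_e)))
            i = max(1, min(i, len(segs)))
            parent_seg = segs[i - 1]
            d_here = diam_profile(s_e, pre_event=True)
            d_child = d_here * math.sqrt(max(1.0 - q_t, 1e-6) / p_t)
            if cfg.branch_azimuth_sd_deg > 0 or cfg.dir_jitter_deg > 0:
                off = rng.normal(cfg.branch_azimuth_offset_deg, cfg.branch_azimuth_sd_deg)
                sign = 1.0 if rng.random() < 0.5 else -1.0
                c_angle = rng.normal(cfg.lateral_angle_mean_deg, cfg.lateral_angle_sd_deg)
            else:
                off, sign, c_angle = cfg.branch_azimuth_offset_deg, 1.0, cfg.lateral_angle_mean_deg
            realize(
                node_e.left,
                parent_seg.tip_xyz,
                parent_seg.segment_id,
                order + 1,
                (az + sign * off) % 360.0,
                c_angle,
                length * cfg.child_length_frac,
                d_child,
            )

    randomize = cfg.azimuth_mode != "stratified"
    for s_origin, az in zip(origins, azimuths):
        parent_seg = find_parent_seg(s_origin)
        if cfg.tips_per_lateral is not None:
            n_tips = cfg.tips_per_lateral
        else:
            n_tips = 1 + int(rng.poisson(cfg.extra_tips_mean))
        node = _build_topology(n_tips, cfg.herringbone_weight, rng)
        if randomize and cfg.lateral_length_sd_m > 0:
            length = max(0.03, rng.normal(cfg.lateral_mean_length_m, cfg.lateral_length_sd_m))
        else:
            length = cfg.lateral_mean_length_m
        if randomize and cfg.lateral_angle_sd_deg > 0:
            angle = rng.normal(cfg.lateral_angle_mean_deg, cfg.lateral_angle_sd_deg)
        else:
            angle = cfg.lateral_angle_mean_deg
        d_lat = tap_diam(s_origin) * math.sqrt(
            max(1.0 - cfg.q_target, 1e-6) / cfg.p_branch_target
        )
        realize(node, parent_seg.tip_xyz, parent_seg.segment_id, 2, az, angle, length, d_lat)

    # ---- additional fine roots -------------------------------------------
    if cfg.fine_root_rate_per_cm > 0:
        for seg in b.segments.values():
            lam = cfg.fine_root_rate_per_cm * seg.length_m * 100.0
            k = int(rng.poisson(lam))
            if k:
                seg.fine_root_count = k
                seg.fine_root_mean_length_m = float(
                    max(0.002, rng.normal(cfg.fine_root_mean_length_m, 0.005))
                )

    segments = {k: b.segments[k] for k in sorted(b.segments)}
    rs = RootSystem(
        segments=segments,
        plant_id=cfg.plant_id,
        slope_deg=cfg.slope_deg,
        flexed=cfg.flexed,
        block=cfg.block,
        container=box,
    )
    # dry weights from volume via a configured tissue density
    from .geometry import segment_volume
    from .compartments import stump_volume

    vol_cm3 = sum(segment_volume(rs, s) for s in rs.segments.values()) * 1e6
    vol_excl = vol_cm3 - stump_volume(rs) * 1e6
    rs.root_dry_weight_g = cfg.dry_weight_density_g_cm3 * vol_excl
    rs.shoot_dry_weight_g = rs.root_dry_weight_g * cfg.shoot_root_ratio
    rs.ground_truth = GroundTruth(
        config=cfg,
        taproot_ideal_direction=ideal,
        taproot_ideal_angle_deg=Frame.angle_to_surface_deg(ideal),
        lateral_azimuths_deg=list(azimuths),
        herringbone_weight=cfg.herringbone_weight,
        azimuth_mode=cfg.azimuth_mode,
        azimuth_mu_deg=cfg.azimuth_mu_deg,
        azimuth_kappa=cfg.azimuth_kappa,
        true_tips=b.true_tips,
        deflected_axes=b.deflected,
    )
    return rs


def even_lateral_config(n: int = 8, seed: int = 0, **overrides) -> GeneratorConfig:
    """A deterministic system with n identical, evenly spaced shallow laterals.

    Azimuths sit at 180/n + k*360/n degrees, away from every sector
    boundary, so sector shares of volume, length and number are exact.
    """
    base = dict(
        seed=seed,
        n_laterals=n,
        azimuth_mode="stratified",
        tips_per_lateral=1,
        lateral_length_sd_m=0.0,
        lateral_angle_sd_deg=0.0,
        lateral_angle_mean_deg=-5.0,
        lateral_mean_length_m=0.10,
        dir_jitter_deg=0.0,
        taproot_jitter_deg=0.0,
        taproot_gravitropism=0.0,
        origin_depth_weights=(1.0, 0.0, 0.0),
        fine_root_rate_per_cm=0.0,
        branch_azimuth_sd_deg=0.0,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def study_group_configs(
    base: Optional[GeneratorConfig] = None,
    slope_kappa: float = 2.0,
    slope_mu_deg: float = 90.0,
    slope_flexed_mu_deg: float = 0.0,
    flexed_taproot_scale: float = 1.25,
    flexed_lateral_scale: float = 0.85,
    flexed_extra_laterals: int = 6,
) -> dict[str, GeneratorConfig]:
    """The four treatment-group configurations of the 2 x 2 design.

    Slope groups get von-Mises azimuth anisotropy (perpendicular-dominant
    on the plain slope, upslope-shifted when also flexed); flexed groups
    get a thicker, shorter taproot and thinner, more numerous laterals —
    the directions of plasticity the study reports.
    """
    if base is None:
        base = GeneratorConfig()
    flex = dict(
        flexed=True,
        taproot_basal_diameter_m=base.taproot_basal_diameter_m * flexed_taproot_scale,
        taproot_length_m=base.taproot_length_m * 0.9,
        lateral_mean_length_m=base.lateral_mean_length_m * 1.15,
        n_laterals=base.n_laterals + flexed_extra_laterals,
    )
    return {
        "control": base,
        "slope": replace(
            base,
            slope_deg=45.0,
            azimuth_mode="vonmises",
            azimuth_mu_deg=slope_mu_deg,
            azimuth_kappa=slope_kappa,
        ),
        "flexed": replace(base, **flex),
        "slope_flexed": replace(
            base,
            slope_deg=45.0,
            azimuth_mode="vonmises",
            azimuth_mu_deg=slope_flexed_mu_deg,
            azimuth_kappa=slope_kappa * 0.75,
            **flex,
        ),
    }


def generate_cohort(
    group_configs: Optional[dict[str, GeneratorConfig]] = None,
    n_per_group: int = 8,
    seed: int = 0,
    n_blocks: int = 2,
):
    """A balanced cohort across treatment groups with block labels.

    Returns (list of RootSystem, metadata DataFrame).  Per-plant seeds are
    spawned from ``seed`` so cohorts are reproducible and plants
    independent.
    """
    if group_configs is None:
        group_configs = study_group_configs()
    systems = []
    meta = []
    for gi, (gname, gcfg) in enumerate(group_configs.items()):
        for i in range(n_per_group):
            child_seed = int(
                np.random.SeedSequence([seed, gi, i]).generate_state(1)[0] % (2**31)
            )
            cfg = replace(
                gcfg,
                seed=child_seed,
                plant_id=f"{gname}_{i + 1}",
                block=f"B{(i % n_blocks) + 1}",
            )
            rs = generate(cfg)
            systems.append(rs)
            meta.append(
                {
                    "plant_id": rs.plant_id,
                    "group": gname,
                    "slope_deg": rs.slope_deg,
                    "flexed": rs.flexed,
                    "block": rs.block,
                    "seed": child_seed,
                }
            )
    return systems, pd.DataFrame(meta)
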