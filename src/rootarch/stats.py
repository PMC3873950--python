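"""The study's statistical layer over the per-plant trait battery.

* :func:`build_trait_table` runs the whole measurement pipeline per plant
  and assembles the plant x trait matrix (missing values are explicit
  NaN, never silent zeros).
* :func:`anova_by_trait` fits, per trait, the three-way fixed-effects
  model  Y ~ Slope + Flexing + Block + Slope:Flexing  and reports
  sequential (Type I) tests; residual normality is checked with the
  Shapiro test and non-normal traits walk the none -> log -> rank
  transformation ladder.  Group means and % variation against the
  control are always computed on the untransformed scale.
* :func:`sector_mixed_model` tests circular heterogeneity per
  compartment with a mixed model (sector fixed, tree random, REML),
  halving the perpendicular sector's value for additive quantities
  (volume, length, number) because it spans two quadrants; pairwise
  sector contrasts feed a compact letter display.
* :func:`pca_traits` is the centred, unit-variance PCA of selected
  traits.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.decomposition import PCA

from .model import RootSystem
from . import compartments as comp
from . import geometry as geo
from . import topology as topo

__all__ = [
    "plant_traits",
    "build_trait_table",
    "AnovaResult",
    "anova_by_trait",
    "SectorModelResult",
    "sector_mixed_model",
    "build_sector_table",
    "PcaResult",
    "pca_traits",
    "DEFAULT_PCA_TRAITS",
    "significance_stars",
]

META_COLS = ("plant_id", "slope_deg", "flexed", "block", "group")


def _nanmean(vals) -> float:
    vals = [v for v in vals if v is not None and np.isfinite(v)]
    return float(np.mean(vals)) if vals else float("nan")


def plant_traits(
    rs: RootSystem,
    zrt_limit_m: float = comp.ZRT_LIMIT_M,
    include_fine_roots: bool = True,
    wall_correct: bool = True,
    solid: str = "frustum",
) -> dict:
    """The full per-plant trait battery (field units: cm, cm3, g, deg, %)."""
    if wall_correct:
        rs = geo.extend_wall_roots(rs)
    axes = rs.axes()
    root_axis = rs.axis_of_root()
    infos = comp.arborescence_info(rs)
    labeled = comp.classify_system(rs, zrt_limit_m=zrt_limit_m, solid=solid)
    counts = topo.counts_and_specifics(rs, solid=solid)
    frac = topo.fractal_params(rs)
    lateral_axes = [a for a in axes if a != root_axis]
    g = {a: geo.axis_geometry(rs, a, solid=solid) for a in axes}

    t: dict = {}
    # ---------------- general size and allocation -------------------------
    vol_excl = counts["total_volume_m3"] * 1e6
    t["total_volume_cm3"] = vol_excl
    t["stump_volume_cm3"] = counts["stump_volume_m3"] * 1e6
    t["root_dry_weight_g"] = rs.root_dry_weight_g if rs.root_dry_weight_g is not None else np.nan
    t["shoot_dry_weight_g"] = rs.shoot_dry_weight_g if rs.shoot_dry_weight_g is not None else np.nan
    t["rpc_biomass_pct"] = counts["rpc_biomass_pct"]
    t["rpc_excl_order1_pct"] = counts["rpc_excl_order1_pct"]
    t["taproot_pc_pct"] = counts["taproot_pc_pct"]
    t["stump_pc_pct"] = counts["stump_pc_pct"]
    t["root_density_g_cm3"] = counts["root_density_g_per_cm3"]
    t["root_number"] = counts["root_number"]
    t["root_number_iafr"] = counts["root_number_iafr"]
    t["srn_iafr_per_g"] = counts["srn_per_g"]
    t["total_length_cm"] = counts["total_length_m"] * 100.0
    t["total_length_iafr_cm"] = counts["total_length_iafr_m"] * 100.0

    o1 = axes[root_axis]
    o1_geo = g[root_axis]
    t["order1_length_cm"] = o1_geo.length_m * 100.0
    o1_vol_cm3 = o1_geo.volume_m3 * 1e6
    t["srl_order1_cm_cm3"] = (o1_geo.length_m * 100.0) / o1_vol_cm3 if o1_vol_cm3 > 0 else np.nan
    lat_len = sum(g[a].length_m for a in lateral_axes) * 100.0
    fine_len = (counts["total_length_iafr_m"] - counts["total_length_m"]) * 100.0
    lat_vol = sum(g[a].volume_m3 for a in lateral_axes) * 1e6
    t["srl_laterals_iafr_cm_cm3"] = (lat_len + fine_len) / lat_vol if lat_vol > 0 else np.nan
    t["mean_tip_diameter_cm"] = _nanmean([g[a].tip_diameter_m * 100.0 for a in lateral_axes])

    verts_all = np.vstack([s.tip_xyz for s in rs.segments.values()])
    t["max_radial_distance_cm"] = float(np.max(np.hypot(verts_all[:, 0], verts_all[:, 1])) * 100.0)
    t["max_depth_cm"] = float(np.min(verts_all[:, 2]) * 100.0)

    # ---------------- compartment relative volumes ------------------------
    vol_by_pool: dict[str, float] = {}
    for vs in labeled:
        vol_by_pool[vs.pooled] = vol_by_pool.get(vs.pooled, 0.0) + vs.volume_m3
    total_incl = sum(vol_by_pool.values())
    stump_v = vol_by_pool.get("stump", 0.0)
    denom = total_incl - stump_v
    t["rv_stump_pct"] = 100.0 * stump_v / total_incl if total_incl > 0 else np.nan
    for pool, key in [
        ("taproot", "rv_taproot_pct"),
        ("zrt", "rv_zrt_pct"),
        ("shallow_beyond_zrt", "rv_beyond_zrt_pct"),
        ("intermediate", "rv_intermediate_pct"),
        ("deep", "rv_deep_pct"),
    ]:
        t[key] = 100.0 * vol_by_pool.get(pool, 0.0) / denom if denom > 0 else np.nan

    # relative volume of order-3+ roots
    o3_vol = sum(g[a].volume_m3 for a in lateral_axes if g[a].order >= 3) * 1e6
    t["rv_order3_pct"] = 100.0 * o3_vol / vol_excl if vol_excl > 0 else np.nan

    # ---------------- per-group axis dimensions ---------------------------
    def arbo_group(aid: str) -> str:
        c = infos[aid].compartment
        if c in (3, 4):
            return "shallow"
        return comp.POOLED[c] if c not in (5,) else "taproot"

    groups = {"shallow": [], "intermediate": [], "deep": []}
    for a in lateral_axes:
        grp = arbo_group(a)
        if grp in groups:
            groups[grp].append(a)
    for grp, ids in groups.items():
        t[f"mean_axis_length_{grp}_cm"] = _nanmean([g[a].length_m * 100.0 for a in ids])
        t[f"mean_axis_diameter_{grp}_cm"] = _nanmean([g[a].mean_diameter_m * 100.0 for a in ids])
        t[f"mean_axis_volume_{grp}_cm3"] = _nanmean([g[a].volume_m3 * 1e6 for a in ids])

    zrt_vol_cm3 = vol_by_pool.get("zrt", 0.0) * 1e6
    n_shallow = len(groups["shallow"])
    t["mean_axis_volume_zrt_cm3"] = zrt_vol_cm3 / n_shallow if n_shallow else np.nan

    # ---------------- tapers ----------------------------------------------
    on_stump = [a for a in lateral_axes if g[a].order == 2 and infos[a].on_stump]
    below_stump = [a for a in lateral_axes if g[a].order == 2 and not infos[a].on_stump]
    t["taper_order1_pct_cm"] = o1_geo.proximal_taper_pct_per_cm
    t["taper_order2_on_stump_pct_cm"] = _nanmean([g[a].proximal_taper_pct_per_cm for a in on_stump])
    t["taper_order2_below_stump_pct_cm"] = _nanmean([g[a].proximal_taper_pct_per_cm for a in below_stump])
    t["taper_laterals_pct_cm"] = _nanmean([g[a].proximal_taper_pct_per_cm for a in lateral_axes])

    # ---------------- topology and fractal parameters ---------------------
    iafr = include_fine_roots
    t["qb_total_iafr"] = topo.qb(rs, include_fine_roots=iafr)
    by_depth = {"shallow": set(), "intermediate": set(), "deep": set()}
    for a in lateral_axes:
        info = infos[a]
        by_depth[info.depth_class].add(info.root_axis_id)
    for cls, arbos in by_depth.items():
        t[f"qb_{cls}_iafr"] = (
            topo.qb(rs, include_fine_roots=iafr, allowed_arborescences=arbos)
            if arbos
            else np.nan
        )
        t[f"mbo_{cls}_iafr"] = (
            topo.mbo(
                rs,
                [a for a in lateral_axes if infos[a].root_axis_id in arbos],
                include_fine_roots=iafr,
            )
            if arbos
            else np.nan
        )
    t["mbo_total_iafr"] = topo.mbo(rs, include_fine_roots=iafr)
    for sc in ("stump", "taproot", "laterals"):
        t[f"p_branch_{sc}"] = frac[f"p_branch_{sc}"]
        t[f"p_within_{sc}"] = frac[f"p_within_{sc}"]
        t[f"q_{sc}"] = frac[f"q_{sc}"]

    # ---------------- branching intervals ---------------------------------
    stump_ill = topo.inter_lateral_length(rs, root_axis, include_fine_roots=iafr)
    t["ill_order1_iafr_cm"] = stump_ill * 100.0 if stump_ill is not None else np.nan
    ills = [topo.inter_lateral_length(rs, a, include_fine_roots=iafr) for a in lateral_axes if g[a].order == 2]
    t["ill_order2_iafr_cm"] = _nanmean([x * 100.0 for x in ills if x is not None])
    auls = [apl for a in axes if (apl := topo.apical_unbranched_length(rs, a)) is not None]
    t["apical_unbranched_cm"] = _nanmean([x * 100.0 for x in auls])

    # ---------------- angles and straightness ------------------------------
    tap_angle, _fl = geo.taproot_angle(rs)
    t["taproot_angle_deg"] = tap_angle
    t["branching_angle_order2_on_stump_deg"] = _nanmean([g[a].branching_angle_deg for a in on_stump])
    t["branching_angle_order2_below_stump_deg"] = _nanmean([g[a].branching_angle_deg for a in below_stump])
    sh_on = [a for a in on_stump if arbo_group(a) == "shallow"]
    sh_below = [a for a in below_stump if arbo_group(a) == "shallow"]
    t["angle_surface_shallow_on_stump_deg"] = _nanmean([g[a].angle_to_surface_deg for a in sh_on])
    t["angle_surface_shallow_below_stump_deg"] = _nanmean([g[a].angle_to_surface_deg for a in sh_below])
    o2 = [a for a in lateral_axes if g[a].order == 2]
    t["rdd_order2_deg"] = _nanmean([g[a].rdd_deg for a in o2])
    t["winding_order2_on_stump"] = _nanmean([g[a].winding for a in on_stump])
    t["winding_order2_below_stump"] = _nanmean([g[a].winding for a in below_stump])

    # ---------------- circular distribution summaries ----------------------
    zrt_shares = comp.sector_shares(labeled, compartment="zrt", quantity="volume")
    t["rvol_up_zrt_pct"] = zrt_shares["us"] if zrt_shares else np.nan
    sh_shares = comp.sector_shares(
        [vs for vs in labeled if vs.pooled in ("zrt", "shallow_beyond_zrt")],
        quantity="volume",
    )
    t["rvol_perp_shallow_pct"] = sh_shares["pp"] if sh_shares else np.nan
    all_shares = comp.sector_shares(labeled, quantity="volume")
    t["reinforcement_up_volume_pct"] = comp.reinforcement(all_shares["us"]) if all_shares else np.nan
    t["reinforcement_down_volume_pct"] = comp.reinforcement(all_shares["ds"]) if all_shares else np.nan
    return t


def build_trait_table(
    cohort: Sequence[RootSystem],
    metadata: Optional[pd.DataFrame] = None,
    **trait_kwargs,
) -> pd.DataFrame:
    """Assemble the plant x trait matrix for a cohort.

    Metadata columns (slope_deg, flexed, block, group) are taken from the
    systems themselves, optionally enriched from ``metadata``.  Duplicate
    plant ids are an error.
    """
    ids = [rs.plant_id for rs in cohort]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate plant ids: {dup}")
    rows = []
    for rs in cohort:
        row = {
            "plant_id": rs.plant_id,
            "slope_deg": rs.slope_deg,
            "flexed": rs.flexed,
            "block": rs.block,
        }
        row.update(plant_traits(rs, **trait_kwargs))
        rows.append(row)
    tt = pd.DataFrame(rows).set_index("plant_id")
    if metadata is not None and "group" in metadata.columns:
        tt = tt.join(metadata.set_index("plant_id")[["group"]])
    else:
        tt["group"] = [
            ("slope_flexed" if (r.slope_deg > 0 and r.flexed) else
             "slope" if r.slope_deg > 0 else
             "flexed" if r.flexed else "control")
            for r in cohort
        ]
    return tt


# ----------------------------------------------------------------- ANOVA
def significance_stars(p: float) -> str:
    """The study's levels: * <5%, ** <1%, *** <0.1%, **** <0.01%."""
    if not np.isfinite(p):
        return ""
    for stars, level in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < level:
            return stars
    return ""


@dataclass
class AnovaResult:
    trait: str
    transform: str  # none | log | rank
    shapiro_p: float
    p_slope: float
    p_flexing: float
    p_interaction: float
    p_block: float
    group_means: dict
    pct_variation: dict  # vs control, untransformed scale
    stars: dict = field(default_factory=dict)
    skipped: Optional[str] = None

    def __post_init__(self):
        if not self.stars:
            self.stars = {
                "slope": significance_stars(self.p_slope),
                "flexing": significance_stars(self.p_flexing),
                "interaction": significance_stars(self.p_interaction),
                "block": significance_stars(self.p_block),
            }


_FORMULA = "yt ~ C(slope) + C(flexing) + C(block) + C(slope):C(flexing)"


def anova_by_trait(
    tt: pd.DataFrame,
    traits: Optional[Iterable[str]] = None,
    shapiro_alpha: float = 0.05,
    ss_type: int = 1,
) -> list[AnovaResult]:
    """Sequential three-way ANOVA per trait with the transformation ladder.

    Type I (sequential) sums of squares in the model order Slope,
    Flexing, Block, Slope x Flexing — order-independent for balanced
    cohorts; pass ``ss_type=2`` for unbalanced data.  Constant traits are
    skipped with a note.  A warning is appropriate below two plants per
    treatment cell; the caller controls cohort size.
    """
    meta = {"slope", "flexed", "block", "group", "slope_deg"}
    if traits is None:
        traits = [c for c in tt.columns if c not in META_COLS and c not in meta and pd.api.types.is_numeric_dtype(tt[c])]
    out: list[AnovaResult] = []
    base = pd.DataFrame(
        {
            "slope": (tt["slope_deg"] > 0).astype(int).values,
            "flexing": tt["flexed"].astype(int).values,
            "block": tt["block"].astype(str).values,
        },
        index=tt.index,
    )
    groups = np.where(
        (base["slope"] == 1) & (base["flexing"] == 1), "slope_flexed",
        np.where(base["slope"] == 1, "slope", np.where(base["flexing"] == 1, "flexed", "control")),
    )
    for trait in traits:
        y = pd.to_numeric(tt[trait], errors="coerce")
        df = base.assign(y=y.values, grp=groups).dropna(subset=["y"])
        if df.empty or df["y"].nunique() <= 1:
            out.append(
                AnovaResult(trait, "none", np.nan, np.nan, np.nan, np.nan, np.nan, {}, {}, skipped="constant or empty trait")
            )
            continue
        chosen = None
        for transform in ("none", "log", "rank"):
            if transform == "log":
                if (df["y"] <= 0).any():
                    continue
                df["yt"] = np.log(df["y"])
            elif transform == "rank":
                df["yt"] = st.rankdata(df["y"])
            else:
                df["yt"] = df["y"]
            try:
                fit = smf.ols(_FORMULA, data=df).fit()
            except Exception:
                continue
            resid = fit.resid
            sp = st.shapiro(resid).pvalue if 3 <= len(resid) <= 5000 and resid.nunique() > 1 else 1.0
            chosen = (transform, fit, sp)
            if transform == "rank" or sp >= shapiro_alpha:
                break
        if chosen is None:
            out.append(AnovaResult(trait, "none", np.nan, np.nan, np.nan, np.nan, np.nan, {}, {}, skipped="model failed"))
            continue
        transform, fit, sp = chosen
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = sm.stats.anova_lm(fit, typ=ss_type)
        pv = table["PR(>F)"]
        means = df.groupby("grp")["y"].mean().to_dict()
        ctrl = means.get("control", np.nan)
        pct = {
            k: (100.0 * (v - ctrl) / ctrl if np.isfinite(ctrl) and ctrl != 0 else np.nan)
            for k, v in means.items()
            if k != "control"
        }
        out.append(
            AnovaResult(
                trait=trait,
                transform=transform,
                shapiro_p=float(sp),
                p_slope=float(pv.get("C(slope)", np.nan)),
                p_flexing=float(pv.get("C(flexing)", np.nan)),
                p_interaction=float(pv.get("C(slope):C(flexing)", np.nan)),
                p_block=float(pv.get("C(block)", np.nan)),
                group_means=means,
                pct_variation=pct,
            )
        )
    return out


def anova_results_frame(results: list[AnovaResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "trait": r.trait,
                "transform": r.transform,
                "shapiro_p": r.shapiro_p,
                "p_slope": r.p_slope,
                "p_flexing": r.p_flexing,
                "p_interaction": r.p_interaction,
                "p_block": r.p_block,
                "stars_slope": r.stars.get("slope", ""),
                "stars_flexing": r.stars.get("flexing", ""),
                **{f"mean_{k}": v for k, v in sorted(r.group_means.items())},
                **{f"pctvar_{k}": v for k, v in sorted(r.pct_variation.items())},
                "skipped": r.skipped or "",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------- sector mixed model
ADDITIVE_HINTS = ("volume", "length", "number", "n_axes", "count", "share")


@dataclass
class SectorModelResult:
    compartment: str
    variable: str
    p_sector: float
    contrast_p: dict  # ('us','pp') -> p, etc.
    letters: dict  # sector -> letter group string
    means: dict
    n_plants: int
    na: bool = False
    note: str = ""


def _compact_letters(order: list[str], different: dict) -> dict[str, str]:
    """Compact letter display: same letter = not significantly different."""
    cliques: list[set] = []
    items = list(order)
    # maximal non-different cliques, largest first
    from itertools import combinations

    for size in range(len(items), 0, -1):
        for sub in combinations(items, size):
            s = set(sub)
            if any(s <= c for c in cliques):
                continue
            ok = all(
                not different.get(frozenset((a_, b_)), False)
                for a_, b_ in combinations(sub, 2)
            )
            if ok:
                cliques.append(s)
    cliques.sort(key=lambda c: min(order.index(x) for x in c))
    letters = {lv: "" for lv in items}
    for i, c in enumerate(cliques):
        ch = chr(ord("a") + i)
        for lv in c:
            letters[lv] += ch
    return letters


def build_sector_table(
    cohort: Sequence[RootSystem],
    zrt_limit_m: float = comp.ZRT_LIMIT_M,
    include_fine_roots: bool = False,
) -> pd.DataFrame:
    """Stack per-plant sector aggregates for a cohort (long format)."""
    frames = [
        comp.sector_table(rs, zrt_limit_m=zrt_limit_m, include_fine_roots=include_fine_roots)
        for rs in cohort
    ]
    return pd.concat(frames, ignore_index=True)


def sector_mixed_model(
    sector_df: pd.DataFrame,
    variable: str,
    compartments_scope: Optional[Iterable[str]] = None,
    halve_pp: Optional[bool] = None,
    alpha: float = 0.05,
    min_presence_frac: float = 0.5,
) -> list[SectorModelResult]:
    """Mixed model per compartment: variable ~ sector (fixed) + tree (random).

    For additive quantities (volume, length, number) the perpendicular
    sector's value is divided by two before testing, since pp spans two
    of the four quadrants.  A compartment present in no more than half of
    the plants is reported NA.  Contrast p-values are unadjusted (a
    multiplicity option is deliberately not the default).
    """
    if halve_pp is None:
        halve_pp = any(h in variable.lower() for h in ADDITIVE_HINTS)
    if compartments_scope is None:
        compartments_scope = [c for c in sector_df["compartment"].unique()]
    out: list[SectorModelResult] = []
    n_plants_all = sector_df["plant_id"].nunique()
    for cname in compartments_scope:
        sub = sector_df[sector_df["compartment"] == cname][["plant_id", "sector", variable]].copy()
        sub = sub.rename(columns={variable: "value"})
        # presence: the plant has anything in this compartment
        pres = sub.groupby("plant_id")["value"].apply(
            lambda v: np.nansum(np.abs(v)) > 0 or v.notna().any() and v.abs().max() > 0
        )
        present_ids = pres[pres].index
        if len(present_ids) <= min_presence_frac * n_plants_all:
            out.append(
                SectorModelResult(cname, variable, np.nan, {}, {}, {}, len(present_ids), na=True,
                                  note="compartment absent in more than half the plants")
            )
            continue
        sub = sub[sub["plant_id"].isin(present_ids)].dropna(subset=["value"])
        sub["value"] = sub["value"].astype(float)
        if halve_pp:
            sub.loc[sub["sector"] == "pp", "value"] /= 2.0
        means = sub.groupby("sector")["value"].mean().to_dict()
        if sub["value"].nunique() <= 1:
            letters = {s: "a" for s in comp.SECTORS}
            out.append(
                SectorModelResult(cname, variable, 1.0, {}, letters, means, len(present_ids),
                                  note="no variation between sectors")
            )
            continue
        sub["sector"] = pd.Categorical(sub["sector"], categories=["us", "pp", "ds"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = None
            err = None
            for method in (None, "powell", "nm"):
                try:
                    md = smf.mixedlm("value ~ C(sector)", data=sub, groups=sub["plant_id"])
                    fit = md.fit(reml=True) if method is None else md.fit(reml=True, method=method)
                    break
                except Exception as e:
                    err = e
            if fit is None:  # pragma: no cover - degenerate inputs
                out.append(
                    SectorModelResult(cname, variable, np.nan, {}, {}, means, len(present_ids),
                                      na=True, note=f"fit failed: {err}")
                )
                continue
        fe = fit.fe_params
        cov = fit.cov_params().iloc[: len(fe), : len(fe)]
        names = list(fe.index)
        i_pp = names.index("C(sector)[T.pp]")
        i_ds = names.index("C(sector)[T.ds]")
        # Wald test of the 2-df sector factor
        L = np.zeros((2, len(fe)))
        L[0, i_pp] = 1.0
        L[1, i_ds] = 1.0
        b = L @ fe.values
        V = L @ cov.values @ L.T
        try:
            chi2 = float(b @ np.linalg.solve(V, b))
            p_sector = float(st.chi2.sf(chi2, df=2))
        except np.linalg.LinAlgError:
            p_sector = np.nan

        def contrast_p(c: np.ndarray) -> float:
            est = float(c @ fe.values)
            se = math.sqrt(float(c @ cov.values @ c))
            if se == 0:
                return 1.0
            return float(2 * st.norm.sf(abs(est) / se))

        c_us_pp = np.zeros(len(fe)); c_us_pp[i_pp] = -1.0
        c_us_ds = np.zeros(len(fe)); c_us_ds[i_ds] = -1.0
        c_pp_ds = np.zeros(len(fe)); c_pp_ds[i_pp] = 1.0; c_pp_ds[i_ds] = -1.0
        cps = {
            ("us", "pp"): contrast_p(c_us_pp),
            ("us", "ds"): contrast_p(c_us_ds),
            ("pp", "ds"): contrast_p(c_pp_ds),
        }
        if p_sector >= alpha or not np.isfinite(p_sector):
            letters = {s: "a" for s in ("us", "pp", "ds")}
        else:
            order = sorted(("us", "pp", "ds"), key=lambda s: -means.get(s, -np.inf))
            different = {
                frozenset(k): (v < alpha) for k, v in cps.items()
            }
            letters = _compact_letters(order, different)
        out.append(
            SectorModelResult(
                compartment=cname,
                variable=variable,
                p_sector=p_sector,
                contrast_p=cps,
                letters=letters,
                means=means,
                n_plants=len(present_ids),
            )
        )
    return out


# ------------------------------------------------------------------- PCA
DEFAULT_PCA_TRAITS = [
    "rpc_biomass_pct",
    "root_dry_weight_g",       # enters as its cube root (size proxy)
    "srn_iafr_per_g",
    "mean_axis_volume_zrt_cm3",
    "srl_laterals_iafr_cm_cm3",
    "qb_shallow_iafr",
    "ill_order1_iafr_cm",
    "srl_order1_cm_cm3",
    "rv_beyond_zrt_pct",
    "rv_taproot_pct",
    "rv_deep_pct",
    "rv_stump_pct",
    "rv_intermediate_pct",
    "rv_zrt_pct",
    "rvol_up_zrt_pct",
    "rvol_perp_shallow_pct",
    "root_number_iafr",
]


@dataclass
class PcaResult:
    scores: pd.DataFrame  # plants x components
    loadings: pd.DataFrame  # traits x components
    explained_pct: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca_traits(
    tt: pd.DataFrame,
    traits: Optional[Sequence[str]] = None,
    n_components: Optional[int] = None,
    missing: str = "drop",
) -> PcaResult:
    """Centred, unit-variance PCA of selected traits.

    ``missing='drop'`` removes plants with any missing selected trait;
    ``'mean'`` imputes column means.  Loading signs are oriented so each
    component's largest-magnitude loading is positive.
    """
    if traits is None:
        traits = [c for c in DEFAULT_PCA_TRAITS if c in tt.columns]
    X = tt[list(traits)].apply(pd.to_numeric, errors="coerce")
    if "root_dry_weight_g" in X.columns:
        X["root_dry_weight_g"] = np.cbrt(X["root_dry_weight_g"])
    if missing == "drop":
        X = X.dropna(axis=0, how="any")
    else:
        X = X.fillna(X.mean())
    X = X.loc[:, X.std(ddof=0) > 0]
    if X.shape[0] < 3:
        raise ValueError("PCA requires at least three plants with complete traits")
    Z = (X - X.mean()) / X.std(ddof=0)
    k = n_components or min(Z.shape)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Z.values)
    load = pca.components_.T  # traits x comps
    for j in range(load.shape[1]):
        i = int(np.argmax(np.abs(load[:, j])))
        if load[i, j] < 0:
            load[:, j] *= -1
            scores[:, j] *= -1
    cols = [f"PC{i+1}" for i in range(load.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=X.index, columns=cols),
        loadings=pd.DataFrame(load, index=X.columns, columns=cols),
        explained_pct=pca.explained_variance_ratio_ * 100.0,
    )
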