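"""End-to-end pipeline: inputs (MTG files or generator settings) to reports.

Writes, under the output directory: per-plant segment tables, the axis
table, the branch-event audit table, the trait table, the sector table,
ANOVA and sector-model reports, PCA scores/loadings and a QC log.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import compartments as comp
from . import geometry as geo
from . import io as rio
from . import stats as rstats
from . import synthetic as syn
from . import topology as topo
from .model import RootSystem

__all__ = ["run_pipeline", "load_config"]


def load_config(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _load_systems(config: dict):
    if "mtg_files" in config:
        systems = []
        for p in config["mtg_files"]:
            if not Path(p).exists():
                raise FileNotFoundError(f"input MTG file not found: {p}")
            systems.append(rio.read_mtg(p))
        meta = None
    elif "segment_tables" in config:
        systems = []
        for p in config["segment_tables"]:
            if not Path(p).exists():
                raise FileNotFoundError(f"input segment table not found: {p}")
            systems.append(rio.read_segment_table(p))
        meta = None
    else:
        gen = config.get("generator", {})
        seed = int(gen.get("seed", config.get("seed", 0)))
        n_per_group = int(gen.get("n_per_group", 8))
        systems, meta = syn.generate_cohort(n_per_group=n_per_group, seed=seed)
    return systems, meta


def run_pipeline(config: dict, out_dir, seed: Optional[int] = None) -> Path:
    """Run the whole analysis; returns the output directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = dict(config)
        config.setdefault("generator", {})
        config["generator"] = {**config["generator"], "seed": seed}
    zrt = float(config.get("zrt_limit_m", comp.ZRT_LIMIT_M))
    iafr = bool(config.get("include_fine_roots", True))
    qc: dict = {"plants": {}}

    systems, meta = _load_systems(config)
    seg_dir = out / "segments"
    seg_dir.mkdir(exist_ok=True)
    axis_rows = []
    event_rows = []
    for rs in systems:
        rs_c = geo.extend_wall_roots(rs)
        rio.write_segment_table(rs_c, seg_dir / f"{rs.plant_id}.csv")
        from .model import validate

        viol = validate(rs_c, tol_m=1e-4)
        qc["plants"][rs.plant_id] = {
            "n_segments": len(rs.segments),
            "violations": [f"{v.segment_id}:{v.rule}" for v in viol],
        }
        for aid in rs_c.axes():
            ag = geo.axis_geometry(rs_c, aid)
            axis_rows.append({"plant_id": rs.plant_id, **{k: v for k, v in asdict(ag).items() if k != "flags"}})
        events, evqc = topo.branch_events(rs_c)
        qc["plants"][rs.plant_id]["branch_event_qc"] = evqc
        for e in events:
            event_rows.append(
                {
                    "plant_id": rs.plant_id,
                    "axis_id": e.axis_id,
                    "s_m": e.s_m,
                    "scope": e.scope,
                    "csa_before_m2": e.csa_before_m2,
                    "csa_after_sum_m2": sum(e.csa_after_m2),
                    "p_branch": e.p_branch,
                    "q": e.q,
                }
            )
    pd.DataFrame(axis_rows).to_csv(out / "axes.csv", index=False)
    pd.DataFrame(event_rows).to_csv(out / "branch_events.csv", index=False)

    tt = rstats.build_trait_table(systems, metadata=meta, zrt_limit_m=zrt, include_fine_roots=iafr)
    tt.to_csv(out / "traits.csv")

    st_df = rstats.build_sector_table(systems, zrt_limit_m=zrt)
    st_df.to_csv(out / "sectors.csv", index=False)

    res = rstats.anova_by_trait(tt)
    rstats.anova_results_frame(res).to_csv(out / "anova.csv", index=False)

    sm_rows = []
    for var in ("volume_cm3", "length_cm", "n_axes"):
        for g, sub in st_df.merge(
            tt.reset_index()[["plant_id", "group"]], on="plant_id"
        ).groupby("group"):
            for r in rstats.sector_mixed_model(sub, var):
                sm_rows.append(
                    {
                        "group": g,
                        "variable": var,
                        "compartment": r.compartment,
                        "p_sector": r.p_sector,
                        "na": r.na,
                        **{f"mean_{k}": v for k, v in sorted(r.means.items())},
                        **{f"letter_{k}": v for k, v in sorted(r.letters.items())},
                    }
                )
    pd.DataFrame(sm_rows).to_csv(out / "sector_models.csv", index=False)

    try:
        pca = rstats.pca_traits(tt)
        pca.scores.to_csv(out / "pca_scores.csv")
        pca.loadings.to_csv(out / "pca_loadings.csv")
        np.savetxt(out / "pca_explained_pct.csv", pca.explained_pct, delimiter=",")
    except ValueError as e:
        qc["pca"] = f"skipped: {e}"

    with open(out / "qc.json", "w") as fh:
        json.dump(qc, fh, indent=1)
    return out
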