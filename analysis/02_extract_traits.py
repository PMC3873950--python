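#!/usr/bin/env python
"""Parse the cohort MTG files and extract the full trait battery.

Reads results/cohort/*.mtg (run 01_simulate_cohort.py first), applies the
wall-artefact correction, and writes the plant x trait matrix to
results/traits.csv plus per-plant sector aggregates to results/sectors.csv.
"""
from pathlib import Path

import pandas as pd

from rootarch import io as rio
from rootarch import stats as rstats

ROOT = Path(__file__).resolve().parents[1]


def main():
    cohort_dir = ROOT / "results" / "cohort"
    paths = sorted(cohort_dir.glob("*.mtg"))
    if not paths:
        raise SystemExit("no cohort found; run analysis/01_simulate_cohort.py first")
    systems = [rio.read_mtg(p) for p in paths]
    meta = pd.read_csv(cohort_dir / "metadata.csv")
    tt = rstats.build_trait_table(systems, metadata=meta)
    tt.to_csv(ROOT / "results" / "traits.csv")
    st = rstats.build_sector_table(systems)
    st.to_csv(ROOT / "results" / "sectors.csv", index=False)
    n_traits = tt.select_dtypes("number").shape[1]
    print(f"{len(systems)} plants, {n_traits} numeric traits -> results/traits.csv")
    print("group means of total root volume (cm3, stump excluded):")
    print(tt.groupby("group")["total_volume_cm3"].mean().round(2).to_string())


if __name__ == "__main__":
    main()
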