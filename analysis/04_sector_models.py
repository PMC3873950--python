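#!/usr/bin/env python
"""Circular heterogeneity: the sector mixed model per treatment group.

Reads results/sectors.csv and results/traits.csv (for group labels),
fits value ~ sector (fixed) with tree as random factor, separately per
group and compartment, halving the perpendicular sector for additive
quantities.  Writes results/sector_models.csv and prints the significant
sector effects with their compact letter displays.
"""
from pathlib import Path

import pandas as pd

from rootarch import stats as rstats

ROOT = Path(__file__).resolve().parents[1]


def main():
    st = pd.read_csv(ROOT / "results" / "sectors.csv")
    tt = pd.read_csv(ROOT / "results" / "traits.csv", index_col=0)
    st = st.merge(tt.reset_index()[["plant_id", "group"]], on="plant_id")
    rows = []
    for var in ("volume_cm3", "length_cm", "n_axes"):
        for g, sub in st.groupby("group"):
            for r in rstats.sector_mixed_model(sub, var):
                rows.append(
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
    frame = pd.DataFrame(rows)
    frame.to_csv(ROOT / "results" / "sector_models.csv", index=False)
    sig = frame[(frame["p_sector"] < 0.05) & (~frame["na"])]
    print(f"{len(frame)} group x compartment x variable models; {len(sig)} significant at 5%:")
    cols = [c for c in frame.columns if c != "na"]
    with pd.option_context("display.width", 140):
        print(sig[cols].round(3).to_string(index=False))


if __name__ == "__main__":
    main()
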