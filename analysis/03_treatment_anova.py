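#!/usr/bin/env python
"""Three-way ANOVA (Slope, Flexing, Block) across every trait.

Reads results/traits.csv, runs the sequential ANOVA with the Shapiro-
driven transformation ladder, and writes results/anova.csv.  Prints the
traits with a significant Slope or Flexing effect.
"""
from pathlib import Path

import pandas as pd

from rootarch import stats as rstats

ROOT = Path(__file__).resolve().parents[1]


def main():
    tt = pd.read_csv(ROOT / "results" / "traits.csv", index_col=0)
    res = rstats.anova_by_trait(tt)
    frame = rstats.anova_results_frame(res)
    frame.to_csv(ROOT / "results" / "anova.csv", index=False)
    sig = frame[(frame["p_slope"] < 0.05) | (frame["p_flexing"] < 0.05)]
    print(f"{len(frame)} traits analysed; {len(sig)} with a Slope or Flexing effect at 5%:")
    cols = ["trait", "transform", "p_slope", "p_flexing", "stars_slope", "stars_flexing"]
    with pd.option_context("display.width", 120):
        print(sig[cols].to_string(index=False))


if __name__ == "__main__":
    main()
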