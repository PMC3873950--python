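#!/usr/bin/env python
"""PCA of the 17-trait selection: overall grouping of the seedlings.

Reads results/traits.csv; writes scores, loadings and explained-variance
shares under results/, and prints how the treatment groups separate on
the first two components.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from rootarch import stats as rstats

ROOT = Path(__file__).resolve().parents[1]


def main():
    tt = pd.read_csv(ROOT / "results" / "traits.csv", index_col=0)
    res = rstats.pca_traits(tt)
    res.scores.to_csv(ROOT / "results" / "pca_scores.csv")
    res.loadings.to_csv(ROOT / "results" / "pca_loadings.csv")
    np.savetxt(ROOT / "results" / "pca_explained_pct.csv", res.explained_pct, delimiter=",")
    print(
        "explained variance (%):",
        ", ".join(f"PC{i+1} {v:.1f}" for i, v in enumerate(res.explained_pct[:4])),
    )
    joined = res.scores.join(tt["group"])
    print("group centroids on PC1/PC2:")
    print(joined.groupby("group")[["PC1", "PC2"]].mean().round(2).to_string())


if __name__ == "__main__":
    main()
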