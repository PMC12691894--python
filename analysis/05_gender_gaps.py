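#!/usr/bin/env python
"""Sex-disaggregated outcome gaps by financing cluster: ANOVA + Tukey.

Reads results/weighted.csv and results/financing_clusters.csv; writes
results/gaps.csv and results/tukey_hale_gap.csv / results/tukey_im_gap.csv.

Usage:  python analysis/05_gender_gaps.py
"""

from pathlib import Path
import sys

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import healthfin as hf

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    out = ROOT / "results"
    weighted = pd.read_csv(out / "weighted.csv", index_col="country")
    financing = pd.read_csv(out / "financing_clusters.csv",
                            index_col="country")["cluster"]

    gaps = hf.compute_gaps(weighted, financing)
    print(gaps.groupby("cluster")[["hale_gap", "im_gap"]].mean()
          .round(2).to_string())

    for col in ("hale_gap", "im_gap"):
        res = hf.oneway_anova(gaps[col], gaps["cluster"])
        print(f"{col}: F({res.df_between},{res.df_within}) = "
              f"{res.f_stat:.2f}, p = {res.p_value:.4f}")
        tab = hf.tukey_hsd(gaps[col], gaps["cluster"])
        tab.to_csv(out / f"tukey_{col}.csv", index=False)
        sig = tab[tab["reject"]]
        for _, row in sig.iterrows():
            print(f"  clusters {row.group_a} vs {row.group_b}: "
                  f"diff {row.difference:+.2f}, p = {row.p_adjusted:.4f}")

    gaps.rename_axis("country").to_csv(out / "gaps.csv")
    print(f"wrote gaps and Tukey tables to {out}/")


if __name__ == "__main__":
    main()
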