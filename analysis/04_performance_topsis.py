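#!/usr/bin/env python
"""Outcome tiers and TOPSIS performance scores, cross-tabulated.

Reads results/weighted.csv and results/financing_clusters.csv; writes
results/topsis_scores.csv, results/outcome_tiers.csv,
results/success_rates.csv and results/cross_tab.csv.

Usage:  python analysis/04_performance_topsis.py [--threshold 70]
"""

import argparse
from pathlib import Path
import sys

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import healthfin as hf

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--threshold", type=float, default=70.0)
    args = ap.parse_args()

    out = ROOT / "results"
    weighted = pd.read_csv(out / "weighted.csv", index_col="country")
    financing = pd.read_csv(out / "financing_clusters.csv",
                            index_col="country")["cluster"]

    scores = hf.topsis_scores(
        hf.normalize_outcomes(weighted[["hale_total", "im_total"]]),
        threshold=args.threshold,
    )
    rates = hf.success_rates(scores, financing, args.threshold)
    print(rates.to_string(index=False))
    q75 = hf.percentile_threshold(scores, 75.0)
    print(f"success threshold {args.threshold:.0f} vs empirical 75th "
          f"percentile {q75:.1f}")

    sol, tiers = hf.outcome_pipeline(weighted)
    print(f"outcome tiers (k={sol.k}): sizes {sol.sizes().tolist()}, "
          f"silhouette {sol.silhouette:.3f}")
    xtab = hf.cross_tabulate(financing, tiers)

    scores.rename_axis("country").to_csv(out / "topsis_scores.csv")
    tiers.rename_axis("country").to_csv(out / "outcome_tiers.csv")
    rates.to_csv(out / "success_rates.csv", index=False)
    xtab.to_csv(out / "cross_tab.csv", index=False)
    print(f"wrote scores, tiers, rates and cross-tab to {out}/")


if __name__ == "__main__":
    main()
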