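#!/usr/bin/env python
"""Financing typologies: K-means on the MDS coordinates, with diagnostics.

Reads results/coordinates.csv; writes results/financing_clusters.csv and
prints silhouette, variance ratio, the silhouette-by-k scan, and the
multi-seed stability check. Compares against results/planted_labels.csv
when present.

Usage:  python analysis/03_cluster_typologies.py [--k 4] [--nstart 50]
"""

import argparse
from pathlib import Path
import sys

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import healthfin as hf
from sklearn.metrics import adjusted_rand_score

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--k", type=int, default=4)
    ap.add_argument("--nstart", type=int, default=50)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    out = ROOT / "results"
    coords = hf.read_coordinates(out / "coordinates.csv")
    X = coords.to_numpy()

    scan = hf.choose_k(X, list(range(2, 7)),
                       hf.RunConfig(nstart=args.nstart, seed=args.seed))
    print(scan.to_string(index=False))
    print(f"recommended k by silhouette: {scan.attrs['recommended_k']}")

    sol = hf.kmeans(X, args.k, nstart=args.nstart, seed=args.seed)
    labels = pd.Series(sol.labels, index=coords.index, name="cluster")
    print(f"k={args.k}: sizes {sol.sizes().tolist()}, "
          f"silhouette {sol.silhouette:.3f}, "
          f"variance ratio {sol.variance_ratio:.3f}")

    stab = hf.stability_check(X, args.k, list(range(10)))
    print(f"stability over 10 seeds: min pairwise ARI {stab.attrs['min_ari']:.3f}")

    planted = out / "planted_labels.csv"
    if planted.exists():
        truth = pd.read_csv(planted, index_col="country")["planted_label"]
        ari = adjusted_rand_score(truth.reindex(labels.index), labels)
        print(f"ARI vs planted typologies: {ari:.3f}")

    labels.rename_axis("country").to_csv(out / "financing_clusters.csv")
    print(f"wrote cluster assignments to {out / 'financing_clusters.csv'}")


if __name__ == "__main__":
    main()
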