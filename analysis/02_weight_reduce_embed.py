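#!/usr/bin/env python
"""Time-weight the panel, fit the group PCs, and embed with classical MDS.

Reads results/panel.csv; writes results/weighted.csv (λ-weighted country
means), results/pc_scores.csv, results/coordinates.csv (3-D MDS), and
results/reference_distances.csv (ranked distances from the reference
country when it is present, else from the first country).

Usage:  python analysis/02_weight_reduce_embed.py [--lam 1.5]
"""

import argparse
from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import healthfin as hf

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--lam", type=float, default=1.5)
    args = ap.parse_args()

    out = ROOT / "results"
    panel = hf.read_panel(out / "panel.csv", schema="long")
    weighted = hf.weight_panel(panel, args.lam)
    pcs = hf.fit_spending_pcs(weighted)
    scores = hf.pc_scores(pcs)
    for group, res in pcs.items():
        print(f"PC1[{group}]: variance explained "
              f"{100 * res.variance_explained:.2f}%")

    D = hf.pairwise_distances(scores)
    emb = hf.classical_mds(D, k=3, countries=list(scores.index))
    print(f"3-D embedding: stress-1 = {emb.stress1:.3e}, "
          f"Shepard r = {emb.shepard_r:.3f}")

    reference = scores.index[0]
    if "Türkiye" in scores.index:
        reference = "Türkiye"
    ref_table = hf.distances_to_reference(emb, reference)

    weighted.to_csv(out / "weighted.csv")
    scores.to_csv(out / "pc_scores.csv")
    emb.coordinates.to_csv(out / "coordinates.csv")
    ref_table.table.to_csv(out / "reference_distances.csv", index=False)
    print(f"wrote weighted means, PC scores, coordinates and distances "
          f"(reference: {reference}) to {out}/")


if __name__ == "__main__":
    main()
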