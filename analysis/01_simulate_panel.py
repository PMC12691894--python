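#!/usr/bin/env python
"""Generate the default synthetic 38-country panel and save it.

Writes results/panel.csv (long format: country, year, indicator, value)
and results/planted_labels.csv with the generator's true typologies.

Usage:  python analysis/01_simulate_panel.py [--seed 7] [--years 22]
"""

import argparse
from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import healthfin as hf

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--years", type=int, default=22)
    args = ap.parse_args()

    truth = hf.truth_defaults()
    panel = hf.simulate_panel(truth, n_years=args.years, seed=args.seed)

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    hf.write_panel(panel, out / "panel.csv")
    truth.planted_label.rename_axis("country").to_csv(out / "planted_labels.csv")
    print(f"wrote {len(panel)} rows for {truth.planted_label.size} countries "
          f"({args.years} years) to {out / 'panel.csv'}")


if __name__ == "__main__":
    main()
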