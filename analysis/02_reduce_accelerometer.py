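#!/usr/bin/env python
"""Reduce the cohort's accelerometer streams to per-day summaries.

Applies the standard reduction: non-wear removal (20+ min of consecutive
zeros), restriction to 06:00-24:00, cpm / MVPA / sedentary outcomes with the
1952 and 100 cpm cut-points, and the 600-min valid-day rule. Writes
results/day_summaries.csv.
"""
import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from activecommute.accel import CutPointConfig, summarise_days
from activecommute.io import read_accel_dir


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    epochs = read_accel_dir(args.cohort_dir / "accel")
    summaries = summarise_days(epochs, CutPointConfig())
    args.outdir.mkdir(parents=True, exist_ok=True)
    out = args.outdir / "day_summaries.csv"
    summaries.to_csv(out, index=False, float_format="%.6g")

    valid = summaries[summaries["valid"]]
    print(f"{len(summaries)} participant-days reduced; {len(valid)} valid "
          f"({100 * len(valid) / len(summaries):.0f}%)")
    print(f"mean daily wear: {valid['wear_minutes'].mean():.1f} min; "
          f"mean cpm: {valid['mean_cpm'].mean():.1f}; "
          f"mean MVPA: {valid['mvpa_minutes'].mean():.1f} min")
    print(f"wrote {out}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
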