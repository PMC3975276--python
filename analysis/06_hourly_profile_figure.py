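#!/usr/bin/env python
"""Plot the mean hourly activity profile by travel group.

Reads results/hourly_profile.csv (written by 05_compare_groups.py) and draws
the weekday hour-by-hour cpm curves for walkers and car commuters; the two
curves should diverge in the morning and late-afternoon commute windows and
overlap during core working hours.
"""
import argparse
import sys
from pathlib import Path

import pandas as pd


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--profile", type=Path, default=Path("results/hourly_profile.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/hourly_profile.png"))
    args = ap.parse_args()

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        print("matplotlib not installed; skipping the figure", file=sys.stderr)
        return 0

    prof = pd.read_csv(args.profile)
    fig, ax = plt.subplots(figsize=(7, 4))
    for group in [c for c in prof.columns if c != "hour"]:
        ax.plot(prof["hour"], prof[group], marker="o", label=group)
    ax.set_xlabel("hour of day")
    ax.set_ylabel("mean counts per minute")
    ax.set_title("Mean hourly physical activity by usual travel mode (weekdays)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(args.out, dpi=150)
    print(f"wrote {args.out}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
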