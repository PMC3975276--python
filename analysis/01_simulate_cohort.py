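#!/usr/bin/env python
"""Generate the synthetic commuter cohort used by the downstream analyses.

Simulates 103 employed adults living within walking distance of work (the
motivating study's sample size) for five weekdays and a weekend: epoch-level
accelerometer counts, commute GPS traces, travel diaries, demographics and a
ground-truth sidecar, written as the on-disk bundle under results/cohort/.
"""
import argparse
import sys
from collections import Counter
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from activecommute.io import write_cohort
from activecommute.simulate import CohortConfig, generate_cohort


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n", type=int, default=103)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--gpx", action="store_true", help="also write per-day GPX tracks")
    args = ap.parse_args()

    cfg = CohortConfig(n_participants=args.n, seed=args.seed)
    cohort, truth = generate_cohort(cfg)
    paths = write_cohort(cohort, args.outdir / "cohort", write_gpx_tracks=args.gpx)

    modes = Counter(truth.true_mode(p) for p in truth.participants)
    print(f"simulated {args.n} participants (seed {args.seed}): {dict(modes)}")
    print(f"epoch rows: {len(cohort.epochs):,}; GPS fixes: {len(cohort.gps):,}; "
          f"diary days: {len(cohort.diary)}")
    print(f"bundle written under {args.outdir / 'cohort'}")
    for k, p in paths.items():
        print(f"  {k}: {p}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
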