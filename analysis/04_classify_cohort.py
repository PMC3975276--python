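#!/usr/bin/env python
"""Classify usual travel modes from the diaries and build the analysis set.

Applies the same-mode-both-ways day rule, majority vote over the measured
week with questionnaire fallback, excludes usual cyclists and mixed/other
modes, and drops participants with no valid accelerometer day. Writes
results/analysis_set.csv and results/flow_report.txt.
"""
import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from activecommute.cohort import build_analysis_set, classify_participants
from activecommute.io import read_demographics_csv, read_diary_csv


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--day-summaries", type=Path, default=Path("results/day_summaries.csv"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    diary = read_diary_csv(args.cohort_dir / "diary.csv")
    demo = read_demographics_csv(args.cohort_dir / "demographics.csv")
    summaries = pd.read_csv(args.day_summaries)
    participants = classify_participants(diary, demo)
    analysis, flow = build_analysis_set(participants, summaries)

    args.outdir.mkdir(parents=True, exist_ok=True)
    analysis.to_csv(args.outdir / "analysis_set.csv", index=False, float_format="%.6g")
    (args.outdir / "flow_report.txt").write_text(flow.render())
    print(flow.render())
    print(participants["usual_mode"].value_counts().to_string())
    print(f"wrote {args.outdir / 'analysis_set.csv'}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
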