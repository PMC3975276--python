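"""File formats and validation.

CSV dialects
------------
* accelerometer: ``participant_id,timestamp,counts`` with ISO-8601 local
  timestamps marking the epoch start; Actigraph-style exports with a 10-line
  metadata header are also accepted (the header is detected and skipped).
* GPS: ``participant_id,timestamp,lat,lon`` and GPX 1.1 tracks (one track per
  participant-day, written with stdlib XML).
* diary: ``participant_id,date,mode_to_work,mode_from_work``.
* demographics: one row per participant with banded covariates.
* anchors: ``participant_id,home_lat,home_lon,work_lat,work_lon``.

All timestamps are naive local time by contract; a UTC offset in any input
is a validation error.
"""
from __future__ import annotations

import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import DAY_MODES
from .simulate import Cohort, GroundTruth

logger = logging.getLogger(__name__)

GPX_NS = "http://www.topografix.com/GPX/1/1"
TS_FORMAT = "%Y-%m-%dT%H:%M:%S"

__all__ = [
    "ValidationReport",
    "write_cohort",
    "read_accel_csv",
    "read_gps_csv",
    "read_diary_csv",
    "read_demographics_csv",
    "read_anchors_csv",
    "write_gpx",
    "read_gpx",
    "validate_inputs",
]


# ---------------------------------------------------------------------------
# writers


def _fmt_ts(series: pd.Series) -> np.ndarray:
    # second-resolution ISO-8601; much faster than strftime on long streams
    values = pd.to_datetime(series).to_numpy().astype("datetime64[s]")
    return np.datetime_as_string(values, unit="s")


def write_gpx(fixes: pd.DataFrame, path: Path, name: str = "track") -> None:
    """Write one GPX 1.1 track (one segment) for a participant-day."""
    gpx = ET.Element("gpx", {"version": "1.1", "creator": "activecommute", "xmlns": GPX_NS})
    trk = ET.SubElement(gpx, "trk")
    ET.SubElement(trk, "name").text = name
    seg = ET.SubElement(trk, "trkseg")
    ts = _fmt_ts(fixes["timestamp"])
    for t, lat, lon in zip(ts, fixes["lat"], fixes["lon"]):
        pt = ET.SubElement(seg, "trkpt", {"lat": f"{lat:.6f}", "lon": f"{lon:.6f}"})
        ET.SubElement(pt, "time").text = t
    tree = ET.ElementTree(gpx)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def read_gpx(path: Path) -> pd.DataFrame:
    """Read a GPX 1.1 track into the GPS frame dialect (no participant_id)."""
    root = ET.parse(path).getroot()
    ns = {"g": GPX_NS}
    rows = []
    for pt in root.iterfind(".//g:trkpt", ns):
        t = pt.findtext("g:time", default="", namespaces=ns)
        rows.append(
            {
                "timestamp": pd.Timestamp(t.rstrip("Z")),
                "lat": float(pt.get("lat")),
                "lon": float(pt.get("lon")),
            }
        )
    return pd.DataFrame(rows, columns=["timestamp", "lat", "lon"])


def write_cohort(cohort: Cohort, outdir: Path, write_gpx_tracks: bool = True) -> dict[str, Path]:
    """Write a cohort bundle to its on-disk dialects; returns the path map.

    Output is deterministic: fixed float formats and sorted ground-truth keys
    make a rerun of the same config byte-identical.
    """
    outdir = Path(outdir)
    (outdir / "accel").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for pid, grp in cohort.epochs.groupby("participant_id", sort=True):
        p = outdir / "accel" / f"{pid}.csv"
        out = grp[["participant_id", "timestamp", "counts"]].copy()
        out["timestamp"] = _fmt_ts(out["timestamp"])
        out.to_csv(p, index=False)
    paths["accel_dir"] = outdir / "accel"

    gps = cohort.gps.copy()
    gps_path = outdir / "gps.csv"
    if len(gps):
        gps_out = gps.copy()
        gps_out["timestamp"] = _fmt_ts(gps_out["timestamp"])
        gps_out["lat"] = gps_out["lat"].map(lambda v: f"{v:.6f}")
        gps_out["lon"] = gps_out["lon"].map(lambda v: f"{v:.6f}")
        gps_out.to_csv(gps_path, index=False)
    else:
        pd.DataFrame(columns=["participant_id", "timestamp", "lat", "lon"]).to_csv(
            gps_path, index=False
        )
    paths["gps"] = gps_path

    if write_gpx_tracks and len(gps):
        gpx_dir = outdir / "gpx"
        gpx_dir.mkdir(exist_ok=True)
        ts = pd.to_datetime(gps["timestamp"])
        for (pid, day), grp in gps.groupby([gps["participant_id"], ts.dt.date], sort=True):
            write_gpx(grp, gpx_dir / f"{pid}_{day}.gpx", name=f"{pid} {day}")
        paths["gpx_dir"] = gpx_dir

    diary_path = outdir / "diary.csv"
    cohort.diary.to_csv(diary_path, index=False)
    paths["diary"] = diary_path

    demo_path = outdir / "demographics.csv"
    cohort.demographics.to_csv(demo_path, index=False)
    paths["demographics"] = demo_path

    anchors_path = outdir / "anchors.csv"
    a = cohort.anchors.copy()
    for c in ("home_lat", "home_lon", "work_lat", "work_lon"):
        a[c] = a[c].map(lambda v: f"{v:.6f}")
    a.to_csv(anchors_path, index=False)
    paths["anchors"] = anchors_path

    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(cohort.truth.to_json())
    paths["ground_truth"] = truth_path
    return paths


# ---------------------------------------------------------------------------
# readers


def _looks_like_actigraph_header(first_line: str) -> bool:
    low = first_line.lower()
    return first_line.startswith("---") or "actigraph" in low or "actilife" in low


def read_accel_csv(path: Path) -> pd.DataFrame:
    """Read an accelerometer CSV, skipping a 10-line metadata header if present."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    skip = 10 if _looks_like_actigraph_header(first) else 0
    df = pd.read_csv(path, skiprows=skip)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["counts"] = df["counts"].astype(np.int64)
    return df


def read_accel_dir(accel_dir: Path) -> pd.DataFrame:
    frames = [read_accel_csv(p) for p in sorted(Path(accel_dir).glob("*.csv"))]
    if not frames:
        raise FileNotFoundError(f"no accelerometer CSVs under {accel_dir}")
    return pd.concat(frames, ignore_index=True)


def read_gps_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if len(df):
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def read_diary_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def read_demographics_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    df["age"] = df["age"].astype(float)
    return df


def read_anchors_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in ("home_lat", "home_lon", "work_lat", "work_lon"):
        df[c] = df[c].astype(float)
    return df


def read_ground_truth(path: Path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    """Every schema / consistency violation found across an input bundle."""

    violations: list[tuple[str, int | None, str]] = field(default_factory=list)

    def add(self, file: str, line: int | None, message: str) -> None:
        self.violations.append((file, line, message))

    @property
    def ok(self) -> bool:
        return not self.violations

    def render(self) -> str:
        if self.ok:
            return "all inputs valid\n"
        lines = []
        for f, ln, msg in self.violations:
            loc = f"{f}:{ln}" if ln is not None else f
            lines.append(f"{loc}: {msg}")
        return "\n".join(lines) + "\n"


_OFFSET_RE = re.compile(r"[+-]\d{2}:?\d{2}$|Z$")


def validate_inputs(paths: Mapping[str, Path]) -> ValidationReport:
    """Schema, timestamp-monotonicity and cross-file ID checks.

    ``paths`` maps {"accel_dir", "gps", "diary", "demographics", "anchors"}
    (any subset) to files; every violation is reported, none is silently
    dropped.
    """
    report = ValidationReport()
    known_pids: set[str] = set()

    demo_path = paths.get("demographics")
    if demo_path is not None:
        try:
            demo = pd.read_csv(demo_path, keep_default_na=False)
        except Exception as exc:  # unreadable file
            raise OSError(f"cannot read {demo_path}: {exc}") from exc
        required = {"participant_id", "age", "sex"}
        missing = required - set(demo.columns)
        if missing:
            report.add(str(demo_path), None, f"missing columns {sorted(missing)}")
        else:
            known_pids = set(demo["participant_id"])
            dup = demo["participant_id"].duplicated()
            for idx in demo.index[dup]:
                report.add(str(demo_path), int(idx) + 2, "duplicate participant_id")

    accel_dir = paths.get("accel_dir")
    if accel_dir is not None:
        for p in sorted(Path(accel_dir).glob("*.csv")):
            df = read_accel_csv(p)
            if not {"participant_id", "timestamp", "counts"} <= set(df.columns):
                report.add(str(p), None, "missing accelerometer columns")
                continue
            if (df["counts"] < 0).any():
                line = int(df.index[df["counts"] < 0][0]) + 2
                report.add(str(p), line, "negative counts")
            ts = df["timestamp"].to_numpy()
            bad = np.flatnonzero(np.diff(ts) <= np.timedelta64(0, "s"))
            for b in bad[:5]:
                report.add(str(p), int(b) + 3, "non-monotone timestamp")
            if known_pids:
                for pid in set(df["participant_id"]) - known_pids:
                    report.add(str(p), None, f"unknown participant {pid!r}")

    gps_path = paths.get("gps")
    if gps_path is not None:
        raw = pd.read_csv(gps_path, dtype=str, keep_default_na=False)
        for idx, t in raw.get("timestamp", pd.Series(dtype=str)).items():
            if _OFFSET_RE.search(t):
                report.add(str(gps_path), int(idx) + 2, f"timestamp carries a UTC offset: {t!r}")
        gps = read_gps_csv(gps_path)
        if len(gps):
            bad_lat = ~gps["lat"].astype(float).between(-90, 90)
            bad_lon = ~gps["lon"].astype(float).between(-180, 180)
            for idx in gps.index[bad_lat | bad_lon][:5]:
                report.add(str(gps_path), int(idx) + 2, "lat/lon out of range")
            for pid, grp in gps.groupby("participant_id"):
                ts = grp["timestamp"].to_numpy()
                bad = np.flatnonzero(np.diff(ts) < np.timedelta64(0, "s"))
                for b in bad[:5]:
                    report.add(
                        str(gps_path),
                        int(grp.index[b]) + 2,
                        f"non-monotone GPS timestamps for {pid}",
                    )
            if known_pids:
                for pid in set(gps["participant_id"]) - known_pids:
                    report.add(str(gps_path), None, f"unknown participant {pid!r}")

    diary_path = paths.get("diary")
    if diary_path is not None:
        diary = read_diary_csv(diary_path)
        req = {"participant_id", "date", "mode_to_work", "mode_from_work"}
        if not req <= set(diary.columns):
            report.add(str(diary_path), None, f"missing columns {sorted(req - set(diary.columns))}")
        else:
            for col in ("mode_to_work", "mode_from_work"):
                bad = ~diary[col].isin(DAY_MODES)
                for idx in diary.index[bad]:
                    report.add(
                        str(diary_path), int(idx) + 2, f"unknown mode {diary.loc[idx, col]!r}"
                    )
            dup = diary.duplicated(subset=["participant_id", "date"])
            for idx in diary.index[dup]:
                report.add(str(diary_path), int(idx) + 2, "duplicate participant-date entry")
            if known_pids:
                for pid in set(diary["participant_id"]) - known_pids:
                    report.add(str(diary_path), None, f"diary references unknown participant {pid!r}")

    anchors_path = paths.get("anchors")
    if anchors_path is not None:
        anchors = read_anchors_csv(anchors_path)
        if known_pids:
            for pid in set(anchors["participant_id"]) - known_pids:
                report.add(str(anchors_path), None, f"anchors reference unknown participant {pid!r}")
    return report
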