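"""Accelerometer–GPS merging and home↔work journey segmentation.

The accelerometer stream is the spine: each epoch is paired with the nearest
GPS fix within a small tolerance of the epoch start, or flagged
position-missing. Journeys are maximal anchor-to-anchor runs of
position-bearing epochs inside a commute window, tolerant of brief fix gaps,
with mid-route stationary stops (e.g. a shop visit on the way home) retained
inside the journey.

Distances are great-circle (haversine) on WGS84, which is accurate to well
under 0.5% at commuting scales.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date as _date, datetime
from typing import Sequence

import numpy as np
import pandas as pd

from .accel import CutPointConfig, classify_intensity

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_008.8

#: default commute windows, minutes since midnight: 06:00–10:00 and 16:00–20:00
DEFAULT_COMMUTE_WINDOWS = ((360, 600), (960, 1200))

__all__ = [
    "AnchorPair",
    "Journey",
    "haversine_m",
    "merge_acc_gps",
    "segment_journeys",
    "summarise_journey",
    "journeys_table",
    "contribution_fraction",
    "commute_contribution",
]


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in metres between WGS84 coordinates (vectorised)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_M * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class AnchorPair:
    """Geocoded home and workplace with a detection geofence."""

    home_lat: float
    home_lon: float
    work_lat: float
    work_lon: float
    geofence_radius_m: float = 100.0

    def __post_init__(self) -> None:
        d = float(haversine_m(self.home_lat, self.home_lon, self.work_lat, self.work_lon))
        if d <= 2 * self.geofence_radius_m:
            raise ValueError(
                f"home–work distance {d:.0f} m must exceed twice the geofence radius "
                f"({2 * self.geofence_radius_m:.0f} m): anchors are degenerate"
            )

    @property
    def home(self) -> tuple[float, float]:
        return (self.home_lat, self.home_lon)

    @property
    def work(self) -> tuple[float, float]:
        return (self.work_lat, self.work_lon)


@dataclass
class Journey:
    """One segmented home↔work trip with its merged epoch+position sequence."""

    participant_id: str
    date: _date
    direction: str                # "to_work" | "from_work"
    start: datetime
    end: datetime
    data: pd.DataFrame            # merged epochs spanning [start, end]
    duration_minutes: float = 0.0
    mean_cpm: float = 0.0
    mvpa_minutes: float = 0.0
    includes_detour: bool = False


def merge_acc_gps(
    epochs: pd.DataFrame,
    fixes: pd.DataFrame,
    max_gap_s: float = 5.0,
) -> pd.DataFrame:
    """Pair each accelerometer epoch with the nearest GPS fix within tolerance.

    The accelerometer stream is the spine: no epoch is dropped and no fix
    creates an epoch. Fixes not matched to any epoch are discarded (a count is
    logged). Inputs may arrive unsorted; sorting is internal.
    """
    acc = epochs.sort_values("timestamp").reset_index(drop=True)
    acc["timestamp"] = pd.to_datetime(acc["timestamp"])
    if fixes is None or len(fixes) == 0:
        out = acc.copy()
        out["lat"] = np.nan
        out["lon"] = np.nan
        return out
    gps = fixes.sort_values("timestamp").reset_index(drop=True)
    gps["timestamp"] = pd.to_datetime(gps["timestamp"])
    merged = pd.merge_asof(
        acc,
        gps[["timestamp", "lat", "lon"]].rename(columns={"timestamp": "fix_time"}),
        left_on="timestamp",
        right_on="fix_time",
        direction="nearest",
        tolerance=pd.Timedelta(seconds=max_gap_s),
    )
    used = merged["fix_time"].dropna().unique()
    n_unmatched = len(gps) - len(used)
    if n_unmatched > 0:
        logger.info("merge_acc_gps: discarded %d unmatched fix(es)", n_unmatched)
    return merged.drop(columns=["fix_time"])


def _runs(indices: np.ndarray, times_s: np.ndarray, max_gap_s: float) -> list[np.ndarray]:
    """Split sorted position-bearing indices into runs by time gap."""
    if len(indices) == 0:
        return []
    gaps = np.diff(times_s[indices])
    cut = np.flatnonzero(gaps > max_gap_s) + 1
    return [seg for seg in np.split(indices, cut) if len(seg) > 0]


def segment_journeys(
    merged_day: pd.DataFrame,
    anchors: AnchorPair,
    commute_windows: Sequence[tuple[int, int]] = DEFAULT_COMMUTE_WINDOWS,
    max_internal_gap_min: float = 5.0,
    config: CutPointConfig | None = None,
    participant_id: str = "",
    detour_cluster_radius_m: float = 30.0,
    detour_min_minutes: float = 3.0,
) -> list[Journey]:
    """Segment home↔work journeys from one merged participant-day.

    Within each commute window, position-bearing epochs are split into runs
    wherever consecutive fixes are more than ``max_internal_gap_min`` apart.
    A run yields a journey when it can start inside one anchor's geofence and
    end inside the other's; the longest such anchor-to-anchor stretch wins,
    ties breaking to the earlier start. Direction is inferred from the
    starting anchor. Mid-route stationary stops are retained inside the
    journey and flagged via ``includes_detour``.

    A day may legitimately yield 0, 1 or 2 journeys.
    """
    cfg = config or CutPointConfig()
    df = merged_day.sort_values("timestamp").reset_index(drop=True)
    ts = pd.to_datetime(df["timestamp"])
    times_s = ts.astype("int64").to_numpy() / 1e9
    minute_of_day = ((times_s % 86400) // 60).astype(int)
    has_pos = df["lat"].notna().to_numpy() & df["lon"].notna().to_numpy()
    lat = df["lat"].to_numpy()
    lon = df["lon"].to_numpy()

    d_home = np.full(len(df), np.inf)
    d_work = np.full(len(df), np.inf)
    d_home[has_pos] = haversine_m(lat[has_pos], lon[has_pos], anchors.home_lat, anchors.home_lon)
    d_work[has_pos] = haversine_m(lat[has_pos], lon[has_pos], anchors.work_lat, anchors.work_lon)
    in_home = d_home <= anchors.geofence_radius_m
    in_work = d_work <= anchors.geofence_radius_m

    journeys: list[Journey] = []
    dates = ts.dt.date.unique()
    day = dates[0] if len(dates) else None

    for w_start, w_end in commute_windows:
        in_window = (minute_of_day >= w_start) & (minute_of_day < w_end)
        idx = np.flatnonzero(has_pos & in_window)
        for run in _runs(idx, times_s, max_internal_gap_min * 60.0):
            cand = _best_anchor_span(run, in_home, in_work)
            if cand is None:
                continue
            i, j, direction = cand
            data = df.iloc[i : j + 1].copy()
            jny = Journey(
                participant_id=participant_id
                or str(df.get("participant_id", pd.Series([""])).iloc[0]),
                date=day,
                direction=direction,
                start=ts.iloc[i].to_pydatetime(),
                end=ts.iloc[j].to_pydatetime(),
                data=data,
            )
            summarise_journey(jny, cfg)
            jny.includes_detour = _has_stationary_stop(
                data, anchors, detour_cluster_radius_m, detour_min_minutes
            )
            journeys.append(jny)
    return journeys


def _best_anchor_span(run: np.ndarray, in_home: np.ndarray, in_work: np.ndarray):
    """Longest (start, end) span of a run starting in one geofence and ending
    in the other; ties break to the earlier start. Returns (i, j, direction)."""
    home_idx = run[in_home[run]]
    work_idx = run[in_work[run]]
    if len(home_idx) == 0 or len(work_idx) == 0:
        return None
    best = None
    # to_work: earliest epoch in the home fence to latest in the work fence
    i, j = int(home_idx.min()), int(work_idx.max())
    if i < j:
        best = (j - i, i, j, "to_work")
    # from_work: earliest in the work fence to latest in the home fence
    i2, j2 = int(work_idx.min()), int(home_idx.max())
    if i2 < j2:
        cand = (j2 - i2, i2, j2, "from_work")
        if best is None or cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
            best = cand
    if best is None:
        return None
    return best[1], best[2], best[3]


def _has_stationary_stop(
    data: pd.DataFrame,
    anchors: AnchorPair,
    cluster_radius_m: float,
    min_minutes: float,
) -> bool:
    """True when the journey contains a mid-route stationary cluster.

    A stop is a dwell: all fixes over at least ``min_minutes`` stay within
    ``cluster_radius_m`` of an anchor fix that lies outside both geofences.
    A dwell criterion is robust to per-fix position jitter, which makes
    instantaneous speed between adjacent fixes unreliable at walking pace.
    """
    pos = data.dropna(subset=["lat", "lon"])
    if len(pos) < 3:
        return False
    t = pd.to_datetime(pos["timestamp"]).astype("int64").to_numpy() / 1e9
    la = pos["lat"].to_numpy()
    lo = pos["lon"].to_numpy()
    away = (
        (haversine_m(la, lo, anchors.home_lat, anchors.home_lon) > anchors.geofence_radius_m)
        & (haversine_m(la, lo, anchors.work_lat, anchors.work_lon) > anchors.geofence_radius_m)
    )
    min_s = min_minutes * 60.0
    n = len(pos)
    j = 0
    for i in range(n):
        if not away[i]:
            continue
        if j <= i:
            j = i + 1
        while j < n and t[j] - t[i] < min_s:
            j += 1
        if j >= n:
            break
        d = haversine_m(la[i : j + 1], lo[i : j + 1], la[i], lo[i])
        if np.max(d) <= cluster_radius_m:
            return True
    return False


def summarise_journey(
    journey: Journey,
    config: CutPointConfig | None = None,
    epoch_s: int | None = None,
) -> Journey:
    """Fill duration, mean cpm and MVPA minutes on a journey in place.

    Duration covers first to last epoch inclusive; mean cpm is total counts
    over that duration; MVPA minutes come from epoch-level cut-point
    classification, so stationary detour epochs add duration but essentially
    no MVPA.
    """
    cfg = config or CutPointConfig()
    data = journey.data
    if len(data) == 0:
        raise ValueError("journey has no epochs")
    ts = pd.to_datetime(data["timestamp"])
    if epoch_s is None:
        if len(ts) > 1:
            from .accel import infer_epoch_s

            epoch_s = infer_epoch_s(ts)
        else:
            epoch_s = 60
    duration_min = (len(data) * epoch_s) / 60.0
    counts = data["counts"].to_numpy()
    levels = classify_intensity(counts, epoch_s, cfg)
    journey.duration_minutes = duration_min
    journey.mean_cpm = float(counts.sum()) / duration_min if duration_min > 0 else float("nan")
    journey.mvpa_minutes = float((levels == "mvpa").sum() * epoch_s / 60.0)
    return journey


def journeys_table(journeys: Sequence[Journey]) -> pd.DataFrame:
    """Tidy one-row-per-journey table (the journeys CSV dialect)."""
    rows = [
        {
            "participant_id": j.participant_id,
            "date": j.date,
            "direction": j.direction,
            "start": j.start,
            "end": j.end,
            "duration_min": j.duration_minutes,
            "mean_cpm": j.mean_cpm,
            "mvpa_min": j.mvpa_minutes,
            "includes_detour": j.includes_detour,
        }
        for j in journeys
    ]
    cols = [
        "participant_id", "date", "direction", "start", "end",
        "duration_min", "mean_cpm", "mvpa_min", "includes_detour",
    ]
    return pd.DataFrame(rows, columns=cols)


def contribution_fraction(journey_mvpa_min: float, total_mvpa_min: float) -> float:
    """Fraction of daily MVPA accrued during the commute journeys."""
    if total_mvpa_min <= 0:
        raise ValueError("total MVPA is zero: contribution undefined")
    return journey_mvpa_min / total_mvpa_min


def commute_contribution(
    journeys: pd.DataFrame,
    day_summaries: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Per-participant and cohort-level commute share of daily MVPA.

    For each participant, restricts to valid weekdays on which at least one
    journey was segmented; computes the mean daily journey MVPA and mean
    daily total MVPA (analysis window) over those days, and their ratio.
    The cohort aggregate is reported two ways: the ratio of the cohort mean
    journey MVPA to the cohort mean total MVPA (the headline form) and the
    mean of the per-participant ratios.
    """
    if len(journeys) == 0:
        raise ValueError("no journeys supplied")
    j = journeys.copy()
    j["date"] = pd.to_datetime(j["date"]).dt.date
    per_day = (
        j.groupby(["participant_id", "date"], as_index=False)["mvpa_min"].sum()
    )
    ds = day_summaries.copy()
    ds["date"] = pd.to_datetime(ds["date"]).dt.date
    valid_wd = ds[(ds["valid"]) & (ds["day_type"] == "weekday")]
    m = per_day.merge(
        valid_wd[["participant_id", "date", "mvpa_minutes"]],
        on=["participant_id", "date"],
        how="inner",
    )
    rows = []
    for pid, grp in m.groupby("participant_id"):
        journey_mean = grp["mvpa_min"].mean()
        total_mean = grp["mvpa_minutes"].mean()
        ratio = journey_mean / total_mean if total_mean > 0 else np.nan
        rows.append(
            {
                "participant_id": pid,
                "n_days": len(grp),
                "journey_mvpa_min": journey_mean,
                "total_mvpa_min": total_mean,
                "fraction": ratio,
            }
        )
    per_pid = pd.DataFrame(rows)
    if len(per_pid) == 0:
        raise ValueError("no participant has a valid weekday with a segmented journey")
    mean_journey = per_pid["journey_mvpa_min"].mean()
    mean_total = per_pid["total_mvpa_min"].mean()
    cohort = {
        "n_participants": int(len(per_pid)),
        "mean_journey_mvpa_min": float(mean_journey),
        "mean_total_mvpa_min": float(mean_total),
        "ratio_of_means": float(contribution_fraction(mean_journey, mean_total)),
        "mean_of_ratios": float(per_pid["fraction"].mean(skipna=True)),
    }
    return per_pid, cohort
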