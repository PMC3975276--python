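"""Accelerometer data reduction.

Epoch-level count processing for waist-worn accelerometers: reintegration to
coarser epochs, non-wear detection, counts-per-minute cut-point classification,
valid-day filtering, and daily / hourly summaries restricted to a waking-hours
analysis window.

Conventions
-----------
* Counts are non-negative integers summed over a fixed epoch (``epoch_s``
  seconds, which must divide 60).
* Cut-points are expressed in counts per minute (cpm) and scaled to the epoch
  by ``epoch_s / 60``; both inequalities are strict (``> mvpa``, ``< sedentary``),
  so a count exactly at the moderate cut-point is classified light.
* A timestamp marks the *start* of its epoch; an epoch belongs to the analysis
  window iff its start time does.
* Non-wear is a maximal run of zero-count epochs lasting at least
  ``nonwear_min_minutes``; runs are found on the full day *before* windowing so
  a run straddling the window edge still counts its full length.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date as _date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_EPOCH_S = (1, 2, 3, 4, 5, 6, 10, 12, 15, 20, 30, 60)

__all__ = [
    "CutPointConfig",
    "DaySummary",
    "reintegrate",
    "nonwear_mask",
    "detect_nonwear",
    "classify_intensity",
    "summarise_day",
    "summarise_days",
    "hourly_profile",
    "working_hours_comparison",
]


@dataclass(frozen=True)
class CutPointConfig:
    """Cut-points and validity thresholds for count data reduction.

    Defaults follow common adult accelerometry practice: moderate-to-vigorous
    physical activity (MVPA) above 1952 cpm, sedentary below 100 cpm, non-wear
    as 20+ minutes of consecutive zeros, a valid day as 600+ minutes of wear,
    and analysis confined to 06:00–24:00 local time.
    """

    mvpa_threshold_cpm: float = 1952.0
    sedentary_threshold_cpm: float = 100.0
    window_start_min: int = 6 * 60     # minutes since midnight, inclusive
    window_end_min: int = 24 * 60      # exclusive
    nonwear_min_minutes: float = 20.0
    valid_day_min_wear_minutes: float = 600.0

    def __post_init__(self) -> None:
        if self.sedentary_threshold_cpm >= self.mvpa_threshold_cpm:
            raise ValueError("sedentary_threshold_cpm must be below mvpa_threshold_cpm")
        if not (0 < self.mvpa_threshold_cpm):
            raise ValueError("thresholds must be positive")
        if not (0 <= self.window_start_min < self.window_end_min <= 1440):
            raise ValueError("analysis window must satisfy 0 <= start < end <= 1440 minutes")
        if self.nonwear_min_minutes <= 0 or self.valid_day_min_wear_minutes <= 0:
            raise ValueError("minute thresholds must be positive")

    def replace(self, **kw) -> "CutPointConfig":
        return replace(self, **kw)


@dataclass
class DaySummary:
    """Per-participant per-day reduction outcome."""

    participant_id: str
    date: _date
    day_type: str                 # "weekday" | "weekend"
    wear_minutes: float
    mean_cpm: float               # NaN when wear_minutes == 0 (flagged, not raised)
    mvpa_minutes: float
    sedentary_minutes: float
    light_minutes: float
    valid: bool

    def as_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "date": self.date,
            "day_type": self.day_type,
            "wear_minutes": self.wear_minutes,
            "mean_cpm": self.mean_cpm,
            "mvpa_minutes": self.mvpa_minutes,
            "sedentary_minutes": self.sedentary_minutes,
            "light_minutes": self.light_minutes,
            "valid": self.valid,
        }


# ---------------------------------------------------------------------------
# epoch utilities


def infer_epoch_s(timestamps: pd.Series | np.ndarray) -> int:
    """Infer the epoch length (seconds) from consecutive timestamps."""
    ts = pd.to_datetime(np.asarray(timestamps))
    if len(ts) < 2:
        raise ValueError("need at least two epochs to infer epoch length")
    diffs = np.diff(ts.astype("datetime64[s]").astype("int64"))
    step = int(np.min(diffs[diffs > 0])) if np.any(diffs > 0) else 0
    if step <= 0:
        raise ValueError("timestamps are not strictly increasing")
    return step


def reintegrate(
    epochs: pd.DataFrame,
    target_epoch_s: int,
    source_epoch_s: int | None = None,
) -> pd.DataFrame:
    """Sum fine epochs into coarser ones, conserving total counts.

    Parameters
    ----------
    epochs
        Frame with ``timestamp`` and ``counts`` columns for one contiguous
        stream (one participant).
    target_epoch_s
        Desired epoch length; must be an integer multiple of the source.
    source_epoch_s
        Input epoch length; inferred from timestamps when omitted.

    A trailing window with fewer than ``target/source`` constituents is
    dropped (and logged): partial windows would under-count.
    """
    df = epochs.sort_values("timestamp").reset_index(drop=True)
    src = source_epoch_s if source_epoch_s is not None else infer_epoch_s(df["timestamp"])
    if target_epoch_s % src != 0:
        raise ValueError(
            f"target epoch {target_epoch_s}s is not a multiple of source epoch {src}s"
        )
    ratio = target_epoch_s // src
    if ratio == 1:
        return df[["timestamp", "counts"]].copy()

    ts = pd.to_datetime(df["timestamp"])
    sec = ts.astype("int64") // 10**9
    offset = (sec - sec.iloc[0]) // src
    if not np.array_equal(offset.to_numpy(), np.arange(len(df))):
        raise ValueError("input epochs must be contiguous at the source epoch length")

    group = np.arange(len(df)) // ratio
    sizes = np.bincount(group)
    full = sizes == ratio
    n_drop = int((~full).sum())
    if n_drop:
        logger.info("reintegrate: dropped %d trailing partial window(s)", n_drop)

    sums = np.bincount(group, weights=df["counts"].to_numpy())
    keep = np.flatnonzero(full)
    out_ts = ts.iloc[0] + pd.to_timedelta(keep * target_epoch_s, unit="s")
    return pd.DataFrame(
        {"timestamp": out_ts, "counts": sums[keep].astype(np.int64)}
    )


# ---------------------------------------------------------------------------
# non-wear


def nonwear_mask(counts: np.ndarray, epoch_s: int, min_minutes: float = 20.0) -> np.ndarray:
    """Boolean mask, True where the epoch lies in a non-wear run.

    A non-wear run is a maximal run of zero counts whose total duration is at
    least ``min_minutes``. A single positive count terminates a run: there is
    no interruption allowance.
    """
    c = np.asarray(counts)
    zero = c == 0
    if not zero.any():
        return np.zeros(len(c), dtype=bool)
    # run-length encode the zero mask
    boundaries = np.flatnonzero(np.diff(zero.astype(np.int8)) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(c)]))
    mask = np.zeros(len(c), dtype=bool)
    min_epochs = int(np.ceil(min_minutes * 60.0 / epoch_s))
    for s, e in zip(starts, ends):
        if zero[s] and (e - s) >= min_epochs:
            mask[s:e] = True
    return mask


def detect_nonwear(epochs: pd.DataFrame, config: CutPointConfig, epoch_s: int | None = None) -> np.ndarray:
    """Wear mask per epoch (True = worn) for a sorted, uniformly spaced stream."""
    ts = pd.to_datetime(epochs["timestamp"]).to_numpy()
    if len(ts) > 1 and (np.diff(ts.astype("datetime64[s]").astype("int64")) <= 0).any():
        raise ValueError("epochs must be sorted by timestamp")
    eps = epoch_s if epoch_s is not None else infer_epoch_s(epochs["timestamp"])
    return ~nonwear_mask(epochs["counts"].to_numpy(), eps, config.nonwear_min_minutes)


# ---------------------------------------------------------------------------
# intensity classification

_LEVELS = np.array(["sedentary", "light", "mvpa"])


def classify_intensity(
    counts: np.ndarray | int,
    epoch_s: int,
    config: CutPointConfig | None = None,
):
    """Classify wear epochs as sedentary / light / mvpa.

    Thresholds are scaled from counts per minute to the epoch: an epoch is
    mvpa iff ``counts > mvpa_cpm * epoch_s / 60`` and sedentary iff
    ``counts < sedentary_cpm * epoch_s / 60`` (both strict).
    """
    cfg = config or CutPointConfig()
    c = np.asarray(counts, dtype=float)
    scale = epoch_s / 60.0
    codes = np.ones(c.shape, dtype=np.int8)  # light
    codes[c > cfg.mvpa_threshold_cpm * scale] = 2
    codes[c < cfg.sedentary_threshold_cpm * scale] = 0
    out = _LEVELS[codes]
    if np.isscalar(counts) or (isinstance(counts, np.ndarray) and counts.ndim == 0):
        return out.item() if out.ndim == 0 else str(out[()])
    return out


# ---------------------------------------------------------------------------
# daily summaries


def _day_type(d: _date) -> str:
    return "weekend" if d.weekday() >= 5 else "weekday"


def _summarise_arrays(
    counts: np.ndarray,
    minute_of_day: np.ndarray,
    epoch_s: int,
    config: CutPointConfig,
) -> tuple[float, float, float, float, float]:
    """Fast core: (wear_min, mean_cpm, mvpa_min, sed_min, light_min)."""
    nw = nonwear_mask(counts, epoch_s, config.nonwear_min_minutes)
    in_window = (minute_of_day >= config.window_start_min) & (
        minute_of_day < config.window_end_min
    )
    wear = in_window & ~nw
    epoch_min = epoch_s / 60.0
    wear_minutes = float(wear.sum() * epoch_min)
    if wear_minutes == 0.0:
        return 0.0, float("nan"), 0.0, 0.0, 0.0
    cw = counts[wear]
    total = float(cw.sum())
    scale = epoch_s / 60.0
    mvpa = int((cw > config.mvpa_threshold_cpm * scale).sum())
    sed = int((cw < config.sedentary_threshold_cpm * scale).sum())
    light = len(cw) - mvpa - sed
    return (
        wear_minutes,
        total / wear_minutes,
        mvpa * epoch_min,
        sed * epoch_min,
        light * epoch_min,
    )


def summarise_day(
    day: pd.DataFrame,
    config: CutPointConfig | None = None,
    epoch_s: int | None = None,
    participant_id: str = "",
) -> DaySummary:
    """Reduce one participant-day of epochs to a :class:`DaySummary`.

    Non-wear runs are found on the whole supplied day, then epochs are
    restricted to the analysis window; wear minutes, mean cpm (total counts
    over wear time divided by wear minutes), MVPA and sedentary minutes and
    the valid-day flag are computed on what remains. A day with zero wear
    minutes yields ``mean_cpm = NaN`` and ``valid = False`` rather than a
    division error.
    """
    cfg = config or CutPointConfig()
    df = day.sort_values("timestamp")
    ts = pd.to_datetime(df["timestamp"])
    dates = ts.dt.date.unique()
    if len(dates) != 1:
        raise ValueError("summarise_day expects epochs from a single calendar date")
    eps = epoch_s if epoch_s is not None else infer_epoch_s(df["timestamp"])
    minute_of_day = (ts.dt.hour * 60 + ts.dt.minute).to_numpy()
    wear_min, mean_cpm, mvpa_min, sed_min, light_min = _summarise_arrays(
        df["counts"].to_numpy(), minute_of_day, eps, cfg
    )
    d = dates[0]
    return DaySummary(
        participant_id=participant_id or str(df.get("participant_id", pd.Series([""])).iloc[0]),
        date=d,
        day_type=_day_type(d),
        wear_minutes=wear_min,
        mean_cpm=mean_cpm,
        mvpa_minutes=mvpa_min,
        sedentary_minutes=sed_min,
        light_minutes=light_min,
        valid=wear_min >= cfg.valid_day_min_wear_minutes,
    )


def summarise_days(epochs: pd.DataFrame, config: CutPointConfig | None = None) -> pd.DataFrame:
    """Reduce a multi-participant epoch table to one row per participant-day."""
    cfg = config or CutPointConfig()
    df = epochs.sort_values(["participant_id", "timestamp"])
    ts = pd.to_datetime(df["timestamp"])
    sec = ts.astype("int64").to_numpy() // 10**9
    minute_of_day = (sec % 86400) // 60
    day_key = sec // 86400
    counts = df["counts"].to_numpy()
    pids = df["participant_id"].to_numpy()

    rows = []
    # group boundaries over (participant, day)
    change = np.flatnonzero((pids[1:] != pids[:-1]) | (day_key[1:] != day_key[:-1])) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(df)]))
    date_index = ts.dt.date.to_numpy()
    for s, e in zip(starts, ends):
        eps = infer_epoch_s(ts.iloc[s : min(s + 3, e)]) if e - s > 1 else 60
        wear_min, mean_cpm, mvpa_min, sed_min, light_min = _summarise_arrays(
            counts[s:e], minute_of_day[s:e], eps, cfg
        )
        d = date_index[s]
        rows.append(
            {
                "participant_id": pids[s],
                "date": d,
                "day_type": _day_type(d),
                "wear_minutes": wear_min,
                "mean_cpm": mean_cpm,
                "mvpa_minutes": mvpa_min,
                "sedentary_minutes": sed_min,
                "light_minutes": light_min,
                "valid": wear_min >= cfg.valid_day_min_wear_minutes,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hourly profiles and working-hours comparison


def _per_participant_hourly(
    epochs: pd.DataFrame, config: CutPointConfig
) -> pd.DataFrame:
    """Per-participant mean cpm by clock hour over valid days.

    Pools each participant's valid days: for each hour, total counts over wear
    epochs divided by wear minutes in that hour; hours with no wear are NaN.
    """
    cfg = config
    df = epochs.sort_values(["participant_id", "timestamp"])
    ts = pd.to_datetime(df["timestamp"])
    sec = ts.astype("int64").to_numpy() // 10**9
    minute_of_day = (sec % 86400) // 60
    hour = minute_of_day // 60
    day_key = sec // 86400
    counts = df["counts"].to_numpy()
    pids = df["participant_id"].to_numpy()

    first_h = cfg.window_start_min // 60
    last_h = (cfg.window_end_min - 1) // 60
    hours = np.arange(first_h, last_h + 1)

    acc: dict[str, np.ndarray] = {}
    wearmin: dict[str, np.ndarray] = {}

    change = np.flatnonzero((pids[1:] != pids[:-1]) | (day_key[1:] != day_key[:-1])) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(df)]))
    for s, e in zip(starts, ends):
        eps = infer_epoch_s(ts.iloc[s : min(s + 3, e)]) if e - s > 1 else 60
        c = counts[s:e]
        mod = minute_of_day[s:e]
        nw = nonwear_mask(c, eps, cfg.nonwear_min_minutes)
        in_window = (mod >= cfg.window_start_min) & (mod < cfg.window_end_min)
        wear = in_window & ~nw
        wear_minutes = wear.sum() * eps / 60.0
        if wear_minutes < cfg.valid_day_min_wear_minutes:
            continue
        pid = pids[s]
        if pid not in acc:
            acc[pid] = np.zeros(len(hours))
            wearmin[pid] = np.zeros(len(hours))
        h = hour[s:e][wear] - first_h
        acc[pid] += np.bincount(h, weights=c[wear], minlength=len(hours))
        wearmin[pid] += np.bincount(h, minlength=len(hours)) * eps / 60.0

    out = {}
    for pid in acc:
        with np.errstate(invalid="ignore", divide="ignore"):
            out[pid] = np.where(wearmin[pid] > 0, acc[pid] / np.maximum(wearmin[pid], 1e-12), np.nan)
    res = pd.DataFrame(out, index=hours).T
    res.columns = hours
    res.index.name = "participant_id"
    return res


def hourly_profile(
    epochs: pd.DataFrame,
    groups: Mapping[str, str],
    config: CutPointConfig | None = None,
) -> pd.DataFrame:
    """Mean cpm per clock hour per group (hours × groups).

    For each hour of the analysis window, each contributing participant's cpm
    is counts-in-hour over wear-minutes-in-hour pooled across their valid
    days; the group value is the mean over participants with wear that hour.
    """
    cfg = config or CutPointConfig()
    per_pid = _per_participant_hourly(epochs, cfg)
    group_names = sorted(set(groups.values()))
    cols = {}
    for g in group_names:
        members = [p for p in per_pid.index if groups.get(p) == g]
        if not members:
            raise ValueError(f"group {g!r} has no participants with valid days")
        cols[g] = per_pid.loc[members].mean(axis=0, skipna=True)
    out = pd.DataFrame(cols)
    out.index.name = "hour"
    return out


def working_hours_comparison(
    epochs: pd.DataFrame,
    groups: Mapping[str, str],
    config: CutPointConfig | None = None,
    start_hour: int = 9,
    end_hour: int = 16,
    weekdays_only: bool = True,
):
    """Group mean cpm within a clock-hour window, compared by one-way ANOVA.

    Defaults to the 09:00–16:00 core working-hours window on weekdays.
    Returns a :class:`activecommute.stats.GroupComparison`.
    """
    from .stats import compare_groups

    if end_hour <= start_hour:
        raise ValueError("empty comparison window")
    cfg = (config or CutPointConfig()).replace(
        window_start_min=max(start_hour * 60, (config or CutPointConfig()).window_start_min),
        window_end_min=min(end_hour * 60, (config or CutPointConfig()).window_end_min),
        # the valid-day criterion is assessed on the full window by callers;
        # within the sub-window we only require some wear
        valid_day_min_wear_minutes=1e-9,
    )
    df = epochs
    if weekdays_only:
        ts = pd.to_datetime(df["timestamp"])
        df = df[ts.dt.weekday < 5]
    per_pid = _per_participant_hourly(df, cfg)
    mean_cpm = per_pid.mean(axis=1, skipna=True)
    values = {}
    for g in sorted(set(groups.values())):
        members = [p for p in mean_cpm.index if groups.get(p) == g]
        values[g] = mean_cpm.loc[members].dropna().to_numpy()
    return compare_groups(values)
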