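"""Synthetic commuter cohorts with known ground truth.

Generates, for each simulated participant, a week of epoch-level
accelerometer counts, GPS traces for the commute to and from work, a travel
diary and demographics, together with a :class:`GroundTruth` record of every
injected event (day modes, journey windows, non-wear windows, MVPA minutes).
Every downstream stage of the pipeline — data reduction, journey
segmentation, mode classification and the comparative statistics — is
therefore testable without any field data.

What the generator emulates
---------------------------
* Counts are produced directly at epoch level (no raw 30 Hz signal): each
  waking minute is drawn as sedentary, light or moderate-to-vigorous from an
  hour-of-day background intensity profile, then commute windows overwrite
  the background with mode-specific count distributions (brisk-walking counts
  for walkers, near-sedentary counts for car passengers).
* The device is worn during waking hours only; outside the wake window and
  during injected non-wear runs counts are exactly zero.
* GPS fixes appear only during commutes, every ``epoch_s`` seconds along a
  waypoint polyline between home and work, with isotropic Gaussian position
  jitter and random fix dropout. A homeward "shop detour" is a mid-route
  stationary cluster with sub-sedentary counts, so it lengthens the journey
  without adding MVPA.
* Weekends have no commute and a flatter background profile.

Reproducibility: one global seed drives per-participant child streams via
``np.random.SeedSequence([seed, participant_index])``, so a cohort is
bit-identical for a fixed seed and reproducible participant by participant.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from datetime import date as _date, datetime, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geo import haversine_m

logger = logging.getLogger(__name__)

MODES = ("walk", "car", "cycle", "mixed_other")

#: nominal travel speeds by day mode, m/s
MODE_SPEED_M_S = {"walk": 5.0 / 3.6, "car": 20.0 / 3.6, "cycle": 15.0 / 3.6, "other": 12.0 / 3.6}

# background minute-state intensity model (counts per minute)
SEDENTARY_CPM = 40.0
LIGHT_CPM = 700.0
LIGHT_CPM_SD = 200.0
BOUT_MVPA_CPM = 3300.0
BOUT_MVPA_CPM_SD = 500.0
LIGHT_TO_MVPA_RATIO = 2.0   # a light minute is twice as likely as an MVPA minute
DETOUR_CPM = 50.0           # standing around in a shop
MVPA_CUTPOINT_CPM = 1952.0  # ground-truth MVPA definition

DEFAULT_WEEKDAY_PROFILE = {
    6: 250.0, 7: 300.0, 8: 330.0, 9: 370.0, 10: 370.0, 11: 370.0, 12: 370.0,
    13: 370.0, 14: 370.0, 15: 370.0, 16: 360.0, 17: 340.0, 18: 320.0,
    19: 300.0, 20: 280.0, 21: 260.0, 22: 250.0, 23: 250.0,
}
DEFAULT_WEEKEND_PROFILE = {
    6: 280.0, 7: 320.0, 8: 360.0, 9: 390.0, 10: 390.0, 11: 390.0, 12: 390.0,
    13: 390.0, 14: 390.0, 15: 390.0, 16: 390.0, 17: 390.0, 18: 370.0,
    19: 340.0, 20: 320.0, 21: 290.0, 22: 260.0, 23: 250.0,
}

__all__ = [
    "ConfigError",
    "GenerationError",
    "CohortConfig",
    "CommuteWindow",
    "NonwearWindow",
    "DayPlan",
    "Cohort",
    "GroundTruth",
    "generate_cohort",
    "generate_day_stream",
    "generate_gps_trace",
    "make_route",
]


class ConfigError(ValueError):
    """Invalid cohort configuration, naming the offending field."""


class GenerationError(RuntimeError):
    """Inconsistent generation plan (e.g. overlapping injected windows)."""


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic commuter cohort.

    Defaults mirror the motivating study's measured conditions: 10-s epochs,
    five weekdays plus a weekend, single-trip commute times of 19.7 ± 8.3 min
    on foot and 10.7 ± 7.6 min by car, and brisk-walking intensities around
    4000 cpm. ``mode_cpm_effect`` is a controlled additive counts offset
    applied to walkers' wear epochs, used by calibration experiments where the
    true marginal travel-mode effect must be known exactly; it is zero in
    ordinary cohorts.
    """

    n_participants: int = 103
    mode_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"walk": 0.55, "car": 0.23, "cycle": 0.15, "mixed_other": 0.07}
    )
    n_weekdays: int = 5
    n_weekend_days: int = 2
    epoch_s: int = 10
    seed: int = 0
    walk_commute_minutes: tuple[float, float] = (19.7, 8.3)
    car_commute_minutes: tuple[float, float] = (10.7, 7.6)
    cycle_commute_minutes: tuple[float, float] = (12.0, 5.0)
    walk_intensity_cpm: tuple[float, float] = (4000.0, 900.0)
    car_intensity_cpm: float = 150.0
    cycle_intensity_cpm: tuple[float, float] = (450.0, 150.0)
    background_intensity: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_WEEKDAY_PROFILE)
    )
    background_intensity_weekend: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_WEEKEND_PROFILE)
    )
    nonwear_runs_per_day: float = 2.2
    nonwear_minutes_range: tuple[float, float] = (15.0, 90.0)
    detour_probability: float = 0.35
    detour_minutes: tuple[float, float] = (7.0, 2.0)
    gps_jitter_sd_m: float = 5.0
    gps_dropout: float = 0.02
    mode_cpm_effect: float = 0.0
    include_commutes: bool = True
    participant_activity_sd: float = 0.2
    day_mode_consistency: float = 0.92
    diary_missing_probability: float = 0.02
    diary_mismatch_probability: float = 0.02
    diary_nonreturn_probability: float = 0.05
    questionnaire_response_probability: float = 0.9
    include_gps: bool = True
    start_date: _date = _date(2012, 5, 7)  # a Monday
    wake_start_minute: tuple[float, float] = (430.0, 20.0)   # ~07:10
    wake_end_minute: tuple[float, float] = (1300.0, 20.0)    # ~21:40

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ConfigError("n_participants must be positive")
        props = dict(self.mode_proportions)
        unknown = set(props) - set(MODES)
        if unknown:
            raise ConfigError(f"mode_proportions has unknown modes: {sorted(unknown)}")
        if any(v < 0 for v in props.values()):
            raise ConfigError("mode_proportions values must be non-negative")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ConfigError("mode_proportions must sum to 1 within 1e-9")
        if self.epoch_s <= 0 or 60 % self.epoch_s != 0:
            raise ConfigError("epoch_s must divide 60")
        if self.n_weekdays < 0 or self.n_weekend_days < 0:
            raise ConfigError("n_weekdays and n_weekend_days must be non-negative")
        for name in (
            "walk_commute_minutes", "car_commute_minutes", "cycle_commute_minutes",
            "walk_intensity_cpm", "cycle_intensity_cpm", "detour_minutes",
            "wake_start_minute", "wake_end_minute",
        ):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ConfigError(f"{name} sd must be >= 0")
            if mean < 0:
                raise ConfigError(f"{name} mean must be >= 0")
        for name in ("nonwear_runs_per_day", "gps_jitter_sd_m", "participant_activity_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in (
            "detour_probability", "gps_dropout", "day_mode_consistency",
            "diary_missing_probability", "diary_mismatch_probability",
            "diary_nonreturn_probability", "questionnaire_response_probability",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.nonwear_minutes_range[0] > self.nonwear_minutes_range[1]:
            raise ConfigError("nonwear_minutes_range must be (low, high) with low <= high")


# ---------------------------------------------------------------------------
# day plans


@dataclass(frozen=True)
class CommuteWindow:
    """One planned commute: [start, end) minutes since midnight, a day mode,
    and an optional stationary detour sub-window (shop stop)."""

    start_min: float
    end_min: float
    mode: str
    direction: str                         # "to_work" | "from_work"
    detour: tuple[float, float] | None = None  # (start_min, end_min) inside the window


@dataclass(frozen=True)
class NonwearWindow:
    start_min: float
    end_min: float


@dataclass
class DayPlan:
    """Everything :func:`generate_day_stream` needs for one participant-day."""

    date: _date
    wake_start_min: float
    wake_end_min: float
    background_cpm: Mapping[int, float]
    commutes: tuple[CommuteWindow, ...] = ()
    nonwear: tuple[NonwearWindow, ...] = ()
    activity_multiplier: float = 1.0
    extra_cpm: float = 0.0


def _windows_overlap(windows: Sequence[tuple[float, float]]) -> bool:
    w = sorted(windows)
    return any(w[i][1] > w[i + 1][0] for i in range(len(w) - 1))


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, low: float, high: float) -> float:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    return float(min(max(mean, low), high))


# ---------------------------------------------------------------------------
# accelerometer day stream


def generate_day_stream(
    plan: DayPlan,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Generate one full calendar day of epoch counts from a day plan.

    Returns ``(epochs, truth)`` where ``epochs`` covers 00:00–24:00 at
    ``config.epoch_s`` spacing with zero counts outside the wake window, and
    ``truth`` records the injected wear, non-wear and MVPA quantities for the
    06:00–24:00 analysis window. Counts are non-negative integers.

    Raises :class:`GenerationError` when injected windows overlap.
    """
    eps = config.epoch_s
    spans = [(c.start_min, c.end_min) for c in plan.commutes] + [
        (w.start_min, w.end_min) for w in plan.nonwear
    ]
    if _windows_overlap(spans):
        raise GenerationError("injected commute/non-wear windows overlap")

    n = 86400 // eps
    per_min = 60 // eps
    counts = np.zeros(n, dtype=np.int64)

    def ep(minute: float) -> int:
        return int(round(minute * 60.0 / eps))

    wake0, wake1 = ep(plan.wake_start_min), ep(plan.wake_end_min)

    # background: draw a state for each waking minute from the hourly profile
    minutes = np.arange(1440)
    profile = np.array([plan.background_cpm.get(h, 250.0) for h in range(24)])
    m_cpm = profile[minutes // 60]
    denom = (BOUT_MVPA_CPM - SEDENTARY_CPM) + LIGHT_TO_MVPA_RATIO * (LIGHT_CPM - SEDENTARY_CPM)
    p_mvpa = np.clip(plan.activity_multiplier * (m_cpm - SEDENTARY_CPM) / denom, 0.0, 0.3)
    p_light = np.clip(LIGHT_TO_MVPA_RATIO * p_mvpa, 0.0, 0.6)
    u = rng.random(1440)
    state = np.zeros(1440, dtype=np.int8)            # 0 sedentary
    state[u < p_mvpa + p_light] = 1                  # 1 light
    state[u < p_mvpa] = 2                            # 2 mvpa bout
    state_ep = np.repeat(state, per_min)

    scale = eps / 60.0
    sed_idx = np.flatnonzero(state_ep == 0)
    counts[sed_idx] = rng.poisson(SEDENTARY_CPM * scale, len(sed_idx))
    light_idx = np.flatnonzero(state_ep == 1)
    counts[light_idx] = np.maximum(
        rng.normal(LIGHT_CPM, LIGHT_CPM_SD, len(light_idx)) * scale, 0.0
    ).astype(np.int64)
    mvpa_idx = np.flatnonzero(state_ep == 2)
    counts[mvpa_idx] = np.maximum(
        rng.normal(BOUT_MVPA_CPM, BOUT_MVPA_CPM_SD, len(mvpa_idx)) * scale, 0.0
    ).astype(np.int64)

    # commute windows overwrite the background
    for c in plan.commutes:
        s, e = ep(c.start_min), ep(c.end_min)
        k = e - s
        if k <= 0:
            continue
        if c.mode == "walk":
            mean, sd = config.walk_intensity_cpm
            counts[s:e] = np.maximum(rng.normal(mean, sd, k) * scale, 0.0).astype(np.int64)
        elif c.mode == "cycle":
            mean, sd = config.cycle_intensity_cpm
            counts[s:e] = np.maximum(rng.normal(mean, sd, k) * scale, 0.0).astype(np.int64)
        else:  # car / other motorised
            counts[s:e] = rng.poisson(config.car_intensity_cpm * scale, k)
        if c.detour is not None:
            ds, de = ep(c.detour[0]), ep(c.detour[1])
            counts[ds:de] = rng.poisson(DETOUR_CPM * scale, max(de - ds, 0))

    # controlled additive mode effect (calibration experiments)
    if plan.extra_cpm > 0:
        wear_idx = np.arange(wake0, wake1)
        counts[wear_idx] += rng.poisson(plan.extra_cpm * scale, len(wear_idx))

    # zero out non-wear and everything outside the wake window
    nonwear_mask = np.zeros(n, dtype=bool)
    for w in plan.nonwear:
        nonwear_mask[ep(w.start_min) : ep(w.end_min)] = True
    counts[nonwear_mask] = 0
    counts[:wake0] = 0
    counts[wake1:] = 0

    base = pd.Timestamp(plan.date)
    timestamps = base + pd.to_timedelta(np.arange(n) * eps, unit="s")
    epochs = pd.DataFrame({"timestamp": timestamps, "counts": counts})

    # ground truth for the 06:00–24:00 analysis window
    window = np.zeros(n, dtype=bool)
    window[ep(360.0) : ep(1440.0)] = True
    wake = np.zeros(n, dtype=bool)
    wake[wake0:wake1] = True
    wear = window & wake & ~nonwear_mask
    mvpa_thr = MVPA_CUTPOINT_CPM * scale
    truth = {
        "wear_minutes": float(wear.sum() * scale),
        "mvpa_minutes": float(((counts > mvpa_thr) & wear).sum() * scale),
        "nonwear": [
            [float(w.start_min), float(w.end_min)] for w in plan.nonwear
        ],
        "wake": [float(plan.wake_start_min), float(plan.wake_end_min)],
    }
    return epochs, truth


# ---------------------------------------------------------------------------
# GPS traces


def make_route(
    home_lat: float,
    home_lon: float,
    bearing_deg: float,
    length_m: float,
    n_segments: int = 5,
    wiggle_deg: float = 20.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Waypoint polyline of roughly ``length_m`` from home along a bearing.

    Not a street network: a gently wiggling polyline is enough to exercise
    geofencing, interpolation and distance arithmetic.
    """
    rng = rng or np.random.default_rng(0)
    seg = length_m / n_segments
    pts = [(home_lat, home_lon)]
    lat, lon = home_lat, home_lon
    b = math.radians(bearing_deg)
    for _ in range(n_segments):
        b += math.radians(rng.normal(0.0, wiggle_deg))
        dy = seg * math.cos(b)
        dx = seg * math.sin(b)
        lat = lat + dy / 111_320.0
        lon = lon + dx / (111_320.0 * math.cos(math.radians(home_lat)))
        pts.append((lat, lon))
    return np.array(pts)


def generate_gps_trace(
    route: np.ndarray,
    start_time: datetime | pd.Timestamp,
    speed_m_s: float,
    epoch_s: int = 10,
    jitter_sd_m: float = 0.0,
    dropout: float = 0.0,
    detour: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fixes every ``epoch_s`` seconds along a polyline at constant speed.

    The trace starts at the route start and ends at the route end (fence-post
    count ``floor(T / epoch_s) + 1`` where ``T`` is the travel time, plus any
    stationary detour). ``detour = (fraction_along_route, stop_seconds)``
    holds the position at that point mid-route. Position jitter is isotropic
    Gaussian with sd ``jitter_sd_m``; each interior fix is dropped with
    probability ``dropout`` (the first and last fixes are always kept so the
    trace touches both anchors).
    """
    route = np.asarray(route, dtype=float)
    if route.ndim != 2 or len(route) < 2:
        raise ValueError("route must contain at least two (lat, lon) waypoints")
    if speed_m_s <= 0:
        raise ValueError("speed must be positive")
    rng = rng or np.random.default_rng(0)

    seg_len = haversine_m(route[:-1, 0], route[:-1, 1], route[1:, 0], route[1:, 1])
    cum = np.concatenate(([0.0], np.cumsum(seg_len)))
    total_len = float(cum[-1])
    travel_t = total_len / speed_m_s
    stop_s = 0.0
    stop_at = None
    if detour is not None:
        frac, stop_s = detour
        if not (0.0 < frac < 1.0) or stop_s < 0:
            raise ValueError("detour must be (fraction in (0,1), stop seconds >= 0)")
        stop_at = frac * total_len
    total_t = travel_t + stop_s
    # fence-post count; a non-multiple travel time gets one extra fix clamped
    # to the route end so every trace terminates at the destination anchor
    n_fix = int(math.ceil(total_t / epoch_s - 1e-9)) + 1
    t = np.arange(n_fix) * float(epoch_s)

    # effective travel time excludes the stationary stop
    if stop_at is not None:
        t_stop0 = stop_at / speed_m_s
        t_eff = np.where(
            t < t_stop0, t, np.where(t < t_stop0 + stop_s, t_stop0, t - stop_s)
        )
    else:
        t_eff = t
    s = np.clip(t_eff * speed_m_s, 0.0, total_len)

    seg_idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg_len) - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_in_seg = np.where(
            seg_len[seg_idx] > 0, (s - cum[seg_idx]) / np.maximum(seg_len[seg_idx], 1e-12), 0.0
        )
    lat = route[seg_idx, 0] + frac_in_seg * (route[seg_idx + 1, 0] - route[seg_idx, 0])
    lon = route[seg_idx, 1] + frac_in_seg * (route[seg_idx + 1, 1] - route[seg_idx, 1])

    if jitter_sd_m > 0:
        lat = lat + rng.normal(0.0, jitter_sd_m, n_fix) / 111_320.0
        lon = lon + rng.normal(0.0, jitter_sd_m, n_fix) / (
            111_320.0 * np.cos(np.radians(route[0, 0]))
        )
    keep = np.ones(n_fix, dtype=bool)
    if dropout > 0 and n_fix > 2:
        keep[1:-1] = rng.random(n_fix - 2) >= dropout

    ts = pd.Timestamp(start_time) + pd.to_timedelta(t[keep], unit="s")
    return pd.DataFrame({"timestamp": ts, "lat": lat[keep], "lon": lon[keep]})


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class GroundTruth:
    """Machine-readable record of everything the generator injected."""

    participants: dict = field(default_factory=dict)

    def true_mode(self, pid: str) -> str:
        return self.participants[pid]["true_mode"]

    def day(self, pid: str, day: _date | str) -> dict:
        return self.participants[pid]["days"][str(day)]

    def to_json(self) -> str:
        return json.dumps({"participants": self.participants}, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(participants=json.loads(text)["participants"])


@dataclass
class Cohort:
    """In-memory synthetic cohort bundle (one table per output dialect)."""

    config: CohortConfig
    epochs: pd.DataFrame        # participant_id, timestamp, counts
    gps: pd.DataFrame           # participant_id, timestamp, lat, lon
    diary: pd.DataFrame         # participant_id, date, mode_to_work, mode_from_work
    demographics: pd.DataFrame
    anchors: pd.DataFrame       # participant_id, home/work lat/lon
    truth: GroundTruth


_INCOME_BANDS = ("lt_10k", "10k_20k", "20k_30k", "30k_40k", "40k_50k", "gt_50k", "not_disclosed")
_INCOME_P = (0.030, 0.121, 0.192, 0.131, 0.131, 0.304, 0.091)
_EDU_BANDS = ("none", "gcse", "btec_national", "a_level", "btec_higher", "degree", "postgraduate")
_EDU_P = (0.020, 0.089, 0.050, 0.128, 0.020, 0.445, 0.248)
_OCC_CLASSES = ("sedentary", "standing", "manual", "heavy_manual")
_OCC_P = (0.802, 0.158, 0.030, 0.010)

_HOME_BASE = (51.4545, -2.5879)  # urban south-west England


def _allocate_modes(config: CohortConfig, rng: np.random.Generator) -> list[str]:
    """Largest-remainder allocation of participants to modes, then shuffled."""
    props = {m: config.mode_proportions.get(m, 0.0) for m in MODES}
    n = config.n_participants
    raw = {m: props[m] * n for m in MODES}
    counts = {m: int(math.floor(raw[m])) for m in MODES}
    short = n - sum(counts.values())
    for m in sorted(MODES, key=lambda m: raw[m] - counts[m], reverse=True)[:short]:
        counts[m] += 1
    out: list[str] = []
    for m in MODES:
        out.extend([m] * counts[m])
    rng.shuffle(out)
    return out


def _dates(config: CohortConfig) -> tuple[list[_date], list[_date]]:
    weekdays, weekends = [], []
    d = config.start_date
    while len(weekdays) < config.n_weekdays:
        if d.weekday() < 5:
            weekdays.append(d)
        d += timedelta(days=1)
    while len(weekends) < config.n_weekend_days:
        if d.weekday() >= 5:
            weekends.append(d)
        d += timedelta(days=1)
    return weekdays, weekends


def _draw_demographics(pid: str, true_mode: str, rng: np.random.Generator, config: CohortConfig) -> dict:
    age = _truncnorm(rng, 36.3, 11.7, 18.0, 65.0)
    sex = "female" if rng.random() < 0.573 else "male"
    income = str(rng.choice(_INCOME_BANDS, p=np.array(_INCOME_P) / sum(_INCOME_P)))
    edu = str(rng.choice(_EDU_BANDS, p=np.array(_EDU_P) / sum(_EDU_P)))
    occ = str(rng.choice(_OCC_CLASSES, p=np.array(_OCC_P) / sum(_OCC_P)))
    emp = "full_time" if rng.random() < 0.875 else "part_time"
    if rng.random() < config.questionnaire_response_probability:
        q = "other" if true_mode == "mixed_other" else true_mode
    else:
        q = ""
    return {
        "participant_id": pid,
        "age": round(age, 1),
        "sex": sex,
        "income_band": income,
        "education_band": edu,
        "occupation_class": occ,
        "employment_pattern": emp,
        "questionnaire_mode": q,
    }


def _draw_day_mode(true_mode: str, rng: np.random.Generator, config: CohortConfig) -> str:
    if true_mode == "mixed_other":
        return str(rng.choice(["walk", "car", "other"], p=[0.4, 0.4, 0.2]))
    if rng.random() < config.day_mode_consistency:
        return true_mode
    alts = [m for m in ("walk", "car", "other") if m != true_mode]
    return str(rng.choice(alts))


def _commute_minutes_params(config: CohortConfig, mode: str) -> tuple[float, float]:
    return {
        "walk": config.walk_commute_minutes,
        "car": config.car_commute_minutes,
        "cycle": config.cycle_commute_minutes,
    }.get(mode, config.car_commute_minutes)


def _place_nonwear(
    rng: np.random.Generator,
    config: CohortConfig,
    wake0: float,
    wake1: float,
    blocked: list[tuple[float, float]],
) -> list[NonwearWindow]:
    runs: list[NonwearWindow] = []
    k = rng.poisson(config.nonwear_runs_per_day)
    lo, hi = config.nonwear_minutes_range
    pad = 2.0
    occupied = [(s - pad, e + pad) for s, e in blocked]
    for _ in range(k):
        dur = float(rng.uniform(lo, hi))
        for _attempt in range(25):
            start = float(rng.uniform(wake0, max(wake0 + 1.0, wake1 - dur)))
            span = (start, start + dur)
            if span[1] > wake1:
                continue
            if any(span[0] < e and s < span[1] for s, e in occupied):
                continue
            runs.append(NonwearWindow(start, start + dur))
            occupied.append((span[0] - pad, span[1] + pad))
            break
    return runs


def generate_cohort(config: CohortConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a full synthetic cohort and its ground truth.

    Deterministic for a fixed ``config.seed``: identical configs produce
    bit-identical bundles.
    """
    config.validate()
    eps = config.epoch_s
    cohort_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC040]))
    modes = _allocate_modes(config, cohort_rng)
    weekdays, weekends = _dates(config)

    epoch_frames: list[pd.DataFrame] = []
    gps_frames: list[pd.DataFrame] = []
    diary_rows: list[dict] = []
    demo_rows: list[dict] = []
    anchor_rows: list[dict] = []
    truth = GroundTruth()

    for i in range(config.n_participants):
        pid = f"P{i + 1:03d}"
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, i + 1]))
        true_mode = modes[i]
        demo = _draw_demographics(pid, true_mode, rng, config)
        demo_rows.append(demo)
        returns_diary = rng.random() >= config.diary_nonreturn_probability
        act_mult = float(np.clip(rng.normal(1.0, config.participant_activity_sd), 0.4, 1.8))

        # home, route and work anchor
        home_lat = _HOME_BASE[0] + rng.uniform(-0.05, 0.05)
        home_lon = _HOME_BASE[1] + rng.uniform(-0.05, 0.05)
        ref_mode = "walk" if true_mode == "mixed_other" else true_mode
        mean_min, sd_min = _commute_minutes_params(config, ref_mode)
        ref_minutes = _truncnorm(rng, mean_min, sd_min, 6.0, 45.0)
        route_len = MODE_SPEED_M_S[ref_mode if ref_mode in MODE_SPEED_M_S else "walk"] * ref_minutes * 60.0
        route = make_route(home_lat, home_lon, rng.uniform(0.0, 360.0), route_len, rng=rng)
        work_lat, work_lon = float(route[-1, 0]), float(route[-1, 1])
        anchor_rows.append(
            {
                "participant_id": pid,
                "home_lat": home_lat,
                "home_lon": home_lon,
                "work_lat": work_lat,
                "work_lon": work_lon,
            }
        )
        seg_len = haversine_m(route[:-1, 0], route[:-1, 1], route[1:, 0], route[1:, 1])
        actual_len = float(np.sum(seg_len))

        days_truth: dict[str, dict] = {}

        for day in weekdays + weekends:
            is_weekend = day.weekday() >= 5
            wake0 = round(_truncnorm(rng, *config.wake_start_minute, 330.0, 500.0))
            wake1 = round(_truncnorm(rng, *config.wake_end_minute, 1230.0, 1410.0))
            commutes: list[CommuteWindow] = []
            day_mode = None
            journeys_truth: list[dict] = []

            if not is_weekend:
                day_mode = _draw_day_mode(true_mode, rng, config)
            if not is_weekend and config.include_commutes:
                speed = MODE_SPEED_M_S.get(day_mode, MODE_SPEED_M_S["other"])
                # outbound
                depart_to = round(_truncnorm(rng, 495.0, 12.0, 465.0, 525.0))
                dur_to = actual_len / speed / 60.0 * float(np.clip(rng.normal(1.0, 0.08), 0.75, 1.25))
                dur_to = max(dur_to, 3.0)
                commutes.append(
                    CommuteWindow(depart_to, depart_to + dur_to, day_mode, "to_work")
                )
                # homeward, possibly with a shop detour
                depart_home = round(_truncnorm(rng, 1025.0, 12.0, 1000.0, 1055.0))
                dur_home = actual_len / speed / 60.0 * float(np.clip(rng.normal(1.0, 0.08), 0.75, 1.25))
                dur_home = max(dur_home, 3.0)
                detour = None
                stop_min = 0.0
                detour_frac = 0.5
                if day_mode == "walk" and rng.random() < config.detour_probability:
                    stop_min = _truncnorm(rng, *config.detour_minutes, 3.0, 12.0)
                    detour_frac = float(rng.uniform(0.35, 0.65))
                    stop_start = depart_home + detour_frac * dur_home
                    detour = (stop_start, stop_start + stop_min)
                commutes.append(
                    CommuteWindow(
                        depart_home,
                        depart_home + dur_home + stop_min,
                        day_mode,
                        "from_work",
                        detour=detour,
                    )
                )

            blocked = [(c.start_min, c.end_min) for c in commutes]
            nonwear = _place_nonwear(rng, config, wake0, wake1, blocked)

            plan = DayPlan(
                date=day,
                wake_start_min=wake0,
                wake_end_min=wake1,
                background_cpm=(
                    config.background_intensity_weekend if is_weekend else config.background_intensity
                ),
                commutes=tuple(commutes),
                nonwear=tuple(nonwear),
                activity_multiplier=act_mult,
                extra_cpm=config.mode_cpm_effect if true_mode == "walk" else 0.0,
            )
            epochs, day_truth = generate_day_stream(plan, config, rng)
            epochs.insert(0, "participant_id", pid)
            epoch_frames.append(epochs)

            # GPS traces for each commute
            if config.include_gps and not is_weekend:
                for c in commutes:
                    # snap to the epoch grid so fixes align with epoch starts
                    start_ts = pd.Timestamp(day) + pd.Timedelta(
                        seconds=round(c.start_min * 60.0 / eps) * eps
                    )
                    r = route if c.direction == "to_work" else route[::-1]
                    det = None
                    if c.detour is not None:
                        det = (detour_frac, (c.detour[1] - c.detour[0]) * 60.0)
                        travel_min = (c.end_min - c.start_min) - (c.detour[1] - c.detour[0])
                    else:
                        travel_min = c.end_min - c.start_min
                    sp = actual_len / (travel_min * 60.0)
                    trace = generate_gps_trace(
                        r,
                        start_ts,
                        sp,
                        epoch_s=eps,
                        jitter_sd_m=config.gps_jitter_sd_m,
                        dropout=config.gps_dropout,
                        detour=det,
                        rng=rng,
                    )
                    trace.insert(0, "participant_id", pid)
                    gps_frames.append(trace)
                    journeys_truth.append(
                        {
                            "direction": c.direction,
                            "start": str(start_ts),
                            "end": str(start_ts + pd.Timedelta(minutes=c.end_min - c.start_min)),
                            "mode": c.mode,
                            "detour": c.detour is not None,
                        }
                    )

            # diary entry
            if not is_weekend and returns_diary and day_mode is not None:
                to_mode, from_mode = day_mode, day_mode
                if rng.random() < config.diary_missing_probability:
                    if rng.random() < 0.5:
                        to_mode = "missing"
                    else:
                        from_mode = "missing"
                elif rng.random() < config.diary_mismatch_probability:
                    from_mode = str(
                        rng.choice([m for m in ("walk", "car", "other") if m != day_mode])
                    )
                diary_rows.append(
                    {
                        "participant_id": pid,
                        "date": str(day),
                        "mode_to_work": to_mode,
                        "mode_from_work": from_mode,
                    }
                )

            day_truth.update(
                {
                    "day_type": "weekend" if is_weekend else "weekday",
                    "day_mode": day_mode,
                    "journeys": journeys_truth,
                }
            )
            days_truth[str(day)] = day_truth

        truth.participants[pid] = {"true_mode": true_mode, "days": days_truth}

    epochs_all = pd.concat(epoch_frames, ignore_index=True)
    gps_all = (
        pd.concat(gps_frames, ignore_index=True)
        if gps_frames
        else pd.DataFrame(columns=["participant_id", "timestamp", "lat", "lon"])
    )
    cohort = Cohort(
        config=config,
        epochs=epochs_all,
        gps=gps_all,
        diary=pd.DataFrame(
            diary_rows, columns=["participant_id", "date", "mode_to_work", "mode_from_work"]
        ),
        demographics=pd.DataFrame(demo_rows),
        anchors=pd.DataFrame(anchor_rows),
        truth=truth,
    )
    return cohort, truth
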