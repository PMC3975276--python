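"""Merging, journey segmentation (vs exhaustive search), journey summaries."""
import numpy as np
import pandas as pd
import pytest

from activecommute.accel import CutPointConfig
from activecommute.geo import (
    AnchorPair,
    DEFAULT_COMMUTE_WINDOWS,
    commute_contribution,
    contribution_fraction,
    haversine_m,
    journeys_table,
    merge_acc_gps,
    segment_journeys,
)
from activecommute.simulate import (
    CohortConfig,
    generate_cohort,
)

from conftest import make_epoch_frame

HOME = (51.4500, -2.5900)
WORK = (51.4500, -2.5755)  # ~1 km east


def _anchors(radius=100.0):
    return AnchorPair(*HOME, *WORK, geofence_radius_m=radius)


def _fixes(times, points):
    return pd.DataFrame(
        {
            "timestamp": pd.to_datetime(times),
            "lat": [p[0] for p in points],
            "lon": [p[1] for p in points],
        }
    )


# ---------------------------------------------------------------------------
# merging


class TestMergeAccGps:
    def _epochs(self, n=30, start="2012-05-07 08:00:00"):
        return make_epoch_frame(np.arange(n) + 1, epoch_s=10, start=start)

    def test_aligned_streams_fully_matched(self):
        acc = self._epochs()
        gps = _fixes(acc["timestamp"], [HOME] * len(acc))
        merged = merge_acc_gps(acc, gps)
        assert merged["lat"].notna().all()
        assert len(merged) == len(acc)

    def test_gap_tolerance_threshold_arithmetic(self):
        # 30-s spine so a 7-s offset is farther than 5 s from *every* epoch
        # start; at 10-s spacing a 7-s-late fix is 3 s early for the next
        # epoch and is correctly matched to it
        acc = make_epoch_frame(np.arange(20), epoch_s=30, start="2012-05-07 08:00:00")
        near = _fixes(acc["timestamp"] + pd.Timedelta(seconds=3), [HOME] * len(acc))
        far = _fixes(acc["timestamp"] + pd.Timedelta(seconds=7), [HOME] * len(acc))
        assert merge_acc_gps(acc, near)["lat"].notna().all()
        assert merge_acc_gps(acc, far)["lat"].isna().all()

    def test_accelerometer_spine_is_preserved(self):
        acc = self._epochs()
        # extra fixes between epochs must not create rows
        mid = _fixes(acc["timestamp"] + pd.Timedelta(seconds=5), [WORK] * len(acc))
        merged = merge_acc_gps(acc, pd.concat([mid]))
        assert len(merged) == len(acc)
        assert merged["counts"].equals(acc["counts"])

    def test_dropout_fraction_matches_generator_parameter(self):
        rng = np.random.default_rng(8)
        acc = self._epochs(n=1000)
        keep = rng.random(1000) >= 0.02
        gps = _fixes(acc["timestamp"][keep], [HOME] * int(keep.sum()))
        merged = merge_acc_gps(acc, gps)
        frac = merged["lat"].notna().mean()
        assert frac == pytest.approx(0.98, abs=0.015)

    def test_order_insensitive_to_shuffling(self):
        rng = np.random.default_rng(3)
        acc = self._epochs()
        gps = _fixes(acc["timestamp"], [HOME] * len(acc))
        shuffled = merge_acc_gps(
            acc.sample(frac=1, random_state=1), gps.sample(frac=1, random_state=2)
        )
        straight = merge_acc_gps(acc, gps)
        pd.testing.assert_frame_equal(shuffled, straight)


# ---------------------------------------------------------------------------
# segmentation vs exhaustive search


def brute_force_journeys(merged, anchors, windows=DEFAULT_COMMUTE_WINDOWS, max_gap_min=5.0):
    """Exhaustive search over all candidate anchor-to-anchor spans.

    Enumerates every pair (i, j) of position-bearing epochs inside one commute
    window with i in one geofence and j in the other and no internal fix gap
    above the tolerance, then greedily keeps non-overlapping candidates by
    (longest span, earliest start). Independent of the production algorithm.
    """
    df = merged.sort_values("timestamp").reset_index(drop=True)
    ts = pd.to_datetime(df["timestamp"])
    sec = ts.astype("int64").to_numpy() / 1e9
    minute = ((sec % 86400) // 60).astype(int)
    has_pos = df["lat"].notna().to_numpy()
    lat, lon = df["lat"].to_numpy(), df["lon"].to_numpy()

    def fence(i):
        dh = haversine_m(lat[i], lon[i], anchors.home_lat, anchors.home_lon)
        dw = haversine_m(lat[i], lon[i], anchors.work_lat, anchors.work_lon)
        if dh <= anchors.geofence_radius_m:
            return "home"
        if dw <= anchors.geofence_radius_m:
            return "work"
        return None

    candidates = []
    for w0, w1 in windows:
        P = [i for i in range(len(df)) if has_pos[i] and w0 <= minute[i] < w1]
        for a in range(len(P)):
            for b in range(a + 1, len(P)):
                i, j = P[a], P[b]
                fi, fj = fence(i), fence(j)
                if fi is None or fj is None or fi == fj:
                    continue
                inner = [k for k in P if i <= k <= j]
                gaps = np.diff(sec[inner])
                if len(gaps) and gaps.max() > max_gap_min * 60.0:
                    continue
                direction = "to_work" if fi == "home" else "from_work"
                candidates.append((j - i, i, j, direction))
    candidates.sort(key=lambda c: (-c[0], c[1]))
    chosen = []
    for span, i, j, direction in candidates:
        if any(i <= cj and ci <= j for _, ci, cj, _ in chosen):
            continue
        chosen.append((span, i, j, direction))
    return sorted(
        (ts.iloc[i], ts.iloc[j], d) for _, i, j, d in chosen
    )


def _random_day(rng):
    """A random merged morning with position runs around the two anchors."""
    n = rng.integers(60, 200)
    start = pd.Timestamp("2012-05-07 07:30:00")
    acc = make_epoch_frame(rng.integers(0, 700, n), epoch_s=10, start=str(start))
    lat = np.full(n, np.nan)
    lon = np.full(n, np.nan)
    pos = 0
    while pos < n:
        run_len = int(rng.integers(3, 40))
        kind = rng.choice(["none", "home", "work", "travel", "far"])
        for k in range(pos, min(pos + run_len, n)):
            if kind == "none":
                continue
            if kind == "home":
                base, spread = HOME, 5e-4
            elif kind == "work":
                base, spread = WORK, 5e-4
            elif kind == "far":
                base, spread = (51.5000, -2.5000), 1e-3
            else:  # travel: drift between anchors
                f = (k - pos) / max(run_len - 1, 1)
                base = (
                    HOME[0] + f * (WORK[0] - HOME[0]),
                    HOME[1] + f * (WORK[1] - HOME[1]),
                )
                spread = 2e-4
            lat[k] = base[0] + rng.normal(0, spread)
            lon[k] = base[1] + rng.normal(0, spread)
        pos += run_len
    acc["lat"] = lat
    acc["lon"] = lon
    return acc


class TestSegmentationOracle:
    def test_matches_exhaustive_search_on_random_days(self):
        rng = np.random.default_rng(42)
        anchors = _anchors()
        checked = with_journeys = 0
        for _ in range(40):
            day = _random_day(rng)
            got = sorted(
                (pd.Timestamp(j.start), pd.Timestamp(j.end), j.direction)
                for j in segment_journeys(day, anchors)
            )
            want = brute_force_journeys(day, anchors)
            assert got == want
            checked += 1
            with_journeys += bool(want)
        assert checked == 40 and with_journeys >= 5  # the cases are not all trivial

    def test_trace_never_leaving_home_yields_no_journey(self):
        acc = make_epoch_frame(np.full(120, 300), epoch_s=10, start="2012-05-07 08:00:00")
        acc["lat"] = HOME[0]
        acc["lon"] = HOME[1]
        assert segment_journeys(acc, _anchors()) == []

    def test_degenerate_anchors_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            AnchorPair(*HOME, HOME[0], HOME[1] + 1e-4, geofence_radius_m=100.0)


# ---------------------------------------------------------------------------
# journeys on generated cohorts


@pytest.fixture(scope="module")
def clean_cohort():
    """Noise-free traces: exact fix positions, no dropout, guaranteed detours."""
    cfg = CohortConfig(
        n_participants=6,
        mode_proportions={"walk": 1.0},
        seed=17,
        gps_jitter_sd_m=0.0,
        gps_dropout=0.0,
        detour_probability=1.0,
        day_mode_consistency=1.0,
        diary_missing_probability=0.0,
        diary_mismatch_probability=0.0,
        diary_nonreturn_probability=0.0,
    )
    return generate_cohort(cfg)


def _segment_all(cohort, cutpoints):
    from activecommute.pipeline import segment_cohort_journeys

    return segment_cohort_journeys(cohort, cutpoints)


class TestJourneyRecovery:
    def test_noise_free_day_yields_two_journeys_within_a_minute(self, clean_cohort, cutpoints):
        cohort, truth = clean_cohort
        journeys = _segment_all(cohort, cutpoints)
        jt = journeys_table(journeys)
        n_true = sum(
            len(d["journeys"]) for p in truth.participants.values() for d in p["days"].values()
        )
        assert len(jt) >= 0.9 * n_true
        per_day = jt.groupby(["participant_id", "date"]).size()
        assert (per_day == 2).all()
        for j in journeys:
            g = next(
                g
                for g in truth.day(j.participant_id, j.date)["journeys"]
                if g["direction"] == j.direction
            )
            assert abs((pd.Timestamp(g["start"]) - pd.Timestamp(j.start)).total_seconds()) <= 60
            assert abs((pd.Timestamp(g["end"]) - pd.Timestamp(j.end)).total_seconds()) <= 60

    def test_homeward_detours_flagged_and_unproductive(self, clean_cohort, cutpoints):
        cohort, truth = clean_cohort
        jt = journeys_table(_segment_all(cohort, cutpoints))
        home = jt[jt["direction"] == "from_work"]
        out = jt[jt["direction"] == "to_work"]
        assert home["includes_detour"].all()          # detour_probability = 1
        assert not out["includes_detour"].any()
        # the stop lengthens the journey without adding MVPA
        assert home["duration_min"].mean() > out["duration_min"].mean() + 3.0
        assert abs(home["mvpa_min"].mean() - out["mvpa_min"].mean()) < 3.0
        # stationary shop time is not MVPA, so journey cpm drops homeward
        assert home["mean_cpm"].mean() < out["mean_cpm"].mean()

    def test_journey_mvpa_never_exceeds_day_total(self, clean_cohort, cutpoints):
        from activecommute.accel import summarise_days

        cohort, _ = clean_cohort
        jt = journeys_table(_segment_all(cohort, cutpoints))
        ds = summarise_days(cohort.epochs, cutpoints)
        per_day = jt.groupby(["participant_id", "date"], as_index=False)["mvpa_min"].sum()
        ds["date"] = pd.to_datetime(ds["date"]).dt.date
        per_day["date"] = pd.to_datetime(per_day["date"]).dt.date
        m = per_day.merge(ds, on=["participant_id", "date"])
        assert (m["mvpa_min"] <= m["mvpa_minutes"] + 1e-9).all()


# ---------------------------------------------------------------------------
# contribution


class TestContribution:
    def test_published_journey_share(self):
        assert contribution_fraction(38.0, 80.3) == pytest.approx(0.473, abs=5e-4)

    def test_all_mvpa_in_journeys_gives_one(self):
        assert contribution_fraction(42.0, 42.0) == 1.0

    def test_zero_total_mvpa_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            contribution_fraction(1.0, 0.0)

    def test_cohort_aggregate_bounded_and_consistent(self, clean_cohort, cutpoints):
        from activecommute.accel import summarise_days

        cohort, _ = clean_cohort
        jt = journeys_table(_segment_all(cohort, cutpoints))
        ds = summarise_days(cohort.epochs, cutpoints)
        per_pid, agg = commute_contribution(jt, ds)
        assert ((per_pid["fraction"] >= 0) & (per_pid["fraction"] <= 1)).all()
        assert 0 < agg["ratio_of_means"] < 1
        assert agg["ratio_of_means"] == pytest.approx(
            agg["mean_journey_mvpa_min"] / agg["mean_total_mvpa_min"]
        )
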