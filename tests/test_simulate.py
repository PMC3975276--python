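"""Synthetic cohort generator: determinism, injected structure, recoverability."""
import numpy as np
import pandas as pd
import pytest

from activecommute.accel import CutPointConfig, nonwear_mask, summarise_day
from activecommute.cohort import classify_participants
from activecommute.geo import haversine_m
from activecommute.simulate import (
    CohortConfig,
    CommuteWindow,
    ConfigError,
    DayPlan,
    DEFAULT_WEEKDAY_PROFILE,
    DEFAULT_WEEKEND_PROFILE,
    GenerationError,
    NonwearWindow,
    generate_cohort,
    generate_day_stream,
    generate_gps_trace,
    make_route,
)
from activecommute.io import write_cohort


def _rng(seed=0):
    return np.random.default_rng(seed)


def _plan(date="2012-05-07", commutes=(), nonwear=(), weekend=False, extra=0.0, mult=1.0):
    return DayPlan(
        date=pd.Timestamp(date).date(),
        wake_start_min=420,
        wake_end_min=1320,
        background_cpm=DEFAULT_WEEKEND_PROFILE if weekend else DEFAULT_WEEKDAY_PROFILE,
        commutes=tuple(commutes),
        nonwear=tuple(nonwear),
        activity_multiplier=mult,
        extra_cpm=extra,
    )


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw,field",
        [
            ({"n_participants": 0}, "n_participants"),
            ({"mode_proportions": {"walk": 0.5, "car": 0.6}}, "mode_proportions"),
            ({"mode_proportions": {"walk": 1.0, "jetpack": 0.0}}, "mode_proportions"),
            ({"epoch_s": 7}, "epoch_s"),
            ({"walk_intensity_cpm": (4000.0, -1.0)}, "walk_intensity_cpm"),
            ({"detour_probability": 1.5}, "detour_probability"),
        ],
    )
    def test_errors_name_the_offending_field(self, kw, field):
        with pytest.raises(ConfigError, match=field):
            CohortConfig(**kw)


class TestDeterminism:
    def test_same_seed_same_cohort(self):
        cfg = CohortConfig(n_participants=3, seed=7)
        c1, t1 = generate_cohort(cfg)
        c2, t2 = generate_cohort(cfg)
        pd.testing.assert_frame_equal(c1.epochs, c2.epochs)
        pd.testing.assert_frame_equal(c1.gps, c2.gps)
        pd.testing.assert_frame_equal(c1.diary, c2.diary)
        assert t1.to_json() == t2.to_json()

    def test_written_bundle_byte_identical(self, tmp_path):
        cfg = CohortConfig(n_participants=2, seed=7)
        for d in ("a", "b"):
            cohort, _ = generate_cohort(cfg)
            write_cohort(cohort, tmp_path / d, write_gpx_tracks=True)
        files_a = sorted((tmp_path / "a").rglob("*"))
        files_b = sorted((tmp_path / "b").rglob("*"))
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            if fa.is_file():
                assert fa.read_bytes() == fb.read_bytes(), fa.name

    def test_different_seeds_differ(self):
        c1, _ = generate_cohort(CohortConfig(n_participants=2, seed=1))
        c2, _ = generate_cohort(CohortConfig(n_participants=2, seed=2))
        assert not c1.epochs["counts"].equals(c2.epochs["counts"])


class TestDayStream:
    def test_injected_nonwear_window_is_all_zeros(self):
        plan = _plan(nonwear=[NonwearWindow(600, 625)])  # 25 min from 10:00
        epochs, truth = generate_day_stream(plan, CohortConfig(n_participants=1, seed=0), _rng(5))
        window = epochs.iloc[3600:3750]  # 10:00–10:25 at 10-s epochs
        assert (window["counts"] == 0).all()
        assert len(window) == 150
        # neighbours of the injected run are worn and (for this seed) non-zero
        assert epochs["counts"].iloc[3599] > 0 and epochs["counts"].iloc[3750] > 0

    def test_overlapping_injections_rejected(self):
        plan = _plan(
            commutes=[CommuteWindow(500, 530, "walk", "to_work")],
            nonwear=[NonwearWindow(520, 560)],
        )
        with pytest.raises(GenerationError, match="overlap"):
            generate_day_stream(plan, CohortConfig(n_participants=1, seed=0), _rng(0))

    def test_weekend_counts_stay_inside_background_envelope(self):
        epochs, _ = generate_day_stream(
            _plan(weekend=True), CohortConfig(n_participants=1, seed=0), _rng(9)
        )
        # highest background state is an MVPA bout ~N(3300, 500) cpm: 6 sd is
        # a generous envelope at 10-s epochs
        envelope = (3300 + 6 * 500) / 6.0
        assert epochs["counts"].max() <= envelope

    def test_walk_commute_intensity_matches_generator_parameter(self):
        cfg = CohortConfig(n_participants=1, seed=0)
        plan = _plan(commutes=[CommuteWindow(500, 540, "walk", "to_work")])
        epochs, _ = generate_day_stream(plan, cfg, _rng(3))
        walk = epochs.iloc[3000:3240]["counts"].to_numpy()  # 08:20–09:00
        mean_cpm = walk.mean() * 6
        mean, sd = cfg.walk_intensity_cpm
        assert abs(mean_cpm - mean) < 3 * sd * 6 / np.sqrt(len(walk))

    def test_walk_day_exceeds_car_day_mvpa_over_replicates(self):
        cfg = CohortConfig(n_participants=1, seed=0)
        cuts = CutPointConfig()
        wins = 0
        diffs = []
        for rep in range(100):
            plans = {}
            for mode in ("walk", "car"):
                commutes = [
                    CommuteWindow(500, 520, mode, "to_work"),
                    CommuteWindow(1030, 1050, mode, "from_work"),
                ]
                epochs, _ = generate_day_stream(
                    _plan(commutes=commutes), cfg, _rng(1000 + rep)
                )
                plans[mode] = summarise_day(epochs, cuts, participant_id="X").mvpa_minutes
            diffs.append(plans["walk"] - plans["car"])
            wins += plans["walk"] > plans["car"]
        assert wins >= 97
        assert np.mean(diffs) > 20  # two ~20-min brisk walks inject real MVPA


class TestGpsTrace:
    def test_fencepost_fix_counts(self):
        meridian_deg_m = 6_371_008.8 * np.pi / 180.0  # metres per degree of latitude
        route = np.array([[51.45, -2.59], [51.45 + 1000 / meridian_deg_m, -2.59]])  # 1 km north
        walk = generate_gps_trace(route, "2012-05-07 08:00:00", 5000 / 3600, epoch_s=10)
        assert len(walk) == 73  # 12 min of travel at 10-s spacing, fence-post
        fine = generate_gps_trace(route, "2012-05-07 08:00:00", 5000 / 3600, epoch_s=1)
        assert len(fine) == 721
        span = walk["timestamp"].iloc[-1] - walk["timestamp"].iloc[0]
        assert span == pd.Timedelta(minutes=12)

    def test_zero_jitter_fixes_lie_on_the_polyline(self):
        route = make_route(51.45, -2.59, 40.0, 1500.0, rng=_rng(2))
        trace = generate_gps_trace(route, "2012-05-07 08:00:00", 1.4, epoch_s=10)
        # every fix interpolates a segment: its distance to the nearest
        # segment endpoint pair sums to the segment length
        lat, lon = trace["lat"].to_numpy(), trace["lon"].to_numpy()
        ok = np.zeros(len(trace), dtype=bool)
        for a, b in zip(route[:-1], route[1:]):
            seg = haversine_m(a[0], a[1], b[0], b[1])
            d = haversine_m(lat, lon, a[0], a[1]) + haversine_m(lat, lon, b[0], b[1])
            ok |= np.abs(d - seg) < 0.15  # metres; 1e-6 degrees
        assert ok.all()

    def test_trace_spans_route_endpoints(self):
        route = make_route(51.45, -2.59, 220.0, 2000.0, rng=_rng(3))
        trace = generate_gps_trace(route, "2012-05-07 08:00:00", 1.4, epoch_s=10)
        assert haversine_m(trace["lat"].iloc[0], trace["lon"].iloc[0], *route[0]) < 1e-6
        assert haversine_m(trace["lat"].iloc[-1], trace["lon"].iloc[-1], *route[-1]) < 1e-6

    def test_car_trace_has_about_six_times_fewer_fixes(self):
        route = np.array([[51.45, -2.59], [51.47, -2.59]])
        walk = generate_gps_trace(route, "2012-05-07 08:00:00", 5 / 3.6, epoch_s=10)
        car = generate_gps_trace(route, "2012-05-07 08:00:00", 30 / 3.6, epoch_s=10)
        assert len(walk) / len(car) == pytest.approx(6.0, rel=0.05)

    def test_detour_holds_position_mid_route(self):
        route = np.array([[51.45, -2.59], [51.46, -2.59]])
        trace = generate_gps_trace(
            route, "2012-05-07 17:00:00", 1.4, epoch_s=10, detour=(0.5, 300.0)
        )
        steps = haversine_m(
            trace["lat"].iloc[:-1], trace["lon"].iloc[:-1], trace["lat"].iloc[1:], trace["lon"].iloc[1:]
        )
        stationary = np.sum(steps < 1e-6)
        assert stationary >= 29  # a 5-min hold at 10-s fixes

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="two"):
            generate_gps_trace(np.array([[51.0, -2.0]]), "2012-05-07", 1.0)
        with pytest.raises(ValueError, match="speed"):
            generate_gps_trace(np.array([[51.0, -2.0], [51.1, -2.0]]), "2012-05-07", 0.0)


class TestRecoverability:
    def test_usual_mode_recovered_for_95_percent(self, walk_car_cohort):
        cohort, truth = walk_car_cohort
        participants = classify_participants(cohort.diary, cohort.demographics)
        merged = participants.set_index("participant_id")["usual_mode"]
        hits = sum(
            merged[pid] == truth.true_mode(pid) for pid in merged.index
        )
        assert hits / len(merged) >= 0.95

    def test_nonwear_minutes_recovered_99_percent(self, small_cohort):
        cohort, truth = small_cohort
        eps = cohort.config.epoch_s
        injected = recovered = 0.0
        for pid, grp in cohort.epochs.groupby("participant_id"):
            for day, day_df in grp.groupby(pd.to_datetime(grp["timestamp"]).dt.date):
                counts = day_df.sort_values("timestamp")["counts"].to_numpy()
                mask = nonwear_mask(counts, eps, 20.0)
                for s, e in truth.day(pid, day)["nonwear"]:
                    if e - s < 20.0:
                        continue
                    i0, i1 = int(round(s * 60 / eps)), int(round(e * 60 / eps))
                    injected += (i1 - i0) * eps / 60.0
                    recovered += mask[i0:i1].sum() * eps / 60.0
        assert injected > 0
        assert recovered / injected >= 0.99

    def test_ground_truth_windows_fall_inside_wear(self, small_cohort):
        _, truth = small_cohort
        for pid, rec in truth.participants.items():
            for day, d in rec["days"].items():
                wake0, wake1 = d["wake"]
                for s, e in d["nonwear"]:
                    assert wake0 <= s < e <= wake1
                for j in d["journeys"]:
                    start_min = pd.Timestamp(j["start"]).hour * 60 + pd.Timestamp(j["start"]).minute
                    assert wake0 <= start_min <= wake1
                spans = [(s, e) for s, e in d["nonwear"]]
                spans += [
                    (
                        pd.Timestamp(j["start"]).hour * 60 + pd.Timestamp(j["start"]).minute,
                        pd.Timestamp(j["end"]).hour * 60 + pd.Timestamp(j["end"]).minute,
                    )
                    for j in d["journeys"]
                ]
                spans.sort()
                assert all(spans[i][1] <= spans[i + 1][0] for i in range(len(spans) - 1))
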