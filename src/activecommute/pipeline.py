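"""End-to-end pipeline orchestration.

Runs synthetic generation (or loads real-format inputs), accelerometer
reduction, journey segmentation, usual-mode classification and the
comparative statistics in order, writing every stage output plus a
machine-readable run manifest. Identical config + seed gives byte-identical
outputs (the manifest contains no wall-clock state).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__, accel, cohort as cohort_mod, geo, stats
from .accel import CutPointConfig
from .geo import AnchorPair, DEFAULT_COMMUTE_WINDOWS
from .io import (
    read_accel_dir,
    read_anchors_csv,
    read_demographics_csv,
    read_diary_csv,
    read_gps_csv,
    write_cohort,
)
from .simulate import Cohort, CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "participant_weekday_table"]

_FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and record context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Exactly one of ``synthetic`` (a :class:`CohortConfig`) or ``inputs``
    (paths to accel_dir / gps / diary / demographics / anchors files) must be
    given.
    """

    outdir: Path
    synthetic: CohortConfig | None = None
    inputs: Mapping[str, Path] | None = None
    cutpoints: CutPointConfig = field(default_factory=CutPointConfig)
    geofence_radius_m: float = 100.0
    max_internal_gap_min: float = 5.0
    commute_windows: tuple = DEFAULT_COMMUTE_WINDOWS
    seed: int = 0
    log_level: str = "INFO"
    write_gpx: bool = False

    def validate(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of synthetic config or input paths must be given")


def _config_hash(cfg: RunConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
        if isinstance(o, Path):
            return str(o)
        if isinstance(o, Mapping):
            return {str(k): enc(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [enc(v) for v in o]
        return o

    payload = enc(cfg)
    payload.pop("outdir", None)  # where a run lands must not change its identity
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def participant_weekday_table(
    analysis_set: pd.DataFrame, day_summaries: pd.DataFrame
) -> pd.DataFrame:
    """One row per analysed participant: valid-weekday means of the outcomes,
    coded regression covariates, and the walk dummy."""
    ds = day_summaries[(day_summaries["valid"]) & (day_summaries["day_type"] == "weekday")]
    agg = ds.groupby("participant_id", as_index=False).agg(
        mean_cpm=("mean_cpm", "mean"),
        mvpa_minutes=("mvpa_minutes", "mean"),
        sedentary_minutes=("sedentary_minutes", "mean"),
        wear_minutes=("wear_minutes", "mean"),
        n_valid_weekdays=("valid", "size"),
    )
    coded = cohort_mod.code_regression_covariates(analysis_set)
    return coded.merge(agg, on="participant_id", how="inner")


def _group_table(
    day_summaries: pd.DataFrame, modes: pd.Series, day_type: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group means ± sd and ANOVA for the three outcomes on one day type."""
    ds = day_summaries[(day_summaries["valid"]) & (day_summaries["day_type"] == day_type)]
    per_pid = ds.groupby("participant_id", as_index=False).agg(
        mean_cpm=("mean_cpm", "mean"),
        mvpa_minutes=("mvpa_minutes", "mean"),
        sedentary_minutes=("sedentary_minutes", "mean"),
    )
    per_pid["mode"] = per_pid["participant_id"].map(modes)
    per_pid = per_pid.dropna(subset=["mode"])
    rows = []
    for outcome in ("mean_cpm", "mvpa_minutes", "sedentary_minutes"):
        values = {
            m: grp[outcome].to_numpy() for m, grp in per_pid.groupby("mode")
        }
        gc = stats.compare_groups(values)
        for g, st in gc.groups.items():
            rows.append(
                {
                    "period": day_type,
                    "outcome": outcome,
                    "group": g,
                    "n": st.n,
                    "mean": st.mean,
                    "sd": st.sd,
                    "f": gc.f,
                    "p": gc.p,
                }
            )
    return pd.DataFrame(rows), per_pid


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write all artefacts under ``config.outdir``.

    Returns a dict of the in-memory stage results (tables and fitted models)
    for programmatic use; files are the canonical record.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    results: dict = {}

    # ---- stage: inputs -----------------------------------------------------
    try:
        if config.synthetic is not None:
            syn = config.synthetic
            if syn.seed != config.seed:
                syn = dataclasses.replace(syn, seed=config.seed)
            cohort, truth = generate_cohort(syn)
            write_cohort(cohort, out / "cohort", write_gpx_tracks=config.write_gpx)
        else:
            paths = dict(config.inputs)
            cohort = Cohort(
                config=None,
                epochs=read_accel_dir(paths["accel_dir"]),
                gps=read_gps_csv(paths["gps"]) if "gps" in paths else pd.DataFrame(
                    columns=["participant_id", "timestamp", "lat", "lon"]
                ),
                diary=read_diary_csv(paths["diary"]),
                demographics=read_demographics_csv(paths["demographics"]),
                anchors=read_anchors_csv(paths["anchors"]) if "anchors" in paths else pd.DataFrame(),
                truth=None,
            )
    except Exception as exc:
        raise PipelineError("inputs", str(exc)) from exc
    results["cohort"] = cohort

    # ---- stage: accelerometer reduction -----------------------------------
    try:
        day_summaries = accel.summarise_days(cohort.epochs, config.cutpoints)
        _write_csv(day_summaries, out / "day_summaries.csv")
    except Exception as exc:
        raise PipelineError("reduce", str(exc)) from exc
    results["day_summaries"] = day_summaries

    # ---- stage: journey segmentation ---------------------------------------
    try:
        journeys = segment_cohort_journeys(
            cohort,
            cutpoints=config.cutpoints,
            geofence_radius_m=config.geofence_radius_m,
            commute_windows=config.commute_windows,
            max_internal_gap_min=config.max_internal_gap_min,
        )
        jt = geo.journeys_table(journeys)
        jt_out = jt.copy()
        _write_csv(jt_out, out / "journeys.csv")
    except Exception as exc:
        raise PipelineError("segment", str(exc)) from exc
    results["journeys"] = jt

    # ---- stage: classification ---------------------------------------------
    try:
        participants = cohort_mod.classify_participants(cohort.diary, cohort.demographics)
        analysis_set, flow = cohort_mod.build_analysis_set(participants, day_summaries)
        _write_csv(participants, out / "participants.csv")
        _write_csv(analysis_set, out / "analysis_set.csv")
        (out / "flow_report.txt").write_text(flow.render())
    except Exception as exc:
        raise PipelineError("classify", str(exc)) from exc
    results["participants"] = participants
    results["analysis_set"] = analysis_set
    results["flow"] = flow

    # ---- stage: statistics --------------------------------------------------
    try:
        results.update(
            analyse(cohort, day_summaries, jt, analysis_set, config, out)
        )
    except Exception as exc:
        raise PipelineError("analyse", str(exc)) from exc

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": _config_hash(config),
        "n_participants": int(cohort.demographics.shape[0]),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    results["manifest"] = manifest
    return results


def segment_cohort_journeys(
    cohort: Cohort,
    cutpoints: CutPointConfig,
    geofence_radius_m: float = 100.0,
    commute_windows=DEFAULT_COMMUTE_WINDOWS,
    max_internal_gap_min: float = 5.0,
) -> list[geo.Journey]:
    """Merge and segment every participant-day with GPS data."""
    journeys: list[geo.Journey] = []
    if len(cohort.gps) == 0 or len(cohort.anchors) == 0:
        return journeys
    anchors_by_pid = {
        r["participant_id"]: AnchorPair(
            r["home_lat"], r["home_lon"], r["work_lat"], r["work_lon"], geofence_radius_m
        )
        for _, r in cohort.anchors.iterrows()
    }
    gps = cohort.gps.copy()
    gps["timestamp"] = pd.to_datetime(gps["timestamp"])
    gps["date"] = gps["timestamp"].dt.date
    epochs = cohort.epochs.copy()
    epochs["timestamp"] = pd.to_datetime(epochs["timestamp"])
    # the accelerometer spine outside the commute windows can never belong to
    # a journey, so restrict it before the per-day merge
    minute_of_day = epochs["timestamp"].dt.hour * 60 + epochs["timestamp"].dt.minute
    in_any_window = np.zeros(len(epochs), dtype=bool)
    for w_start, w_end in commute_windows:
        in_any_window |= ((minute_of_day >= w_start) & (minute_of_day < w_end)).to_numpy()
    epochs = epochs[in_any_window]
    epochs = epochs.assign(date=epochs["timestamp"].dt.date)
    acc_groups = {k: g for k, g in epochs.groupby(["participant_id", "date"])}
    for (pid, day), fixes in gps.groupby(["participant_id", "date"]):
        if pid not in anchors_by_pid:
            continue
        day_epochs = acc_groups.get((pid, day))
        if day_epochs is None:
            continue
        merged = geo.merge_acc_gps(
            day_epochs[["participant_id", "timestamp", "counts"]], fixes
        )
        journeys.extend(
            geo.segment_journeys(
                merged,
                anchors_by_pid[pid],
                commute_windows=commute_windows,
                max_internal_gap_min=max_internal_gap_min,
                config=cutpoints,
                participant_id=pid,
            )
        )
    return journeys


def analyse(
    cohort: Cohort,
    day_summaries: pd.DataFrame,
    journeys: pd.DataFrame,
    analysis_set: pd.DataFrame,
    config: RunConfig,
    out: Path,
) -> dict:
    """The comparative statistics over the analysis cohort; writes the
    presentation-shaped CSV outputs."""
    results: dict = {}
    modes = analysis_set.set_index("participant_id")["usual_mode"]
    groups = modes.to_dict()

    # group summaries (weekday + weekend), paired tests
    tables = []
    per_pid_frames = {}
    for day_type in ("weekday", "weekend"):
        try:
            tbl, per_pid = _group_table(day_summaries, modes, day_type)
        except ValueError:
            continue
        tables.append(tbl)
        per_pid_frames[day_type] = per_pid
    group_summaries = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    _write_csv(group_summaries, out / "group_summaries.csv")
    results["group_summaries"] = group_summaries

    paired_rows = []
    if {"weekday", "weekend"} <= set(per_pid_frames):
        wd = per_pid_frames["weekday"].set_index("participant_id")
        we = per_pid_frames["weekend"].set_index("participant_id")
        both = wd.join(we, lsuffix="_wd", rsuffix="_we", how="inner")
        for outcome in ("mean_cpm", "mvpa_minutes", "sedentary_minutes"):
            if len(both) >= 2:
                t, p = stats.paired_weekday_weekend(
                    both[f"{outcome}_wd"], both[f"{outcome}_we"]
                )
                paired_rows.append({"outcome": outcome, "n_pairs": len(both), "t": t, "p": p})
    paired = pd.DataFrame(paired_rows, columns=["outcome", "n_pairs", "t", "p"])
    _write_csv(paired, out / "paired_weekday_weekend.csv")
    results["paired_weekday_weekend"] = paired

    # percent differences on the weekday group means
    pct_rows = []
    wd_tbl = group_summaries[group_summaries["period"] == "weekday"] if len(group_summaries) else None
    if wd_tbl is not None:
        for outcome in ("mean_cpm", "mvpa_minutes"):
            sub = wd_tbl[wd_tbl["outcome"] == outcome].set_index("group")["mean"]
            if {"walk", "car"} <= set(sub.index):
                pct_rows.append(
                    {
                        "outcome": outcome,
                        "walk_mean": sub["walk"],
                        "car_mean": sub["car"],
                        "percent_difference": stats.percent_difference(sub["walk"], sub["car"]),
                    }
                )
    pct = pd.DataFrame(pct_rows, columns=["outcome", "walk_mean", "car_mean", "percent_difference"])
    _write_csv(pct, out / "percent_differences.csv")
    results["percent_differences"] = pct

    # adjusted linear models (one row per participant, weekday means)
    reg_table = participant_weekday_table(analysis_set, day_summaries)
    models = {}
    reg_rows = []
    for outcome in ("mean_cpm", "mvpa_minutes", "sedentary_minutes"):
        try:
            model = stats.fit_adjusted_model(reg_table, outcome)
        except ValueError as exc:
            logger.warning("adjusted model for %s not fitted: %s", outcome, exc)
            continue
        models[outcome] = model
        for t in model.terms:
            reg_rows.append(
                {
                    "outcome": outcome,
                    "term": t.term,
                    "coef": t.coef,
                    "ci_low": t.ci_low,
                    "ci_high": t.ci_high,
                    "p": t.p,
                }
            )
    _write_csv(
        pd.DataFrame(reg_rows, columns=["outcome", "term", "coef", "ci_low", "ci_high", "p"]),
        out / "adjusted_models.csv",
    )
    results["adjusted_models"] = models
    results["regression_table"] = reg_table

    # hourly profile + working-hours window
    analysed_pids = set(analysis_set["participant_id"])
    epochs_analysed = cohort.epochs[cohort.epochs["participant_id"].isin(analysed_pids)]
    wd_mask = pd.to_datetime(epochs_analysed["timestamp"]).dt.weekday < 5
    try:
        profile = accel.hourly_profile(
            epochs_analysed[wd_mask], groups, config.cutpoints
        )
        profile.reset_index().to_csv(out / "hourly_profile.csv", index=False, float_format=_FLOAT_FMT)
        results["hourly_profile"] = profile
    except ValueError as exc:
        logger.warning("hourly profile skipped: %s", exc)
    try:
        wh = accel.working_hours_comparison(epochs_analysed, groups, config.cutpoints)
        _write_csv(
            pd.DataFrame(
                [
                    {"group": g, "n": s.n, "mean": s.mean, "sd": s.sd, "f": wh.f, "p": wh.p}
                    for g, s in wh.groups.items()
                ]
            ),
            out / "working_hours.csv",
        )
        results["working_hours"] = wh
    except ValueError as exc:
        logger.warning("working-hours comparison skipped: %s", exc)

    # day-level comparison: label each valid weekday by its diary day mode
    diary = cohort.diary.copy()
    if len(diary):
        diary["day_mode"] = [
            cohort_mod.classify_day(a, b)
            for a, b in zip(diary["mode_to_work"], diary["mode_from_work"])
        ]
        diary["date"] = pd.to_datetime(diary["date"]).dt.date
        ds = day_summaries.copy()
        ds["date"] = pd.to_datetime(ds["date"]).dt.date
        day_rows = ds[(ds["valid"]) & (ds["day_type"] == "weekday")].merge(
            diary[["participant_id", "date", "day_mode"]],
            on=["participant_id", "date"],
            how="inner",
        )
        day_rows = day_rows[day_rows["day_mode"].isin(("walk", "car"))]
        try:
            dl = stats.day_level_comparison(day_rows)
            _write_csv(
                pd.DataFrame(
                    [
                        {"day_mode": g, "n_days": s.n, "mean_cpm": s.mean, "sd": s.sd, "f": dl.f, "p": dl.p}
                        for g, s in dl.groups.items()
                    ]
                ),
                out / "day_level_comparison.csv",
            )
            results["day_level"] = dl
        except ValueError as exc:
            logger.warning("day-level comparison skipped: %s", exc)

    # commute contribution to daily MVPA (walkers with GPS journeys)
    if len(journeys):
        walk_pids = {p for p, m in groups.items() if m == "walk"}
        jw = journeys[journeys["participant_id"].isin(walk_pids)]
        if len(jw):
            per_pid, agg = geo.commute_contribution(jw, day_summaries)
            _write_csv(per_pid, out / "commute_contribution.csv")
            (out / "commute_contribution_cohort.json").write_text(
                json.dumps(agg, indent=1, sort_keys=True)
            )
            results["contribution_per_participant"] = per_pid
            results["contribution_cohort"] = agg
    return results
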