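"""Travel-diary processing and participant classification.

Participants are categorised by their usual commute mode over the measured
week: only days reporting the same mode both to and from work count, the most
frequent such mode wins, and participants with no classifiable diary days
fall back to their questionnaire-reported mode. Usual cyclists are excluded
(waist-worn accelerometers under-record cycling) as are mixed/other modes,
and the analysis set keeps only usual walkers and drivers with at least one
valid accelerometer day.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DAY_MODES = ("walk", "car", "cycle", "other", "missing")
USUAL_MODES = ("walk", "car", "cycle", "mixed_other", "unclassifiable")
ANALYSIS_MODES = ("walk", "car")

__all__ = [
    "DAY_MODES",
    "USUAL_MODES",
    "FlowReport",
    "classify_day",
    "classify_usual_mode",
    "classify_participants",
    "build_analysis_set",
    "code_regression_covariates",
]


@dataclass
class FlowReport:
    """Participant-flow bookkeeping for the analysis set."""

    classified: int = 0
    excluded_cycle: int = 0
    excluded_mixed: int = 0
    excluded_unclassifiable: int = 0
    excluded_no_valid_days: int = 0
    analysed: int = 0

    def check_partition(self) -> bool:
        return self.classified == (
            self.analysed
            + self.excluded_cycle
            + self.excluded_mixed
            + self.excluded_unclassifiable
            + self.excluded_no_valid_days
        )

    def render(self) -> str:
        lines = [
            "Participant flow",
            "================",
            f"classified:                {self.classified}",
            f"excluded, usual cyclists:  {self.excluded_cycle}",
            f"excluded, mixed/other:     {self.excluded_mixed}",
            f"excluded, unclassifiable:  {self.excluded_unclassifiable}",
            f"excluded, no valid days:   {self.excluded_no_valid_days}",
            f"analysed (walk + car):     {self.analysed}",
        ]
        return "\n".join(lines) + "\n"


def classify_day(mode_to_work: str, mode_from_work: str) -> str | None:
    """Mode of one diary day, or None when the day is excluded.

    Only days where the same non-missing mode was used both to and from work
    are classifiable.
    """
    if mode_to_work == mode_from_work and mode_to_work not in ("missing", "", None):
        return mode_to_work
    return None


def classify_usual_mode(
    entries: Iterable[tuple[str, str]],
    questionnaire_mode: str | None = None,
) -> str:
    """Usual travel mode for one participant.

    ``entries`` are (mode_to_work, mode_from_work) diary pairs. The mode with
    the most classifiable days wins; a tie (no strict majority winner) maps to
    ``mixed_other``. With zero classifiable days the questionnaire mode is
    used; failing that the participant is ``unclassifiable``. A shared day
    mode outside walk/car/cycle counts toward ``mixed_other``.
    """
    day_modes = [m for m in (classify_day(a, b) for a, b in entries) if m is not None]
    if not day_modes:
        q = (questionnaire_mode or "").strip().lower()
        if q in ("walk", "car", "cycle"):
            return q
        if q in ("other", "mixed", "mixed_other"):
            return "mixed_other"
        return "unclassifiable"
    counts = Counter("mixed_other" if m not in ("walk", "car", "cycle") else m for m in day_modes)
    top = counts.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        logger.info("usual-mode tie (%s): assigned mixed_other", dict(counts))
        return "mixed_other"
    return top[0][0]


def classify_participants(
    diary: pd.DataFrame,
    demographics: pd.DataFrame,
) -> pd.DataFrame:
    """Classify every participant's usual mode from diary + questionnaire.

    Returns the demographics table with ``usual_mode`` and
    ``included_in_analysis`` columns appended. Participants present in the
    demographics table but absent from the diary are handled through the
    questionnaire fallback.
    """
    q_modes = (
        demographics.set_index("participant_id")["questionnaire_mode"]
        if "questionnaire_mode" in demographics.columns
        else pd.Series(dtype=object)
    )
    by_pid = {pid: grp for pid, grp in diary.groupby("participant_id")}
    rows = []
    for pid in demographics["participant_id"]:
        grp = by_pid.get(pid)
        pairs = (
            list(zip(grp["mode_to_work"], grp["mode_from_work"])) if grp is not None else []
        )
        q = q_modes.get(pid) if pid in q_modes.index else None
        usual = classify_usual_mode(pairs, q if isinstance(q, str) else None)
        rows.append({"participant_id": pid, "usual_mode": usual})
    out = demographics.merge(pd.DataFrame(rows), on="participant_id")
    out["included_in_analysis"] = out["usual_mode"].isin(ANALYSIS_MODES)
    return out


def build_analysis_set(
    participants: pd.DataFrame,
    day_summaries: pd.DataFrame,
) -> tuple[pd.DataFrame, FlowReport]:
    """Apply the inclusion rules and report the participant flow.

    Keeps usual walkers and usual drivers with at least one valid
    accelerometer day. Raises when the final cohort is empty.
    """
    report = FlowReport(classified=len(participants))
    valid_pids = set(
        day_summaries.loc[day_summaries["valid"], "participant_id"].unique()
    )
    keep = []
    for _, row in participants.iterrows():
        mode = row["usual_mode"]
        if mode == "cycle":
            report.excluded_cycle += 1
        elif mode == "mixed_other":
            report.excluded_mixed += 1
        elif mode == "unclassifiable":
            report.excluded_unclassifiable += 1
        elif row["participant_id"] not in valid_pids:
            report.excluded_no_valid_days += 1
        else:
            keep.append(row)
            report.analysed += 1
    if not keep:
        raise ValueError("analysis set is empty after exclusions")
    analysis = pd.DataFrame(keep).reset_index(drop=True)
    assert report.check_partition()
    return analysis, report


# ---------------------------------------------------------------------------
# covariate coding for the adjusted models

_DEGREE_BANDS = {"degree", "postgraduate"}
_HIGH_INCOME_BANDS = {"30k_40k", "40k_50k", "gt_50k"}


def code_regression_covariates(participants: pd.DataFrame) -> pd.DataFrame:
    """Dichotomise demographics to the adjusted-model coding.

    Reference levels: male, no degree, income ≤ £30,000 (undisclosed income
    is treated as the reference level), sedentary occupation, part-time work,
    car travel. Adds female / age_years / degree / income_gt_30k /
    nonsedentary / fulltime / walk columns.
    """
    df = participants.copy()
    df["female"] = (df["sex"].str.lower() == "female").astype(int)
    df["age_years"] = df["age"].astype(float)
    df["degree"] = df["education_band"].isin(_DEGREE_BANDS).astype(int)
    df["income_gt_30k"] = df["income_band"].isin(_HIGH_INCOME_BANDS).astype(int)
    df["nonsedentary"] = (df["occupation_class"].str.lower() != "sedentary").astype(int)
    df["fulltime"] = (df["employment_pattern"].str.lower() == "full_time").astype(int)
    if "usual_mode" in df.columns:
        df["walk"] = (df["usual_mode"] == "walk").astype(int)
    return df
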