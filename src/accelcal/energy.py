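"""Criterion intensity from indirect calorimetry.

Breath-by-breath VO2 is averaged over each bout's trimmed analysis window
(time-weighted, because breaths are irregular), divided by the participant's
resting VO2 to give METs, and coded into intensity categories:
sedentary < 1.5 METs, light [1.5, 3), moderate [3, 6), vigorous >= 6.  The
four categories are then collapsed to three (SB / LPA / MPA) by merging
vigorous into MPA.  Intensity is assigned per bout — the trimming exists to
make each bout a steady-state representative of one intensity — and broadcast
to the bout's epochs.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import ParticipantProfile, Vo2Trace
from .protocol import BoutAnnotation

INTENSITY4 = ("sedentary", "light", "moderate", "vigorous")
INTENSITY3 = ("SB", "LPA", "MPA")

LABELED_COLUMNS = [
    "participant_id",
    "location",
    "activity",
    "epoch_start_s",
    "svmgs",
    "mets",
    "intensity3",
]


def bout_mean_vo2(
    trace: Vo2Trace, annotation: BoutAnnotation, trim_s: float = 60.0
) -> float:
    """Time-weighted mean VO2 over the bout's analysis window.

    Each breath is weighted by the interval to the next breath; the last
    breath in the window is weighted to the window end.
    """
    w_start = annotation.bout_start_s + trim_s
    w_end = annotation.bout_end_s - trim_s
    if w_end <= w_start:
        raise ValueError("trim leaves an empty analysis window")
    in_win = (trace.times >= w_start) & (trace.times < w_end)
    t = trace.times[in_win]
    v = trace.vo2[in_win]
    if len(t) < 3:
        raise ValueError(
            f"participant {annotation.participant_id}, bout "
            f"{annotation.activity_name!r}: only {len(t)} breaths in the "
            "analysis window (need >= 3)"
        )
    weights = np.diff(np.append(t, w_end))
    return float(np.sum(weights * v) / np.sum(weights))


def vo2_to_mets(vo2: float, profile: ParticipantProfile) -> float:
    """METs = VO2 / the participant's age-specific resting VO2."""
    if profile.resting_vo2 <= 0:
        raise ValueError("profile has non-positive resting VO2")
    if vo2 <= 0:
        raise ValueError("vo2 must be positive")
    return vo2 / profile.resting_vo2


def code_intensity(
    mets: float,
    sed_max: float = 1.5,
    light_max: float = 3.0,
    vig_min: float = 6.0,
) -> str:
    """Four-category intensity with half-open boundaries [1.5, 3), [3, 6)."""
    if mets <= 0:
        raise ValueError("mets must be positive")
    if mets < sed_max:
        return "sedentary"
    if mets < light_max:
        return "light"
    if mets < vig_min:
        return "moderate"
    return "vigorous"


def recode_three(intensity4: str) -> str:
    """Collapse to SB / LPA / MPA; vigorous merges into MPA."""
    mapping = {"sedentary": "SB", "light": "LPA", "moderate": "MPA", "vigorous": "MPA"}
    try:
        return mapping[intensity4]
    except KeyError:
        raise ValueError(f"unknown intensity category {intensity4!r}") from None


def compute_bout_mets(
    traces: dict[str, Vo2Trace],
    annotations: Sequence[BoutAnnotation],
    profiles: Sequence[ParticipantProfile],
    trim_s: float = 60.0,
    sed_max: float = 1.5,
    light_max: float = 3.0,
    vig_min: float = 6.0,
) -> pd.DataFrame:
    """Per-bout criterion table: mean VO2, METs, 4- and 3-level intensity."""
    by_id = {p.id: p for p in profiles}
    rows = []
    for ann in annotations:
        profile = by_id[ann.participant_id]
        trace = traces[ann.participant_id]
        vo2 = bout_mean_vo2(trace, ann, trim_s)
        mets = vo2_to_mets(vo2, profile)
        i4 = code_intensity(mets, sed_max, light_max, vig_min)
        rows.append(
            {
                "participant_id": ann.participant_id,
                "activity": ann.activity_name,
                "bout_mean_vo2": vo2,
                "mets": mets,
                "intensity4": i4,
                "intensity3": recode_three(i4),
            }
        )
    return pd.DataFrame(rows)


def build_labeled_table(epochs: pd.DataFrame, bout_mets: pd.DataFrame) -> pd.DataFrame:
    """Join in-window epochs to their bout's criterion intensity.

    One row per analysis-window epoch per location; rest epochs are excluded.
    Every represented (participant, activity) bout must have a criterion entry.
    """
    win = epochs[epochs["in_analysis_window"] & (epochs["activity"] != "rest")]
    if win.empty:
        return pd.DataFrame(columns=LABELED_COLUMNS)
    have = set(zip(bout_mets["participant_id"], bout_mets["activity"]))
    need = set(zip(win["participant_id"], win["activity"]))
    missing = sorted(need - have)
    if missing:
        raise ValueError(f"bouts lacking a criterion MET value: {missing}")
    merged = win.merge(
        bout_mets[["participant_id", "activity", "mets", "intensity3"]],
        on=["participant_id", "activity"],
        how="left",
        validate="many_to_one",
    )
    return merged[LABELED_COLUMNS].reset_index(drop=True)
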