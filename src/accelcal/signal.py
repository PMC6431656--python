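"""Reduce raw triaxial signals to gravity-subtracted vector-magnitude epochs.

The epoch statistic is SVMgs, the convention of raw-accelerometry
post-processing: within each epoch, sum over samples of ``|sqrt(x²+y²+z²) − 1|``
with acceleration in g.  Gravity subtraction uses the absolute deviation from
1 g (not the positive part), so the statistic is rotation invariant and zero
exactly when every sample sits on the unit sphere.  Epochs are half-open
``[t, t+L)`` windows aligned to the recording start; a trailing partial epoch
is discarded.

Epoch tables are plain pandas DataFrames with columns
``participant_id, location, epoch_start_s, svmgs, activity, in_analysis_window``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import RawRecording
from .protocol import BoutAnnotation

EPOCH_COLUMNS = [
    "participant_id",
    "location",
    "epoch_start_s",
    "svmgs",
    "activity",
    "in_analysis_window",
]


def compute_svmgs(recording: RawRecording, epoch_length_s: float = 1.0) -> pd.DataFrame:
    """Summarise a uniform-rate recording into per-epoch SVMgs values.

    Each complete epoch of ``epoch_length_s`` seconds aggregates exactly
    ``sampling_rate * epoch_length_s`` samples; that product must be integral.
    """
    n = len(recording.times)
    if n == 0:
        raise ValueError("empty recording")
    if n < 2:
        raise ValueError("recording too short to establish a sampling rate")
    dt = np.diff(recording.times)
    if not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
        raise ValueError("non-uniform time step in recording")
    fs = 1.0 / dt[0]
    spe_f = fs * epoch_length_s
    spe = round(spe_f)
    if abs(spe_f - spe) > 1e-6 or spe < 1:
        raise ValueError(
            f"sampling rate {fs:.6g} Hz x epoch length {epoch_length_s} s is not an "
            "integral number of samples"
        )
    deviation = np.abs(recording.magnitude() - 1.0)
    n_epochs = n // spe
    if n_epochs == 0:
        raise ValueError("recording shorter than one epoch")
    svmgs = deviation[: n_epochs * spe].reshape(n_epochs, spe).sum(axis=1)
    t0 = recording.times[0]
    return pd.DataFrame(
        {
            "participant_id": recording.participant_id,
            "location": recording.location,
            "epoch_start_s": t0 + np.arange(n_epochs) * epoch_length_s,
            "svmgs": svmgs,
            "activity": "rest",
            "in_analysis_window": False,
        }
    )[EPOCH_COLUMNS]


def _check_annotations(annotations: Sequence[BoutAnnotation]) -> None:
    by_pid: dict[str, list[BoutAnnotation]] = {}
    for a in annotations:
        by_pid.setdefault(a.participant_id, []).append(a)
    for pid, anns in by_pid.items():
        anns = sorted(anns, key=lambda a: a.bout_start_s)
        for prev, nxt in zip(anns, anns[1:]):
            if nxt.bout_start_s < prev.bout_end_s:
                raise ValueError(
                    f"overlapping annotations for participant {pid}: "
                    f"{prev.activity_name} and {nxt.activity_name}"
                )


def annotate_epochs(
    epochs: pd.DataFrame, annotations: Sequence[BoutAnnotation]
) -> pd.DataFrame:
    """Label each epoch with the bout whose ``[start, end)`` holds its start.

    Epochs outside every bout are labelled ``"rest"``.
    """
    _check_annotations(annotations)
    out = epochs.copy()
    out["activity"] = "rest"
    for ann in annotations:
        mask = (
            (out["participant_id"] == ann.participant_id)
            & (out["epoch_start_s"] >= ann.bout_start_s)
            & (out["epoch_start_s"] < ann.bout_end_s)
        )
        out.loc[mask, "activity"] = ann.activity_name
    return out


def trim_bouts(
    epochs: pd.DataFrame,
    annotations: Sequence[BoutAnnotation],
    trim_s: float = 60.0,
) -> pd.DataFrame:
    """Discard the first and last ``trim_s`` seconds of every bout.

    ``in_analysis_window`` becomes true exactly for epochs whose bout-relative
    start lies in ``[trim_s, duration − trim_s)``; rest epochs never enter the
    analysis window.
    """
    if trim_s < 0:
        raise ValueError("trim_s must be >= 0")
    _check_annotations(annotations)
    for ann in annotations:
        if trim_s > 0 and ann.duration_s <= 2 * trim_s:
            raise ValueError(
                f"bout {ann.activity_name!r} of participant {ann.participant_id} "
                f"lasts {ann.duration_s:.0f} s, not more than twice the trim "
                f"({trim_s:.0f} s)"
            )
    out = epochs.copy()
    out["in_analysis_window"] = False
    for ann in annotations:
        mask = (
            (out["participant_id"] == ann.participant_id)
            & (out["epoch_start_s"] >= ann.bout_start_s + trim_s)
            & (out["epoch_start_s"] < ann.bout_end_s - trim_s)
        )
        out.loc[mask, "in_analysis_window"] = True
    return out
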