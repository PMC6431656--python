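"""CSV serialisation of datasets and reports, plus whole-study generation.

File formats (all plain CSV):

* ``participants.csv``  — id, age, sex, height_m, mass_kg, dominant_side,
  resting_vo2
* ``raw_signals.csv``   — participant_id, location, t_s, ax_g, ay_g, az_g
* ``vo2.csv``           — participant_id, t_s, vo2_mlkgmin, vco2_mlkgmin
* ``annotations.csv``   — participant_id, activity, start_s, end_s
* ``labeled_epochs.csv``— participant_id, location, activity, epoch_start_s,
  svmgs, mets, intensity3
* ``calibration.csv`` / ``validity.csv`` — the report tables.

The raw-signal file for a full default study holds tens of millions of rows,
so it is written through a streaming Arrow CSV writer, one recording at a
time, and never fully materialised during generation.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pyarrow as pa
import pyarrow.csv as pacsv

from .calibration import CALIBRATION_COLUMNS, VALIDITY_COLUMNS
from .cohort import (
    ParticipantProfile,
    RawRecording,
    Vo2Trace,
    build_annotations,
    generate_cohort,
    iter_session_recordings,
    simulate_session_vo2,
)
from .config import RunConfig
from .energy import LABELED_COLUMNS
from .protocol import BoutAnnotation, ProtocolSpec

log = logging.getLogger("accelcal")

DATASET_FILES = ("participants.csv", "raw_signals.csv", "vo2.csv", "annotations.csv")

_RAW_SCHEMA = pa.schema(
    [
        ("participant_id", pa.string()),
        ("location", pa.string()),
        ("t_s", pa.float64()),
        ("ax_g", pa.float64()),
        ("ay_g", pa.float64()),
        ("az_g", pa.float64()),
    ]
)


# ----------------------------------------------------------------- participants


def write_participants(profiles: Sequence[ParticipantProfile], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": [p.id for p in profiles],
            "age": [p.age for p in profiles],
            "sex": [p.sex for p in profiles],
            "height_m": [p.height for p in profiles],
            "mass_kg": [p.mass for p in profiles],
            "dominant_side": [p.dominant_side for p in profiles],
            "resting_vo2": [p.resting_vo2 for p in profiles],
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")


def read_participants(path: str | Path) -> list[ParticipantProfile]:
    df = pd.read_csv(path)
    return [
        ParticipantProfile(
            id=str(r.id),
            age=int(r.age),
            sex=str(r.sex),
            height=float(r.height_m),
            mass=float(r.mass_kg),
            dominant_side=str(r.dominant_side),
            resting_vo2=float(r.resting_vo2),
        )
        for r in df.itertuples()
    ]


# ----------------------------------------------------------------- annotations


def write_annotations(annotations: Sequence[BoutAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "participant_id": [a.participant_id for a in annotations],
            "activity": [a.activity_name for a in annotations],
            "start_s": [a.bout_start_s for a in annotations],
            "end_s": [a.bout_end_s for a in annotations],
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")


def read_annotations(path: str | Path) -> list[BoutAnnotation]:
    df = pd.read_csv(path)
    return [
        BoutAnnotation(str(r.participant_id), str(r.activity), float(r.start_s), float(r.end_s))
        for r in df.itertuples()
    ]


# ----------------------------------------------------------------- VO2


def write_vo2(traces: Iterable[Vo2Trace], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "participant_id": t.participant_id,
                "t_s": t.times,
                "vo2_mlkgmin": t.vo2,
                "vco2_mlkgmin": t.vco2,
            }
        )
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_vo2(path: str | Path) -> dict[str, Vo2Trace]:
    df = pd.read_csv(path)
    out = {}
    for pid, g in df.groupby("participant_id", sort=True):
        out[str(pid)] = Vo2Trace(
            participant_id=str(pid),
            times=g["t_s"].to_numpy(),
            vo2=g["vo2_mlkgmin"].to_numpy(),
            vco2=g["vco2_mlkgmin"].to_numpy(),
        )
    return out


# ----------------------------------------------------------------- raw signals


def write_raw_signals(recordings: Iterable[RawRecording], path: str | Path) -> int:
    """Stream recordings to CSV; returns the number of recordings written."""
    n = 0
    with pacsv.CSVWriter(str(path), _RAW_SCHEMA) as writer:
        for rec in recordings:
            table = pa.table(
                {
                    "participant_id": np.repeat(rec.participant_id, len(rec.times)),
                    "location": np.repeat(rec.location, len(rec.times)),
                    "t_s": np.round(rec.times, 6),
                    "ax_g": np.round(rec.ax, 6),
                    "ay_g": np.round(rec.ay, 6),
                    "az_g": np.round(rec.az, 6),
                },
                schema=_RAW_SCHEMA,
            )
            writer.write_table(table)
            n += 1
    return n


def iter_raw_recordings(path: str | Path) -> Iterator[RawRecording]:
    """Read a raw-signal CSV back as per participant x location recordings."""
    table = pacsv.read_csv(str(path))
    df = table.to_pandas()
    for (pid, loc), g in df.groupby(["participant_id", "location"], sort=True):
        yield RawRecording(
            participant_id=str(pid),
            location=str(loc),
            times=g["t_s"].to_numpy(),
            ax=g["ax_g"].to_numpy(),
            ay=g["ay_g"].to_numpy(),
            az=g["az_g"].to_numpy(),
        )


# ----------------------------------------------------------------- study generation


def generate_study(
    protocol: ProtocolSpec,
    n: int,
    seed: int,
    out_dir: str | Path,
    cfg: RunConfig | None = None,
) -> dict:
    """Generate and serialise a full synthetic study to ``out_dir``.

    Writes the four dataset CSVs and returns a manifest of what was written.
    Per-participant seed streams derive deterministically from ``seed``.
    """
    cfg = (cfg or RunConfig()).replace(master_seed=seed, n_participants=n)
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create output directory {out}: {e}") from e
    profiles = generate_cohort(n, seed, cfg)
    annotations = build_annotations(profiles, protocol)
    write_participants(profiles, out / "participants.csv")
    write_annotations(annotations, out / "annotations.csv")
    traces = [simulate_session_vo2(p, i, protocol, cfg, seed) for i, p in enumerate(profiles)]
    write_vo2(traces, out / "vo2.csv")
    n_rec = write_raw_signals(
        iter_session_recordings(profiles, protocol, cfg, seed), out / "raw_signals.csv"
    )
    log.info(
        "generated study: %d participants, %d recordings, %d annotations (seed %d)",
        n,
        n_rec,
        len(annotations),
        seed,
    )
    return {
        "n_participants": n,
        "n_recordings": n_rec,
        "n_annotations": len(annotations),
        "seed": seed,
        "files": {name: str(out / name) for name in DATASET_FILES},
    }


# ----------------------------------------------------------------- report tables


def write_labeled_epochs(labeled: pd.DataFrame, path: str | Path) -> None:
    labeled[LABELED_COLUMNS].to_csv(path, index=False, float_format="%.6f")


def read_labeled_epochs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(LABELED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"labeled-epoch file {path} lacks columns: {sorted(missing)}")
    return df[LABELED_COLUMNS]


def write_calibration(calibration: pd.DataFrame, path: str | Path) -> None:
    calibration[CALIBRATION_COLUMNS].to_csv(path, index=False, float_format="%.6f")


def read_calibration(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CALIBRATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"calibration file {path} lacks columns: {sorted(missing)}")
    return df[CALIBRATION_COLUMNS]


def write_validity(validity: pd.DataFrame, path: str | Path) -> None:
    validity[VALIDITY_COLUMNS].to_csv(path, index=False, float_format="%.6f")


def read_validity(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(VALIDITY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"validity file {path} lacks columns: {sorted(missing)}")
    return df[VALIDITY_COLUMNS]
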