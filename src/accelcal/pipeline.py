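"""End-to-end orchestration: simulate → reduce → label → calibrate → report.

Two execution paths produce identical bout-level results:

* the file path (``generate_study`` then ``calibrate_dataset``) serialises a
  complete study, rests included, through the CSV interfaces;
* the in-memory path (``simulate_labeled_epochs``) simulates per-bout raw
  segments, reduces each to SVMgs epochs immediately and discards the raw
  samples, which keeps a full 30-child, 4-location study small enough to run
  in seconds.  Bout segments use the same per-(participant, location, segment)
  seed streams on both paths.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import __version__
from .calibration import LightBand, run_both_variants
from .cohort import (
    ParticipantProfile,
    RawRecording,
    Vo2Trace,
    build_annotations,
    generate_cohort,
    simulate_segment_recording,
    simulate_session_vo2,
)
from .config import RunConfig
from .energy import build_labeled_table, compute_bout_mets
from .protocol import BoutAnnotation, ProtocolSpec, default_protocol
from .signal import annotate_epochs, compute_svmgs, trim_bouts

log = logging.getLogger("accelcal")


@dataclass
class PipelineResult:
    """Everything one simulate-and-calibrate run produces."""

    config: RunConfig
    profiles: list[ParticipantProfile]
    annotations: list[BoutAnnotation]
    labeled: pd.DataFrame
    bout_mets: pd.DataFrame
    calibration: pd.DataFrame
    validity: pd.DataFrame
    light_bands: dict[str, list[LightBand]]
    counts: dict[str, int] = field(default_factory=dict)


def simulate_labeled_epochs(
    cfg: RunConfig, protocol: ProtocolSpec | None = None
) -> tuple[list[ParticipantProfile], list[BoutAnnotation], pd.DataFrame, pd.DataFrame]:
    """Simulate the study and return ``(profiles, annotations, labeled, bout_mets)``.

    Raw acceleration is generated bout by bout and reduced to epochs on the
    fly; rest-period raw signal is never needed because rest epochs are
    excluded from the labeled table by construction.
    """
    protocol = protocol or default_protocol(cfg)
    seed = cfg.master_seed
    profiles = generate_cohort(cfg.n_participants, seed, cfg)
    annotations = build_annotations(profiles, protocol)

    frames = []
    for i, p in enumerate(profiles):
        for loc in protocol.locations:
            for seg, name, t0, t1 in protocol.schedule():
                if name == "rest":
                    continue
                rec = simulate_segment_recording(
                    p, i, protocol, loc, seg, name, t0, t1, cfg, seed
                )
                frames.append(compute_svmgs(rec, protocol.epoch_length_s))
    epochs = pd.concat(frames, ignore_index=True)
    epochs = annotate_epochs(epochs, annotations)
    epochs = trim_bouts(epochs, annotations, cfg.trim_s)

    traces = {
        p.id: simulate_session_vo2(p, i, protocol, cfg, seed)
        for i, p in enumerate(profiles)
    }
    bout_mets = compute_bout_mets(
        traces,
        annotations,
        profiles,
        cfg.trim_s,
        cfg.sed_max_met,
        cfg.light_max_met,
        cfg.vig_min_met,
    )
    labeled = build_labeled_table(epochs, bout_mets)
    n_trimmed = int(((epochs["activity"] != "rest") & ~epochs["in_analysis_window"]).sum())
    log.info(
        "labeled epochs: %d (discarded %d bout epochs by trimming)",
        len(labeled),
        n_trimmed,
    )
    return profiles, annotations, labeled, bout_mets


def calibrate_labeled(
    labeled: pd.DataFrame,
    cfg: RunConfig,
    locations: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[LightBand]]]:
    """Both analysis variants (cycling included / excluded) on a labeled table."""
    exclude = cfg.exclude_activities or ("cycle",)
    present = set(labeled["location"].unique())
    if locations is None:
        wanted = [loc for loc in cfg.locations if loc in present]
        missing = [loc for loc in cfg.locations if loc not in present]
        if missing:
            log.warning("locations absent from data, skipped: %s", ", ".join(missing))
        locations = wanted
    n_excluded = int(labeled["activity"].isin(set(exclude)).sum())
    log.info(
        "calibrating %d epochs at %d locations (%d epochs drop in the "
        "cycling-excluded variant)",
        len(labeled),
        len(locations),
        n_excluded,
    )
    return run_both_variants(
        labeled,
        locations,
        exclude_activities=exclude,
        min_se_sp=cfg.min_se_sp,
        display_resolution=cfg.display_resolution,
    )


def run_endtoend(
    cfg: RunConfig, out_dir: str | Path | None = None
) -> PipelineResult:
    """Simulate the default study in memory and calibrate it, both variants."""
    profiles, annotations, labeled, bout_mets = simulate_labeled_epochs(cfg)
    calibration, validity, bands = calibrate_labeled(labeled, cfg)
    counts = {
        "n_participants": len(profiles),
        "n_locations": labeled["location"].nunique(),
        "n_labeled_epochs": len(labeled),
        "n_bouts": len(annotations),
    }
    result = PipelineResult(
        config=cfg,
        profiles=profiles,
        annotations=annotations,
        labeled=labeled,
        bout_mets=bout_mets,
        calibration=calibration,
        validity=validity,
        light_bands=bands,
        counts=counts,
    )
    if out_dir is not None:
        write_report(result, out_dir)
    return result


def process_dataset(
    dataset_dir: str | Path, cfg: RunConfig
) -> tuple[list[ParticipantProfile], list[BoutAnnotation], pd.DataFrame, pd.DataFrame]:
    """Load a serialised study and build its labeled-epoch table."""
    from . import io as acio

    d = Path(dataset_dir)
    profiles = acio.read_participants(d / "participants.csv")
    annotations = acio.read_annotations(d / "annotations.csv")
    traces = acio.read_vo2(d / "vo2.csv")
    frames = []
    for rec in acio.iter_raw_recordings(d / "raw_signals.csv"):
        frames.append(compute_svmgs(rec, cfg.epoch_length_s))
    epochs = pd.concat(frames, ignore_index=True)
    epochs = annotate_epochs(epochs, annotations)
    epochs = trim_bouts(epochs, annotations, cfg.trim_s)
    bout_mets = compute_bout_mets(
        traces,
        annotations,
        profiles,
        cfg.trim_s,
        cfg.sed_max_met,
        cfg.light_max_met,
        cfg.vig_min_met,
    )
    labeled = build_labeled_table(epochs, bout_mets)
    return profiles, annotations, labeled, bout_mets


def calibrate_dataset(
    dataset_dir: str | Path, cfg: RunConfig, out_dir: str | Path | None = None
) -> PipelineResult:
    """File-based variant of :func:`run_endtoend`: read dataset, calibrate, report."""
    profiles, annotations, labeled, bout_mets = process_dataset(dataset_dir, cfg)
    calibration, validity, bands = calibrate_labeled(labeled, cfg)
    result = PipelineResult(
        config=cfg,
        profiles=profiles,
        annotations=annotations,
        labeled=labeled,
        bout_mets=bout_mets,
        calibration=calibration,
        validity=validity,
        light_bands=bands,
        counts={
            "n_participants": len(profiles),
            "n_locations": labeled["location"].nunique(),
            "n_labeled_epochs": len(labeled),
            "n_bouts": len(annotations),
        },
    )
    if out_dir is not None:
        write_report(result, out_dir)
    return result


def summarize(result: PipelineResult) -> str:
    """Human-readable summary of cut-points, grades and validity."""
    lines = [
        f"accelcal {__version__} — calibration summary",
        f"participants: {result.counts.get('n_participants')}  "
        f"labeled epochs: {result.counts.get('n_labeled_epochs')}",
        "",
    ]
    for variant, label in (("all", "cycling included"), ("no_cycling", "cycling excluded")):
        lines.append(f"[{label}]")
        sub = result.calibration[result.calibration["analysis_variant"] == variant]
        for r in sub.itertuples():
            flag = "" if r.constraint_met else "  (min Se/Sp floor NOT met)"
            lines.append(
                f"  {r.intensity:>3} @ {r.location:<12} AUC {r.auc:.3f} "
                f"({r.ci_lo:.3f}-{r.ci_hi:.3f}) {r.grade:<9} "
                f"Se {r.sensitivity_pct:5.1f}%  Sp {r.specificity_pct:5.1f}%  "
                f"cut {r.cutpoint_gs:8.2f} gs{flag}"
            )
        for band in result.light_bands[variant]:
            lines.append(
                f"  LPA @ {band.location:<12} band {band.lower:.1f}-{band.upper:.1f} gs"
            )
        val = result.validity[
            (result.validity["analysis_variant"] == variant)
            & (result.validity["stratum"] == "overall")
        ]
        rhos = "  ".join(f"{r.location}: {r.rho:.3f}" for r in val.itertuples())
        lines.append(f"  overall Spearman rho — {rhos}")
        lines.append("")
    return "\n".join(lines)


def write_report(result: PipelineResult, out_dir: str | Path) -> dict:
    """Write calibration/validity CSVs, a text summary, and a run manifest."""
    from . import io as acio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    acio.write_calibration(result.calibration, out / "calibration.csv")
    acio.write_validity(result.validity, out / "validity.csv")
    (out / "summary.txt").write_text(summarize(result) + "\n")
    manifest = {
        "package_version": __version__,
        "master_seed": result.config.master_seed,
        "config_hash": result.config.config_hash(),
        "counts": result.counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
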