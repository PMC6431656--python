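"""Run configuration: every tunable of the simulator and the calibration.

The configuration is flat — one key, one scalar — so it round-trips through a
plain key-value YAML file.  Nested tables (per-activity MET targets, the
activity x location amplitude table) are expressed with dotted keys, e.g.
``met_mean.run: 4.4`` or ``amplitude.cycle.ankle: 0.60``.

All study-design constants (80 Hz sampling, 1 s epochs, 5-min bouts and rests,
60 s trimming, the 1.5/3/6 MET intensity boundaries, the 60% sensitivity/
specificity floor and the AUC grading scale) live here with their protocol
values as defaults, so a zero-argument run reproduces the default study.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

LOCATIONS: tuple[str, ...] = ("nondom_wrist", "dom_wrist", "waist", "ankle")

ACTIVITY_ORDER: tuple[str, ...] = (
    "supine",
    "lego",
    "slow_walk",
    "medium_walk",
    "run",
    "throw_catch",
    "instep_pass",
    "cycle",
)

#: Object-control skills: one complete action every ``cadence_s`` seconds.
OBJECT_CONTROL: frozenset[str] = frozenset({"throw_catch", "instep_pass"})

# Steady-state MET targets.  Chosen so that in expectation supine and Lego fall
# below 1.5 METs, the walks and throwing/catching fall in [1.5, 3), and
# running, cycling and instep passing reach >= 3 METs.
DEFAULT_MET_MEAN: dict[str, float] = {
    "supine": 1.10,
    "lego": 1.25,
    "slow_walk": 2.20,
    "medium_walk": 2.70,
    "run": 4.40,
    "throw_catch": 2.50,
    "instep_pass": 3.30,
    "cycle": 3.50,
}

DEFAULT_MET_SD: dict[str, float] = {
    "supine": 0.12,
    "lego": 0.12,
    "slow_walk": 0.25,
    "medium_walk": 0.25,
    "run": 0.40,
    "throw_catch": 0.25,
    "instep_pass": 0.30,
    "cycle": 0.30,
}

#: Dominant movement frequency per activity (Hz): step/pedal/action rate.
DEFAULT_MOVEMENT_FREQ: dict[str, float] = {
    "supine": 0.25,
    "lego": 0.80,
    "slow_walk": 1.60,
    "medium_walk": 1.90,
    "run": 2.60,
    "throw_catch": 2.20,
    "instep_pass": 2.00,
    "cycle": 1.00,
}

# Dynamic acceleration scale (g) per activity and wear location.  Encodes the
# ordinal structure the calibration exploits: locomotion amplitude rises
# supine < slow walk < medium walk < run at every location; cycling moves the
# ankle (pedalling) at least 5x more than the near-stationary wrists/waist;
# object-control skills load the segments that execute the skill (arms for
# throwing/catching, kicking leg for instep passing).  Object-control values
# are burst peaks, gated by the 3-s action cadence.
DEFAULT_AMPLITUDE: dict[str, dict[str, float]] = {
    "supine": {"nondom_wrist": 0.004, "dom_wrist": 0.004, "waist": 0.003, "ankle": 0.003},
    "lego": {"nondom_wrist": 0.050, "dom_wrist": 0.060, "waist": 0.008, "ankle": 0.005},
    "slow_walk": {"nondom_wrist": 0.14, "dom_wrist": 0.14, "waist": 0.12, "ankle": 0.30},
    "medium_walk": {"nondom_wrist": 0.24, "dom_wrist": 0.24, "waist": 0.20, "ankle": 0.55},
    "run": {"nondom_wrist": 0.50, "dom_wrist": 0.50, "waist": 0.42, "ankle": 1.10},
    "throw_catch": {"nondom_wrist": 0.80, "dom_wrist": 1.00, "waist": 0.10, "ankle": 0.08},
    "instep_pass": {"nondom_wrist": 0.55, "dom_wrist": 0.60, "waist": 0.35, "ankle": 1.50},
    "cycle": {"nondom_wrist": 0.05, "dom_wrist": 0.05, "waist": 0.05, "ankle": 0.60},
}

#: Resting VO2 (ml·kg⁻¹·min⁻¹), the participant's 1-MET basis, by age in years.
#: A configurable stand-in: the literature's child values cluster near
#: 5.5–6 ml/kg/min for this age band.
DEFAULT_RESTING_VO2: dict[int, float] = {8: 5.8, 9: 5.8, 10: 5.8, 11: 5.8}


@dataclass(frozen=True)
class RunConfig:
    """Complete, flat parameterisation of one simulate-and-calibrate run."""

    # cohort
    n_participants: int = 30
    master_seed: int = 1234
    age_min: int = 8
    age_max: int = 11
    mass_mean_kg: float = 34.6
    mass_sd_kg: float = 8.6
    mass_min_kg: float = 15.0
    height_mean_m: float = 1.4
    height_sd_m: float = 0.1
    resting_vo2_by_age: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_RESTING_VO2)
    )

    # recording / protocol
    locations: tuple[str, ...] = LOCATIONS
    sampling_rate_hz: float = 80.0
    epoch_length_s: float = 1.0
    bout_duration_s: float = 300.0
    rest_duration_s: float = 300.0
    trim_s: float = 60.0

    # raw-signal generator
    noise_sd_g: float = 0.01
    participant_cv: float = 0.25     # lognormal sigma of per-bout movement vigour
    modulation_depth: float = 0.30   # slow amplitude modulation within a bout
    burst_duration_s: float = 0.9    # active phase of an object-control action
    burst_baseline: float = 0.25     # relative amplitude between actions
    cadence_s: float = 3.0           # one complete skill action every 3 s
    rest_amplitude_g: float = 0.02   # fidgeting between bouts
    rest_movement_freq_hz: float = 0.5

    # VO2 generator
    vo2_tau_s: float = 30.0          # mono-exponential on/off kinetics
    vo2_noise_sd: float = 0.07       # multiplicative breath-to-breath noise
    breath_interval_min_s: float = 2.0   # 30 breaths/min
    breath_interval_max_s: float = 4.0   # 15 breaths/min
    rest_met: float = 1.1
    met_mean: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MET_MEAN))
    met_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MET_SD))
    movement_freq_hz: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MOVEMENT_FREQ)
    )
    amplitude: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {a: dict(t) for a, t in DEFAULT_AMPLITUDE.items()}
    )

    # criterion coding
    sed_max_met: float = 1.5
    light_max_met: float = 3.0
    vig_min_met: float = 6.0

    # calibration
    min_se_sp: float = 0.60
    ci_method: str = "hanley-mcneil"
    display_resolution: float = 0.1
    exclude_activities: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not self.locations or len(set(self.locations)) != len(self.locations):
            raise ValueError("locations must be non-empty and unique")
        spe = self.sampling_rate_hz * self.epoch_length_s
        if abs(spe - round(spe)) > 1e-9:
            raise ValueError(
                "sampling_rate_hz x epoch_length_s must be a whole number of samples"
            )
        if not (self.sed_max_met < self.light_max_met < self.vig_min_met):
            raise ValueError("intensity boundaries must be strictly increasing")
        if self.bout_duration_s <= 2 * self.trim_s:
            raise ValueError("bout_duration_s must exceed twice trim_s")

    # ------------------------------------------------------------------ flat IO

    def to_flat_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "resting_vo2_by_age":
                for age, vo2 in sorted(v.items()):
                    out[f"resting_vo2_by_age.{age}"] = float(vo2)
            elif f.name in ("met_mean", "met_sd", "movement_freq_hz"):
                for a in ACTIVITY_ORDER:
                    out[f"{f.name}.{a}"] = float(v[a])
            elif f.name == "amplitude":
                for a in ACTIVITY_ORDER:
                    for loc in LOCATIONS:
                        out[f"amplitude.{a}.{loc}"] = float(v[a][loc])
            elif f.name in ("locations", "exclude_activities"):
                out[f.name] = list(v)
            else:
                out[f.name] = v
        return out

    @classmethod
    def from_flat_dict(cls, flat: Mapping[str, Any]) -> "RunConfig":
        base = cls()
        kwargs: dict[str, Any] = {}
        resting = dict(base.resting_vo2_by_age)
        met_mean = dict(base.met_mean)
        met_sd = dict(base.met_sd)
        freqs = dict(base.movement_freq_hz)
        amp = {a: dict(t) for a, t in base.amplitude.items()}
        simple = {f.name: f for f in dataclasses.fields(cls)}
        unknown: list[str] = []
        for key, value in flat.items():
            parts = key.split(".")
            if parts[0] == "resting_vo2_by_age" and len(parts) == 2:
                resting[int(parts[1])] = float(value)
            elif parts[0] in ("met_mean", "met_sd", "movement_freq_hz") and len(parts) == 2:
                table = {"met_mean": met_mean, "met_sd": met_sd, "movement_freq_hz": freqs}[
                    parts[0]
                ]
                if parts[1] not in table:
                    unknown.append(key)
                else:
                    table[parts[1]] = float(value)
            elif parts[0] == "amplitude" and len(parts) == 3:
                if parts[1] not in amp or parts[2] not in amp[parts[1]]:
                    unknown.append(key)
                else:
                    amp[parts[1]][parts[2]] = float(value)
            elif key in ("locations", "exclude_activities"):
                kwargs[key] = tuple(value)
            elif key in simple:
                kwargs[key] = value
            else:
                unknown.append(key)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        kwargs["resting_vo2_by_age"] = resting
        kwargs["met_mean"] = met_mean
        kwargs["met_sd"] = met_sd
        kwargs["movement_freq_hz"] = freqs
        kwargs["amplitude"] = amp
        return cls(**kwargs)

    def replace(self, **kwargs: Any) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_flat_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides: Any) -> RunConfig:
    """Load a flat YAML config; missing file/keys fall back to defaults."""
    flat: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a flat mapping")
        flat.update(loaded)
    cfg = RunConfig.from_flat_dict(flat)
    return cfg.replace(**overrides) if overrides else cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_flat_dict(), fh, sort_keys=True)
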