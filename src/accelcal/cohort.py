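"""Synthetic study generator: cohort, raw triaxial signals, breath-by-breath VO2.

The simulator produces a complete laboratory calibration session for each
child: triaxial acceleration (gravity included) at 80 Hz at four wear
locations, and an irregular breath-by-breath VO2 trace coupled to the activity
schedule.  The signal model is deliberately minimal — a randomly oriented unit
gravity vector plus a quasi-periodic movement component whose amplitude is set
per activity and wear location, plus white noise — because the calibration
only needs the *ordinal* structure of dynamic acceleration across activities
and locations, not biomechanical realism.

Seed derivation
---------------
All randomness flows from a single master seed through
``numpy.random.SeedSequence`` entropy tuples::

    (master_seed, domain, participant_index, ...)

with domain 0 = cohort anthropometrics, 1 = raw signal (then location index,
segment index), 2 = VO2 (then segment index).  Any participant / location /
bout subset is therefore reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .config import RunConfig
from .protocol import ActivitySpec, BoutAnnotation, ProtocolSpec

_DOMAIN_COHORT = 0
_DOMAIN_RAW = 1
_DOMAIN_VO2 = 2


def _rng(*entropy: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(tuple(int(e) for e in entropy)))


# --------------------------------------------------------------------------- types


@dataclass(frozen=True)
class ParticipantProfile:
    """One child: anthropometrics plus the resting VO2 that defines 1 MET."""

    id: str
    age: int
    sex: str
    height: float  # m
    mass: float  # kg
    dominant_side: str
    resting_vo2: float  # ml/kg/min

    def __post_init__(self) -> None:
        if not (8 <= self.age <= 11):
            raise ValueError(f"participant {self.id}: age must be in [8, 11]")
        if self.sex not in ("F", "M"):
            raise ValueError(f"participant {self.id}: sex must be 'F' or 'M'")
        if self.mass <= 0 or self.height <= 0 or self.resting_vo2 <= 0:
            raise ValueError(f"participant {self.id}: anthropometrics must be positive")


@dataclass
class RawRecording:
    """Uniform-rate triaxial acceleration series in g (gravity included)."""

    participant_id: str
    location: str
    times: np.ndarray  # s from session start
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.ax) == len(self.ay) == len(self.az) == n):
            raise ValueError("axis series must have equal length")
        if n == 0:
            raise ValueError("empty recording")
        if n > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
                raise ValueError("recording must have a uniform time step")
        if not (
            np.all(np.isfinite(self.ax))
            and np.all(np.isfinite(self.ay))
            and np.all(np.isfinite(self.az))
        ):
            raise ValueError("acceleration samples must be finite")

    @property
    def sampling_rate(self) -> float:
        if len(self.times) < 2:
            raise ValueError("cannot infer sampling rate from a single sample")
        return 1.0 / (self.times[1] - self.times[0])

    def magnitude(self) -> np.ndarray:
        return np.sqrt(self.ax**2 + self.ay**2 + self.az**2)


@dataclass
class Vo2Trace:
    """Breath-by-breath oxygen uptake, irregular in time."""

    participant_id: str
    times: np.ndarray  # s
    vo2: np.ndarray  # ml/kg/min
    vco2: np.ndarray  # ml/kg/min (carried through I/O; unused in computation)

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.vo2) == len(self.vco2)):
            raise ValueError("VO2 trace arrays must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("breath times must be strictly increasing")
        if np.any(self.vo2 <= 0):
            raise ValueError("vo2 must be positive")


# --------------------------------------------------------------------------- cohort


def generate_cohort(n: int, seed: int, cfg: RunConfig | None = None) -> list[ParticipantProfile]:
    """Draw ``n`` child profiles; deterministic given ``seed``.

    Sexes are split as evenly as ``n`` allows (girls first on odd ``n``); ages
    are uniform on the configured integer range; mass and height are normal
    (mass truncated above ``mass_min_kg``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = cfg or RunConfig()
    rng = _rng(seed, _DOMAIN_COHORT)
    width = max(2, len(str(n)))
    profiles = []
    for i in range(n):
        age = int(rng.integers(cfg.age_min, cfg.age_max + 1))
        mass = float(rng.normal(cfg.mass_mean_kg, cfg.mass_sd_kg))
        while mass <= cfg.mass_min_kg:
            mass = float(rng.normal(cfg.mass_mean_kg, cfg.mass_sd_kg))
        height = float(rng.normal(cfg.height_mean_m, cfg.height_sd_m))
        while height <= 0.8:
            height = float(rng.normal(cfg.height_mean_m, cfg.height_sd_m))
        side = "left" if rng.random() < 0.1 else "right"
        profiles.append(
            ParticipantProfile(
                id=f"P{i + 1:0{width}d}",
                age=age,
                sex="F" if i % 2 == 0 else "M",
                height=round(height, 3),
                mass=round(mass, 2),
                dominant_side=side,
                resting_vo2=float(cfg.resting_vo2_by_age.get(age, 5.8)),
            )
        )
    return profiles


# --------------------------------------------------------------------------- raw signal


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    n = np.linalg.norm(v)
    while n < 1e-8:
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
    return v / n


def _raw_segment(
    rng: np.random.Generator,
    *,
    t_start: float,
    duration_s: float,
    fs: float,
    amplitude: float,
    freq_hz: float,
    cadence_s: float | None,
    cfg: RunConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one contiguous segment; returns ``(times, xyz[n, 3])``."""
    n = round(duration_s * fs)
    t = t_start + np.arange(n) / fs
    gravity = _unit_vector(rng)
    v1 = _unit_vector(rng)
    v2 = np.cross(v1, _unit_vector(rng))
    nv2 = np.linalg.norm(v2)
    v2 = v2 / nv2 if nv2 > 1e-8 else np.cross(v1, [1.0, 0.0, 0.0])

    xyz = np.broadcast_to(gravity, (n, 3)).copy()
    if amplitude > 0:
        vigour = float(rng.lognormal(mean=0.0, sigma=cfg.participant_cv))
        fm = rng.uniform(0.05, 0.2)
        amp = amplitude * vigour * (
            1.0 + cfg.modulation_depth * np.sin(2 * np.pi * fm * t + rng.uniform(0, 2 * np.pi))
        )
        if cadence_s is not None:
            rel = (t - t_start) % cadence_s
            amp = amp * np.where(rel < cfg.burst_duration_s, 1.0, cfg.burst_baseline)
        phase = rng.uniform(0, 2 * np.pi)
        osc1 = np.sin(2 * np.pi * freq_hz * t + phase)
        osc2 = 0.5 * np.cos(2 * np.pi * freq_hz * t + phase)
        xyz = xyz + np.outer(amp * osc1, v1) + np.outer(amp * osc2, v2)
    if cfg.noise_sd_g > 0:
        xyz = xyz + rng.normal(0.0, cfg.noise_sd_g, size=(n, 3))
    return t, xyz


def simulate_raw_signal(
    participant: ParticipantProfile,
    protocol: ProtocolSpec,
    activity: ActivitySpec,
    location: str,
    seed: int | Sequence[int],
    *,
    t_start: float = 0.0,
    cfg: RunConfig | None = None,
) -> RawRecording:
    """Simulate one bout's raw triaxial segment at one wear location.

    The signal is a randomly oriented unit gravity vector plus an elliptically
    polarised oscillation at the activity's movement frequency (burst-gated at
    the action cadence for object-control skills) plus white noise.
    """
    if location not in protocol.locations:
        raise ValueError(f"unknown location {location!r}; protocol has {protocol.locations}")
    cfg = cfg or RunConfig()
    entropy = (seed,) if isinstance(seed, (int, np.integer)) else tuple(seed)
    rng = _rng(*entropy)
    t, xyz = _raw_segment(
        rng,
        t_start=t_start,
        duration_s=activity.duration_s,
        fs=protocol.sampling_rate,
        amplitude=float(activity.amplitude_by_location[location]),
        freq_hz=activity.movement_freq_hz,
        cadence_s=activity.cadence_s,
        cfg=cfg,
    )
    return RawRecording(
        participant_id=participant.id,
        location=location,
        times=t,
        ax=xyz[:, 0],
        ay=xyz[:, 1],
        az=xyz[:, 2],
    )


# --------------------------------------------------------------------------- VO2


def _vo2_segment(
    rng: np.random.Generator,
    *,
    t_start: float,
    t_end: float,
    start_vo2: float,
    target_vo2: float,
    cfg: RunConfig,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Breath times/values over [t_start, t_end); returns model level at t_end."""
    times = []
    t = t_start + rng.uniform(cfg.breath_interval_min_s, cfg.breath_interval_max_s)
    while t < t_end:
        times.append(t)
        t += rng.uniform(cfg.breath_interval_min_s, cfg.breath_interval_max_s)
    times = np.asarray(times)
    tau = cfg.vo2_tau_s
    if tau <= 0:
        model = np.full_like(times, target_vo2)
        end_level = target_vo2
    else:
        model = target_vo2 + (start_vo2 - target_vo2) * np.exp(-(times - t_start) / tau)
        end_level = target_vo2 + (start_vo2 - target_vo2) * np.exp(-(t_end - t_start) / tau)
    if cfg.vo2_noise_sd > 0 and len(times):
        model = model * np.exp(rng.normal(0.0, cfg.vo2_noise_sd, size=len(times)))
    return times, model, float(end_level)


def _draw_met_target(rng: np.random.Generator, met_mean: float, met_sd: float) -> float:
    """Per-bout steady-state MET target, normal truncated above 0.5."""
    if met_sd <= 0:
        return max(met_mean, 0.5)
    m = float(rng.normal(met_mean, met_sd))
    while m <= 0.5:
        m = float(rng.normal(met_mean, met_sd))
    return m


def simulate_vo2(
    participant: ParticipantProfile,
    annotation: BoutAnnotation,
    activity: ActivitySpec,
    seed: int | Sequence[int],
    *,
    start_level: float | None = None,
    cfg: RunConfig | None = None,
) -> Vo2Trace:
    """Simulate breath-by-breath VO2 over one bout.

    VO2 rises mono-exponentially (time constant ``vo2_tau_s``) from the prior
    level toward ``met_target * resting_vo2`` with multiplicative noise; the
    MET target is drawn once per bout.
    """
    if activity.met_mean <= 0:
        raise ValueError("met_mean must be positive")
    cfg = cfg or RunConfig()
    entropy = (seed,) if isinstance(seed, (int, np.integer)) else tuple(seed)
    rng = _rng(*entropy)
    target = _draw_met_target(rng, activity.met_mean, activity.met_sd) * participant.resting_vo2
    start = cfg.rest_met * participant.resting_vo2 if start_level is None else start_level
    times, vo2, _ = _vo2_segment(
        rng,
        t_start=annotation.bout_start_s,
        t_end=annotation.bout_end_s,
        start_vo2=start,
        target_vo2=target,
        cfg=cfg,
    )
    vco2 = vo2 * 0.85
    return Vo2Trace(participant_id=participant.id, times=times, vo2=vo2, vco2=vco2)


def simulate_session_vo2(
    participant: ParticipantProfile,
    p_index: int,
    protocol: ProtocolSpec,
    cfg: RunConfig | None = None,
    master_seed: int | None = None,
) -> Vo2Trace:
    """Chain VO2 segments over the whole session (bouts and rests)."""
    cfg = cfg or RunConfig()
    seed = protocol.master_seed if master_seed is None else master_seed
    level = cfg.rest_met * participant.resting_vo2
    all_t: list[np.ndarray] = []
    all_v: list[np.ndarray] = []
    for seg, name, t0, t1 in protocol.schedule():
        rng = _rng(seed, _DOMAIN_VO2, p_index, seg)
        if name == "rest":
            target = cfg.rest_met * participant.resting_vo2
        else:
            act = protocol.activity(name)
            target = _draw_met_target(rng, act.met_mean, act.met_sd) * participant.resting_vo2
        t, v, level = _vo2_segment(
            rng, t_start=t0, t_end=t1, start_vo2=level, target_vo2=target, cfg=cfg
        )
        all_t.append(t)
        all_v.append(v)
    times = np.concatenate(all_t)
    vo2 = np.concatenate(all_v)
    return Vo2Trace(participant_id=participant.id, times=times, vo2=vo2, vco2=vo2 * 0.85)


# --------------------------------------------------------------------------- study


def build_annotations(
    profiles: Sequence[ParticipantProfile], protocol: ProtocolSpec
) -> list[BoutAnnotation]:
    """Activity-bout annotations per participant, in protocol order."""
    out = []
    for p in profiles:
        for _, name, t0, t1 in protocol.schedule():
            if name != "rest":
                out.append(BoutAnnotation(p.id, name, t0, t1))
    return out


def simulate_segment_recording(
    participant: ParticipantProfile,
    p_index: int,
    protocol: ProtocolSpec,
    location: str,
    segment_index: int,
    segment_name: str,
    t_start: float,
    t_end: float,
    cfg: RunConfig | None = None,
    master_seed: int | None = None,
) -> RawRecording:
    """Raw signal for one schedule segment under the documented seed scheme."""
    cfg = cfg or RunConfig()
    seed = protocol.master_seed if master_seed is None else master_seed
    loc_index = protocol.locations.index(location)
    rng = _rng(seed, _DOMAIN_RAW, p_index, loc_index, segment_index)
    if segment_name == "rest":
        amplitude, freq, cadence = cfg.rest_amplitude_g, cfg.rest_movement_freq_hz, None
    else:
        act = protocol.activity(segment_name)
        amplitude = float(act.amplitude_by_location[location])
        freq, cadence = act.movement_freq_hz, act.cadence_s
    t, xyz = _raw_segment(
        rng,
        t_start=t_start,
        duration_s=t_end - t_start,
        fs=protocol.sampling_rate,
        amplitude=amplitude,
        freq_hz=freq,
        cadence_s=cadence,
        cfg=cfg,
    )
    return RawRecording(participant.id, location, t, xyz[:, 0], xyz[:, 1], xyz[:, 2])


def simulate_session_recording(
    participant: ParticipantProfile,
    p_index: int,
    protocol: ProtocolSpec,
    location: str,
    cfg: RunConfig | None = None,
    master_seed: int | None = None,
) -> RawRecording:
    """Full-session raw recording (bouts and rests) at one wear location."""
    parts = [
        simulate_segment_recording(
            participant, p_index, protocol, location, seg, name, t0, t1, cfg, master_seed
        )
        for seg, name, t0, t1 in protocol.schedule()
    ]
    return RawRecording(
        participant_id=participant.id,
        location=location,
        times=np.concatenate([r.times for r in parts]),
        ax=np.concatenate([r.ax for r in parts]),
        ay=np.concatenate([r.ay for r in parts]),
        az=np.concatenate([r.az for r in parts]),
    )


def iter_session_recordings(
    profiles: Sequence[ParticipantProfile],
    protocol: ProtocolSpec,
    cfg: RunConfig | None = None,
    master_seed: int | None = None,
) -> Iterator[RawRecording]:
    """Yield one full-session recording per participant x location."""
    for i, p in enumerate(profiles):
        for loc in protocol.locations:
            yield simulate_session_recording(p, i, protocol, loc, cfg, master_seed)
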