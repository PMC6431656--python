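"""Activity protocol: eight 5-min activity bouts separated by 5-min rests.

The protocol drives both the simulator (what signal and VO2 to generate when)
and the processing (which epochs belong to which bout).  Activities run in the
fixed order supine, Lego play, slow walk (3 km/h), medium walk (4.5 km/h),
run (6.5 km/h), overarm throw-and-catch, instep football pass, cycling (35 W);
the two object-control skills are paced at one complete action every 3 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .config import ACTIVITY_ORDER, OBJECT_CONTROL, RunConfig


@dataclass(frozen=True)
class ActivitySpec:
    """One scripted activity bout and the generator parameters that shape it."""

    name: str
    duration_s: float
    met_mean: float
    met_sd: float
    amplitude_by_location: Mapping[str, float]
    movement_freq_hz: float
    cadence_s: float | None = None  # object-control skills only

    def __post_init__(self) -> None:
        if self.duration_s <= 120:
            raise ValueError(
                f"activity {self.name!r}: duration_s must exceed 120 s so that "
                "trimming leaves a non-empty analysis window"
            )
        if self.met_mean <= 0:
            raise ValueError(f"activity {self.name!r}: met_mean must be > 0")
        if any(a < 0 for a in self.amplitude_by_location.values()):
            raise ValueError(f"activity {self.name!r}: amplitudes must be >= 0")


@dataclass(frozen=True)
class ProtocolSpec:
    """Ordered activity schedule plus recording settings."""

    activities: tuple[ActivitySpec, ...]
    rest_duration_s: float
    locations: tuple[str, ...]
    sampling_rate: float = 80.0
    epoch_length_s: float = 1.0
    master_seed: int = 1234

    def __post_init__(self) -> None:
        if not self.locations or len(set(self.locations)) != len(self.locations):
            raise ValueError("locations must be non-empty and unique")
        spe = self.sampling_rate * self.epoch_length_s
        if abs(spe - round(spe)) > 1e-9:
            raise ValueError("sampling_rate x epoch_length_s must be integral")

    @property
    def samples_per_epoch(self) -> int:
        return round(self.sampling_rate * self.epoch_length_s)

    def schedule(self) -> Iterator[tuple[int, str, float, float]]:
        """Yield ``(segment_index, name, start_s, end_s)`` for bouts and rests.

        Rests separate consecutive bouts ("5-min rest in between"); there is no
        leading or trailing rest.  Rest segments are named ``"rest"``.
        """
        t = 0.0
        seg = 0
        for i, act in enumerate(self.activities):
            yield seg, act.name, t, t + act.duration_s
            t += act.duration_s
            seg += 1
            if i < len(self.activities) - 1 and self.rest_duration_s > 0:
                yield seg, "rest", t, t + self.rest_duration_s
                t += self.rest_duration_s
                seg += 1

    @property
    def session_duration_s(self) -> float:
        return sum(a.duration_s for a in self.activities) + self.rest_duration_s * max(
            0, len(self.activities) - 1
        )

    def activity(self, name: str) -> ActivitySpec:
        for a in self.activities:
            if a.name == name:
                return a
        raise KeyError(f"no activity named {name!r} in protocol")


@dataclass(frozen=True)
class BoutAnnotation:
    """Time interval [start, end) of one activity bout for one participant."""

    participant_id: str
    activity_name: str
    bout_start_s: float
    bout_end_s: float

    def __post_init__(self) -> None:
        if self.bout_end_s <= self.bout_start_s:
            raise ValueError("bout_end_s must exceed bout_start_s")

    @property
    def duration_s(self) -> float:
        return self.bout_end_s - self.bout_start_s


def default_protocol(cfg: RunConfig | None = None) -> ProtocolSpec:
    """The study protocol implied by ``cfg`` (defaults: the full default study)."""
    cfg = cfg or RunConfig()
    acts = tuple(
        ActivitySpec(
            name=name,
            duration_s=cfg.bout_duration_s,
            met_mean=cfg.met_mean[name],
            met_sd=cfg.met_sd[name],
            amplitude_by_location=dict(cfg.amplitude[name]),
            movement_freq_hz=cfg.movement_freq_hz[name],
            cadence_s=cfg.cadence_s if name in OBJECT_CONTROL else None,
        )
        for name in ACTIVITY_ORDER
    )
    return ProtocolSpec(
        activities=acts,
        rest_duration_s=cfg.rest_duration_s,
        locations=tuple(cfg.locations),
        sampling_rate=cfg.sampling_rate_hz,
        epoch_length_s=cfg.epoch_length_s,
        master_seed=cfg.master_seed,
    )
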