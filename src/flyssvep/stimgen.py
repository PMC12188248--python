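"""Oddball visual stimulus schedules.

Trials are 20 s trains of full-field 50 ms flashes delivered at the carrier
frequency F1 (10 Hz, 50% duty cycle).  Three trial types are supported:

* ``carrier_only`` — a single color at F1;
* ``phasic`` — every ``deviant_every``-th event is a differently colored
  deviant, i.e. a fixed 2 Hz oddball embedded in the 10 Hz carrier;
* ``jittering`` — deviant positions are displaced by a rounded Gaussian
  offset around their nominal (every fifth) position, so the number of
  carriers between deviants varies while the mean deviant rate stays 2 Hz.

Color/role assignment is counterbalanced across trials so that each color
serves as the deviant in an equal number of trials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Color",
    "Role",
    "TrialType",
    "StimulusEvent",
    "TrialSpec",
    "ExperimentSchedule",
    "build_carrier_trial",
    "build_phasic_trial",
    "build_jittering_trial",
    "build_trial",
    "counterbalance_schedule",
    "render_stimulus_trace",
    "events_to_frame",
    "InvalidSpecError",
]


class InvalidSpecError(ValueError):
    """A trial or schedule specification violates its invariants."""


class Color(str, Enum):
    GREEN = "green"
    BLUE = "blue"


class Role(str, Enum):
    CARRIER = "carrier"
    DEVIANT = "deviant"


class TrialType(str, Enum):
    CARRIER_ONLY = "carrier_only"
    PHASIC = "phasic"
    JITTERING = "jittering"


@dataclass(frozen=True)
class StimulusEvent:
    """One 50 ms flash.

    ``seq_index`` is the 1-based position within the trial (positions are
    1-based throughout so that "every fifth event" means positions 5, 10, ...).
    """

    onset_time: float  # seconds from experiment start
    duration: float
    color: Color
    role: Role
    seq_index: int
    trial_id: int


@dataclass(frozen=True)
class TrialSpec:
    trial_type: TrialType
    carrier_color: Color
    deviant_color: Color | None = None
    n_events: int = 200
    f1_hz: float = 10.0
    deviant_every: int = 5
    jitter_sd: float = 1.0
    start_time: float = 0.0
    duration_s: float = 0.05  # per-event flash duration (50% duty at 10 Hz)
    trial_id: int = 0

    def __post_init__(self) -> None:
        if self.n_events <= 0 or self.f1_hz <= 0:
            raise InvalidSpecError("n_events and f1_hz must be positive")
        if self.trial_type is TrialType.CARRIER_ONLY:
            if self.deviant_color is not None:
                raise InvalidSpecError("carrier_only trials have no deviant color")
        else:
            if self.deviant_color is None:
                raise InvalidSpecError(f"{self.trial_type.value} trials need a deviant color")
            if self.deviant_color == self.carrier_color:
                raise InvalidSpecError("carrier and deviant colors must differ")
            if self.deviant_every <= 0:
                raise InvalidSpecError("deviant_every must be positive")
        if self.jitter_sd < 0:
            raise InvalidSpecError("jitter_sd must be non-negative")

    @property
    def trial_span_s(self) -> float:
        """Duration of the stimulus train (20 s for 200 events at 10 Hz)."""
        return self.n_events / self.f1_hz


def _onset(spec: TrialSpec, seq_index: int) -> float:
    return spec.start_time + (seq_index - 1) / spec.f1_hz


def build_carrier_trial(spec: TrialSpec) -> list[StimulusEvent]:
    """Uniform single-color train at F1 (the 100%-probability condition)."""
    if spec.trial_type is not TrialType.CARRIER_ONLY:
        raise InvalidSpecError("spec.trial_type must be carrier_only")
    return [
        StimulusEvent(
            onset_time=_onset(spec, k),
            duration=spec.duration_s,
            color=spec.carrier_color,
            role=Role.CARRIER,
            seq_index=k,
            trial_id=spec.trial_id,
        )
        for k in range(1, spec.n_events + 1)
    ]


def _events_from_deviant_positions(
    spec: TrialSpec, deviant_positions: Sequence[int]
) -> list[StimulusEvent]:
    devset = set(deviant_positions)
    events = []
    for k in range(1, spec.n_events + 1):
        is_dev = k in devset
        events.append(
            StimulusEvent(
                onset_time=_onset(spec, k),
                duration=spec.duration_s,
                color=spec.deviant_color if is_dev else spec.carrier_color,
                role=Role.DEVIANT if is_dev else Role.CARRIER,
                seq_index=k,
                trial_id=spec.trial_id,
            )
        )
    return events


def nominal_deviant_positions(spec: TrialSpec) -> list[int]:
    """Positions deviant_every, 2*deviant_every, ... ("every fifth event")."""
    return list(range(spec.deviant_every, spec.n_events + 1, spec.deviant_every))


def build_phasic_trial(spec: TrialSpec) -> list[StimulusEvent]:
    """Fixed-position oddball train: deviants at every ``deviant_every``-th event.

    With the defaults (200 events at 10 Hz, every fifth) the deviant rate is
    exactly 2 Hz: 40 deviants and 160 carriers per trial.
    """
    if spec.trial_type is not TrialType.PHASIC:
        raise InvalidSpecError("spec.trial_type must be phasic")
    return _events_from_deviant_positions(spec, nominal_deviant_positions(spec))


def jittered_deviant_positions(spec: TrialSpec, rng: np.random.Generator) -> list[int]:
    """Gaussian-displaced deviant positions.

    Each nominal position p becomes ``p + round(N(0, jitter_sd))``.  Offsets
    that would land at/below the previously accepted deviant or before
    position 1 are redrawn (up to 100 times, then the nominal position is
    kept); positions displaced past ``n_events`` drop that deviant.
    """
    positions: list[int] = []
    prev = 0
    for p in nominal_deviant_positions(spec):
        pos = None
        for _ in range(100):
            cand = p + int(np.rint(rng.normal(0.0, spec.jitter_sd))) if spec.jitter_sd > 0 else p
            if cand > spec.n_events:
                pos = cand  # dropped below
                break
            if cand > prev and cand >= 1:
                pos = cand
                break
        else:
            pos = p if p > prev else None
        if pos is None or pos > spec.n_events:
            continue
        positions.append(pos)
        prev = pos
    return positions


def build_jittering_trial(spec: TrialSpec, rng: np.random.Generator) -> list[StimulusEvent]:
    """Oddball train with Gaussian-jittered deviant positions.

    With ``jitter_sd=0`` the output is identical to :func:`build_phasic_trial`.
    """
    if spec.trial_type is not TrialType.JITTERING:
        raise InvalidSpecError("spec.trial_type must be jittering")
    return _events_from_deviant_positions(spec, jittered_deviant_positions(spec, rng))


def build_trial(spec: TrialSpec, rng: np.random.Generator | None = None) -> list[StimulusEvent]:
    if spec.trial_type is TrialType.CARRIER_ONLY:
        return build_carrier_trial(spec)
    if spec.trial_type is TrialType.PHASIC:
        return build_phasic_trial(spec)
    if rng is None:
        raise InvalidSpecError("jittering trials require an rng")
    return build_jittering_trial(spec, rng)


@dataclass
class ExperimentSchedule:
    """Ordered trials separated by fixed pauses, with counterbalanced colors."""

    trials: list[TrialSpec]
    pause_s: float = 3.0
    rng_seed: int | None = None
    _events: list[StimulusEvent] | None = field(default=None, repr=False, compare=False)

    def events(self, rng: np.random.Generator | None = None) -> list[StimulusEvent]:
        """All stimulus events in time order (jittered trials realized once)."""
        if self._events is None:
            if rng is None:
                rng = np.random.default_rng(self.rng_seed)
            evs: list[StimulusEvent] = []
            for spec in self.trials:
                evs.extend(build_trial(spec, rng))
            self._events = evs
        return self._events

    @property
    def span_s(self) -> float:
        if not self.trials:
            return 0.0
        last = self.trials[-1]
        return last.start_time + last.trial_span_s

    def to_json(self) -> str:
        payload = {
            "pause_s": self.pause_s,
            "rng_seed": self.rng_seed,
            "trials": [
                {
                    "trial_type": t.trial_type.value,
                    "carrier_color": t.carrier_color.value,
                    "deviant_color": t.deviant_color.value if t.deviant_color else None,
                    "n_events": t.n_events,
                    "f1_hz": t.f1_hz,
                    "deviant_every": t.deviant_every,
                    "jitter_sd": t.jitter_sd,
                    "start_time": t.start_time,
                    "duration_s": t.duration_s,
                    "trial_id": t.trial_id,
                }
                for t in self.trials
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentSchedule":
        payload = json.loads(text)
        trials = [
            TrialSpec(
                trial_type=TrialType(t["trial_type"]),
                carrier_color=Color(t["carrier_color"]),
                deviant_color=Color(t["deviant_color"]) if t["deviant_color"] else None,
                n_events=t["n_events"],
                f1_hz=t["f1_hz"],
                deviant_every=t["deviant_every"],
                jitter_sd=t["jitter_sd"],
                start_time=t["start_time"],
                duration_s=t["duration_s"],
                trial_id=t["trial_id"],
            )
            for t in payload["trials"]
        ]
        return cls(trials=trials, pause_s=payload["pause_s"], rng_seed=payload["rng_seed"])


def counterbalance_schedule(
    n_trials: int,
    trial_type: TrialType | str,
    rng: np.random.Generator,
    *,
    n_events: int = 200,
    f1_hz: float = 10.0,
    deviant_every: int = 5,
    jitter_sd: float = 1.0,
    pause_s: float = 3.0,
    start_time: float = 0.0,
) -> ExperimentSchedule:
    """Build a schedule in which each color is carrier/deviant equally often.

    For deviant trial types, green-deviant and blue-deviant counts differ by
    at most one (exactly equal when ``n_trials`` is even); for carrier-only
    trials the carrier color is balanced the same way.  The trial order is
    randomized by ``rng``.
    """
    trial_type = TrialType(trial_type)
    if n_trials < 1:
        raise InvalidSpecError("n_trials must be >= 1")

    # balanced assignment (odd counts: the extra trial's color is random),
    # then shuffle order
    half = n_trials // 2
    extra = int(rng.integers(2)) if n_trials % 2 else 0
    assignment = np.array([True] * (half + extra) + [False] * (n_trials - half - extra))
    rng.shuffle(assignment)

    trials: list[TrialSpec] = []
    t0 = start_time
    trial_span = n_events / f1_hz
    for i, green_dev in enumerate(assignment):
        if trial_type is TrialType.CARRIER_ONLY:
            carrier = Color.GREEN if green_dev else Color.BLUE
            deviant = None
        else:
            deviant = Color.GREEN if green_dev else Color.BLUE
            carrier = Color.BLUE if green_dev else Color.GREEN
        trials.append(
            TrialSpec(
                trial_type=trial_type,
                carrier_color=carrier,
                deviant_color=deviant,
                n_events=n_events,
                f1_hz=f1_hz,
                deviant_every=deviant_every,
                jitter_sd=jitter_sd,
                start_time=t0,
                trial_id=i,
            )
        )
        t0 += trial_span + pause_s
    return ExperimentSchedule(trials=trials, pause_s=pause_s)


def events_to_frame(events: Sequence[StimulusEvent]) -> pd.DataFrame:
    """Event log as a table (trial_id, seq_index, onset_time_s, duration_s, color, role)."""
    return pd.DataFrame(
        {
            "trial_id": [e.trial_id for e in events],
            "seq_index": [e.seq_index for e in events],
            "onset_time_s": [e.onset_time for e in events],
            "duration_s": [e.duration for e in events],
            "color": [e.color.value for e in events],
            "role": [e.role.value for e in events],
        }
    )


def render_stimulus_trace(
    schedule: ExperimentSchedule | Sequence[StimulusEvent], fs: float
) -> pd.DataFrame:
    """Sample-aligned stimulus channels: on/off square wave plus color and role.

    Returns a DataFrame with columns ``on`` (0/1), ``color`` ('' when off) and
    ``role`` ('' when off), one row per sample.  Onsets/offsets are rounded to
    the nearest sample.
    """
    events = schedule.events() if isinstance(schedule, ExperimentSchedule) else list(schedule)
    if events and fs < 1.0 / min(e.duration for e in events):
        # at 50% duty this is fs >= 2*f1
        raise InvalidSpecError(f"fs={fs} too low to represent the stimulus duty cycle")
    if not events:
        return pd.DataFrame({"on": np.zeros(0, dtype=np.int8), "color": [], "role": []})
    end_s = max(e.onset_time + e.duration for e in events)
    n = int(np.rint(end_s * fs)) + 1
    on = np.zeros(n, dtype=np.int8)
    color = np.full(n, "", dtype=object)
    role = np.full(n, "", dtype=object)
    for e in events:
        i0 = int(np.rint(e.onset_time * fs))
        i1 = int(np.rint((e.onset_time + e.duration) * fs))
        on[i0:i1] = 1
        color[i0:i1] = e.color.value
        role[i0:i1] = e.role.value
    return pd.DataFrame({"on": on, "color": color, "role": role})
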