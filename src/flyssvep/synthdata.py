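"""Forward simulation of overnight fly-brain recordings.

Generates a multichannel local field potential (LFP) with known ground truth:

* a 16-channel transect whose visually evoked responses flip polarity at a
  configurable "reversal" channel (the lobula landmark used for
  re-referencing) and taper to zero amplitude there;
* per-event evoked responses built from a biphasic kernel, scaled by a gain
  table indexed by (region group, stimulus role, behavioral state) — the
  simulator's explicit encoding of probability- and state-dependent
  responsiveness (deviant < carrier in central channels; deviant further
  attenuated during deep sleep, central channels only; carrier gains
  state-invariant);
* 1/f (pink) background activity with a component shared across channels,
  plus 50 Hz line noise;
* alternating wake/sleep bouts drawn from a lognormal bout model (target
  medians ~11.2 / 12.8 min), a movement trace that is active during wake and
  quiescent during sleep, and a proboscis-extension trace with rhythmic
  spells concentrated in mid-sleep (deep sleep) plus questing-like "reaches"
  during wake.

Everything is deterministic given the master seed; per-component substreams
are derived from it.  Recordings round-trip losslessly through an HDF5
container.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .stimgen import (
    Color,
    ExperimentSchedule,
    Role,
    TrialType,
    counterbalance_schedule,
    events_to_frame,
)

__all__ = [
    "SimConfig",
    "KernelConfig",
    "NoiseConfig",
    "BoutModelConfig",
    "PEModelConfig",
    "GroundTruth",
    "Recording",
    "SyntheticRecording",
    "InvalidConfigError",
    "FormatError",
    "UnsupportedVersionError",
    "region_group",
    "channel_profile",
    "evoked_kernel",
    "simulate_behavior",
    "simulate_proboscis",
    "simulate_lfp",
    "simulate_recording",
    "write_recording",
    "read_recording",
]

FORMAT_VERSION = 1

STATE_WAKE = 0
STATE_SLEEP = 1
STATE_DEEP = 2  # deep (quiet) sleep: mid-bout minutes of a sleep bout

_STATE_NAMES = {STATE_WAKE: "wake", STATE_SLEEP: "sleep", STATE_DEEP: "deep"}


class InvalidConfigError(ValueError):
    pass


class FormatError(IOError):
    """The recording container is missing a required component."""


class UnsupportedVersionError(FormatError):
    pass


# ---------------------------------------------------------------------------
# configuration


@dataclass
class KernelConfig:
    """Biphasic evoked-response kernel: a fast positive lobe followed by a
    slower negative rebound, each a difference of exponentials.

    The kernel is normalized to unit peak-trough amplitude and then scaled by
    the per-color amplitude, so configured amplitudes are directly the
    noise-free peak-trough values (before channel/gain scaling).  Latency +
    span stay below one 10 Hz inter-stimulus interval so successive responses
    do not overlap.
    """

    latency_s: float = 0.020
    tau_rise_s: float = 0.004
    tau_decay_s: float = 0.012
    rebound_tau_rise_s: float = 0.010
    rebound_tau_decay_s: float = 0.025
    rebound_frac: float = 0.2
    span_s: float = 0.075  # kernel support after latency
    amplitude: dict = field(default_factory=lambda: {"green": 1.0, "blue": 0.9})


@dataclass
class NoiseConfig:
    pink_sd: float = 0.05  # per-channel 1/f background, a.u. volts
    shared_frac: float = 0.5  # weight of the across-channel common component
    pink_exponent: float = 1.0
    line_amp: float = 0.02
    line_base_hz: float = 50.0


@dataclass
class BoutModelConfig:
    """Lognormal wake/sleep bout durations.

    Medians target the values observed under continuous visual stimulation
    (wake 11.2 min, sleep 12.8 min).  Sleep draws are truncated above the
    5 min immobility criterion so that every generated sleep bout is scorable
    as sleep.
    """

    wake_median_s: float = 11.2 * 60.0
    sleep_median_s: float = 12.8 * 60.0
    sigma: float = 0.5
    min_sleep_s: float = 330.0
    min_wake_s: float = 60.0


@dataclass
class PEModelConfig:
    """Proboscis-extension activity model (rates per minute)."""

    spell_rate_deep: float = 0.8
    spell_rate_light_sleep: float = 0.15
    spell_rate_wake: float = 0.08
    reach_rate_wake: float = 0.3
    events_per_spell: tuple = (4, 8)
    inter_event_s: float = 1.5
    extension_dur_s: float = 0.4
    reach_dur_s: float = 2.5
    extension_amp: float = 1.0
    reach_amp: float = 0.8
    sensor_noise_sd: float = 0.005


def _default_order_gains() -> dict:
    # carrier-order (1-4 after a deviant) amplitude modulation, applied outside
    # the central region: the first carrier after a color change responds
    # differently, with opposite sign for the two colors; central channels are
    # insensitive to carrier order.
    return {
        "green": [1.20, 1.08, 1.00, 0.92],
        "blue": [0.80, 0.92, 1.00, 1.08],
    }


def _default_gains() -> dict:
    g = {}
    for region in ("central", "intermediate", "peripheral"):
        for state in ("wake", "sleep", "deep"):
            g[(region, "carrier", state)] = 1.0
    dev_wake = {"central": 0.75, "intermediate": 0.85, "peripheral": 0.95}
    for region, gw in dev_wake.items():
        g[(region, "deviant", "wake")] = gw
        g[(region, "deviant", "sleep")] = gw
        # deep-sleep attenuation in central channels only
        g[(region, "deviant", "deep")] = gw * 0.6 if region == "central" else gw
    return g


@dataclass
class SimConfig:
    n_channels: int = 16
    fs: float = 1000.0
    reversal_channel: int = 12  # 1-based; typical insertions land at 11-14
    kernel: KernelConfig = field(default_factory=KernelConfig)
    gains: dict = field(default_factory=_default_gains)
    order_gains: dict = field(default_factory=_default_order_gains)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    bout_model: BoutModelConfig = field(default_factory=BoutModelConfig)
    pe_model: PEModelConfig = field(default_factory=PEModelConfig)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.reversal_channel <= self.n_channels):
            raise InvalidConfigError("reversal_channel out of range")
        if any(v <= 0 for v in self.gains.values()):
            raise InvalidConfigError("all gains must be positive")
        if self.bout_model.wake_median_s <= 0 or self.bout_model.sleep_median_s <= 0:
            raise InvalidConfigError("bout medians must be positive")
        if min(self.pe_model.spell_rate_deep, self.pe_model.spell_rate_light_sleep,
               self.pe_model.spell_rate_wake, self.pe_model.reach_rate_wake) < 0:
            raise InvalidConfigError("PE rates must be non-negative")

    def to_json(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, dict):
                return {"|".join(k) if isinstance(k, tuple) else k: v for k, v in obj.items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return json.dumps(enc(self))

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        gains = {tuple(k.split("|")): v for k, v in d["gains"].items()}
        pe = d["pe_model"]
        pe["events_per_spell"] = tuple(pe["events_per_spell"])
        return cls(
            n_channels=d["n_channels"],
            fs=d["fs"],
            reversal_channel=d["reversal_channel"],
            kernel=KernelConfig(**d["kernel"]),
            gains=gains,
            order_gains={k: list(v) for k, v in d["order_gains"].items()},
            noise=NoiseConfig(**d["noise"]),
            bout_model=BoutModelConfig(**d["bout_model"]),
            pe_model=PEModelConfig(**pe),
            rng_seed=d["rng_seed"],
        )


# ---------------------------------------------------------------------------
# data containers


@dataclass
class GroundTruth:
    states: np.ndarray  # per-sample uint8: 0 wake, 1 light sleep, 2 deep sleep
    bouts: pd.DataFrame  # columns: start_s, end_s, state ('wake'/'sleep')
    pe_events: pd.DataFrame | None = None  # start_s, duration_s, amplitude, kind, spell_id
    amplitudes: np.ndarray | None = None  # (n_events, n_channels) noise-free peak-trough

    def state_at(self, t_s: float, fs: float) -> str:
        i = min(int(round(t_s * fs)), len(self.states) - 1)
        return _STATE_NAMES[int(self.states[i])]


@dataclass
class Recording:
    """A multichannel recording with synchronized behavior and stimulus log.

    ``channel_ids`` maps matrix rows to the original 1-based electrode
    numbers (rows shrink by one after re-referencing).  ``truth`` is None for
    real data.
    """

    lfp: np.ndarray  # (n_channels, n_samples) float32
    fs: float
    movement: np.ndarray
    proboscis: np.ndarray
    events: pd.DataFrame  # trial_id, seq_index, onset_time_s, duration_s, color, role
    schedule: ExperimentSchedule | None = None
    truth: GroundTruth | None = None
    config: SimConfig | None = None
    channel_ids: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.channel_ids is None:
            self.channel_ids = np.arange(1, self.lfp.shape[0] + 1)
        ns = self.lfp.shape[1]
        if len(self.movement) != ns or len(self.proboscis) != ns:
            raise InvalidConfigError("all traces must share the sample count")

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[0]

    @property
    def n_samples(self) -> int:
        return self.lfp.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_row(self, channel_id: int) -> int:
        """Matrix row for a 1-based original electrode number."""
        rows = np.flatnonzero(self.channel_ids == channel_id)
        if len(rows) == 0:
            raise KeyError(f"channel {channel_id} not present")
        return int(rows[0])


SyntheticRecording = Recording


# ---------------------------------------------------------------------------
# building blocks


def region_group(channel: int, reversal_channel: int) -> str:
    """Coarse region of a 1-based channel relative to the polarity reversal.

    Channels well inboard of the reversal (>=6 channels) are 'central',
    closer inboard channels 'intermediate', the reversal and everything
    outboard 'peripheral'.
    """
    d = reversal_channel - channel
    if d >= 6:
        return "central"
    if d >= 1:
        return "intermediate"
    return "peripheral"


def channel_profile(n_channels: int, reversal_channel: int) -> np.ndarray:
    """Signed per-channel amplitude scaling.

    Positive inboard of the reversal, negative outboard, exactly zero at the
    reversal channel, saturating with distance — the polarity-reversal
    structure seen along the probe transect.
    """
    ch = np.arange(1, n_channels + 1)
    d = reversal_channel - ch
    return np.sign(d) * np.tanh(np.abs(d) / 4.0)


def evoked_kernel(kernel: KernelConfig, fs: float, color: str) -> np.ndarray:
    """Sampled evoked kernel for one color, including the pre-response latency.

    Returns samples covering [0, latency + span) seconds after stimulus
    onset; peak-trough amplitude equals ``kernel.amplitude[color]``.
    """
    n_lat = int(round(kernel.latency_s * fs))
    t = np.arange(int(round(kernel.span_s * fs))) / fs
    lobe1 = np.exp(-t / kernel.tau_decay_s) - np.exp(-t / kernel.tau_rise_s)
    lobe2 = np.exp(-t / kernel.rebound_tau_decay_s) - np.exp(-t / kernel.rebound_tau_rise_s)
    k = lobe1 - kernel.rebound_frac * lobe2
    ptp = k.max() - k.min()
    if ptp > 0:
        k = k / ptp
    k = k * float(kernel.amplitude[color])
    return np.concatenate([np.zeros(n_lat), k])


def pink_noise(n: int, rng: np.random.Generator, exponent: float = 1.0) -> np.ndarray:
    """Unit-variance 1/f^exponent noise via spectral shaping (zero mean, no DC)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    out = np.fft.irfft(spec * scale, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _lognormal_duration(rng: np.random.Generator, median_s: float, sigma: float,
                        floor_s: float) -> float:
    for _ in range(1000):
        d = float(rng.lognormal(mean=np.log(median_s), sigma=sigma))
        if d >= floor_s:
            return d
    return max(median_s, floor_s)


# ---------------------------------------------------------------------------
# simulation stages


def simulate_behavior(
    config: SimConfig, duration_s: float, rng: np.random.Generator
) -> tuple[np.ndarray, GroundTruth]:
    """Movement trace plus ground-truth bouts and per-sample states.

    Wake and sleep bouts alternate (starting awake); movement is rectified
    noise during wake and near-zero sensor noise during sleep.  Mid-bout
    sleep samples — everything except the first and last minute of each
    sleep bout — are flagged as deep sleep.
    """
    if duration_s <= 0:
        raise InvalidConfigError("duration_s must be positive")
    bm = config.bout_model
    fs = config.fs
    n = int(round(duration_s * fs))
    movement = np.abs(rng.standard_normal(n)).astype(np.float32) * 0.005
    states = np.zeros(n, dtype=np.uint8)

    bouts = []
    t = 0.0
    state = "wake"
    while t < duration_s:
        if state == "wake":
            dur = _lognormal_duration(rng, bm.wake_median_s, bm.sigma, bm.min_wake_s)
        else:
            dur = _lognormal_duration(rng, bm.sleep_median_s, bm.sigma, bm.min_sleep_s)
        end = min(t + dur, duration_s)
        bouts.append({"start_s": t, "end_s": end, "state": state})
        i0, i1 = int(round(t * fs)), int(round(end * fs))
        if state == "wake":
            movement[i0:i1] = np.abs(rng.standard_normal(i1 - i0)).astype(np.float32)
            states[i0:i1] = STATE_WAKE
        else:
            states[i0:i1] = STATE_SLEEP
            # deep sleep: mid-bout minutes
            d0, d1 = int(round((t + 60.0) * fs)), int(round((end - 60.0) * fs))
            if d1 > d0:
                states[d0:d1] = STATE_DEEP
        t = end
        state = "sleep" if state == "wake" else "wake"

    truth = GroundTruth(states=states, bouts=pd.DataFrame(bouts))
    return movement, truth


def _place_bump(trace: np.ndarray, fs: float, start_s: float, dur_s: float, amp: float) -> None:
    i0 = int(round(start_s * fs))
    nlen = max(int(round(dur_s * fs)), 2)
    i1 = min(i0 + nlen, len(trace))
    if i1 <= i0:
        return
    bump = amp * np.sin(np.pi * np.arange(i1 - i0) / nlen) ** 2
    trace[i0:i1] = np.maximum(trace[i0:i1], bump.astype(trace.dtype))


def simulate_proboscis(
    config: SimConfig, truth: GroundTruth, rng: np.random.Generator
) -> np.ndarray:
    """Proboscis extension-distance trace; truth PE events are appended in place.

    Rhythmic spells (several ~0.4 s extensions at regular intervals) are
    placed at a high rate in deep sleep, sparsely in light sleep and wake;
    singular, slower "reaches" occur during wake only.
    """
    pm = config.pe_model
    fs = config.fs
    n = len(truth.states)
    trace = np.abs(rng.standard_normal(n)).astype(np.float32) * pm.sensor_noise_sd
    rows = []
    spell_id = 0

    def place_spells(w0: float, w1: float, rate_per_min: float) -> None:
        nonlocal spell_id
        span_min = (w1 - w0) / 60.0
        if span_min <= 0 or rate_per_min <= 0:
            return
        n_spells = rng.poisson(rate_per_min * span_min)
        for _ in range(n_spells):
            n_ev = int(rng.integers(pm.events_per_spell[0], pm.events_per_spell[1] + 1))
            span = (n_ev - 1) * pm.inter_event_s + pm.extension_dur_s
            if w1 - w0 <= span:
                continue
            s0 = float(rng.uniform(w0, w1 - span))
            for j in range(n_ev):
                st = s0 + j * pm.inter_event_s
                _place_bump(trace, fs, st, pm.extension_dur_s, pm.extension_amp)
                rows.append(
                    {"start_s": st, "duration_s": pm.extension_dur_s,
                     "amplitude": pm.extension_amp, "kind": "rhythmic_extension",
                     "spell_id": spell_id}
                )
            spell_id += 1

    for _, b in truth.bouts.iterrows():
        b0, b1 = float(b.start_s), float(b.end_s)
        if b.state == "sleep":
            d0, d1 = b0 + 60.0, b1 - 60.0
            if d1 > d0:
                place_spells(d0, d1, pm.spell_rate_deep)
                place_spells(b0, d0, pm.spell_rate_light_sleep)
                place_spells(d1, b1, pm.spell_rate_light_sleep)
            else:
                place_spells(b0, b1, pm.spell_rate_light_sleep)
        else:
            place_spells(b0, b1, pm.spell_rate_wake)
            n_reach = rng.poisson(pm.reach_rate_wake * (b1 - b0) / 60.0)
            for _ in range(n_reach):
                if b1 - b0 <= pm.reach_dur_s:
                    continue
                s0 = float(rng.uniform(b0, b1 - pm.reach_dur_s))
                _place_bump(trace, fs, s0, pm.reach_dur_s, pm.reach_amp)
                rows.append(
                    {"start_s": s0, "duration_s": pm.reach_dur_s,
                     "amplitude": pm.reach_amp, "kind": "reach", "spell_id": -1}
                )

    pe = pd.DataFrame(rows, columns=["start_s", "duration_s", "amplitude", "kind", "spell_id"])
    truth.pe_events = pe.sort_values("start_s").reset_index(drop=True)
    return trace


def simulate_lfp(
    config: SimConfig,
    schedule: ExperimentSchedule,
    truth: GroundTruth,
    rng: np.random.Generator,
    *,
    movement: np.ndarray,
    proboscis: np.ndarray,
) -> Recording:
    """Superpose evoked responses, 1/f background and line noise into a recording.

    Each stimulus event contributes its color kernel scaled by the signed
    channel profile and the (region, role, state) gain; the noise-free
    peak-trough amplitude of every event on every channel is recorded as
    truth.
    """
    fs = config.fs
    n = len(truth.states)
    C = config.n_channels
    noise = config.noise

    lfp = np.zeros((C, n), dtype=np.float64)
    if noise.pink_sd > 0:
        shared = pink_noise(n, rng, exponent=noise.pink_exponent + 0.5)
        for c in range(C):
            own = pink_noise(n, rng, exponent=noise.pink_exponent)
            lfp[c] = noise.pink_sd * (noise.shared_frac * shared + (1 - noise.shared_frac) * own)
    if noise.line_amp > 0:
        t = np.arange(n) / fs
        nyq = fs / 2.0
        for c in range(C):
            h = noise.line_base_hz
            amp = noise.line_amp
            while h < nyq:
                lfp[c] += amp * np.sin(2 * np.pi * h * t + rng.uniform(0, 2 * np.pi))
                h += noise.line_base_hz
                amp *= 0.5

    profile = channel_profile(C, config.reversal_channel)
    regions = [region_group(c, config.reversal_channel) for c in range(1, C + 1)]
    kernels = {color: evoked_kernel(config.kernel, fs, color)
               for color in config.kernel.amplitude}
    kern_ptp = {color: float(k.max() - k.min()) for color, k in kernels.items()}

    events = schedule.events()
    kept = []
    amps = []
    last_dev: dict[int, int] = {}  # trial_id -> seq_index of last deviant
    for e in events:
        i0 = int(round(e.onset_time * fs))
        kern = kernels[e.color.value]
        if e.role is Role.DEVIANT:
            last_dev[e.trial_id] = e.seq_index
        if i0 < 0 or i0 + len(kern) > n:
            continue
        # carrier-order modulation (non-central regions only)
        order_mult = 1.0
        if e.role is Role.CARRIER and e.trial_id in last_dev:
            order = e.seq_index - last_dev[e.trial_id]
            og = config.order_gains.get(e.color.value)
            if og and 1 <= order <= len(og):
                order_mult = float(og[order - 1])
        state = _STATE_NAMES[int(truth.states[i0])]
        scales = np.array(
            [
                profile[c]
                * config.gains[(regions[c], e.role.value, state)]
                * (order_mult if regions[c] != "central" else 1.0)
                for c in range(C)
            ]
        )
        lfp[:, i0:i0 + len(kern)] += np.outer(scales, kern)
        kept.append(e)
        amps.append(np.abs(scales) * kern_ptp[e.color.value])

    truth.amplitudes = np.array(amps) if amps else np.zeros((0, C))
    rec = Recording(
        lfp=lfp.astype(np.float32),
        fs=fs,
        movement=np.asarray(movement, dtype=np.float32),
        proboscis=np.asarray(proboscis, dtype=np.float32),
        events=events_to_frame(kept),
        schedule=schedule,
        truth=truth,
        config=config,
        meta={"format_version": FORMAT_VERSION},
    )
    return rec


def simulate_recording(
    config: SimConfig,
    duration_s: float,
    trial_type: TrialType | str = TrialType.PHASIC,
    *,
    seed: int | None = None,
    pause_s: float = 3.0,
) -> Recording:
    """One-call forward simulation: schedule + behavior + proboscis + LFP.

    Deterministic per-component substreams are derived from ``seed`` (falls
    back to ``config.rng_seed``).  Trials tile the recording, separated by
    ``pause_s`` pauses.
    """
    if seed is None:
        seed = config.rng_seed
    ss = np.random.SeedSequence(seed)
    rng_sched, rng_beh, rng_pe, rng_lfp = (np.random.default_rng(c) for c in ss.spawn(4))

    trial_type = TrialType(trial_type)
    trial_span = 20.0  # 200 events at 10 Hz
    n_trials = max(int((duration_s + pause_s) // (trial_span + pause_s)), 1)
    schedule = counterbalance_schedule(n_trials, trial_type, rng_sched, pause_s=pause_s)
    # realize jittered positions now, with the schedule substream
    schedule.events(rng_sched)

    movement, truth = simulate_behavior(config, duration_s, rng_beh)
    proboscis = simulate_proboscis(config, truth, rng_pe)
    return simulate_lfp(config, schedule, truth, rng_lfp,
                        movement=movement, proboscis=proboscis)


# ---------------------------------------------------------------------------
# container I/O


def _write_frame(grp: h5py.Group, name: str, df: pd.DataFrame) -> None:
    sub = grp.create_group(name)
    sub.attrs["columns"] = json.dumps(list(df.columns))
    for col in df.columns:
        data = df[col].to_numpy()
        if data.dtype == object:
            data = data.astype("S")
        sub.create_dataset(col, data=data)


def _read_frame(grp: h5py.Group, name: str) -> pd.DataFrame:
    sub = grp[name]
    cols = json.loads(sub.attrs["columns"])
    out = {}
    for col in cols:
        data = sub[col][()]
        if data.dtype.kind == "S":
            data = data.astype(str)
        out[col] = data
    return pd.DataFrame(out)


def write_recording(rec: Recording, path) -> None:
    """Serialize a recording (HDF5: /lfp, /traces, /stimulus, /truth, /meta)."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = rec.meta.get("format_version", FORMAT_VERSION)
        f.create_dataset("lfp", data=rec.lfp.astype(np.float32))
        tr = f.create_group("traces")
        tr.create_dataset("movement", data=rec.movement.astype(np.float32))
        tr.create_dataset("proboscis", data=rec.proboscis.astype(np.float32))
        st = f.create_group("stimulus")
        _write_frame(st, "events", rec.events)
        meta = f.create_group("meta")
        meta.attrs["fs"] = rec.fs
        meta.attrs["channel_ids"] = rec.channel_ids
        meta.attrs["meta_json"] = json.dumps(
            {k: v for k, v in rec.meta.items() if k != "format_version"}
        )
        if rec.config is not None:
            meta.attrs["config_json"] = rec.config.to_json()
        if rec.schedule is not None:
            meta.attrs["schedule_json"] = rec.schedule.to_json()
        if rec.truth is not None:
            tg = f.create_group("truth")
            tg.create_dataset("states", data=rec.truth.states)
            _write_frame(tg, "bouts", rec.truth.bouts)
            if rec.truth.pe_events is not None:
                _write_frame(tg, "pe_events", rec.truth.pe_events)
            if rec.truth.amplitudes is not None:
                tg.create_dataset("amplitudes", data=rec.truth.amplitudes)


def read_recording(path) -> Recording:
    """Load a recording; files without a /truth group load in real-data mode."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise UnsupportedVersionError(
                f"unsupported container format version {version} (expected {FORMAT_VERSION})"
            )
        for component in ("lfp", "traces", "stimulus", "meta"):
            if component not in f:
                raise FormatError(f"container missing required component '{component}'")
        lfp = f["lfp"][()]
        movement = f["traces/movement"][()]
        proboscis = f["traces/proboscis"][()]
        events = _read_frame(f["stimulus"], "events")
        meta_grp = f["meta"]
        fs = float(meta_grp.attrs["fs"])
        channel_ids = np.asarray(meta_grp.attrs["channel_ids"])
        meta = json.loads(meta_grp.attrs.get("meta_json", "{}"))
        meta["format_version"] = version
        config = None
        if "config_json" in meta_grp.attrs:
            config = SimConfig.from_json(meta_grp.attrs["config_json"])
        schedule = None
        if "schedule_json" in meta_grp.attrs:
            schedule = ExperimentSchedule.from_json(meta_grp.attrs["schedule_json"])
        truth = None
        if "truth" in f:
            tg = f["truth"]
            truth = GroundTruth(
                states=tg["states"][()],
                bouts=_read_frame(tg, "bouts"),
                pe_events=_read_frame(tg, "pe_events") if "pe_events" in tg else None,
                amplitudes=tg["amplitudes"][()] if "amplitudes" in tg else None,
            )
    return Recording(
        lfp=lfp, fs=fs, movement=movement, proboscis=proboscis, events=events,
        schedule=schedule, truth=truth, config=config, channel_ids=channel_ids, meta=meta,
    )
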