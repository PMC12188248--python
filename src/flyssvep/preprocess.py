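"""Raw-recording conditioning.

Fixed pipeline order: downsample -> line-noise removal -> polarity-reversal
detection -> re-referencing -> region assignment.  The polarity reversal of
the visually evoked response along the probe (near the lobula, typically
channels 11-14) serves both as the reference channel for common-mode
subtraction and as the anatomical landmark from which the three analysis
regions are placed: central = reversal-8, intermediate = reversal-3,
peripheral = reversal+3.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .synthdata import Recording

__all__ = [
    "ChannelMap",
    "NoReversalError",
    "downsample",
    "remove_line_noise",
    "find_reversal_channel",
    "rereference",
    "assign_regions",
    "preprocess",
]


class NoReversalError(RuntimeError):
    """No polarity inversion found along the probe (poor insertion)."""


@dataclass
class ChannelMap:
    """Analysis channels derived from the polarity-reversal landmark (1-based)."""

    reversal_channel: int
    central: int
    intermediate: int
    peripheral: int
    all_channels_mode: bool = False
    warnings: list = field(default_factory=list)

    def region_channels(self) -> dict:
        return {
            "central": self.central,
            "intermediate": self.intermediate,
            "peripheral": self.peripheral,
        }

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _resample_trace(x: np.ndarray, up: int, down: int) -> np.ndarray:
    if up == 1 and down == 1:
        return x
    return signal.resample_poly(np.asarray(x, dtype=np.float64), up, down).astype(np.float32)


def downsample(rec: Recording, target_fs: float) -> Recording:
    """Anti-aliased resampling of every trace onto a common clock.

    Event onsets are stored in seconds and are unchanged.  Ground-truth
    per-sample states are carried over by nearest-neighbour indexing.
    """
    if target_fs > rec.fs:
        raise ValueError(f"target_fs={target_fs} exceeds recording fs={rec.fs}")
    if target_fs == rec.fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    lfp = np.stack([_resample_trace(row, up, down) for row in rec.lfp])
    movement = _resample_trace(rec.movement, up, down)
    proboscis = _resample_trace(rec.proboscis, up, down)

    truth = rec.truth
    if truth is not None:
        n_new = lfp.shape[1]
        idx = np.minimum(
            np.round(np.arange(n_new) * rec.fs / target_fs).astype(np.int64),
            len(truth.states) - 1,
        )
        truth = dataclasses.replace(truth, states=truth.states[idx])

    return Recording(
        lfp=lfp, fs=float(target_fs), movement=movement, proboscis=proboscis,
        events=rec.events, schedule=rec.schedule, truth=truth, config=rec.config,
        channel_ids=rec.channel_ids.copy(), meta=dict(rec.meta),
    )


def remove_line_noise(rec: Recording, base_hz: float = 50.0, bandwidth_hz: float = 1.0) -> Recording:
    """Notch out mains noise at ``base_hz`` and all harmonics below Nyquist."""
    if base_hz >= rec.fs / 2.0:
        return rec
    lfp = rec.lfp.astype(np.float64)
    h = base_hz
    while h < rec.fs / 2.0:
        b, a = signal.iirnotch(h, Q=h / bandwidth_hz, fs=rec.fs)
        lfp = signal.filtfilt(b, a, lfp, axis=1)
        h += base_hz
    return Recording(
        lfp=lfp.astype(np.float32), fs=rec.fs, movement=rec.movement,
        proboscis=rec.proboscis, events=rec.events, schedule=rec.schedule,
        truth=rec.truth, config=rec.config, channel_ids=rec.channel_ids.copy(),
        meta=dict(rec.meta),
    )


def _mean_erps(rec: Recording, events: pd.DataFrame, window_s: float = 0.1,
               max_events: int = 2000) -> np.ndarray:
    """Per-channel event-locked average waveforms over [0, window_s)."""
    nwin = int(round(window_s * rec.fs))
    onsets = events["onset_time_s"].to_numpy()[:max_events]
    starts = np.round(onsets * rec.fs).astype(np.int64)
    starts = starts[(starts >= 0) & (starts + nwin <= rec.n_samples)]
    if len(starts) == 0:
        raise ValueError("no usable events for ERP averaging")
    idx = starts[:, None] + np.arange(nwin)[None, :]
    erps = rec.lfp[:, idx].mean(axis=1)  # (n_channels, nwin)
    return erps


def find_reversal_channel(rec: Recording, events: pd.DataFrame | None = None,
                          window_s: float = 0.1, min_events: int = 100) -> int:
    """Locate the polarity-reversal channel from event-locked averages.

    The dominant deflection (signed extremum of the average ERP in the
    0-100 ms window) must change sign between a pair of adjacent channels;
    among channels adjacent to a sign flip, the one with the smallest ERP
    peak-trough amplitude is returned (ties break to the lower channel
    number).  Raises :class:`NoReversalError` when no inversion exists,
    which mirrors the exclusion of insertions without a visual response.
    """
    if events is None:
        events = rec.events
    if len(events) < min_events:
        raise ValueError(f"need >= {min_events} stimulus events, got {len(events)}")
    erps = _mean_erps(rec, events, window_s=window_s)
    extrema = erps[np.arange(erps.shape[0]), np.abs(erps).argmax(axis=1)]
    signs = np.sign(extrema)
    flips = np.flatnonzero(signs[:-1] * signs[1:] < 0)
    if len(flips) == 0:
        raise NoReversalError("no polarity inversion along the probe")
    candidates = sorted(set(np.concatenate([flips, flips + 1]).tolist()))
    amps = erps.max(axis=1) - erps.min(axis=1)
    best = min(candidates, key=lambda c: (amps[c], c))
    return int(rec.channel_ids[best])


def rereference(rec: Recording, ref_channel: int) -> Recording:
    """Subtract the reference channel from all others (common-mode removal).

    A 16-channel recording yields 15 channels; ``channel_ids`` keeps the
    mapping to the original electrode numbers.
    """
    ref_row = rec.channel_row(ref_channel)  # KeyError if out of range
    keep = np.arange(rec.n_channels) != ref_row
    lfp = rec.lfp[keep] - rec.lfp[ref_row][None, :]
    meta = dict(rec.meta)
    meta["reference_channel"] = int(ref_channel)
    return Recording(
        lfp=lfp, fs=rec.fs, movement=rec.movement, proboscis=rec.proboscis,
        events=rec.events, schedule=rec.schedule, truth=rec.truth, config=rec.config,
        channel_ids=rec.channel_ids[keep].copy(), meta=meta,
    )


def assign_regions(reversal_channel: int, n_channels: int,
                   all_channels_mode: bool = False) -> ChannelMap:
    """Place the three analysis channels relative to the reversal landmark.

    central = reversal-8, intermediate = reversal-3, peripheral = reversal+3
    (typically channels 3, 8 and 14 for a reversal at 11), clamped into
    1..n_channels with a recorded warning when clamping occurs.
    """
    if not (1 <= reversal_channel <= n_channels):
        raise ValueError("reversal_channel out of range")
    warnings = []

    def clamp(ch: int, name: str) -> int:
        c = min(max(ch, 1), n_channels)
        if c != ch:
            warnings.append(f"{name} channel {ch} clamped to {c}")
        return c

    return ChannelMap(
        reversal_channel=reversal_channel,
        central=clamp(reversal_channel - 8, "central"),
        intermediate=clamp(reversal_channel - 3, "intermediate"),
        peripheral=clamp(reversal_channel + 3, "peripheral"),
        all_channels_mode=all_channels_mode,
        warnings=warnings,
    )


def preprocess(
    rec: Recording,
    target_fs: float | None = None,
    line_base_hz: float = 50.0,
    max_duration_s: float | None = 6 * 3600.0,
    all_channels_mode: bool = False,
) -> tuple[Recording, ChannelMap, dict]:
    """Run the full conditioning pipeline in its fixed order.

    Returns the re-referenced recording, the region channel map and a report
    dict (reversal channel, region map, warnings, fraction of the recording
    retained).  Refuses to run twice on the same data.
    """
    if rec.meta.get("preprocessed"):
        raise ValueError("recording is already preprocessed")
    total = rec.duration_s
    if max_duration_s is not None and rec.duration_s > max_duration_s:
        n_keep = int(round(max_duration_s * rec.fs))
        truth = rec.truth
        if truth is not None:
            truth = dataclasses.replace(truth, states=truth.states[:n_keep])
        rec = Recording(
            lfp=rec.lfp[:, :n_keep], fs=rec.fs, movement=rec.movement[:n_keep],
            proboscis=rec.proboscis[:n_keep],
            events=rec.events[rec.events["onset_time_s"] < max_duration_s].reset_index(drop=True),
            schedule=rec.schedule, truth=truth, config=rec.config,
            channel_ids=rec.channel_ids.copy(), meta=dict(rec.meta),
        )
    if target_fs is not None:
        rec = downsample(rec, target_fs)
    rec = remove_line_noise(rec, base_hz=line_base_hz)
    reversal = find_reversal_channel(rec)
    rec = rereference(rec, reversal)
    cmap = assign_regions(reversal, int(rec.channel_ids.max()), all_channels_mode)
    rec.meta["preprocessed"] = True
    report = {
        "reversal_channel": reversal,
        "region_map": cmap.region_channels(),
        "warnings": cmap.warnings,
        "fraction_retained": rec.duration_s / total,
    }
    return rec, cmap, report
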