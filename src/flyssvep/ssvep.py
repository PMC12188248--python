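"""Event-locked SSVEP amplitude extraction and contrast selection.

The primary metric is the peak-trough amplitude of the evoked response in
the 100 ms following each stimulus onset (one inter-stimulus interval at
10 Hz, so epochs never overlap).  Amplitudes are normalized within fly and
channel as a proportion of the mean amplitude of all events of the same
color (pooled across roles: "all green stimuli, regardless of identity"),
and contrasts use the comparison-specific *corrected amplitude*: the
within-fly mean of the compared group means is subtracted from every
normalized value, so each fly's groups are centred on zero.

Stimulus history labels support the probability contrasts: every event
carries its predecessor's color/role, and carriers are numbered 1-4 by
position after the most recent deviant, so that carrier-vs-deviant
comparisons can be restricted to events sharing a color-transition history
(carrier 1, i.e. a carrier preceded by a deviant, versus a deviant preceded
by a carrier).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .behavior import Bout, PESpell, Segment, inter_pe_windows
from .preprocess import ChannelMap
from .synthdata import Recording

__all__ = [
    "extract_epochs",
    "amplitude",
    "label_history",
    "build_amplitude_records",
    "normalize_amplitudes",
    "corrected_amplitude",
    "select_contrast",
    "power_spectrum",
    "average_erp",
    "DegenerateNormalizationError",
]

log = logging.getLogger(__name__)

EPOCH_WINDOW_S = (0.0, 0.1)
MAX_CARRIER_ORDER = 4


class DegenerateNormalizationError(ValueError):
    """A normalization cell has zero mean amplitude."""


def extract_epochs(
    rec: Recording,
    events: pd.DataFrame | None = None,
    channels: list[int] | None = None,
    window_s: tuple[float, float] = EPOCH_WINDOW_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-locked waveform slices, one per (event, channel).

    Returns ``(epochs, kept)`` where ``epochs`` has shape
    (n_kept_events, n_channels, n_samples) and ``kept`` is the boolean mask
    of events whose window fits inside the recording (the dropped count is
    logged).  ``channels`` are 1-based electrode ids; default all.
    """
    if events is None:
        events = rec.events
    w0, w1 = window_s
    isi = _inter_stimulus_interval(events)
    if isi is not None and (w1 - w0) > isi + 1e-9:
        raise ValueError(f"epoch window {w1 - w0}s exceeds inter-stimulus interval {isi}s")
    rows = (
        np.arange(rec.n_channels)
        if channels is None
        else np.array([rec.channel_row(c) for c in channels])
    )
    i0 = np.round((events["onset_time_s"].to_numpy() + w0) * rec.fs).astype(np.int64)
    nwin = int(round((w1 - w0) * rec.fs))
    kept = (i0 >= 0) & (i0 + nwin <= rec.n_samples)
    dropped = int((~kept).sum())
    if dropped:
        log.info("extract_epochs: dropped %d events outside the recording span", dropped)
    idx = i0[kept][:, None] + np.arange(nwin)[None, :]
    epochs = rec.lfp[rows][:, idx].transpose(1, 0, 2)
    return epochs, kept


def _inter_stimulus_interval(events: pd.DataFrame) -> float | None:
    if len(events) < 2:
        return None
    one = events[events["trial_id"] == events["trial_id"].iloc[0]]
    if len(one) < 2:
        return None
    return float(np.diff(one["onset_time_s"].to_numpy()[:2])[0])


def amplitude(epoch: np.ndarray) -> float:
    """Peak-trough amplitude: max minus min over the post-onset window.

    Order-agnostic (the trough may precede the peak); invariant to adding a
    constant and linear in a scaling of the epoch.
    """
    epoch = np.asarray(epoch)
    if epoch.size == 0:
        raise ValueError("empty epoch")
    return float(epoch.max() - epoch.min())


def label_history(events: pd.DataFrame) -> pd.DataFrame:
    """Annotate each event with its local stimulus history.

    Adds ``prev_role``/``prev_color`` (the immediately preceding event in
    the trial; None for the first event) and ``carrier_order``: carriers
    are numbered 1-4 by position after the most recent deviant; deviants,
    carriers more than 4 past a deviant, and carriers before the first
    deviant get no order.
    """
    df = events.sort_values(["trial_id", "seq_index"]).reset_index(drop=True).copy()
    grp = df.groupby("trial_id", sort=False)
    df["prev_role"] = grp["role"].shift()
    df["prev_color"] = grp["color"].shift()
    seq = df["seq_index"].to_numpy(dtype=float)
    dev_seq = np.where(df["role"].to_numpy() == "deviant", seq, np.nan)
    last_dev = (
        pd.Series(dev_seq).groupby(df["trial_id"], sort=False).ffill().to_numpy()
    )
    order = seq - last_dev
    order[(df["role"] != "carrier") | (order > MAX_CARRIER_ORDER) | np.isnan(order)] = np.nan
    order[order < 1] = np.nan
    df["carrier_order"] = order
    return df


def _lookup_intervals(times: np.ndarray, starts: np.ndarray, ends: np.ndarray,
                      labels: list) -> np.ndarray:
    """Label each time by the (sorted, disjoint) interval containing it, else None."""
    out = np.full(len(times), None, dtype=object)
    if len(starts) == 0:
        return out
    j = np.searchsorted(starts, times, side="right") - 1
    ok = (j >= 0) & (times < ends[np.clip(j, 0, len(ends) - 1)])
    for i in np.flatnonzero(ok):
        out[i] = labels[j[i]]
    return out


def build_amplitude_records(
    rec: Recording,
    cmap: ChannelMap,
    *,
    fly_id: int | str = 0,
    bouts: list[Bout] | None = None,
    segments: list[Segment] | None = None,
    spells: list[PESpell] | None = None,
    window_s: tuple[float, float] = EPOCH_WINDOW_S,
) -> pd.DataFrame:
    """Assemble the long-form amplitude table for one fly.

    One row per (stimulus event, analysis channel) with all grouping labels:
    region, color, role, history (prev_role/prev_color/carrier_order),
    behavioral state, segment label and proboscis-extension context.
    """
    if cmap.all_channels_mode:
        channels = {f"ch{int(c)}": int(c) for c in rec.channel_ids}
    else:
        channels = cmap.region_channels()
    ch_ids = list(channels.values())
    events = label_history(rec.events)
    epochs, kept = extract_epochs(rec, events, channels=ch_ids, window_s=window_s)
    events = events[kept].reset_index(drop=True)
    amps = epochs.max(axis=2) - epochs.min(axis=2)  # (n_events, n_channels)

    onsets = events["onset_time_s"].to_numpy()

    state = np.full(len(events), "wake", dtype=object)
    if bouts is not None and bouts:
        bs = np.array([b.start_s for b in bouts])
        be = np.array([b.end_s for b in bouts])
        state = _lookup_intervals(onsets, bs, be, [b.state for b in bouts])
        state[state == None] = "wake"  # noqa: E711 — events outside the scored span

    seg_label = np.full(len(events), None, dtype=object)
    if segments:
        segs = sorted(segments, key=lambda s: s.start_s)
        seg_label = _lookup_intervals(
            onsets,
            np.array([s.start_s for s in segs]),
            np.array([s.end_s for s in segs]),
            [s.label for s in segs],
        )

    pe_context = np.full(len(events), "none", dtype=object)
    if spells:
        wins, win_states = [], []
        for spell in spells:
            if len(spell.events) < 2:
                continue
            for w in inter_pe_windows(spell):
                wins.append(w)
                win_states.append(spell.state or "wake")
        if wins:
            order = np.argsort([w[0] for w in wins])
            ws = np.array([wins[i][0] for i in order])
            we = np.array([wins[i][1] for i in order])
            lab = [f"in_spell_window_{win_states[i]}" for i in order]
            ctx = _lookup_intervals(onsets, ws, we, lab)
            pe_context[ctx != None] = ctx[ctx != None]  # noqa: E711

    trial_types = {}
    if rec.schedule is not None:
        trial_types = {t.trial_id: t.trial_type.value for t in rec.schedule.trials}

    frames = []
    for j, (region, ch) in enumerate(channels.items()):
        frames.append(
            pd.DataFrame(
                {
                    "fly_id": fly_id,
                    "trial_id": events["trial_id"],
                    "seq_index": events["seq_index"],
                    "channel": ch,
                    "region": region,
                    "color": events["color"],
                    "role": events["role"],
                    "carrier_order": events["carrier_order"],
                    "prev_role": events["prev_role"],
                    "prev_color": events["prev_color"],
                    "state": state,
                    "segment": seg_label,
                    "pe_context": pe_context,
                    "trial_type": events["trial_id"].map(trial_types).fillna("unknown")
                    if trial_types
                    else "unknown",
                    "amp_raw": amps[:, j],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def normalize_amplitudes(records: pd.DataFrame) -> pd.DataFrame:
    """Express each amplitude as a proportion of its (fly, channel, color) mean.

    The denominator pools all events of that color regardless of role, so
    mean(amp_norm) is exactly 1 over each normalization cell.
    """
    df = records.copy()
    df["amp_raw"] = df["amp_raw"].astype(np.float64)
    means = df.groupby(["fly_id", "channel", "color"])["amp_raw"].transform("mean")
    if (means == 0).any():
        raise DegenerateNormalizationError("zero mean amplitude in a normalization cell")
    df["amp_norm"] = df["amp_raw"] / means
    return df


def corrected_amplitude(groups: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Comparison-specific corrected amplitudes for a named set of groups.

    For each fly present in *every* group, the mean of the per-group mean
    normalized amplitudes is subtracted from that fly's values; flies
    missing any group are excluded (logged).  Returns the concatenated
    groups with ``group`` and ``amp_corrected`` columns; per fly, the mean
    of the group means of ``amp_corrected`` is exactly zero.
    """
    if not groups:
        raise ValueError("no groups given")
    flies = None
    for name, df in groups.items():
        f = set(df["fly_id"].unique())
        flies = f if flies is None else (flies & f)
    all_flies = set().union(*(set(df["fly_id"].unique()) for df in groups.values()))
    excluded = all_flies - flies
    if excluded:
        log.info("corrected_amplitude: excluding flies missing a group: %s", sorted(excluded))

    out = []
    for name, df in groups.items():
        sub = df[df["fly_id"].isin(flies)].copy()
        sub["group"] = name
        out.append(sub)
    cat = pd.concat(out, ignore_index=True)
    group_means = cat.groupby(["fly_id", "group"])["amp_norm"].mean()
    fly_center = group_means.groupby("fly_id").mean()
    cat["amp_corrected"] = cat["amp_norm"] - cat["fly_id"].map(fly_center)
    return cat


CONTRAST_NAMES = (
    "carrier_vs_deviant",
    "carrier_order",
    "wake_vs_sleep",
    "segments",
    "pe_context",
    "jitter_gap",
)


def _history_matched(records: pd.DataFrame, role: str) -> pd.DataFrame:
    """Events whose immediate history is a color transition.

    Carriers restricted to carrier order 1 (preceded by a deviant); deviants
    restricted to those preceded by a carrier.
    """
    if role == "carrier":
        return records[(records["role"] == "carrier") & (records["carrier_order"] == 1)]
    return records[(records["role"] == "deviant") & (records["prev_role"] == "carrier")]


def select_contrast(
    records: pd.DataFrame,
    contrast_name: str,
    *,
    color: str | None = None,
    role: str | None = None,
    region: str | None = None,
) -> dict[str, pd.DataFrame]:
    """Named event selections for the study's comparisons.

    Returns an ordered dict of group name -> record subset.  All contrasts
    are within color when ``color`` is given; ``region`` filters rows to one
    analysis channel.
    """
    df = records
    if region is not None:
        df = df[df["region"] == region]
    if color is not None:
        df = df[df["color"] == color]

    if contrast_name == "carrier_vs_deviant":
        return {
            "carrier": _history_matched(df, "carrier"),
            "deviant": _history_matched(df, "deviant"),
        }
    if contrast_name == "carrier_order":
        return {
            f"order_{k}": df[(df["role"] == "carrier") & (df["carrier_order"] == k)]
            for k in range(1, MAX_CARRIER_ORDER + 1)
        }
    if contrast_name == "wake_vs_sleep":
        if role is None:
            raise ValueError("wake_vs_sleep requires role=")
        sub = _history_matched(df, role)
        return {st: sub[sub["state"] == st] for st in ("wake", "sleep")}
    if contrast_name == "segments":
        if role is None:
            raise ValueError("segments requires role=")
        sub = _history_matched(df, role)
        sub = sub[sub["segment"].notna()]
        labels = [l for l in
                  ("mid_wake", "last_wake", "sleep_1st", "sleep_2nd", "mid_sleep",
                   "sleep_2nd_last", "sleep_last")
                  if (sub["segment"] == l).any()]
        return {l: sub[sub["segment"] == l] for l in labels}
    if contrast_name == "pe_context":
        if role is None:
            raise ValueError("pe_context requires role=")
        sub = _history_matched(df, role)
        sub = sub[sub["pe_context"] != "none"]
        return {
            "mid_sleep": sub[sub["segment"] == "mid_sleep"],
            "other": sub[sub["segment"] != "mid_sleep"],
        }
    if contrast_name == "jitter_gap":
        # deviants preceded by exactly four carriers, jittering vs phasic trials
        dev = df[(df["role"] == "deviant") & (df["prev_role"] == "carrier")]
        # the preceding carrier must itself be order 4 — i.e. a gap of 4 carriers;
        # in phasic trials this always holds, in jittering trials it selects gap==4
        key = records.set_index(["fly_id", "channel", "trial_id", "seq_index"])["carrier_order"]
        prev_idx = pd.MultiIndex.from_arrays(
            [dev["fly_id"], dev["channel"], dev["trial_id"], dev["seq_index"] - 1]
        )
        prev_order = key.reindex(prev_idx).to_numpy()
        dev = dev[prev_order == MAX_CARRIER_ORDER]
        return {
            "jittering": dev[dev["trial_type"] == "jittering"],
            "phasic": dev[dev["trial_type"] == "phasic"],
        }
    raise ValueError(f"unknown contrast {contrast_name!r}; known: {CONTRAST_NAMES}")


def power_spectrum(
    rec: Recording,
    trial_ids: list[int] | None = None,
    channel: int | None = None,
    trial_span_s: float = 20.0,
) -> pd.DataFrame:
    """Trial-averaged normalized LFP power spectrum (frequency tagging).

    Computes a periodogram over each full trial span (0.05 Hz resolution for
    20 s trials), normalizes each to unit total power, and averages across
    trials.  The carrier frequency F1 appears as the dominant peak (10 Hz)
    and the deviant rate F2 as a low-frequency peak (2 Hz) in oddball trials.
    """
    if channel is None:
        raise ValueError("channel (1-based electrode id) is required")
    row = rec.channel_row(channel)
    ev = rec.events
    if trial_ids is None:
        trial_ids = sorted(ev["trial_id"].unique())
    n = int(round(trial_span_s * rec.fs))
    spectra = []
    freqs = None
    for tid in trial_ids:
        t0 = ev.loc[ev["trial_id"] == tid, "onset_time_s"].min()
        i0 = int(round(t0 * rec.fs))
        if i0 < 0 or i0 + n > rec.n_samples:
            continue
        f, p = sp_signal.periodogram(
            rec.lfp[row, i0:i0 + n].astype(np.float64), fs=rec.fs, window="boxcar"
        )
        tot = p.sum()
        if tot > 0:
            p = p / tot
        spectra.append(p)
        freqs = f
    if not spectra:
        raise ValueError("selection contains no full trial")
    power = np.mean(spectra, axis=0)
    return pd.DataFrame({"freq_hz": freqs, "power": power})


def average_erp(
    epochs: np.ndarray, fly_ids: np.ndarray
) -> tuple[np.ndarray, pd.Series]:
    """Grand-average waveform: mean within fly, then across flies.

    ``epochs`` is (n_events, n_samples) for one channel; returns the grand
    mean and the per-fly epoch counts.
    """
    fly_ids = np.asarray(fly_ids)
    if len(fly_ids) != len(epochs):
        raise ValueError("fly_ids must match epochs")
    if len(epochs) == 0:
        raise ValueError("no epochs")
    flies = pd.unique(fly_ids)
    per_fly = np.stack([epochs[fly_ids == f].mean(axis=0) for f in flies])
    counts = pd.Series([int((fly_ids == f).sum()) for f in flies], index=flies)
    return per_fly.mean(axis=0), counts
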