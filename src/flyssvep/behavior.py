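"""Behavioral state scoring and proboscis-extension analysis.

Sleep is defined by the field's immobility criterion: any maximal run of
behavioral quiescence lasting at least 5 min is a sleep bout; all remaining
time is wake.  Sleep bouts are segmented into five labeled 1-minute windows
(first, second, middle, second-to-last and last minute) and the immediately
preceding wake bout contributes two more (its middle and final minute).

Proboscis activity is classified into rhythmic extension spells — bursts of
several short extensions at regular intervals, characteristic of deep
sleep — versus singular, slower questing-like "reaches", which mostly occur
during wake.  Because extensions themselves perturb brain activity, SSVEP
sampling windows are the guarded intervals *between* the extensions of a
spell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Bout",
    "Segment",
    "PEEvent",
    "PESpell",
    "quantify_movement",
    "score_bouts",
    "segment_bouts",
    "detect_pe_events",
    "classify_pe",
    "inter_pe_windows",
    "bouts_to_frame",
    "segments_to_frame",
]

SEGMENT_LABELS = (
    "mid_wake", "last_wake",
    "sleep_1st", "sleep_2nd", "mid_sleep", "sleep_2nd_last", "sleep_last",
)


@dataclass(frozen=True)
class Bout:
    start_s: float
    end_s: float
    state: str  # 'wake' | 'sleep'

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class Segment:
    label: str
    start_s: float
    end_s: float
    bout_index: int


@dataclass(frozen=True)
class PEEvent:
    start_s: float
    duration_s: float
    amplitude: float
    kind: str = "unclassified"  # rhythmic_extension | reach | unclassified

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    @property
    def peak_time_s(self) -> float:
        return self.start_s + self.duration_s / 2.0


@dataclass
class PESpell:
    events: list
    segment_label: str | None = None
    state: str | None = None

    @property
    def start_s(self) -> float:
        return self.events[0].start_s

    @property
    def end_s(self) -> float:
        return self.events[-1].end_s


def quantify_movement(movement: np.ndarray, fs: float, bin_s: float = 1.0,
                      threshold: float | None = None) -> np.ndarray:
    """Binary per-bin activity from the movement-magnitude trace.

    Default threshold: ten times the 5th percentile of the per-bin means
    (a low quantile tracks the sensor floor during quiescence), with a tiny
    absolute floor so an all-zero trace scores fully inactive.
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    movement = np.asarray(movement, dtype=np.float64)
    if movement.size == 0:
        raise ValueError("empty movement trace")
    spb = int(round(bin_s * fs))
    n_bins = movement.size // spb
    if n_bins == 0:
        raise ValueError("trace shorter than one bin")
    binned = movement[: n_bins * spb].reshape(n_bins, spb).mean(axis=1)
    if threshold is None:
        threshold = max(10.0 * np.quantile(binned, 0.05), 1e-9)
    return binned > threshold


def score_bouts(active: np.ndarray, bin_s: float = 1.0, min_sleep_s: float = 300.0) -> list[Bout]:
    """Immobility-criterion sleep scoring on a binary activity series.

    Maximal inactive runs of at least ``min_sleep_s`` (boundary inclusive:
    exactly 5 min of quiescence is sleep) become sleep bouts; everything else
    is wake.  The returned bouts tile the scored span and alternate states.
    """
    active = np.asarray(active, dtype=bool)
    if active.size == 0:
        raise ValueError("empty activity series")
    bouts: list[Bout] = []
    # run-length encode the inactive mask
    edges = np.flatnonzero(np.diff(active.astype(np.int8))) + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [active.size]])
    raw = []
    for s, e in zip(starts, ends):
        quiescent = not active[s]
        dur = (e - s) * bin_s
        state = "sleep" if quiescent and dur >= min_sleep_s else "wake"
        raw.append((s * bin_s, e * bin_s, state))
    # merge adjacent same-state bouts
    for s, e, st in raw:
        if bouts and bouts[-1].state == st:
            bouts[-1] = Bout(bouts[-1].start_s, e, st)
        else:
            bouts.append(Bout(s, e, st))
    return bouts


def _minute_window(bout_start_s: float, minute_index: int) -> tuple[float, float]:
    return bout_start_s + 60.0 * minute_index, bout_start_s + 60.0 * (minute_index + 1)


def segment_bouts(bouts: list[Bout]) -> list[Segment]:
    """Labeled 1-minute windows within each sleep bout and its preceding wake.

    Sleep bouts yield sleep_1st, sleep_2nd, mid_sleep (minute index
    floor((M-1)/2) of the M whole minutes — deterministic "middle minute"),
    sleep_2nd_last and sleep_last.  The wake bout immediately preceding each
    sleep bout yields mid_wake and last_wake (wake bouts shorter than 2 min
    yield none).  Windows are kept in priority order first/last before
    middle, dropping any window that would overlap one already placed (this
    only matters when the sleep criterion is configured below 5 min).
    """
    segments: list[Segment] = []
    for i, bout in enumerate(bouts):
        if bout.state != "sleep":
            continue
        m = int(bout.duration_s // 60)
        if m >= 1:
            candidates = [
                ("sleep_1st", 0),
                ("sleep_last", None),  # resolved against duration, not whole minutes
                ("sleep_2nd", 1),
                ("sleep_2nd_last", None),
                ("mid_sleep", (m - 1) // 2),
            ]
            placed: list[tuple[float, float]] = []
            for label, minute in candidates:
                if label == "sleep_last":
                    win = (bout.start_s + bout.duration_s - 60.0, bout.end_s)
                elif label == "sleep_2nd_last":
                    win = (bout.start_s + bout.duration_s - 120.0, bout.end_s - 60.0)
                else:
                    win = _minute_window(bout.start_s, minute)
                if win[0] < bout.start_s - 1e-9 or win[1] > bout.end_s + 1e-9:
                    continue
                if any(win[0] < p1 - 1e-9 and win[1] > p0 + 1e-9 for p0, p1 in placed):
                    continue
                placed.append(win)
                segments.append(Segment(label, win[0], win[1], i))
        # wake segments from the immediately preceding wake bout
        if i > 0 and bouts[i - 1].state == "wake":
            w = bouts[i - 1]
            mw = int(w.duration_s // 60)
            if mw >= 2:
                last = (w.end_s - 60.0, w.end_s)
                mid = _minute_window(w.start_s, (mw - 1) // 2)
                segments.append(Segment("last_wake", last[0], last[1], i - 1))
                if not (mid[0] < last[1] and mid[1] > last[0]):
                    segments.append(Segment("mid_wake", mid[0], mid[1], i - 1))
    return sorted(segments, key=lambda s: s.start_s)


def detect_pe_events(proboscis: np.ndarray, fs: float, threshold: float = 0.3,
                     merge_gap_s: float = 0.1) -> list[PEEvent]:
    """Threshold-crossing detection on the proboscis extension-distance trace.

    Crossings separated by less than ``merge_gap_s`` are merged into one
    event; each event records its start, duration and peak extension.
    """
    x = np.asarray(proboscis, dtype=np.float64)
    above = x > threshold
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [len(x)]])
    # merge close crossings
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if (s - merged[-1][1]) / fs < merge_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [
        PEEvent(start_s=s / fs, duration_s=(e - s) / fs, amplitude=float(x[s:e].max()))
        for s, e in merged
    ]


def classify_pe(
    events: list[PEEvent],
    bouts: list[Bout] | None = None,
    segments: list[Segment] | None = None,
    spell_gap_s: float = 5.0,
    min_spell_events: int = 3,
    reach_min_duration_s: float = 1.5,
) -> tuple[list[PEEvent], list[PESpell]]:
    """Group extensions into rhythmic spells and label isolated events.

    Events whose inter-event interval is at most ``spell_gap_s`` form a
    spell when at least ``min_spell_events`` strong; spell members are
    rhythmic extensions.  Isolated events longer than
    ``reach_min_duration_s`` are reaches; other isolated events stay
    unclassified.  Spells never span a wake/sleep bout boundary, so each
    spell has an unambiguous behavioral context (and a segment label when
    its onset falls inside a labeled minute).
    """
    events = sorted(events, key=lambda e: e.start_s)

    def bout_of(t: float) -> int | None:
        if bouts is None:
            return None
        for i, b in enumerate(bouts):
            if b.start_s <= t < b.end_s:
                return i
        return len(bouts) - 1 if bouts else None

    groups: list[list[PEEvent]] = []
    for ev in events:
        if (
            groups
            and ev.start_s - groups[-1][-1].end_s <= spell_gap_s
            and bout_of(ev.peak_time_s) == bout_of(groups[-1][-1].peak_time_s)
        ):
            groups[-1].append(ev)
        else:
            groups.append([ev])

    out_events: list[PEEvent] = []
    spells: list[PESpell] = []
    for grp in groups:
        if len(grp) >= min_spell_events:
            members = [
                PEEvent(e.start_s, e.duration_s, e.amplitude, "rhythmic_extension")
                for e in grp
            ]
            out_events.extend(members)
            spell = PESpell(events=members)
            bi = bout_of(spell.start_s)
            if bi is not None:
                spell.state = bouts[bi].state
            if segments is not None:
                for seg in segments:
                    if seg.start_s <= spell.start_s < seg.end_s:
                        spell.segment_label = seg.label
                        break
            spells.append(spell)
        else:
            for e in grp:
                kind = "reach" if e.duration_s > reach_min_duration_s else "unclassified"
                out_events.append(PEEvent(e.start_s, e.duration_s, e.amplitude, kind))
    return sorted(out_events, key=lambda e: e.start_s), spells


def inter_pe_windows(spell: PESpell, guard_s: float = 0.05,
                     min_window_s: float = 0.1) -> list[tuple[float, float]]:
    """Guarded sampling intervals between consecutive extensions of a spell.

    Each window runs from one extension's end plus the guard margin to the
    next extension's start minus the guard; windows shorter than one
    stimulus period are dropped.
    """
    if len(spell.events) < 2:
        raise ValueError("spell needs >= 2 events")
    windows = []
    for a, b in zip(spell.events[:-1], spell.events[1:]):
        w0, w1 = a.end_s + guard_s, b.start_s - guard_s
        if w1 - w0 >= min_window_s:
            windows.append((w0, w1))
    return windows


def bouts_to_frame(bouts: list[Bout], fly_id: int | str | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        {"state": [b.state for b in bouts],
         "start_s": [b.start_s for b in bouts],
         "end_s": [b.end_s for b in bouts]}
    )
    if fly_id is not None:
        df.insert(0, "fly_id", fly_id)
    return df


def segments_to_frame(segments: list[Segment], fly_id: int | str | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        {"label": [s.label for s in segments],
         "start_s": [s.start_s for s in segments],
         "end_s": [s.end_s for s in segments],
         "bout_index": [s.bout_index for s in segments]}
    )
    if fly_id is not None:
        df.insert(0, "fly_id", fly_id)
    return df
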