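"""Register-transition counting, dwell statistics and occupancy intervals.

A transition is any change of the identity or number of nucleotides occupying
the binding pocket, detected as a change of the occupant residue-number
multiset between consecutive frames. Direction is read from the change of the
mean occupant register: increase = 3' (downstream), decrease = 5' (upstream).
Mode-only changes over an unchanged occupant set (e.g. a confidence reflag)
are not transitions.

Entering the empty pocket is an ``unbind`` and leaving it a ``rebind``; a
rebind whose occupant set differs from the last bound state is additionally
scored as a ``jump`` (the register moved across the unbound gap), with its
direction computed across that gap. Unbind/rebind themselves carry no
direction; jumps and shifts count toward the 5'/3' tallies.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .state_classifier import UNBOUND, PocketState, StateTrack

__all__ = [
    "TransitionEvent",
    "TransitionSummary",
    "DwellStats",
    "OccupancyInterval",
    "events",
    "summarize",
    "dwell_stats",
    "occupancy_intervals",
    "FIVE_PRIME",
    "THREE_PRIME",
    "NO_DIRECTION",
]

FIVE_PRIME = "5'"
THREE_PRIME = "3'"
NO_DIRECTION = "none"

SHIFT = "shift"
UNBIND = "unbind"
REBIND = "rebind"
JUMP = "jump"


@dataclass(frozen=True)
class TransitionEvent:
    time_ns: float
    from_label: str
    to_label: str
    direction: str  # 5' / 3' / none
    kind: str  # shift / unbind / rebind / jump


@dataclass(frozen=True)
class TransitionSummary:
    n_5prime: int
    n_3prime: int
    n_unbind: int
    n_rebind: int
    n_jump: int
    track_length_us: float


@dataclass
class DwellStats:
    by_label: pd.DataFrame  # columns: label, total_us, visits, mean_dwell_us
    by_mode: pd.DataFrame
    duration_us: float


@dataclass(frozen=True)
class OccupancyInterval:
    label: str
    t_start_ns: float
    t_end_ns: float  # half-open [t_start, t_end)


def _multiset(state: PocketState) -> tuple[int, ...]:
    return tuple(sorted(o.res_seq for o in state.occupants))


def _mean(ms: tuple[int, ...]) -> float:
    return sum(ms) / len(ms)


def _direction(before: tuple[int, ...], after: tuple[int, ...]) -> str:
    delta = _mean(after) - _mean(before)
    if delta > 0:
        return THREE_PRIME
    if delta < 0:
        return FIVE_PRIME
    return NO_DIRECTION


def events(track: StateTrack) -> list[TransitionEvent]:
    """Ordered transition events at every occupant-multiset change."""
    if len(track) == 0:
        raise ValueError("events() requires a non-empty track")
    evs: list[TransitionEvent] = []
    entries = track.entries
    prev = entries[0]
    last_bound_ms = _multiset(prev.state) if prev.state.mode != UNBOUND else None
    for cur in entries[1:]:
        ms_prev = _multiset(prev.state)
        ms_cur = _multiset(cur.state)
        if ms_cur != ms_prev:
            t = cur.time_ns
            frm, to = prev.state.label, cur.state.label
            if cur.state.mode == UNBOUND:
                evs.append(TransitionEvent(t, frm, to, NO_DIRECTION, UNBIND))
            elif prev.state.mode == UNBOUND:
                evs.append(TransitionEvent(t, frm, to, NO_DIRECTION, REBIND))
                if last_bound_ms is not None and ms_cur != last_bound_ms:
                    evs.append(
                        TransitionEvent(
                            t, frm, to, _direction(last_bound_ms, ms_cur), JUMP
                        )
                    )
            else:
                evs.append(
                    TransitionEvent(t, frm, to, _direction(ms_prev, ms_cur), SHIFT)
                )
        if cur.state.mode != UNBOUND:
            last_bound_ms = _multiset(cur.state)
        prev = cur
    return evs


def summarize(track: StateTrack) -> TransitionSummary:
    """Tally events by direction and kind (the transition-count table row)."""
    evs = events(track)
    n5 = sum(1 for e in evs if e.direction == FIVE_PRIME)
    n3 = sum(1 for e in evs if e.direction == THREE_PRIME)
    dt = track.frame_interval_ns()
    length_us = len(track) * dt / 1000.0
    return TransitionSummary(
        n_5prime=n5,
        n_3prime=n3,
        n_unbind=sum(1 for e in evs if e.kind == UNBIND),
        n_rebind=sum(1 for e in evs if e.kind == REBIND),
        n_jump=sum(1 for e in evs if e.kind == JUMP),
        track_length_us=length_us,
    )


def events_to_dataframe(evs: list[TransitionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "time_ns": e.time_ns,
                "from_label": e.from_label,
                "to_label": e.to_label,
                "direction": e.direction,
                "kind": e.kind,
            }
            for e in evs
        ],
        columns=["time_ns", "from_label", "to_label", "direction", "kind"],
    )


def dwell_stats(track: StateTrack, frame_interval_ns: float | None = None) -> DwellStats:
    """Run-length dwell statistics per label and per mode.

    Each frame contributes one frame interval of residence time, so per-label
    totals conserve the track duration exactly.
    """
    if len(track) == 0:
        raise ValueError("dwell_stats() requires a non-empty track")
    dt_us = (frame_interval_ns or track.frame_interval_ns()) / 1000.0

    def tally(key) -> pd.DataFrame:
        totals: dict[str, float] = {}
        visits: dict[str, int] = {}
        prev_key = None
        for e in track.entries:
            k = key(e.state)
            totals[k] = totals.get(k, 0.0) + dt_us
            if k != prev_key:
                visits[k] = visits.get(k, 0) + 1
            prev_key = k
        rows = [
            {
                "key": k,
                "total_us": totals[k],
                "visits": visits[k],
                "mean_dwell_us": totals[k] / visits[k],
            }
            for k in sorted(totals)
        ]
        return pd.DataFrame(rows, columns=["key", "total_us", "visits", "mean_dwell_us"])

    by_label = tally(lambda s: s.label).rename(columns={"key": "label"})
    by_mode = tally(lambda s: s.mode).rename(columns={"key": "mode"})
    return DwellStats(by_label=by_label, by_mode=by_mode, duration_us=len(track) * dt_us)


def occupancy_intervals(track: StateTrack) -> list[OccupancyInterval]:
    """Maximal constant-label runs as half-open intervals tiling the track."""
    if len(track) == 0:
        raise ValueError("occupancy_intervals() requires a non-empty track")
    dt = track.frame_interval_ns()
    out: list[OccupancyInterval] = []
    start = track.entries[0].time_ns
    cur_label = track.entries[0].state.label
    for prev, cur in zip(track.entries, track.entries[1:]):
        if cur.state.label != cur_label:
            out.append(OccupancyInterval(cur_label, start, cur.time_ns))
            start = cur.time_ns
            cur_label = cur.state.label
    out.append(OccupancyInterval(cur_label, start, track.entries[-1].time_ns + dt))
    return out


def intervals_to_dataframe(intervals: list[OccupancyInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"label": iv.label, "t_start_ns": iv.t_start_ns, "t_end_ns": iv.t_end_ns}
            for iv in intervals
        ],
        columns=["label", "t_start_ns", "t_end_ns"],
    )
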