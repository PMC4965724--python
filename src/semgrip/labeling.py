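"""Assigning class labels to MAV instances from the schedule plus ACC evidence.

Movements announce themselves mechanically: the summed ACC difference
statistic exceeding twice its run median marks activity.  Above-threshold
steps close in time form one *event*; a movement's label starts at the event
nearest its scheduled time, while a grip's label starts at the *end* of the
nearest event (the reach toward the object ends when the grip is
established), clamped to at most 500 ms from the scheduled second.  A grip is
sustained for up to three seconds or until the next movement onset; a
movement lasts until the next onset (when the script runs activities
back-to-back) or its scheduled end.  Everything else is neutral/rest (NR).

The class-imbalanced NR instances are then subsampled to the run-start window
(seconds 1-4, when the subject is reliably at rest): 60 instances per run,
480 across the eight runs.  Finally the labelled stream is cut into activity
segments of at most 40 instances each, the unit the DTW classifier consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .preprocess import AccSummary, MavStream
from .protocol import NR, ProtocolSchedule

__all__ = [
    "LabeledStream",
    "ActivitySegment",
    "detect_acc_events",
    "detect_movement_onsets",
    "align_acc_to_emg",
    "label_run",
    "subsample_nr",
    "segment_activities",
    "NR_WINDOW",
    "MAX_SEGMENT_LEN",
]

logger = logging.getLogger(__name__)

NR_WINDOW = (1.0, 4.0)  # run-start NR retention window, seconds
MAX_SEGMENT_LEN = 40  # instances (100 ms windows)
MAX_ADJUST_S = 0.5  # labels move at most this far from the scheduled second
GRIP_HOLD_S = 3.0
EVENT_GAP_S = 0.15  # above-threshold ACC steps closer than this merge


@dataclass
class LabeledStream:
    """A MAV stream with one class code per instance."""

    times: np.ndarray
    values: np.ndarray
    labels: np.ndarray  # (m,) of class codes
    step: float = 0.05
    group_id: Optional[str] = None
    schedule: Optional[ProtocolSchedule] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.labels = np.asarray(self.labels)
        if not (len(self.times) == len(self.values) == len(self.labels)):
            raise ValueError("times, values and labels must have equal length")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def stream(self) -> MavStream:
        return MavStream(times=self.times, values=self.values, step=self.step)


@dataclass
class ActivitySegment:
    """One maximal run of identically labelled, consecutive instances."""

    label: str
    times: np.ndarray
    values: np.ndarray  # (L, 8) MAV instances
    rep_index: int = 0  # 1..12; 0 for pre-repetition NR
    run_id: Optional[str] = None
    words: Optional[np.ndarray] = None  # (L, 8) symbol ranks, set after encoding

    def __post_init__(self) -> None:
        if len(self.values) < 1:
            raise ValueError("segment must contain at least one instance")

    def __len__(self) -> int:
        return len(self.values)


def detect_acc_events(summary: AccSummary, gap_s: float = EVENT_GAP_S) -> list[tuple[float, float]]:
    """Cluster above-threshold ACC steps into (start, end) events.

    A step is active when the statistic strictly exceeds twice the run
    median; active steps separated by at most ``gap_s`` belong to one event.
    """
    thr = 2.0 * summary.median
    active = summary.times[summary.stat > thr]
    if active.size == 0:
        return []
    events = []
    start = prev = active[0]
    for t in active[1:]:
        if t - prev > gap_s:
            events.append((start, prev))
            start = t
        prev = t
    events.append((start, prev))
    return events


def detect_movement_onsets(summary: AccSummary, gap_s: float = EVENT_GAP_S) -> np.ndarray:
    """First time of each ACC event (candidate movement onsets)."""
    return np.asarray([s for s, _ in detect_acc_events(summary, gap_s)])


def align_acc_to_emg(summary: AccSummary, mav: MavStream) -> np.ndarray:
    """Map each ACC summary instant to the nearest MAV instant (index map).

    Ties (an ACC instant exactly between two MAV instants) resolve to the
    earlier instant.
    """
    if len(mav) == 0 or summary.times.size == 0:
        raise ValueError("both streams must be non-empty")
    pos = np.searchsorted(mav.times, summary.times)
    pos = np.clip(pos, 1, len(mav) - 1)
    left, right = mav.times[pos - 1], mav.times[pos]
    use_right = (summary.times - left) > (right - summary.times)  # tie -> earlier
    idx = np.where(use_right, pos, pos - 1)
    # handle instants before the first MAV time
    idx[summary.times <= mav.times[0]] = 0
    return idx


def _nearest_event(
    events: Sequence[tuple[float, float]],
    scheduled: float,
    key: int,
    used: set[int],
    max_adjust: float,
) -> Optional[tuple[int, float]]:
    """Index and anchor time (start or end per ``key``) of the closest event."""
    best = None
    for i, ev in enumerate(events):
        if i in used:
            continue
        anchor = ev[key]
        d = abs(anchor - scheduled)
        if d <= max_adjust and (best is None or d < best[1]):
            best = (i, d, anchor)
    if best is None:
        return None
    return best[0], best[2]


def label_run(
    mav: MavStream,
    acc: AccSummary,
    schedule: ProtocolSchedule,
    max_adjust_s: float = MAX_ADJUST_S,
    grip_hold_s: float = GRIP_HOLD_S,
    event_gap_s: float = EVENT_GAP_S,
) -> LabeledStream:
    """Label every MAV instance of one run using schedule + ACC evidence."""
    events = detect_acc_events(acc, event_gap_s)
    used: set[int] = set()
    intervals: list[tuple[str, float, float]] = []  # non-NR only

    nominal = schedule.nominal_intervals(hybrid_as_activity=True)
    grip_code = schedule.grip_code
    by_rep: dict[int, list[tuple[str, float, float]]] = {}
    for code, t0, t1 in nominal:
        if code != NR:
            by_rep.setdefault(schedule.rep_index_at(t0), []).append((code, t0, t1))

    for rep in sorted(by_rep):
        acts = by_rep[rep]
        onsets: list[float] = []
        for code, t0, t1 in acts:
            key = 1 if code == grip_code else 0  # grips anchor on event end
            hit = _nearest_event(events, t0, key, used, max_adjust_s)
            if hit is None:
                logger.warning(
                    "%s rep %d: no ACC event within %.0f ms of scheduled %s at %.1f s; "
                    "falling back to the scheduled time",
                    schedule.group_id, rep, 1e3 * max_adjust_s, code, t0,
                )
                onsets.append(t0)
            else:
                used.add(hit[0])
                onsets.append(float(np.clip(hit[1], t0 - max_adjust_s, t0 + max_adjust_s)))
        # ends: next onset when the script runs activities back-to-back,
        # else the scheduled end; grips are capped at grip_hold_s
        for i, (code, t0, t1) in enumerate(acts):
            start = onsets[i]
            contiguous = i + 1 < len(acts) and abs(acts[i + 1][1] - t1) < 1e-9
            end = onsets[i + 1] if contiguous else t1
            if code == grip_code:
                end = min(end, start + grip_hold_s)
            if end > start:
                intervals.append((code, start, end))

    # monotone, non-overlapping boundary track
    intervals.sort(key=lambda iv: iv[1])
    labels = np.full(len(mav), NR, dtype=object)
    for code, t0, t1 in intervals:
        sel = (mav.times >= t0) & (mav.times < t1)
        labels[sel] = code
    return LabeledStream(
        times=mav.times, values=mav.values, labels=labels.astype(str),
        step=mav.step, group_id=schedule.group_id, schedule=schedule,
    )


def subsample_nr(
    stream: "LabeledStream | Iterable[LabeledStream]",
    window: tuple[float, float] = NR_WINDOW,
) -> "LabeledStream | list[LabeledStream]":
    """Retain NR instances only from the run-start rest window.

    Non-NR instances are never touched.  With the default 3 s window and the
    20/s instance rate this keeps 60 NR instances per run (480 over 8 runs).
    """
    if not isinstance(stream, LabeledStream):
        return [subsample_nr(s, window) for s in stream]
    keep = (stream.labels != NR) | (
        (stream.times >= window[0]) & (stream.times < window[1])
    )
    return replace(
        stream, times=stream.times[keep], values=stream.values[keep], labels=stream.labels[keep]
    )


def segment_activities(
    stream: LabeledStream,
    max_len: int = MAX_SEGMENT_LEN,
    include_nr: bool = True,
) -> list[ActivitySegment]:
    """Cut a labelled stream into maximal same-label consecutive runs.

    Runs break on a label change or a timestamp gap (> 1.5 steps).  Each
    segment keeps only its first ``max_len`` instances; the repetition index
    is taken from the schedule at the segment start.
    """
    if len(stream) == 0:
        return []
    labels = stream.labels
    gaps = np.diff(stream.times) > 1.5 * stream.step
    new_run = np.empty(len(stream), dtype=bool)
    new_run[0] = True
    new_run[1:] = (labels[1:] != labels[:-1]) | gaps
    starts = np.flatnonzero(new_run)
    bounds = np.append(starts, len(stream))
    out = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        label = str(labels[s])
        if label == NR and not include_nr:
            continue
        e_trunc = min(e, s + max_len)
        # midpoint, so a grip whose adjusted onset precedes the scheduled
        # second still counts to its repetition
        mid = stream.times[(s + e - 1) // 2]
        rep = stream.schedule.rep_index_at(mid) if stream.schedule else 0
        out.append(
            ActivitySegment(
                label=label,
                times=stream.times[s:e_trunc],
                values=stream.values[s:e_trunc],
                rep_index=rep,
                run_id=stream.group_id,
            )
        )
    return out
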