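"""Vocal-event construction and behavioral context.

Raw call timestamps (from synchronized audio/video review) are merged
into vocal events: calls separated by less than 5 s belong to the same
event.  Each event carries a behavioral context — every logged behavior
within 10 s before the first call and 10 s after the last call — and
behaviors are mapped to four ethogram categories (aggression, social,
sleep, other).  Events are binned by clock hour across the night window
(17:00–06:00), wrapping midnight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RawCall",
    "VocalEvent",
    "BehaviorRecord",
    "EventContext",
    "HourlyCounts",
    "BEHAVIOR_CATEGORIES",
    "CATEGORIES",
    "merge_calls",
    "classify_behavior",
    "attach_context",
    "night_hours",
    "hourly_counts",
    "context_category_table",
]

CATEGORIES = ("aggression", "social", "sleep", "other")

#: Ethogram dictionary: behavior name -> category.
BEHAVIOR_CATEGORIES: dict[str, str] = {
    # aggression-related
    "Agonistic support": "aggression",
    "Ground slap": "aggression",
    "Long lunge": "aggression",
    "Short lunge": "aggression",
    "Redirection": "aggression",
    "Stare": "aggression",
    # social-related
    "Bridging": "social",
    "Embrace": "social",
    "Holding an infant": "social",
    "Homosexual mount": "social",
    "Proximity < 1 m": "social",
    "Penis showing": "social",
    "Penis sucking": "social",
    # sleep-related
    "Huddling sleep": "sleep",
    "Sleep": "sleep",
    "Sleeping with eyes closed": "sleep",
    "Wake up with eyes open": "sleep",
    "Raise the head": "sleep",
    # other
    "Appear": "other",
    "Self-scratch": "other",
    "Sit": "other",
}


@dataclass(frozen=True)
class RawCall:
    time: datetime
    caller_id: str | None = None


@dataclass(frozen=True)
class VocalEvent:
    """A run of calls whose inter-call gaps are all under the merge gap."""

    start: datetime
    end: datetime
    n_calls: int
    caller_id: str | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("event end precedes start")
        if self.n_calls < 1:
            raise ValueError("event must contain at least one call")


@dataclass(frozen=True)
class BehaviorRecord:
    time: datetime
    individual_id: str
    behavior: str

    @property
    def category(self) -> str:
        return classify_behavior(self.behavior)


@dataclass
class EventContext:
    """Behaviors around one vocal event.

    ``pre`` covers [start - w, start], ``post`` covers [end, end + w]
    (closed at both boundaries); behaviors falling strictly inside the
    event go to ``during`` and are kept out of the context tables.
    """

    event: VocalEvent
    pre: list[BehaviorRecord] = field(default_factory=list)
    post: list[BehaviorRecord] = field(default_factory=list)
    during: list[BehaviorRecord] = field(default_factory=list)


@dataclass(frozen=True)
class HourlyCounts:
    hour: int
    n_events: int


def classify_behavior(name: str) -> str:
    """Map a behavior name to its ethogram category.

    Unknown names raise rather than defaulting to "other", so typos in
    field logs surface instead of silently inflating a category.
    """
    try:
        return BEHAVIOR_CATEGORIES[name]
    except KeyError:
        raise ValueError(f"unmapped behavior: {name!r}") from None


def merge_calls(
    calls: list[RawCall], gap_s: float = 5.0, per_caller: bool = False
) -> list[VocalEvent]:
    """Merge raw calls into vocal events.

    Calls are sorted by time; a call within strictly less than ``gap_s``
    seconds of the previous call extends the current event (a gap of
    exactly ``gap_s`` starts a new event).  By default all calls are
    merged in one stream regardless of caller (caller identity is often
    unknown at night); ``per_caller=True`` merges each caller's stream
    separately, with unattributed calls forming their own stream.
    """
    if per_caller:
        streams: dict[str | None, list[RawCall]] = {}
        for c in calls:
            streams.setdefault(c.caller_id, []).append(c)
        events: list[VocalEvent] = []
        for sub in streams.values():
            events.extend(merge_calls(sub, gap_s=gap_s, per_caller=False))
        events.sort(key=lambda e: e.start)
        return events

    if not calls:
        return []
    ordered = sorted(calls, key=lambda c: c.time)
    events = []
    run = [ordered[0]]
    for c in ordered[1:]:
        if (c.time - run[-1].time).total_seconds() < gap_s:
            run.append(c)
        else:
            events.append(_finish_run(run))
            run = [c]
    events.append(_finish_run(run))
    return events


def _finish_run(run: list[RawCall]) -> VocalEvent:
    callers = {c.caller_id for c in run}
    caller = callers.pop() if len(callers) == 1 else None
    return VocalEvent(start=run[0].time, end=run[-1].time, n_calls=len(run), caller_id=caller)


def attach_context(
    events: list[VocalEvent],
    log: list[BehaviorRecord],
    window_s: float = 10.0,
) -> list[EventContext]:
    """Attach the behaviors within ``window_s`` of each event.

    Boundary times are included (closed intervals); a behavior may appear
    in the contexts of several events.
    """
    w = timedelta(seconds=window_s)
    ordered = sorted(log, key=lambda r: r.time)
    out = []
    for ev in events:
        ctx = EventContext(event=ev)
        for rec in ordered:
            if ev.start - w <= rec.time <= ev.start:
                ctx.pre.append(rec)
            elif ev.end <= rec.time <= ev.end + w:
                ctx.post.append(rec)
            elif ev.start < rec.time < ev.end:
                ctx.during.append(rec)
        out.append(ctx)
    return out


def night_hours(night_start: int = 17, night_end: int = 6) -> list[int]:
    """Clock hours of the night window, in night order, end-exclusive.

    ``night_hours(17, 6)`` -> [17, 18, ..., 23, 0, 1, ..., 5].
    """
    if night_start == night_end:
        raise ValueError("night window must be non-empty")
    hours = []
    h = night_start
    while h != night_end:
        hours.append(h)
        h = (h + 1) % 24
    return hours


def hourly_counts(
    events: list[VocalEvent], night_start: int = 17, night_end: int = 6
) -> list[HourlyCounts]:
    """Bin events by the clock hour of their start, over the night window.

    Every hour of the window appears (zero-filled); events outside the
    window are dropped, with the dropped count logged.
    """
    hours = night_hours(night_start, night_end)
    counts = {h: 0 for h in hours}
    dropped = 0
    for ev in events:
        h = ev.start.hour
        if h in counts:
            counts[h] += 1
        else:
            dropped += 1
    if dropped:
        logger.warning("hourly_counts: %d events outside the night window dropped", dropped)
    return [HourlyCounts(hour=h, n_events=counts[h]) for h in hours]


def context_category_table(
    contexts: list[EventContext],
    night_start: int = 17,
    night_end: int = 6,
) -> pd.DataFrame:
    """Hour x category counts of context behaviors (pre + post).

    Rows are the night-window hours in night order, columns the four
    ethogram categories.  A behavior shared by two events is counted once
    per context.  Empty input yields an empty-but-shaped table.
    """
    hours = night_hours(night_start, night_end)
    table = pd.DataFrame(0, index=pd.Index(hours, name="hour"), columns=list(CATEGORIES))
    for ctx in contexts:
        h = ctx.event.start.hour
        if h not in table.index:
            continue
        for rec in ctx.pre + ctx.post:
            table.loc[h, rec.category] += 1
    return table
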