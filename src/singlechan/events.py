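"""Idealized event sequences: alternating open/closed dwells.

Unit convention (deliberate, and a classic trap): event onsets are in
seconds, durations in ms.  Dwell-time tables are conventionally printed
in ms while records are indexed in seconds; every consumer in this
package follows the same rule.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np

__all__ = ["Event", "EventList", "apply_dead_time"]


@dataclass(frozen=True)
class Event:
    onset: float          # seconds
    duration: float       # ms
    kind: str             # "open" | "closed"
    amplitude: float      # pA; 0 for closed
    class_label: str = ""  # "O_S" | "O_L" | "single" for open events
    censored: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("open", "closed"):
            raise ValueError(f"kind must be open/closed, got {self.kind!r}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.kind == "closed" and self.amplitude != 0:
            raise ValueError("closed events must have amplitude 0")
        if self.kind == "open" and self.amplitude <= 0:
            raise ValueError("open events must have amplitude > 0")

    @property
    def end(self) -> float:
        """Event end time in seconds."""
        return self.onset + self.duration * 1e-3

    def replace(self, **kw) -> "Event":
        return _dc_replace(self, **kw)


class EventList:
    """Contiguous, strictly alternating open/closed events."""

    def __init__(self, events: list[Event], check: bool = True):
        self.events = list(events)
        if check:
            self._check()

    def _check(self) -> None:
        for i in range(1, len(self.events)):
            prev, cur = self.events[i - 1], self.events[i]
            if cur.kind == prev.kind:
                raise ValueError(
                    f"events {i - 1} and {i} are both {cur.kind}: "
                    "event list must alternate"
                )
            if abs(cur.onset - prev.end) > 1e-9:
                raise ValueError(
                    f"event {i} not contiguous: onset {cur.onset} vs "
                    f"previous end {prev.end}"
                )

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    @property
    def total_duration_ms(self) -> float:
        return float(sum(e.duration for e in self.events))

    def dwells(
        self, kind: str, include_censored: bool = False, class_label: str | None = None
    ) -> np.ndarray:
        """Dwell durations (ms) of one kind, censored events excluded by default."""
        out = [
            e.duration
            for e in self.events
            if e.kind == kind
            and (include_censored or not e.censored)
            and (class_label is None or e.class_label == class_label)
        ]
        return np.asarray(out, dtype=float)

    def open_events(self, include_censored: bool = True) -> list[Event]:
        return [
            e
            for e in self.events
            if e.kind == "open" and (include_censored or not e.censored)
        ]

    def amplitudes(self) -> np.ndarray:
        return np.asarray(
            [e.amplitude for e in self.events if e.kind == "open"], dtype=float
        )

    def reversed(self) -> "EventList":
        """Time-reversed copy (duration multiset preserved)."""
        if not self.events:
            return EventList([])
        end = self.events[-1].end
        out = []
        for e in reversed(self.events):
            out.append(e.replace(onset=end - e.end + self.events[0].onset))
        return EventList(out)


def apply_dead_time(events: EventList, dead_time: float) -> EventList:
    """Impose a finite time resolution on an event list.

    Events shorter than ``dead_time`` (ms) are unresolvable: each is
    merged into the flanking events of opposite kind, which absorb its
    duration.  Alternation and total duration are preserved exactly.
    Interior events are processed shortest-first so that cascades of
    sub-resolution events resolve deterministically; edge events are
    merged into their single neighbour.
    """
    if dead_time < 0:
        raise ValueError("dead_time must be >= 0")
    if dead_time == 0 or len(events) <= 1:
        return EventList(list(events.events), check=False)

    evs = list(events.events)
    while True:
        short = [
            i for i, e in enumerate(evs) if e.duration < dead_time and len(evs) > 1
        ]
        if not short:
            break
        i = min(short, key=lambda j: evs[j].duration)
        e = evs[i]
        if 0 < i < len(evs) - 1:
            left, right = evs[i - 1], evs[i + 1]
            tot = left.duration + e.duration + right.duration
            amp = 0.0
            if left.kind == "open":
                amp = (
                    left.amplitude * left.duration + right.amplitude * right.duration
                ) / (left.duration + right.duration)
            merged = Event(
                onset=left.onset,
                duration=tot,
                kind=left.kind,
                amplitude=amp,
                class_label=left.class_label,
                censored=left.censored or right.censored,
            )
            evs[i - 1 : i + 2] = [merged]
        else:
            j = 1 if i == 0 else len(evs) - 2
            nb = evs[j]
            merged = Event(
                onset=min(e.onset, nb.onset),
                duration=e.duration + nb.duration,
                kind=nb.kind,
                amplitude=nb.amplitude,
                class_label=nb.class_label,
                censored=True,  # edge-adjacent; true extent unknown
            )
            if i == 0:
                evs[0:2] = [merged]
            else:
                evs[-2:] = [merged]
    return EventList(evs)
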