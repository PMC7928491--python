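"""Patch-level quality control: stability profiling, truncation, outliers.

Recordings are profiled in non-overlapping windows to detect run-down
(systematic drift of amplitude or kinetics over time); analysis is then
limited to the stable initial window (60 s for HS-group records, 120 s
for LS-group records, set per group in the run configuration).  Patches
whose event rate deviates from their group by more than two standard
deviations are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .events import Event, EventList

__all__ = [
    "PatchSummary",
    "stability_profile",
    "truncate_events",
    "event_rate_outlier_filter",
]


@dataclass
class PatchSummary:
    """Per-patch summary used for grouping, QC and fold-change tables."""

    patch_id: str
    group: str                     # e.g. "HS", "LS_lowACh" — free-form label
    analyzed_duration: float       # s
    n_open_events: int
    properties: dict = field(default_factory=dict)  # property name -> value
    excluded: bool = False
    exclusion_reason: str = ""

    @property
    def events_per_second(self) -> float:
        return self.n_open_events / self.analyzed_duration


def stability_profile(events: EventList, window_s: float = 10.0) -> pd.DataFrame:
    """Windowed statistics with linear-trend tests.

    Events are assigned to non-overlapping windows by onset time.  Each
    row holds the window midpoint, mean open amplitude, mean open and
    closed durations, and event rate; the frame's ``attrs["trends"]``
    maps each statistic to its OLS slope against the window midpoint
    and the slope's p-value.
    """
    if len(events) == 0:
        raise ValueError("no events")
    record_end = events[-1].end
    n_windows = int(np.floor(record_end / window_s))
    if n_windows < 2:
        raise ValueError(
            f"record of {record_end:.1f} s yields {n_windows} windows of "
            f"{window_s} s; need >= 2"
        )
    rows = []
    for w in range(n_windows):
        lo, hi = w * window_s, (w + 1) * window_s
        in_win = [e for e in events if lo <= e.onset < hi]
        opens = [e for e in in_win if e.kind == "open"]
        closeds = [e for e in in_win if e.kind == "closed"]
        rows.append(
            {
                "t_mid": (lo + hi) / 2,
                "mean_open_amplitude": (
                    np.mean([e.amplitude for e in opens]) if opens else np.nan
                ),
                "mean_open_duration": (
                    np.mean([e.duration for e in opens]) if opens else np.nan
                ),
                "mean_closed_duration": (
                    np.mean([e.duration for e in closeds]) if closeds else np.nan
                ),
                "event_rate": len(opens) / window_s,
            }
        )
    df = pd.DataFrame(rows)
    trends = {}
    for col in df.columns.drop("t_mid"):
        ok = df[col].notna()
        if ok.sum() >= 3:
            res = sps.linregress(df.loc[ok, "t_mid"], df.loc[ok, col])
            trends[col] = {"slope": res.slope, "p_value": res.pvalue}
        else:
            trends[col] = {"slope": np.nan, "p_value": np.nan}
    df.attrs["trends"] = trends
    return df


def truncate_events(events: EventList, cutoff_s: float) -> EventList:
    """Keep only activity before ``cutoff_s``.

    Events with onset before the cutoff are retained; one straddling
    the cutoff is cut at the cutoff and flagged censored; later events
    are dropped.
    """
    if cutoff_s <= 0:
        raise ValueError("cutoff_s must be > 0")
    out: list[Event] = []
    for e in events:
        if e.onset >= cutoff_s:
            break
        if e.end > cutoff_s + 1e-12:
            new_dur = (cutoff_s - e.onset) * 1e3
            out.append(e.replace(duration=new_dur, censored=True))
            break
        out.append(e)
    return EventList(out)


def event_rate_outlier_filter(
    summaries: list[PatchSummary], n_sd: float = 2.0
) -> list[PatchSummary]:
    """Flag patches whose event rate lies outside mean +/- 2 SD of the group.

    Single pass, candidate included in the group mean/SD (no
    iteration).  Groups with fewer than three patches are left
    unfiltered with a warning recorded on each summary.
    """
    by_group: dict[str, list[PatchSummary]] = {}
    for s in summaries:
        by_group.setdefault(s.group, []).append(s)
    out: list[PatchSummary] = []
    for group, members in by_group.items():
        rates = np.array([m.events_per_second for m in members])
        if len(members) < 3:
            for m in members:
                out.append(
                    _with_flags(
                        m,
                        excluded=False,
                        reason="group too small for outlier test (n < 3)",
                    )
                )
            continue
        mean, sd = rates.mean(), rates.std(ddof=1)
        lo, hi = mean - n_sd * sd, mean + n_sd * sd
        for m, r in zip(members, rates):
            if r < lo or r > hi:
                out.append(
                    _with_flags(
                        m,
                        excluded=True,
                        reason=(
                            f"event rate {r:.3g}/s outside "
                            f"{mean:.3g} +/- {n_sd:g} x {sd:.3g}/s"
                        ),
                    )
                )
            else:
                out.append(_with_flags(m, excluded=False, reason=""))
    # preserve input order
    order = {id(s): i for i, s in enumerate(summaries)}
    out.sort(key=lambda s: order[id(s._source)])
    return [s for s in out]


def _with_flags(m: PatchSummary, excluded: bool, reason: str) -> PatchSummary:
    new = PatchSummary(
        patch_id=m.patch_id,
        group=m.group,
        analyzed_duration=m.analyzed_duration,
        n_open_events=m.n_open_events,
        properties=dict(m.properties),
        excluded=excluded,
        exclusion_reason=reason,
    )
    new._source = m  # type: ignore[attr-defined]
    return new
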