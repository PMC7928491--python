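"""Reading and writing traces, event tables, and run configurations.

Trace formats: raw little-endian float32 with a JSON sidecar (fully
supported both directions), CSV with a (time_s, current_pA) header, and
Axon Binary Format (read-only, requires the optional ``pyabf``
dependency).  Event tables are CSV with columns onset_s, duration_ms,
kind, amplitude_pA, class_label, censored — onsets in seconds,
durations in ms (the package-wide unit rule).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .events import Event, EventList
from .simulate import Trace

__all__ = [
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "GroupConfig",
    "RunConfig",
    "load_config",
]

EVENT_COLUMNS = [
    "onset_s", "duration_ms", "kind", "amplitude_pA", "class_label", "censored",
]


def read_trace(path, format: str | None = None) -> Trace:
    """Read a current trace.

    ``format``: ``"raw"`` (f32 + JSON sidecar), ``"csv"``, or ``"abf"``;
    inferred from the suffix when omitted.
    """
    path = Path(path)
    if format is None:
        format = {".raw": "raw", ".f32": "raw", ".csv": "csv", ".abf": "abf"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise ValueError(f"cannot infer trace format from {path.name!r}")
    if format == "raw":
        return _read_raw(path)
    if format == "csv":
        return _read_csv(path)
    if format == "abf":
        return _read_abf(path)
    raise ValueError(f"unknown trace format {format!r}")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _read_raw(path: Path) -> Trace:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"raw trace sidecar missing: {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as err:
        raise ValueError(f"corrupt sidecar {sidecar}: {err}") from err
    for key in ("sampling_rate",):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} missing field {key!r}")
    units = meta.get("units", "pA")
    if units != "pA":
        raise ValueError(f"unsupported units {units!r} in {sidecar}; expected pA")
    samples = np.fromfile(path, dtype="<f4").astype(float)
    samples *= float(meta.get("scale", 1.0))
    return Trace(
        samples=samples,
        sampling_rate=float(meta["sampling_rate"]),
        online_filter_hz=meta.get("online_filter_hz"),
        offline_filter_hz=meta.get("offline_filter_hz"),
        metadata=meta.get("metadata", {}),
    )


def write_trace(trace: Trace, path) -> None:
    """Write raw f32 + JSON sidecar (lossless for float32 data)."""
    path = Path(path)
    trace.samples.astype("<f4").tofile(path)
    meta = {
        "sampling_rate": trace.sampling_rate,
        "online_filter_hz": trace.online_filter_hz,
        "offline_filter_hz": trace.offline_filter_hz,
        "scale": 1.0,
        "units": "pA",
        "metadata": {
            k: v for k, v in trace.metadata.items()
            if isinstance(v, (str, int, float, bool, type(None)))
        },
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def _read_csv(path: Path) -> Trace:
    df = pd.read_csv(path)
    for col in ("time_s", "current_pA"):
        if col not in df.columns:
            raise ValueError(f"CSV trace {path} missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(dt) == 0:
        raise ValueError(f"CSV trace {path} has fewer than 2 samples")
    if np.max(np.abs(dt - dt[0])) > 1e-9 * max(dt[0], 1e-12):
        raise ValueError(f"CSV trace {path} has non-uniform timestamps")
    return Trace(
        samples=df["current_pA"].to_numpy(dtype=float),
        sampling_rate=1.0 / dt[0],
    )


def _read_abf(path: Path) -> Trace:
    try:
        import pyabf  # optional dependency
    except ImportError as err:
        raise ImportError(
            "reading Axon Binary Format requires the optional dependency "
            "pyabf (pip install singlechan[abf])"
        ) from err
    abf = pyabf.ABF(str(path))
    abf.setSweep(0)
    return Trace(
        samples=np.asarray(abf.sweepY, dtype=float),
        sampling_rate=float(abf.dataRate),
        metadata={"source": str(path), "units": abf.sweepUnitsY},
    )


def write_events(events: EventList, path) -> None:
    rows = [
        {
            "onset_s": e.onset,
            "duration_ms": e.duration,
            "kind": e.kind,
            "amplitude_pA": e.amplitude,
            "class_label": e.class_label,
            "censored": e.censored,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(
        path, index=False, float_format="%.9f"
    )


def read_events(path) -> EventList:
    df = pd.read_csv(path)
    for col in ("onset_s", "duration_ms", "kind", "amplitude_pA"):
        if col not in df.columns:
            raise ValueError(f"event file {path} missing column {col!r}")
    if "class_label" not in df.columns:
        df["class_label"] = "single"  # legacy files without class labels
    if "censored" not in df.columns:
        df["censored"] = False
    events = []
    for i, row in df.iterrows():
        if row["duration_ms"] <= 0:
            raise ValueError(f"row {i}: non-positive duration")
        label = row["class_label"]
        if pd.isna(label) or label == "":
            label = "single" if row["kind"] == "open" else ""
        try:
            events.append(
                Event(
                    onset=float(row["onset_s"]),
                    duration=float(row["duration_ms"]),
                    kind=str(row["kind"]),
                    amplitude=float(row["amplitude_pA"]),
                    class_label=str(label) if row["kind"] == "open" else "",
                    censored=bool(row["censored"]),
                )
            )
        except ValueError as err:
            raise ValueError(f"row {i}: {err}") from err
    try:
        return EventList(events)
    except ValueError as err:
        raise ValueError(f"event file {path}: {err}") from err


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class GroupConfig:
    """One experimental group (isoform x mutant x agonist condition)."""

    label: str
    isoform: str = ""              # "HS" | "LS"
    mutant: str = ""
    ach_label: str = ""            # e.g. "1.3 uM"
    analyzed_window_s: float = 60.0
    n_open_classes: int = 1
    n_patches: int = 5
    duration_s: float = 60.0
    model_file: str | None = None


@dataclass
class RunConfig:
    groups: list[GroupConfig]
    sampling_rate: float = 50_000.0
    online_filter_hz: float = 5_000.0
    offline_filter_hz: float | None = 1_000.0
    noise_sd: float = 0.15
    dead_time_ms: float = 0.3
    k_max: int = 5
    tcrit_boundary: int = 1
    tcrit_criterion: str = "equal_counts"
    seed: int = 0
    reference_means: dict = field(default_factory=dict)
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("config must define at least one group")
        for g in self.groups:
            if g.analyzed_window_s <= 0:
                raise ValueError(
                    f"group {g.label!r} must name a positive analyzed window"
                )
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an explicit integer (no wall-clock seeding)")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        doc = json.load(fh)
    groups = [GroupConfig(**g) for g in doc.pop("groups", [])]
    return RunConfig(groups=groups, **doc)
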