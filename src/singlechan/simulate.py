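"""Synthetic single-channel records from gating models.

Emulates cell-attached acquisition as used for alpha4beta2 nicotinic
receptor recordings: 50 kHz digitisation, 5 kHz on-line low-pass
(approximated by a Gaussian FIR with matched -3 dB corner), optional
1 kHz off-line re-filtering, Gaussian baseline noise, optional run-down
and multi-channel contamination.  Openings are rendered as positive
deflections from a 0 pA baseline; all amplitudes are magnitudes, the
convention used for reported unitary currents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .events import Event, EventList
from .gating import GatingModel

__all__ = [
    "Trajectory",
    "Trace",
    "AcquisitionConfig",
    "sample_trajectory",
    "render_trace",
    "simulate_patch",
    "gaussian_filter_sigma_samples",
    "filter_noise_gain",
]


@dataclass
class Trajectory:
    """Piecewise-constant state path of a continuous-time Markov chain.

    ``jump_times`` (s) are the sojourn start times, strictly increasing
    and starting at 0; ``states`` holds the state index occupied from
    each jump time until the next (or until ``total_duration``).
    """

    jump_times: np.ndarray
    states: np.ndarray
    total_duration: float

    def __post_init__(self) -> None:
        self.jump_times = np.asarray(self.jump_times, dtype=float)
        self.states = np.asarray(self.states, dtype=int)
        if len(self.jump_times) != len(self.states):
            raise ValueError("jump_times and states must have equal length")
        if len(self.jump_times) and self.jump_times[0] != 0.0:
            raise ValueError("trajectory must start at t = 0")
        if np.any(np.diff(self.jump_times) <= 0):
            raise ValueError("jump_times must be strictly increasing")
        if len(self.jump_times) and self.jump_times[-1] > self.total_duration:
            raise ValueError("last jump beyond total_duration")

    @property
    def sojourn_durations(self) -> np.ndarray:
        """Sojourn lengths in seconds (last one runs to total_duration)."""
        ends = np.append(self.jump_times[1:], self.total_duration)
        return ends - self.jump_times


@dataclass
class Trace:
    """Sampled current record with acquisition metadata."""

    samples: np.ndarray
    sampling_rate: float
    online_filter_hz: float | None = None
    offline_filter_hz: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        nyq = self.sampling_rate / 2
        for corner in (self.online_filter_hz, self.offline_filter_hz):
            if corner is not None and corner >= nyq:
                raise ValueError(
                    f"filter corner {corner} Hz >= Nyquist {nyq} Hz"
                )

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


@dataclass
class AcquisitionConfig:
    """Recording/analysis parameters.

    Defaults mirror the study conditions: 50 kHz sampling, 5 kHz
    on-line corner, 1 kHz off-line corner, ~0.15 pA baseline noise.
    """

    sampling_rate: float = 50_000.0
    online_filter_hz: float = 5_000.0
    offline_filter_hz: float | None = 1_000.0
    noise_sd: float = 0.15
    n_channels: int = 1
    rundown: dict | None = None  # {"start_s": float, "amplitude_slope_per_s": float}


def sample_trajectory(
    model: GatingModel, duration: float, seed: int | np.random.Generator
) -> Trajectory:
    """Gillespie sample of the gating chain for ``duration`` seconds."""
    from .gating import validate_model

    problems = validate_model(model)
    if problems:
        raise ValueError("invalid gating model: " + "; ".join(problems))
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)

    Q = model.Q
    n = model.n_states
    exit_rates = -np.diag(Q)
    # Jump probabilities per state (rows normalised off-diagonal rates).
    probs = np.zeros((n, n))
    for i in range(n):
        if exit_rates[i] > 0:
            probs[i] = Q[i] / exit_rates[i]
            probs[i, i] = 0.0

    p0 = model.initial()
    state = int(rng.choice(n, p=p0 / p0.sum()))
    t = 0.0
    times = [0.0]
    states = [state]
    while True:
        if exit_rates[state] == 0.0:
            if model.n_states > 1:
                raise ValueError(
                    f"absorbing state {model.state_names[state]!r} reached"
                )
            break
        t += rng.exponential(1.0 / exit_rates[state])
        if t >= duration:
            break
        state = int(rng.choice(n, p=probs[state]))
        times.append(t)
        states.append(state)
    return Trajectory(np.array(times), np.array(states), float(duration))


def gaussian_filter_sigma_samples(corner_hz: float, sampling_rate: float) -> float:
    """Gaussian kernel sigma (in samples) with -3 dB point at ``corner_hz``.

    For a Gaussian impulse response the transfer magnitude is
    exp(-2 pi^2 sigma_t^2 f^2); solving for -3 dB gives
    sigma_t = sqrt(ln 2) / (2 pi fc) ~= 0.1325 / fc.
    """
    sigma_t = np.sqrt(np.log(2.0)) / (2.0 * np.pi * corner_hz)
    return sigma_t * sampling_rate


def filter_noise_gain(corner_hz: float, sampling_rate: float) -> float:
    """Std-dev attenuation of white noise through the Gaussian filter.

    The filtered variance of unit white noise equals the sum of squared
    kernel coefficients, 1 / (2 sqrt(pi) sigma) for a normalised
    Gaussian; the returned value is the std-dev factor.
    """
    sigma = gaussian_filter_sigma_samples(corner_hz, sampling_rate)
    return float(np.sqrt(1.0 / (2.0 * np.sqrt(np.pi) * sigma)))


def _level_series(
    traj: Trajectory, model: GatingModel, n_samples: int, sampling_rate: float
) -> np.ndarray:
    """Noiseless conductance level per sample (sample-and-hold at onset)."""
    amps = np.array([model.amplitude_of(i) for i in range(model.n_states)])
    t = np.arange(n_samples) / sampling_rate
    idx = np.searchsorted(traj.jump_times, t, side="right") - 1
    return amps[traj.states[idx]]


def render_trace(
    traj: Trajectory,
    model: GatingModel,
    sampling_rate: float = 50_000.0,
    noise_sd: float = 0.15,
    online_filter_hz: float | None = 5_000.0,
    seed: int | np.random.Generator = 0,
    rundown: dict | None = None,
    n_channels: int = 1,
    _extra_trajs: list[Trajectory] | None = None,
    metadata: dict | None = None,
) -> Trace:
    """Render a trajectory into a noisy, filtered current trace.

    Additional independent channels (``n_channels > 1``) are sampled
    from the same model and summed, producing the multi-channel
    contamination that burst analysis must discard; pass
    ``_extra_trajs`` to supply them explicitly.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n_samples = int(round(traj.total_duration * sampling_rate))
    level = _level_series(traj, model, n_samples, sampling_rate)

    extra = list(_extra_trajs or [])
    while len(extra) < n_channels - 1:
        extra.append(
            sample_trajectory(model, traj.total_duration, rng.integers(2**31))
        )
    for other in extra[: n_channels - 1]:
        level = level + _level_series(other, model, n_samples, sampling_rate)

    if rundown is not None:
        start = float(rundown["start_s"])
        slope = float(rundown["amplitude_slope_per_s"])
        t = np.arange(n_samples) / sampling_rate
        ramp = 1.0 + slope * np.clip(t - start, 0.0, None)
        level = level * np.clip(ramp, 0.0, None)

    samples = level
    if noise_sd > 0:
        samples = samples + rng.normal(0.0, noise_sd, size=n_samples)
    if online_filter_hz is not None:
        sigma = gaussian_filter_sigma_samples(online_filter_hz, sampling_rate)
        samples = gaussian_filter1d(samples, sigma, mode="nearest")
    md = dict(metadata or {})
    md.setdefault("n_channels", n_channels)
    return Trace(
        samples=samples,
        sampling_rate=sampling_rate,
        online_filter_hz=online_filter_hz,
        metadata=md,
    )


def refilter_trace(trace: Trace, offline_filter_hz: float) -> Trace:
    """Off-line low-pass (Gaussian FIR, matched -3 dB corner)."""
    sigma = gaussian_filter_sigma_samples(offline_filter_hz, trace.sampling_rate)
    out = gaussian_filter1d(trace.samples, sigma, mode="nearest")
    return Trace(
        samples=out,
        sampling_rate=trace.sampling_rate,
        online_filter_hz=trace.online_filter_hz,
        offline_filter_hz=offline_filter_hz,
        metadata=dict(trace.metadata),
    )


def trajectory_events(traj: Trajectory, model: GatingModel) -> EventList:
    """Exact open/closed event list implied by a trajectory.

    Adjacent sojourns of equal gross class are merged; class labels are
    ``single`` for a one-open-class model and ``O_S``/``O_L`` otherwise
    (by ascending class amplitude).  First and last events are censored
    by the record edges.
    """
    open_classes = sorted(
        (c for c in model.class_amplitude if c != "closed"),
        key=lambda c: model.class_amplitude[c],
    )
    if len(open_classes) == 1:
        label_of = {open_classes[0]: "single"}
    else:
        label_of = {open_classes[0]: "O_S", open_classes[-1]: "O_L"}
        for c in open_classes[1:-1]:
            label_of[c] = "O_M"

    durations = traj.sojourn_durations
    events: list[Event] = []
    for t0, dur, st in zip(traj.jump_times, durations, traj.states):
        is_open = model.is_open(st)
        amp = model.amplitude_of(st)
        label = label_of[model.class_of(st)] if is_open else ""
        if events and (events[-1].kind == ("open" if is_open else "closed")):
            prev = events[-1]
            # Merge same-class sojourns; amplitude: duration-weighted mean.
            tot = prev.duration + dur * 1e3
            amp = (prev.amplitude * prev.duration + amp * dur * 1e3) / tot
            events[-1] = Event(
                onset=prev.onset,
                duration=tot,
                kind=prev.kind,
                amplitude=amp,
                class_label=prev.class_label if prev.kind == "open" else "",
            )
        else:
            events.append(
                Event(
                    onset=float(t0),
                    duration=float(dur) * 1e3,
                    kind="open" if is_open else "closed",
                    amplitude=amp if is_open else 0.0,
                    class_label=label,
                )
            )
    ev = EventList(events)
    if len(ev):
        ev.events[0] = ev.events[0].replace(censored=True)
        ev.events[-1] = ev.events[-1].replace(censored=True)
    return ev


def simulate_patch(
    model: GatingModel,
    duration: float,
    acquisition: AcquisitionConfig | None = None,
    seed: int | np.random.Generator = 0,
    metadata: dict | None = None,
) -> tuple[Trace, EventList]:
    """Simulate one patch: (rendered trace, ground-truth event list)."""
    acq = acquisition or AcquisitionConfig()
    rng = np.random.default_rng(seed)
    traj = sample_trajectory(model, duration, rng.integers(2**31))
    extra = [
        sample_trajectory(model, duration, rng.integers(2**31))
        for _ in range(acq.n_channels - 1)
    ]
    trace = render_trace(
        traj,
        model,
        sampling_rate=acq.sampling_rate,
        noise_sd=acq.noise_sd,
        online_filter_hz=acq.online_filter_hz,
        seed=rng.integers(2**31),
        rundown=acq.rundown,
        n_channels=acq.n_channels,
        _extra_trajs=extra,
        metadata=metadata,
    )
    if acq.offline_filter_hz is not None:
        trace = refilter_trace(trace, acq.offline_filter_hz)
    truth = trajectory_events(traj, model)
    if acq.n_channels > 1:
        trace.metadata["extra_trajectories"] = extra
    return trace, truth
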