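"""Burst segmentation, critical time, amplitude classes, burst statistics.

A burst is a run of two or more openings separated by closures shorter
than the critical closed time T_crit; a closure >= T_crit separates
bursts (and isolated openings).  T_crit is placed between two adjacent
closed-dwell components so that equal *numbers* of closed events are
misclassified on either side; equal-probability and pdf-crossing
variants are available for sensitivity analysis.  Bursts whose openings
span more than one amplitude class are discarded (they indicate
simultaneously active channels); remaining bursts are split into
small/large (O_S/O_L) classes by k-means with BIC selection of the
class count, mirroring the X-means separation used in single-channel
practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from sklearn.cluster import KMeans

from .dwell import ExponentialMixtureResults
from .events import Event, EventList

__all__ = [
    "Burst",
    "BurstSet",
    "compute_tcrit",
    "segment_bursts",
    "discard_mixed_amplitude_bursts",
    "classify_burst_amplitudes",
    "burst_statistics",
]


@dataclass
class Burst:
    """One burst: its member events and derived quantities."""

    events: list[Event]                # alternating, starts and ends open
    class_label: str = "single"

    @property
    def openings(self) -> list[Event]:
        return [e for e in self.events if e.kind == "open"]

    @property
    def n_openings(self) -> int:
        return len(self.openings)

    @property
    def open_time(self) -> float:
        """Total open time within the burst, ms."""
        return float(sum(e.duration for e in self.openings))

    @property
    def duration(self) -> float:
        """Span from first opening onset to last opening end, ms."""
        return float(sum(e.duration for e in self.events))

    @property
    def p_open(self) -> float:
        return self.open_time / self.duration

    @property
    def mean_open_amplitude(self) -> float:
        """Duration-weighted mean amplitude of member openings, pA."""
        w = np.array([e.duration for e in self.openings])
        a = np.array([e.amplitude for e in self.openings])
        return float((w * a).sum() / w.sum())


@dataclass
class BurstSet:
    t_crit: float                      # ms
    bursts: list[Burst]
    isolated_openings: list[Event]
    discarded_mixed: list[Burst] = field(default_factory=list)

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    def per_class(self) -> dict[str, list[Burst]]:
        out: dict[str, list[Burst]] = {}
        for b in self.bursts:
            out.setdefault(b.class_label, []).append(b)
        return out


def compute_tcrit(
    closed_fit: ExponentialMixtureResults,
    boundary_index: int = 1,
    criterion: str = "equal_counts",
) -> float:
    """Critical closed time between components i and i+1 (1-based i).

    ``equal_counts`` (default) solves a_i exp(-t/tau_i) =
    a_{i+1} (1 - exp(-t/tau_{i+1})): equal numbers of closed events
    misclassified on each side.  ``equal_proportions`` drops the areas;
    ``pdf_crossing`` intersects the two component densities.
    Root-finding is bracketed bisection (Brent) to 1e-9 ms.
    """
    comps = closed_fit.components
    if len(comps) < 2:
        raise ValueError("need >= 2 closed components to place T_crit")
    if not 1 <= boundary_index <= len(comps) - 1:
        raise ValueError(
            f"boundary_index must be in 1..{len(comps) - 1}, got {boundary_index}"
        )
    c1, c2 = comps[boundary_index - 1], comps[boundary_index]
    t1, a1, t2, a2 = c1.tau, c1.area, c2.tau, c2.area

    if criterion == "equal_counts":
        def g(t):
            return a1 * np.exp(-t / t1) - a2 * (1.0 - np.exp(-t / t2))
    elif criterion == "equal_proportions":
        def g(t):
            return np.exp(-t / t1) - (1.0 - np.exp(-t / t2))
    elif criterion == "pdf_crossing":
        def g(t):
            return (a1 / t1) * np.exp(-t / t1) - (a2 / t2) * np.exp(-t / t2)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    lo, hi = 1e-9 * t1, t2 * (1 + 1e-9)
    # g decreases from ~a1 to negative on (0, tau2]; widen if needed.
    while g(hi) > 0 and hi < 1e6 * t2:
        hi *= 2
    if g(lo) <= 0 or g(hi) >= 0:
        raise ValueError(
            "no sign change for T_crit between components "
            f"{boundary_index} and {boundary_index + 1}"
        )
    return float(brentq(g, lo, hi, xtol=1e-9))


def segment_bursts(events: EventList, t_crit: float) -> BurstSet:
    """Partition openings into bursts and isolated openings.

    Maximal runs of openings whose internal closures are all shorter
    than ``t_crit`` (ms); runs of length one are isolated openings.
    Censored events never start or end a burst (their true duration is
    unknown), nor count as isolated openings.
    """
    if t_crit <= 0:
        raise ValueError("t_crit must be > 0")
    evs = events.events
    bursts: list[Burst] = []
    isolated: list[Event] = []
    run: list[Event] = []   # alternating, starts with an opening

    def flush(run: list[Event]) -> None:
        while run and run[-1].kind == "closed":
            run.pop()
        if not run:
            return
        opens = [e for e in run if e.kind == "open"]
        if len(opens) >= 2:
            bursts.append(Burst(events=list(run)))
        elif len(opens) == 1 and not opens[0].censored:
            isolated.append(opens[0])

    for e in evs:
        if e.kind == "open":
            if e.censored:
                flush(run)
                run = []
                continue
            run.append(e)
        else:
            if not run:
                continue
            if e.duration < t_crit and not e.censored:
                run.append(e)
            else:
                # closure ends the run; drop the trailing closed event
                flush(run)
                run = []
    flush(run)
    return BurstSet(t_crit=float(t_crit), bursts=bursts, isolated_openings=isolated)


def discard_mixed_amplitude_bursts(
    burst_set: BurstSet,
    class_amplitudes=None,
    amplitude_tolerance: float = 0.3,
) -> BurstSet:
    """Discard bursts whose openings span more than one amplitude class.

    Such bursts indicate multiple simultaneously active channels.  Each
    member opening is assigned to the nearest of ``class_amplitudes``
    (pA); a burst is discarded when the assignments disagree, or when
    any opening sits further than ``amplitude_tolerance`` pA from every
    class (e.g. a summed double opening).  If ``class_amplitudes`` is
    omitted it defaults to the distinct amplitudes of the openings'
    fitted classes.
    """
    if class_amplitudes is None:
        amps = sorted(
            {
                round(e.amplitude, 6)
                for b in burst_set.bursts
                for e in b.openings
            }
        )
        class_amplitudes = np.asarray(amps, dtype=float)
    centers = np.sort(np.asarray(class_amplitudes, dtype=float))
    kept: list[Burst] = []
    discarded = list(burst_set.discarded_mixed)
    for b in burst_set.bursts:
        a = np.array([e.amplitude for e in b.openings])
        nearest = np.argmin(np.abs(a[:, None] - centers[None, :]), axis=1)
        resid = np.abs(a - centers[nearest])
        if np.unique(nearest).size > 1 or (resid > amplitude_tolerance).any():
            discarded.append(b)
        else:
            kept.append(b)
    return BurstSet(
        t_crit=burst_set.t_crit,
        bursts=kept,
        isolated_openings=list(burst_set.isolated_openings),
        discarded_mixed=discarded,
    )


def _spherical_bic(x: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    """BIC of a 1-D k-means partition under a shared-variance Gaussian."""
    n, k = x.size, centers.size
    resid = x - centers[labels]
    sigma2 = max(float(np.mean(resid**2)), 1e-12)
    counts = np.bincount(labels, minlength=k)
    counts = counts[counts > 0]
    ll = (
        -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        + np.sum(counts * np.log(counts / n))
    )
    n_params = 2 * k  # k centers, k-1 weights, 1 variance
    return -2.0 * ll + n_params * np.log(n)


def classify_burst_amplitudes(
    burst_set: BurstSet, max_classes: int = 2, seed: int = 0
) -> BurstSet:
    """Label bursts O_S/O_L (or single) by mean open amplitude.

    k-means on the per-burst mean open amplitude for k = 1..max_classes;
    the class count is chosen by BIC under a spherical Gaussian model
    (the X-means criterion).  With k = 2 the lower-mean cluster is O_S
    and the higher O_L; with k = 1 all bursts are labelled ``single``.
    """
    if len(burst_set.bursts) < 2:
        raise ValueError("need >= 2 retained bursts to classify")
    x = np.array([b.mean_open_amplitude for b in burst_set.bursts])
    best = None
    for k in range(1, max_classes + 1):
        if k > x.size or np.unique(x).size < k:
            continue  # fewer bursts (or distinct values) than candidate k
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x[:, None])
        labels = km.labels_
        centers = km.cluster_centers_.ravel()
        bic = _spherical_bic(x, labels, centers)
        if best is None or bic < best[0]:
            best = (bic, k, labels, centers)
    _, k, labels, centers = best
    order = np.argsort(centers)
    rank = np.empty_like(order)
    rank[order] = np.arange(k)
    if k == 1:
        names = ["single"]
    elif k == 2:
        names = ["O_S", "O_L"]
    else:
        names = [f"class_{i}" for i in range(k)]
    bursts = []
    for b, lab in zip(burst_set.bursts, labels):
        bursts.append(
            Burst(events=b.events, class_label=names[rank[lab]])
        )
    return BurstSet(
        t_crit=burst_set.t_crit,
        bursts=bursts,
        isolated_openings=list(burst_set.isolated_openings),
        discarded_mixed=list(burst_set.discarded_mixed),
    )


def burst_statistics(
    burst_set: BurstSet, per_class: bool = False, isolated_by_class: dict | None = None
) -> dict:
    """Summary statistics of a segmented (optionally classified) burst set.

    Per class (or overall): proportion of bursts among all events
    (bursts + isolated openings), mean openings per burst, burst
    duration from a single-exponential MLE (= mean, reported in ms),
    and mean within-burst P_open.

    ``isolated_by_class`` optionally maps class label -> isolated-opening
    count so the per-class proportions use class-matched denominators;
    otherwise all isolated openings enter every class's denominator.
    """
    groups: dict[str, list[Burst]]
    if per_class:
        groups = burst_set.per_class()
    else:
        groups = {"all": list(burst_set.bursts)}
    out = {}
    n_iso_total = len(burst_set.isolated_openings)
    for label, bursts in sorted(groups.items()):
        n_b = len(bursts)
        if isolated_by_class is not None and label in isolated_by_class:
            n_iso = isolated_by_class[label]
        else:
            n_iso = n_iso_total
        entry = {
            "n_bursts": n_b,
            "n_isolated": n_iso,
            "proportion_bursts": (
                n_b / (n_b + n_iso) if n_b + n_iso > 0 else np.nan
            ),
        }
        if n_b > 0:
            durations = np.array([b.duration for b in bursts])
            entry.update(
                mean_openings_per_burst=float(
                    np.mean([b.n_openings for b in bursts])
                ),
                burst_duration_tau=float(durations.mean()),
                mean_p_open=float(np.mean([b.p_open for b in bursts])),
                mean_amplitude=float(
                    np.mean([b.mean_open_amplitude for b in bursts])
                ),
            )
        out[label] = entry
    return out
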