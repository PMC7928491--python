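"""T_crit placement, burst segmentation, class separation, statistics."""

import numpy as np
import pytest

from singlechan.bursts import (
    Burst,
    BurstSet,
    burst_statistics,
    classify_burst_amplitudes,
    compute_tcrit,
    discard_mixed_amplitude_bursts,
    segment_bursts,
)
from singlechan.dwell import ExponentialMixtureResults
from singlechan.events import Event, EventList
from singlechan.gating import DwellComponent


def mixture(taus, areas):
    comps = [DwellComponent(tau=t, area=a) for t, a in zip(taus, areas)]
    return ExponentialMixtureResults(
        components=comps, n_dwells=1000, log_likelihood=0.0, t_min=0.0,
        kind="closed",
    )


def event_list(spec):
    """Build a contiguous list from (duration_ms, kind[, amplitude]) tuples."""
    events, t = [], 0.0
    for item in spec:
        dur, kind = item[0], item[1]
        amp = item[2] if len(item) > 2 else (1.0 if kind == "open" else 0.0)
        events.append(Event(t, dur, kind, amp))
        t += dur * 1e-3
    return EventList(events)


class TestComputeTcrit:
    def test_symmetric_case_is_tau_ln2(self):
        fit = mixture([5.0, 5.0 + 1e-9], [0.5, 0.5])
        t = compute_tcrit(fit)
        assert t == pytest.approx(5.0 * np.log(2.0), rel=1e-6)

    def test_matches_bisection_oracle(self):
        t1, a1, t2, a2 = 0.5, 0.5, 50.0, 0.5
        fit = mixture([t1, t2], [a1, a2])
        t = compute_tcrit(fit)
        # independent bisection on a1 e^(-t/t1) = a2 (1 - e^(-t/t2))
        lo, hi = 1e-12, t2
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if a1 * np.exp(-mid / t1) > a2 * (1 - np.exp(-mid / t2)):
                lo = mid
            else:
                hi = mid
        assert t == pytest.approx(0.5 * (lo + hi), abs=1e-6)

    def test_root_between_separated_taus(self):
        fit = mixture([0.8, 250.0], [0.3, 0.7])
        t = compute_tcrit(fit)
        assert 0.8 < t < 250.0

    def test_scale_equivariance(self):
        fit1 = mixture([0.8, 250.0], [0.3, 0.7])
        fit2 = mixture([8.0, 2500.0], [0.3, 0.7])
        assert compute_tcrit(fit2) == pytest.approx(
            10.0 * compute_tcrit(fit1), rel=1e-9
        )

    def test_requires_two_components(self):
        with pytest.raises(ValueError, match=">= 2"):
            compute_tcrit(mixture([1.0], [1.0]))

    def test_alternative_criteria_available(self):
        fit = mixture([0.8, 250.0], [0.3, 0.7])
        te = compute_tcrit(fit, criterion="equal_counts")
        tp = compute_tcrit(fit, criterion="equal_proportions")
        tx = compute_tcrit(fit, criterion="pdf_crossing")
        assert len({round(v, 6) for v in (te, tp, tx)}) == 3

    def test_boundary_index_selects_component_pair(self):
        fit = mixture([0.6, 170.0, 2000.0], [0.14, 0.43, 0.43])
        t1 = compute_tcrit(fit, boundary_index=1)
        t2 = compute_tcrit(fit, boundary_index=2)
        assert t1 < t2


class TestSegmentBursts:
    def test_hand_segmentable_example(self):
        # O(1) C(0.2) O(1) C(500) O(1), t_crit = 3 ms
        ev = event_list([
            (1.0, "open"), (0.2, "closed"), (1.0, "open"),
            (500.0, "closed"), (1.0, "open"),
        ])
        bs = segment_bursts(ev, t_crit=3.0)
        assert bs.n_bursts == 1
        assert bs.bursts[0].n_openings == 2
        assert bs.bursts[0].duration == pytest.approx(2.2)
        assert len(bs.isolated_openings) == 1
        stats = burst_statistics(bs)
        assert stats["all"]["proportion_bursts"] == pytest.approx(0.5)

    def test_burst_arithmetic(self):
        ev = event_list([
            (1000.0, "closed"), (2.0, "open"), (1.0, "closed"),
            (2.0, "open"), (1000.0, "closed"),
        ])
        bs = segment_bursts(ev, t_crit=3.0)
        b = bs.bursts[0]
        assert b.open_time == pytest.approx(4.0)
        assert b.duration == pytest.approx(5.0)
        assert b.p_open == pytest.approx(0.8)

    def test_matches_exhaustive_scan_oracle(self, fast_burst_model):
        from singlechan.simulate import sample_trajectory, trajectory_events

        traj = sample_trajectory(fast_burst_model, 120.0, seed=17)
        ev = trajectory_events(traj, fast_burst_model)
        t_crit = 8.0
        bs = segment_bursts(ev, t_crit)
        # oracle: brute-force scan over openings and separating closures
        evs = [e for e in ev if not e.censored]
        runs, cur = [], []
        for i, e in enumerate(ev.events):
            if e.kind == "open":
                if e.censored:
                    runs.append(cur)
                    cur = []
                else:
                    cur.append(i)
            else:
                if e.duration >= t_crit or e.censored:
                    runs.append(cur)
                    cur = []
        runs.append(cur)
        oracle_bursts = [r for r in runs if len(r) >= 2]
        oracle_isolated = [r for r in runs if len(r) == 1]
        assert bs.n_bursts == len(oracle_bursts)
        assert len(bs.isolated_openings) == len(oracle_isolated)
        for b, r in zip(bs.bursts, oracle_bursts):
            assert b.n_openings == len(r)

    def test_censored_events_never_bound_bursts(self):
        ev = EventList([
            Event(0.0, 1.0, "open", 1.0, censored=True),
            Event(0.001, 0.5, "closed", 0.0),
            Event(0.0015, 1.0, "open", 1.0),
            Event(0.0025, 500.0, "closed", 0.0),
        ])
        bs = segment_bursts(ev, t_crit=3.0)
        assert bs.n_bursts == 0
        assert len(bs.isolated_openings) == 1  # the uncensored opening

    def test_partition_invariant(self, fast_burst_model):
        from singlechan.simulate import sample_trajectory, trajectory_events

        traj = sample_trajectory(fast_burst_model, 60.0, seed=18)
        ev = trajectory_events(traj, fast_burst_model)
        bs = segment_bursts(ev, t_crit=5.0)
        bs = discard_mixed_amplitude_bursts(bs, class_amplitudes=[1.35])
        n_open = len([e for e in ev if e.kind == "open" and not e.censored])
        counted = (
            len(bs.isolated_openings)
            + sum(b.n_openings for b in bs.bursts)
            + sum(b.n_openings for b in bs.discarded_mixed)
        )
        assert counted == n_open

    def test_monotone_in_tcrit(self, fast_burst_model):
        from singlechan.simulate import sample_trajectory, trajectory_events

        traj = sample_trajectory(fast_burst_model, 60.0, seed=19)
        ev = trajectory_events(traj, fast_burst_model)
        prev = -1
        for t_crit in (0.5, 2.0, 8.0, 50.0, 200.0):
            bs = segment_bursts(ev, t_crit)
            in_bursts = sum(b.n_openings for b in bs.bursts)
            assert in_bursts >= prev
            prev = in_bursts


class TestDiscardMixed:
    def test_mixed_amplitude_burst_discarded(self):
        ev = event_list([
            (1.0, "open", 1.0), (0.5, "closed"), (1.0, "open", 1.9),
        ])
        bs = segment_bursts(ev, t_crit=3.0)
        out = discard_mixed_amplitude_bursts(bs, class_amplitudes=[1.0, 2.0])
        assert out.n_bursts == 0
        assert len(out.discarded_mixed) == 1

    def test_homogeneous_burst_retained(self):
        ev = event_list([
            (1.0, "open", 1.0), (0.5, "closed"), (1.0, "open", 1.05),
        ])
        bs = segment_bursts(ev, t_crit=3.0)
        out = discard_mixed_amplitude_bursts(bs, class_amplitudes=[1.0, 2.0])
        assert out.n_bursts == 1
        assert not out.discarded_mixed

    def test_double_opening_from_two_channels_discarded(self):
        # summed amplitude far from any single-channel class
        ev = event_list([
            (1.0, "open", 1.35), (0.5, "closed"), (1.0, "open", 2.7),
        ])
        bs = segment_bursts(ev, t_crit=3.0)
        out = discard_mixed_amplitude_bursts(
            bs, class_amplitudes=[1.35], amplitude_tolerance=0.3
        )
        assert out.n_bursts == 0 and len(out.discarded_mixed) == 1


class TestClassifyBursts:
    @staticmethod
    def burst_with_amplitude(a):
        ev = [
            Event(0.0, 1.0, "open", a),
            Event(0.001, 0.5, "closed", 0.0),
            Event(0.0015, 1.0, "open", a),
        ]
        return Burst(events=ev)

    def test_perfectly_separated_classes(self):
        bursts = [self.burst_with_amplitude(a) for a in (1.0, 1.0, 2.0, 2.0)]
        bs = BurstSet(t_crit=3.0, bursts=bursts, isolated_openings=[])
        out = classify_burst_amplitudes(bs)
        assert [b.class_label for b in out.bursts] == ["O_S", "O_S", "O_L", "O_L"]

    def test_single_population_stays_single(self):
        rng = np.random.default_rng(51)
        bursts = [
            self.burst_with_amplitude(a)
            for a in rng.normal(1.3, 0.07, size=50)
        ]
        bs = BurstSet(t_crit=3.0, bursts=bursts, isolated_openings=[])
        out = classify_burst_amplitudes(bs)
        assert {b.class_label for b in out.bursts} == {"single"}

    def test_ls_regime_labels_match_truth(self):
        rng = np.random.default_rng(52)
        true = rng.choice([1.05, 2.06], size=60)
        bursts = [
            self.burst_with_amplitude(rng.normal(mu, 0.08)) for mu in true
        ]
        bs = BurstSet(t_crit=3.0, bursts=bursts, isolated_openings=[])
        out = classify_burst_amplitudes(bs, seed=0)
        pred = np.array(
            [1.05 if b.class_label == "O_S" else 2.06 for b in out.bursts]
        )
        assert np.mean(pred == true) >= 0.95

    def test_needs_two_bursts(self):
        bs = BurstSet(t_crit=3.0, bursts=[self.burst_with_amplitude(1.0)],
                      isolated_openings=[])
        with pytest.raises(ValueError, match=">= 2"):
            classify_burst_amplitudes(bs)


class TestBurstStatistics:
    def test_mean_openings(self):
        def burst_with_n(n):
            spec = []
            for i in range(n):
                spec.append((1.0, "open"))
                if i < n - 1:
                    spec.append((0.5, "closed"))
            ev = event_list(spec)
            return Burst(events=list(ev.events))

        bs = BurstSet(
            t_crit=3.0,
            bursts=[burst_with_n(2), burst_with_n(3), burst_with_n(4)],
            isolated_openings=[],
        )
        stats = burst_statistics(bs)
        assert stats["all"]["mean_openings_per_burst"] == pytest.approx(3.0)

    def test_per_class_popen_matches_ground_truth(self, ls_model):
        from singlechan.simulate import sample_trajectory, trajectory_events

        traj = sample_trajectory(ls_model, 300.0, seed=61)
        ev = trajectory_events(traj, ls_model)
        bs = segment_bursts(ev, t_crit=30.0)
        bs = classify_burst_amplitudes(bs, seed=0)
        stats = burst_statistics(bs, per_class=True)
        # ground truth: class-pure bursts alternate tau_open and that
        # class's within-burst closed tau
        for label, tau_open, tau_gap in (("O_S", 0.7, 0.55), ("O_L", 2.3, 0.7)):
            if label not in stats or stats[label]["n_bursts"] < 5:
                continue
            expected = tau_open / (tau_open + tau_gap)
            assert stats[label]["mean_p_open"] == pytest.approx(
                expected, abs=0.1
            )

    def test_empty_class_reports_counts_only(self):
        bs = BurstSet(t_crit=3.0, bursts=[], isolated_openings=[])
        stats = burst_statistics(bs)
        assert stats["all"]["n_bursts"] == 0
        assert "mean_p_open" not in stats["all"]
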