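"""Trajectory sampling and trace rendering."""

import numpy as np
import pytest

from singlechan.gating import GatingModel, equilibrium_distribution
from singlechan.simulate import (
    AcquisitionConfig,
    Trajectory,
    filter_noise_gain,
    gaussian_filter_sigma_samples,
    render_trace,
    sample_trajectory,
    simulate_patch,
    trajectory_events,
)


def one_state_closed_model():
    return GatingModel(
        state_names=["C", "O"],
        conductance_class=["closed", "open_small"],
        class_amplitude={"closed": 0.0, "open_small": 1.0},
        Q=np.array([[-1e-9, 1e-9], [1e9, -1e9]]),  # effectively always closed
    )


class TestSampleTrajectory:
    def test_open_sojourn_mean_matches_exit_rate(self, two_state_model):
        # Open exit rate 500 /s -> mean open sojourn 2 ms, within 3 SE.
        traj = sample_trajectory(two_state_model, 60.0, seed=4)
        open_idx = traj.states == 1
        durations = traj.sojourn_durations[open_idx][:-1]  # drop edge sojourn
        assert durations.size > 500
        se = durations.std(ddof=1) / np.sqrt(durations.size)
        assert abs(durations.mean() - 2e-3) < 3 * se

    def test_determinism_and_seed_sensitivity(self, two_state_model):
        a = sample_trajectory(two_state_model, 10.0, seed=7)
        b = sample_trajectory(two_state_model, 10.0, seed=7)
        c = sample_trajectory(two_state_model, 10.0, seed=8)
        np.testing.assert_array_equal(a.jump_times, b.jump_times)
        np.testing.assert_array_equal(a.states, b.states)
        assert len(a.states) != len(c.states) or not np.array_equal(
            a.jump_times, c.jump_times
        )

    def test_absorbing_state_raises(self):
        m = GatingModel(
            state_names=["C", "O"],
            conductance_class=["closed", "open_small"],
            class_amplitude={"closed": 0.0, "open_small": 1.0},
            Q=np.array([[-5.0, 5.0], [0.0, 0.0]]),
        )
        with pytest.raises(ValueError, match="absorbing"):
            sample_trajectory(m, 10.0, seed=0)

    def test_occupancy_matches_equilibrium(self, two_state_model):
        # Fraction of time open over 600 s within 1% absolute of pi_open.
        traj = sample_trajectory(two_state_model, 600.0, seed=2)
        open_time = traj.sojourn_durations[traj.states == 1].sum()
        pi = equilibrium_distribution(two_state_model)
        assert abs(open_time / 600.0 - pi[1]) < 0.01

    def test_trajectory_invariants(self, hs_model):
        traj = sample_trajectory(hs_model, 30.0, seed=1)
        assert traj.jump_times[0] == 0.0
        assert (np.diff(traj.jump_times) > 0).all()
        assert traj.jump_times[-1] <= traj.total_duration
        assert len(traj.states) == len(traj.jump_times)


class TestRenderTrace:
    def test_all_closed_model_renders_zero(self):
        traj = Trajectory(np.array([0.0]), np.array([0]), 1.0)
        m = one_state_closed_model()
        trace = render_trace(traj, m, sampling_rate=10_000, noise_sd=0.0,
                             online_filter_hz=None, seed=0)
        np.testing.assert_array_equal(trace.samples, 0.0)

    def test_noiseless_plateau_equals_amplitude(self, two_state_model):
        # Alternating C/O with open amplitude 1.35 pA: plateau samples
        # away from transitions equal 1.35 exactly.
        traj = Trajectory(
            np.array([0.0, 0.1, 0.2]), np.array([0, 1, 0]), 0.3
        )
        trace = render_trace(traj, two_state_model, sampling_rate=10_000,
                             noise_sd=0.0, online_filter_hz=1_000.0, seed=0)
        mid_open = trace.samples[1200:1800]
        np.testing.assert_allclose(mid_open, 1.35, atol=1e-9)

    def test_filter_has_unit_dc_gain(self, two_state_model):
        traj = Trajectory(np.array([0.0]), np.array([1]), 0.5)
        raw = render_trace(traj, two_state_model, sampling_rate=50_000,
                           noise_sd=0.0, online_filter_hz=None, seed=0)
        filt = render_trace(traj, two_state_model, sampling_rate=50_000,
                            noise_sd=0.0, online_filter_hz=5_000.0, seed=0)
        assert filt.samples[5000:-5000].mean() == pytest.approx(
            raw.samples[5000:-5000].mean(), rel=1e-6
        )

    def test_noise_attenuation_matches_closed_form(self):
        # Filtered white-noise sd = noise_sd x known gain factor (5%).
        traj = Trajectory(np.array([0.0]), np.array([0]), 2.0)
        m = one_state_closed_model()
        trace = render_trace(traj, m, sampling_rate=50_000, noise_sd=0.15,
                             online_filter_hz=5_000.0, seed=3)
        expected = 0.15 * filter_noise_gain(5_000.0, 50_000.0)
        assert trace.samples.std() == pytest.approx(expected, rel=0.05)

    def test_rundown_reduces_late_amplitude(self, two_state_model):
        traj = sample_trajectory(two_state_model, 60.0, seed=5)
        trace = render_trace(
            traj, two_state_model, sampling_rate=5_000, noise_sd=0.0,
            online_filter_hz=None, seed=0,
            rundown={"start_s": 20.0, "amplitude_slope_per_s": -0.01},
        )
        amps = trace.samples
        first = amps[: 10 * 5_000]
        last = amps[-10 * 5_000:]
        assert last[last > 0.1].mean() < first[first > 0.1].mean()

    def test_invalid_channel_count(self, two_state_model):
        traj = sample_trajectory(two_state_model, 1.0, seed=0)
        with pytest.raises(ValueError, match="n_channels"):
            render_trace(traj, two_state_model, n_channels=0)

    def test_filter_sigma_matches_3db_corner(self):
        # |H(f)|^2 at the corner is 1/2 for the matched Gaussian kernel.
        fs, fc = 50_000.0, 5_000.0
        sigma_t = gaussian_filter_sigma_samples(fc, fs) / fs
        gain2 = np.exp(-4 * np.pi**2 * sigma_t**2 * fc**2)
        assert gain2 == pytest.approx(0.5, rel=1e-12)


class TestSimulatePatch:
    def test_ground_truth_durations_match_trajectory(self, two_state_model):
        acq = AcquisitionConfig(sampling_rate=10_000, online_filter_hz=1_000,
                                offline_filter_hz=None, noise_sd=0.0)
        trace, truth = simulate_patch(two_state_model, 5.0, acq, seed=9)
        assert truth.total_duration_ms == pytest.approx(5_000.0, abs=1e-6)
        assert trace.duration == pytest.approx(5.0)

    def test_hs_like_patch_has_single_class_labels(self, hs_model):
        _, truth = simulate_patch(
            hs_model, 10.0,
            AcquisitionConfig(sampling_rate=5_000, online_filter_hz=1_000,
                              offline_filter_hz=None, noise_sd=0.0),
            seed=1,
        )
        labels = {e.class_label for e in truth.open_events()}
        assert labels == {"single"}

    def test_ls_like_patch_has_both_classes(self, ls_model):
        _, truth = simulate_patch(
            ls_model, 60.0,
            AcquisitionConfig(sampling_rate=5_000, online_filter_hz=1_000,
                              offline_filter_hz=None, noise_sd=0.0),
            seed=1,
        )
        labels = {e.class_label for e in truth.open_events()}
        assert {"O_S", "O_L"} <= labels

    def test_multichannel_patch_has_summed_levels(self, two_state_model):
        acq = AcquisitionConfig(sampling_rate=10_000, online_filter_hz=None,
                                offline_filter_hz=None, noise_sd=0.0,
                                n_channels=2)
        trace, _ = simulate_patch(two_state_model, 20.0, acq, seed=3)
        # with two channels open simultaneously the level reaches 2x
        assert trace.samples.max() > 1.9

    def test_ground_truth_events_alternate(self, hs_model):
        _, truth = simulate_patch(
            hs_model, 5.0,
            AcquisitionConfig(sampling_rate=5_000, online_filter_hz=1_000,
                              offline_filter_hz=None, noise_sd=0.0),
            seed=2,
        )
        kinds = [e.kind for e in truth]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))


class TestTrajectoryEvents:
    def test_merges_same_class_sojourns(self, ls_model):
        traj = sample_trajectory(ls_model, 30.0, seed=6)
        ev = trajectory_events(traj, ls_model)
        kinds = [e.kind for e in ev]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))
        # total duration preserved
        assert ev.total_duration_ms == pytest.approx(30_000.0, abs=1e-6)

    def test_edges_are_censored(self, two_state_model):
        traj = sample_trajectory(two_state_model, 5.0, seed=0)
        ev = trajectory_events(traj, two_state_model)
        assert ev[0].censored and ev[-1].censored
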