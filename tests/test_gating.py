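"""Gating-model validation, equilibrium, and theoretical dwell mixtures."""

import json

import numpy as np
import pytest

from singlechan.gating import (
    GatingModel,
    equilibrium_distribution,
    hyperexponential_model,
    load_model,
    predicted_dwell_components,
    save_model,
    validate_model,
)
from singlechan.simulate import sample_trajectory, trajectory_events


def make_two_state(opening=100.0, closing=500.0, amp=1.35):
    Q = np.array([[-opening, opening], [closing, -closing]])
    return GatingModel(
        state_names=["C", "O"],
        conductance_class=["closed", "open_small"],
        class_amplitude={"closed": 0.0, "open_small": amp},
        Q=Q,
    )


class TestValidateModel:
    def test_well_formed_model_passes(self, two_state_model):
        assert validate_model(two_state_model) == []

    def test_negative_off_diagonal_rate_is_named(self):
        m = make_two_state()
        m.Q = np.array([[1.0, -1.0], [500.0, -500.0]])
        problems = validate_model(m)
        assert any("Q[0,1]" in p for p in problems)

    def test_no_open_class_is_reported(self):
        m = GatingModel(
            state_names=["C1", "C2"],
            conductance_class=["closed", "closed"],
            class_amplitude={"closed": 0.0},
            Q=np.array([[-1.0, 1.0], [1.0, -1.0]]),
        )
        assert any("no open class" in p for p in validate_model(m))

    def test_row_sum_violation_reported(self):
        m = make_two_state()
        m.Q = np.array([[-100.0, 101.0], [500.0, -500.0]])
        assert any("sums to" in p for p in validate_model(m))

    def test_closed_amplitude_must_be_zero(self):
        m = make_two_state()
        m.class_amplitude = {"closed": 0.5, "open_small": 1.0}
        assert any("closed-class amplitude" in p for p in validate_model(m))

    def test_bad_initial_distribution(self):
        m = make_two_state()
        m.initial_distribution = np.array([0.7, 0.7])
        assert any("initial_distribution" in p for p in validate_model(m))

    def test_validation_never_raises(self):
        m = make_two_state()
        m.Q = np.zeros((2, 2))
        assert isinstance(validate_model(m), list)


class TestEquilibrium:
    def test_symmetric_two_state_is_half_half(self):
        m = make_two_state(opening=100.0, closing=100.0)
        pi = equilibrium_distribution(m)
        np.testing.assert_allclose(pi, [0.5, 0.5], atol=1e-12)

    def test_chain_matches_nullspace_oracle(self, chain_model):
        pi = equilibrium_distribution(chain_model)
        # Independent oracle: direct linear solve of pi Q = 0, sum pi = 1
        # (replace one equation with the normalisation).
        A = chain_model.Q.T.copy()
        A[-1, :] = 1.0
        b = np.zeros(3)
        b[-1] = 1.0
        oracle = np.linalg.solve(A, b)
        np.testing.assert_allclose(pi, oracle, atol=1e-10)

    @pytest.mark.parametrize("fixture", ["two_state_model", "chain_model",
                                         "hs_model", "ls_model"])
    def test_normalisation_and_residual(self, fixture, request):
        m = request.getfixturevalue(fixture)
        pi = equilibrium_distribution(m)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)
        assert (pi >= 0).all()
        assert np.abs(pi @ m.Q).max() < 1e-10

    def test_reducible_model_raises(self):
        m = GatingModel(
            state_names=["C", "O", "X"],
            conductance_class=["closed", "open_small", "closed"],
            class_amplitude={"closed": 0.0, "open_small": 1.0},
            Q=np.array(
                [[-1.0, 1.0, 0.0], [1.0, -1.0, 0.0], [0.0, 0.0, 0.0]]
            ),
        )
        with pytest.raises(ValueError, match="disconnected"):
            equilibrium_distribution(m)

    def test_agrees_with_long_run_occupancy(self, two_state_model):
        # State-occupancy fractions of a ~1e6-jump trajectory vs pi
        # (0.5% absolute).
        traj = sample_trajectory(two_state_model, 6000.0, seed=11)
        assert len(traj.states) > 900_000
        occ = np.zeros(two_state_model.n_states)
        for s, d in zip(traj.states, traj.sojourn_durations):
            occ[s] += d
        occ /= occ.sum()
        pi = equilibrium_distribution(two_state_model)
        np.testing.assert_allclose(occ, pi, atol=5e-3)


class TestPredictedDwellComponents:
    def test_two_state_taus_are_inverse_exit_rates(self):
        m = make_two_state(opening=100.0, closing=500.0)
        closed = predicted_dwell_components(m, "closed")
        opened = predicted_dwell_components(m, "open")
        assert len(closed) == len(opened) == 1
        assert closed[0].tau == pytest.approx(10.0)
        assert closed[0].area == pytest.approx(1.0)
        assert opened[0].tau == pytest.approx(2.0)

    def test_chain_closed_taus_match_eigen_oracle(self, chain_model):
        comps = predicted_dwell_components(chain_model, "closed")
        Qcc = chain_model.Q[:2, :2]
        eig = np.sort(-1.0 / np.linalg.eigvals(Qcc).real) * 1e3
        np.testing.assert_allclose(sorted(c.tau for c in comps), eig, rtol=1e-10)

    def test_chain_areas_match_simulated_sojourns(self, chain_model):
        # Empirical closed-sojourn distribution over ~1e5 sojourns vs
        # the predicted mixture, compared through the mean (2% tol).
        comps = predicted_dwell_components(chain_model, "closed")
        traj = sample_trajectory(chain_model, 4000.0, seed=3)
        ev = trajectory_events(traj, chain_model)
        dwells = ev.dwells("closed")
        assert dwells.size > 5_000
        pred_mean = sum(c.area * c.tau for c in comps)
        assert dwells.mean() == pytest.approx(pred_mean, rel=0.02)

    def test_sojourn_survival_matches_mixture(self, hs_model):
        # Kolmogorov distance between empirical closed-sojourn survival
        # and the predicted mixture survival below 0.01.
        comps = predicted_dwell_components(hs_model, "closed")
        traj = sample_trajectory(hs_model, 20000.0, seed=5)
        dwells = trajectory_events(traj, hs_model).dwells("closed")
        assert dwells.size >= 1e5 * 0 + 5000  # sparse model: thousands suffice
        t = np.sort(dwells)
        emp = 1.0 - np.arange(1, t.size + 1) / t.size
        pred = sum(c.area * np.exp(-t / c.tau) for c in comps)
        assert np.abs(emp - pred).max() < 0.015

    @pytest.mark.parametrize("fixture", ["two_state_model", "chain_model",
                                         "hs_model", "ls_model"])
    @pytest.mark.parametrize("group", ["open", "closed"])
    def test_areas_sum_to_one_and_taus_positive(self, fixture, group, request):
        m = request.getfixturevalue(fixture)
        comps = predicted_dwell_components(m, group)
        assert sum(c.area for c in comps) == pytest.approx(1.0, abs=1e-9)
        assert all(c.tau > 0 for c in comps)
        assert len(comps) <= len(m.state_indices(group))


class TestPresetModels:
    def test_hs_closed_aggregate_matches_target_regime(self, hs_model):
        comps = predicted_dwell_components(hs_model, "closed")
        taus = [c.tau for c in comps]
        areas = [c.area for c in comps]
        np.testing.assert_allclose(taus, [0.8, 250.0], rtol=1e-9)
        np.testing.assert_allclose(areas, [0.30, 0.70], atol=1e-9)

    def test_ls_model_spans_three_closed_time_scales(self, ls_model):
        # Two sub-ms within-burst closures (one per amplitude class)
        # plus ~170 ms and ~2 s interburst components: dwell fits
        # resolve them as three time scales.
        comps = predicted_dwell_components(ls_model, "closed")
        taus = sorted(c.tau for c in comps)
        assert sum(t < 1.0 for t in taus) == 2
        assert sum(100.0 < t < 500.0 for t in taus) == 1
        assert sum(t > 1000.0 for t in taus) == 1
        open_amps = {
            c: a for c, a in ls_model.class_amplitude.items() if c != "closed"
        }
        assert len(open_amps) == 2

    def test_hyperexponential_areas_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            hyperexponential_model([(1.0, 0.5), (10.0, 0.4)], [(1.0, 1.0)])


class TestModelIO:
    def test_round_trip(self, tmp_path, hs_model):
        path = tmp_path / "model.json"
        save_model(hs_model, path)
        loaded = load_model(path)
        np.testing.assert_allclose(loaded.Q, hs_model.Q)
        assert loaded.state_names == hs_model.state_names
        assert loaded.class_amplitude == hs_model.class_amplitude

    def test_missing_key_raises(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"states": ["C", "O"]}))
        with pytest.raises(ValueError, match="missing required key"):
            load_model(path)

    def test_invalid_model_rejected_on_load(self, tmp_path):
        doc = {
            "states": ["C", "O"],
            "classes": ["closed", "open_small"],
            "amplitudes_pA": {"closed": 0.0, "open_small": 1.0},
            "Q_per_s": [[-1.0, 2.0], [1.0, -1.0]],
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="invalid model"):
            load_model(path)
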