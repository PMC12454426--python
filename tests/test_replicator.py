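"""Expected payoffs, replicator rates, integration and convergence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carbongame.errors import ConfigurationError, ParameterValidationError
from carbongame.payoffs import PROFILES, build_payoff_tensor, payoff_at
from carbongame.replicator import (
    Trajectory,
    detect_convergence,
    expected_payoffs,
    integrate,
    printed_rhs,
    replicator_rhs,
)

from conftest import oracle_rates, random_params

UNIFORM = (0.5, 0.5, 0.5, 0.5)


class TestExpectedPayoffs:
    def test_pure_state_degenerates_to_tensor_entry(self, baseline_tensor):
        e_active, e_passive, e_avg = expected_payoffs(baseline_tensor, "hospital", (1, 1, 1, 1))
        assert e_active == pytest.approx(payoff_at(baseline_tensor, "hospital", (1, 1, 1, 1)))
        assert e_passive == pytest.approx(payoff_at(baseline_tensor, "hospital", (1, 0, 1, 1)))
        assert e_avg == pytest.approx(e_active)  # own frequency is 1

    def test_hospital_at_uniform_baseline(self, baseline_tensor):
        # closed forms: E_active = -C_h + x z R_h + w k_h, E_passive = S_h - x D_h - w k_h
        e_active, e_passive, e_avg = expected_payoffs(baseline_tensor, "hospital", UNIFORM)
        assert e_active == pytest.approx(-2.5)
        assert e_passive == pytest.approx(6.0)
        assert e_avg == pytest.approx(0.5 * -2.5 + 0.5 * 6.0)


class TestReplicatorRates:
    def test_every_vertex_is_a_fixed_point(self, rng):
        for _ in range(5):
            tensor = build_payoff_tensor(random_params(rng))
            for vertex in PROFILES:
                np.testing.assert_allclose(replicator_rhs(tensor, vertex), 0.0, atol=1e-14)

    def test_uniform_baseline_rates(self, baseline_tensor):
        rates = replicator_rhs(baseline_tensor, UNIFORM)
        # hospital: 0.25 * [x(D_h + z R_h) + 2 w k_h - S_h - C_h] = 0.25 * (3.5 + 2 - 14)
        assert rates[1] == pytest.approx(-2.125)
        # pharma: 0.25 * [x(D_c + y R_c) + 2 w k_c - S_c - C_c] = 0.25 * (4 + 6 - 8)
        assert rates[2] == pytest.approx(0.5)

    def test_matches_sixteen_profile_enumeration_oracle(self, rng):
        # 1000 random (state, parameter) pairs against the brute-force oracle
        for _ in range(50):
            tensor = build_payoff_tensor(random_params(rng))
            for _ in range(20):
                state = rng.uniform(size=4)
                expected = oracle_rates(tensor, state)
                got = replicator_rhs(tensor, state)
                np.testing.assert_allclose(got, expected, rtol=1e-10, atol=1e-12)

    def test_dynamics_independent_of_nonentering_parameters(self, baseline, rng):
        tensor = build_payoff_tensor(baseline)
        for name in ("R_g", "L_g", "L_p", "S_p"):
            perturbed = build_payoff_tensor(
                baseline.with_updates(**{name: getattr(baseline, name) + 3.7})
            )
            for _ in range(25):
                state = rng.uniform(size=4)
                np.testing.assert_allclose(
                    replicator_rhs(tensor, state),
                    replicator_rhs(perturbed, state),
                    atol=1e-12,
                )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4))
    def test_printed_forms_match_canonical_except_government(self, baseline_tensor, state):
        """Hospital, pharma and public published closed forms agree with the
        tensor-derived rates everywhere; the published government equation
        differs by x(1-x)*y*z*w*(C_g - k_g)."""
        params = baseline_tensor.params
        canonical = replicator_rhs(baseline_tensor, state)
        printed = printed_rhs(params, state)
        np.testing.assert_allclose(printed[1:], canonical[1:], atol=1e-12)
        x, y, z, w = state
        expected_gap = x * (1 - x) * y * z * w * (params.C_g - params.k_g)
        assert printed[0] - canonical[0] == pytest.approx(expected_gap, abs=1e-12)

    def test_government_printed_gap_at_uniform_baseline(self, baseline_tensor):
        canonical = replicator_rhs(baseline_tensor, UNIFORM)[0]
        printed = printed_rhs(baseline_tensor.params, UNIFORM)[0]
        # x(1-x) y z w (C_g - k_g) = 0.25 * 0.125 * 1
        assert printed - canonical == pytest.approx(0.03125)


class TestIntegration:
    def test_vertex_initial_state_stays_constant(self, baseline_tensor):
        traj = integrate(baseline_tensor, (1, 0, 1, 1), 10.0)
        np.testing.assert_allclose(traj.states, np.tile([1, 0, 1, 1], (len(traj.times), 1)), atol=1e-9)

    def test_faces_are_invariant(self, baseline_tensor, rng):
        start = rng.uniform(0.2, 0.8, size=4)
        start[2] = 0.0  # pharma exactly on a face
        traj = integrate(baseline_tensor, start, 20.0)
        np.testing.assert_allclose(traj.states[:, 2], 0.0, atol=1e-9)

    def test_baseline_converges_to_strict_weak_sd_participating(self, baseline_tensor):
        traj = integrate(baseline_tensor, UNIFORM, 100.0)
        np.testing.assert_allclose(traj.final_state, [1, 0, 1, 1], atol=0.01)

    def test_high_regulation_cost_drives_x_down(self, baseline):
        tensor = build_payoff_tensor(baseline.with_updates(C_g=12.0))
        traj = integrate(tensor, UNIFORM, 100.0)
        # D_c + D_h - C_g = 0 here, so x decays without the exponential tail;
        # it heads to 0 but has not entered the 0.01-ball by t = 100
        assert traj.final_state[0] < 0.05
        early = np.searchsorted(traj.times, 5.0)
        assert traj.final_state[0] < traj.states[early, 0]

    def test_states_stay_in_cube_within_tolerance(self, baseline_tensor):
        traj = integrate(baseline_tensor, UNIFORM, 100.0)
        assert traj.states.min() > -1e-6
        assert traj.states.max() < 1 + 1e-6

    def test_nonpositive_horizon_rejected(self, baseline_tensor):
        with pytest.raises(ConfigurationError):
            integrate(baseline_tensor, UNIFORM, 0.0)

    def test_invalid_initial_state_rejected(self, baseline_tensor):
        with pytest.raises(ParameterValidationError):
            integrate(baseline_tensor, (0.5, 0.5, 1.2, 0.5), 1.0)


class TestConvergenceDetection:
    def test_constant_vertex_trajectory(self):
        times = np.linspace(0, 10, 101)
        states = np.tile([1.0, 0.0, 1.0, 1.0], (101, 1))
        res = detect_convergence(Trajectory(times=times, states=states))
        assert res.vertex == (1, 0, 1, 1)
        assert res.first_passage_time == 0.0

    def test_baseline_trajectory_detects_vertex(self, baseline_tensor):
        traj = integrate(baseline_tensor, UNIFORM, 100.0)
        res = detect_convergence(traj)
        assert res.vertex == (1, 0, 1, 1)
        assert res.first_passage_time is not None and 0 < res.first_passage_time < 100

    def test_center_state_is_not_converged(self):
        times = np.linspace(0, 10, 11)
        states = np.tile([0.5, 0.5, 0.5, 0.5], (11, 1))
        res = detect_convergence(Trajectory(times=times, states=states))
        assert res.vertex is None
        assert res.final_distance == pytest.approx(0.5)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ConfigurationError):
            detect_convergence(Trajectory(times=np.array([]), states=np.empty((0, 4))))

    def test_bad_tolerance_rejected(self, baseline_tensor):
        traj = integrate(baseline_tensor, UNIFORM, 1.0)
        with pytest.raises(ConfigurationError):
            detect_convergence(traj, tol=0.7)
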