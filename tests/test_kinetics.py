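"""Unit and property tests of the three-state pool kinetics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import synpool as sp
from synpool.kinetics import generator_matrix, integrate_state, propagate_states_at

from _oracles import euler_checkpoints, euler_final


def rates_states(draw_rates_min=0.0):
    rate = st.floats(min_value=draw_rates_min, max_value=2.0, allow_nan=False)
    weights = st.tuples(*[st.floats(0.01, 1.0) for _ in range(3)])
    return st.tuples(rate, rate, rate, weights)


def _state_from_weights(w) -> sp.PoolState:
    arr = np.asarray(w, dtype=float)
    return sp.PoolState.from_array(arr / arr.sum())


class TestDerivative:
    def test_printed_rates_from_full_pool(self, paper_rates):
        d = sp.derivative(sp.PoolState(1.0, 0.0, 0.0), paper_rates)
        assert d == pytest.approx((-0.008, 0.008, 0.0), abs=1e-15)

    def test_vanishes_at_steady_state(self, paper_rates, equilibrium):
        assert np.abs(sp.derivative(equilibrium, paper_rates)).max() < 1e-12

    @given(rates_states())
    def test_components_sum_to_zero(self, rs):
        a, b, s, w = rs
        d = sp.derivative(_state_from_weights(w), sp.RateSet(a, b, s))
        assert abs(sum(d)) < 1e-15

    def test_rejects_broken_simplex(self):
        with pytest.raises(ValueError, match="sum"):
            sp.PoolState(0.5, 0.2, 0.2)
        with pytest.raises(ValueError, match=r"outside \[0, 1\]"):
            sp.PoolState(1.2, -0.2, 0.0)


class TestGeneratorMatrix:
    @given(rates_states())
    def test_matches_derivative_and_conserves(self, rs):
        a, b, s, w = rs
        rates = sp.RateSet(a, b, s)
        state = _state_from_weights(w)
        M = generator_matrix(rates)
        assert np.abs(M.sum(axis=0)).max() == 0.0
        assert np.all(M[~np.eye(3, dtype=bool)] >= 0)
        np.testing.assert_allclose(M @ state.as_array(), sp.derivative(state, rates), atol=1e-15)

    def test_zero_rates_give_zero_matrix(self):
        assert np.all(generator_matrix(sp.RateSet(0, 0, 0)) == 0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="finite and >= 0"):
            sp.RateSet(-0.1, 0.5, 1.67)


class TestSteadyState:
    def test_closed_form_matches_euler_oracle(self, paper_rates):
        # independent check: naive integration from a pool fully at rest
        M = generator_matrix(paper_rates)
        num = euler_final(M, np.array([1.0, 0.0, 0.0]), h=1e-3, t_end=1e4)
        ss = sp.steady_state(paper_rates).as_array()
        np.testing.assert_allclose(ss, num, atol=1e-6)
        np.testing.assert_allclose(ss, [0.979634, 0.004693, 0.015674], atol=1e-6)

    def test_independent_of_start(self, paper_rates):
        M = generator_matrix(paper_rates)
        rng = np.random.default_rng(5)
        ss = sp.steady_state(paper_rates).as_array()
        for _ in range(5):
            x0 = rng.dirichlet([1.0, 1.0, 1.0])
            np.testing.assert_allclose(euler_final(M, x0, 1e-3, 1e4), ss, atol=1e-6)

    def test_no_exocytosis_rests_in_u1(self):
        assert sp.steady_state(sp.RateSet(0.0, 0.5, 1.67)) == sp.PoolState(1.0, 0.0, 0.0)

    @pytest.mark.parametrize("k", [0.01, 1.0, 1.9])
    def test_equal_rates_give_uniform_occupancy(self, k):
        np.testing.assert_allclose(
            sp.steady_state(sp.RateSet(k, k, k)).as_array(), [1 / 3] * 3, atol=1e-12
        )

    def test_degenerate_rates_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            sp.steady_state(sp.RateSet(0.5, 0.0, 1.0))
        with pytest.raises(ValueError, match="degenerate"):
            sp.steady_state(sp.RateSet(0.5, 1.0, 0.0))


class TestPropagate:
    def test_zero_interval_is_identity(self, paper_rates, equilibrium):
        assert sp.propagate(equilibrium, paper_rates, 0.0) is equilibrium

    def test_negative_interval_rejected(self, paper_rates, equilibrium):
        with pytest.raises(ValueError, match=">= 0"):
            sp.propagate(equilibrium, paper_rates, -1.0)

    def test_long_time_limit_is_steady_state(self, paper_rates):
        out = sp.propagate(sp.PoolState(0.2, 0.3, 0.5), paper_rates, 1e6)
        np.testing.assert_allclose(
            out.as_array(), sp.steady_state(paper_rates).as_array(), atol=1e-9
        )

    def test_agrees_with_euler_oracle_at_paper_rates(self, paper_rates):
        M = generator_matrix(paper_rates)
        num = euler_final(M, np.array([1.0, 0.0, 0.0]), h=1e-4, t_end=120.0)
        exact = sp.propagate(sp.PoolState(1.0, 0.0, 0.0), paper_rates, 120.0)
        np.testing.assert_allclose(exact.as_array(), num, atol=1e-5)

    @given(rates_states(), st.floats(0.0, 100.0))
    def test_maps_simplex_into_simplex(self, rs, dt):
        a, b, s, w = rs
        out = sp.propagate(_state_from_weights(w), sp.RateSet(a, b, s), dt)
        arr = out.as_array()  # PoolState construction already validates
        assert abs(arr.sum() - 1.0) < 1e-9
        assert np.all(arr >= -1e-9) and np.all(arr <= 1 + 1e-9)


class TestSimulate:
    def test_equilibrium_is_a_fixed_point(self, paper_rates, equilibrium):
        traj = sp.simulate(
            sp.RateSchedule.constant(paper_rates), equilibrium, np.linspace(0, 600, 61)
        )
        assert np.abs(traj.states - equilibrium.as_array()).max() < 1e-12

    def test_grid_refinement_leaves_shared_times_unchanged(self, equilibrium):
        schedule = sp.build_lpa_schedule(sp.ScenarioParams())
        coarse = np.arange(0.0, 1081.0, 10.0)
        fine = np.arange(0.0, 1081.0, 1.0)
        tc = sp.simulate(schedule, equilibrium, coarse)
        tf = sp.simulate(schedule, equilibrium, fine)
        shared = np.isin(fine, coarse)
        np.testing.assert_allclose(tf.states[shared], tc.states, atol=1e-12)

    def test_conservation_along_lpa_scenario(self, lpa_trajectory):
        assert np.abs(lpa_trajectory.states.sum(axis=1) - 1.0).max() < 1e-9

    def test_matches_euler_oracle_over_lpa_schedule(self, equilibrium):
        schedule = sp.build_lpa_schedule(sp.ScenarioParams())
        grid = np.arange(0.0, 1081.0, 1.0)
        traj = sp.simulate(schedule, equilibrium, grid)
        # chain the naive oracle across the three constant-rate segments
        h = 1e-4
        states = [equilibrium.as_array()]
        for t0, t1, seg in schedule.iter_segments(0.0, 1080.0):
            M = generator_matrix(seg)
            chunk = euler_checkpoints(M, states[-1], h, 1.0, int(round(t1 - t0)))
            states.extend(list(chunk))
        oracle = np.asarray(states)
        assert np.abs(traj.states - oracle).max() < 1e-5

    def test_unsorted_grid_rejected(self, paper_rates, equilibrium):
        with pytest.raises(ValueError, match="strictly increasing"):
            sp.simulate(sp.RateSchedule.constant(paper_rates), equilibrium, [0.0, 2.0, 1.0])


class TestSpectralHelpers:
    """The spectral fast paths must agree with dense matrix exponentials."""

    @given(rates_states(draw_rates_min=1e-3))
    def test_propagate_states_at_matches_expm(self, rs):
        from scipy.linalg import expm

        a, b, s, w = rs
        M = generator_matrix(sp.RateSet(a, b, s))
        x0 = _state_from_weights(w).as_array()
        dts = np.array([0.0, 0.7, 13.0, 240.0])
        got = propagate_states_at(M, x0, dts)
        want = np.stack([expm(M * d) @ x0 for d in dts])
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_integrate_state_matches_quadrature(self, paper_rates, equilibrium):
        from scipy.integrate import quad
        from scipy.linalg import expm

        M = generator_matrix(sp.RateSet(0.1, 0.9, 1.3))
        x0 = equilibrium.as_array()
        got = integrate_state(M, x0, 37.0)
        for i in range(3):
            want, _ = quad(lambda t, i=i: (expm(M * t) @ x0)[i], 0, 37.0, limit=200)
            assert got[i] == pytest.approx(want, rel=1e-8)


class TestScheduleValidation:
    def test_breakpoint_segment_count_mismatch(self, paper_rates):
        with pytest.raises(ValueError, match="segments"):
            sp.RateSchedule(breakpoints=(10.0,), segments=(paper_rates,))

    def test_decreasing_breakpoints_rejected(self, paper_rates):
        with pytest.raises(ValueError, match="strictly increasing"):
            sp.RateSchedule(breakpoints=(10.0, 5.0), segments=(paper_rates,) * 3)

    def test_rates_are_right_continuous_at_breakpoints(self, paper_rates):
        other = sp.RateSet(0.012, 0.005, 1.67)
        sched = sp.RateSchedule(breakpoints=(100.0,), segments=(paper_rates, other))
        assert sched.rates_at(100.0) == other
        assert sched.rates_at(99.999999) == paper_rates
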