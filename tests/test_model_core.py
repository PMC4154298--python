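"""Core model: right-hand side, exact segment solution, signal, gluing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fatekinetics import (
    N2B27,
    AC,
    PopulationState,
    Protocol,
    RateParameters,
    RateRegime,
    ValidationError,
    constant_rate_segment,
    crossing_time,
    numeric_oracle,
    rhs,
    signal_level,
    simulate_protocol,
)

from conftest import random_params, random_protocol


class TestRhs:
    @pytest.mark.parametrize(
        "state, rates, expected",
        [
            # only exit-from-pluripotency flux at t=0
            ((1, 0, 0, 0), (1.0, 0.5, 0.0), (-1.0, 1.0, 0.0, 0.0)),
            # linear fluxes read off the system
            ((0, 1, 0, 0), (1.0, 0.5, 2.0), (0.0, -2.5, 0.5, 2.0)),
            # frozen dynamics
            ((0.25, 0.25, 0.25, 0.25), (0.0, 0.0, 0.0), (0.0, 0.0, 0.0, 0.0)),
        ],
    )
    def test_flux_balance_examples(self, state, rates, expected):
        pop = PopulationState(0.0, *state)
        regime = RateRegime(*rates)
        deriv = rhs(pop, regime)
        assert deriv == pytest.approx(expected, abs=1e-12)
        assert abs(deriv.sum()) < 1e-12

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            RateRegime(-1.0, 0.5, 0.0)

    def test_malformed_state_rejected(self):
        with pytest.raises(ValidationError):
            PopulationState(0.0, p=0.9, d=0.5, n=0.0, m=0.0)  # sums to 1.4


class TestConstantRateSegment:
    def test_generic_segment_matches_closed_form(self):
        # frozen expected values from adaptive numerical integration of rhs
        state = constant_rate_segment(
            PopulationState.pluripotent(), RateRegime(1.0, 0.5, 0.0), 1.0
        )
        assert state.p == pytest.approx(0.367879, abs=1e-6)
        assert state.d == pytest.approx(0.477303, abs=1e-6)
        assert state.n == pytest.approx(0.154818, abs=1e-6)
        assert state.m == 0.0

    def test_degenerate_lambda_equal(self):
        # confluent branch Lambda = lambda_D; limit and numeric oracle agree
        state = constant_rate_segment(
            PopulationState.pluripotent(), RateRegime(1.0, 1.0, 0.0), 1.0
        )
        assert state.p == pytest.approx(0.367879, abs=1e-6)
        assert state.d == pytest.approx(0.367879, abs=1e-6)
        assert state.n == pytest.approx(0.264241, abs=1e-6)

    def test_dt_zero_is_identity(self):
        init = PopulationState(0.0, 0.3, 0.3, 0.2, 0.2)
        assert constant_rate_segment(init, RateRegime(1.0, 2.0, 3.0), 0.0) is init

    def test_negative_dt_rejected(self):
        with pytest.raises(ValidationError):
            constant_rate_segment(PopulationState.pluripotent(), RateRegime(1, 1, 0), -0.5)

    def test_degenerate_branch_is_continuous(self, rng):
        """Solution at |Lambda - lambda_D| = 1e-10 matches the confluent branch."""
        lam_d = 1.3
        near = constant_rate_segment(
            PopulationState.pluripotent(), RateRegime(lam_d, lam_d + 1e-10, 0.0), 2.0
        )
        exact = constant_rate_segment(
            PopulationState.pluripotent(), RateRegime(lam_d, lam_d, 0.0), 2.0
        )
        assert np.max(np.abs(near.as_array() - exact.as_array())) < 1e-6

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        lam_d=st.floats(0.0, 5.0),
        lam_n=st.floats(0.0, 5.0),
        lam_m=st.floats(0.0, 5.0),
        dt=st.floats(0.0, 5.0),
    )
    def test_conservation_property(self, lam_d, lam_n, lam_m, dt):
        state = constant_rate_segment(
            PopulationState.pluripotent(), RateRegime(lam_d, lam_n, lam_m), dt
        )
        assert abs(state.p + state.d + state.n + state.m - 1.0) < 1e-9


class TestSignal:
    def test_no_signal_at_time_zero(self, params):
        state = signal_level(params, 0.0)
        assert state.s == 0.0
        assert not state.crossed

    def test_half_signal_at_half_life(self):
        params = RateParameters(lambda_D=math.log(2.0), lambda_N=0.5, theta=0.5)
        assert signal_level(params, 1.0).s == pytest.approx(0.5, abs=1e-12)

    def test_no_differentiation_means_no_signal(self):
        params = RateParameters(lambda_D=0.0, lambda_N=0.5, theta=0.3)
        for t in (0.0, 1.0, 10.0, 100.0):
            assert signal_level(params, t).s == 0.0
        assert crossing_time(params) == math.inf

    def test_negative_time_rejected(self, params):
        with pytest.raises(ValidationError):
            signal_level(params, -0.1)

    @pytest.mark.parametrize("theta, expected", [(0.5, 1.0), (0.75, 2.0)])
    def test_crossing_time_closed_form(self, theta, expected):
        params = RateParameters(lambda_D=math.log(2.0), lambda_N=0.5, theta=theta)
        assert crossing_time(params) == pytest.approx(expected, abs=1e-10)

    def test_boundary_thresholds(self):
        assert crossing_time(RateParameters(1.0, 1.0, theta=0.0)) == 0.0
        assert crossing_time(RateParameters(1.0, 1.0, theta=1.0)) == math.inf

    def test_crossing_matches_bisection(self, rng):
        """Closed-form crossing equals bisection on the signal itself."""
        for _ in range(20):
            params = random_params(rng)
            t_star = crossing_time(params)
            if not math.isfinite(t_star):
                continue
            lo, hi = 0.0, max(2.0 * t_star, 1.0)
            while signal_level(params, hi).s < params.theta:
                hi *= 2
            while hi - lo > 1e-12:
                mid = 0.5 * (lo + hi)
                if signal_level(params, mid).s >= params.theta:
                    hi = mid
                else:
                    lo = mid
            assert t_star == pytest.approx(hi, abs=1e-8)

    def test_cumulative_law_monotone_and_crossable(self):
        params = RateParameters(lambda_D=1.0, lambda_N=0.5, theta=0.8)
        levels = [signal_level(params, t, law="cumulative").s for t in np.linspace(0, 5, 30)]
        assert all(b >= a for a, b in zip(levels, levels[1:]))
        t_star = crossing_time(params, law="cumulative")
        assert signal_level(params, t_star, law="cumulative").s == pytest.approx(
            params.theta, abs=1e-9
        )


class TestSimulateProtocol:
    def test_neutral_medium_closes_ps_channel(self, params):
        """m stays identically 0 in N2B27 even with lambda_M_high > 0."""
        traj = simulate_protocol(
            Protocol([(6.0, N2B27)]), params, output_grid=np.linspace(0, 6, 61)
        )
        assert np.all(traj.m == 0.0)

    def test_all_nect_limit(self):
        """With the PS channel closed everywhere, every cell ends in NECT."""
        params = RateParameters(lambda_D=2.0, lambda_N=2.0, lambda_M_high=0.0, theta=0.5)
        traj = simulate_protocol(Protocol([(30.0, AC)]), params, output_grid=[30.0])
        assert traj.n[-1] == pytest.approx(1.0, abs=1e-9)

    def test_ac_protocol_matches_numeric_oracle(self):
        params = RateParameters(1.0, 0.5, 0.0, 5.0, theta=0.8)
        grid = np.linspace(0, 6, 25)
        analytic = simulate_protocol(Protocol([(6.0, AC)]), params, output_grid=grid)
        numeric = numeric_oracle(Protocol([(6.0, AC)]), params, output_grid=grid)
        assert np.max(np.abs(analytic.states - numeric.states)) < 1e-6

    def test_pulse_gains_ps_only_during_pulse(self, params):
        """A single AC pulse: m increases only inside the pulse interval."""
        protocol = Protocol([(2.0, N2B27), (1.0, AC), (3.0, N2B27)])
        grid = np.linspace(0, 6, 121)
        traj = simulate_protocol(protocol, params, output_grid=grid)
        assert abs(traj.states[-1].sum() - 1.0) < 1e-9
        dm = np.diff(traj.m)
        growing = grid[1:][dm > 1e-12]
        if growing.size:
            assert growing.min() >= 2.0 - 1e-9
            assert growing.max() <= 3.0 + 1e-9

    def test_grid_outside_span_rejected(self, params, n2b27_6d):
        with pytest.raises(ValidationError):
            simulate_protocol(n2b27_6d, params, output_grid=[0.0, 7.0])

    def test_empty_protocol_rejected(self):
        with pytest.raises(ValidationError):
            Protocol([])

    def test_states_continuous_at_breakpoints(self, params):
        """The glued solution is continuous across segment and crossing joints."""
        protocol = Protocol([(2.0, N2B27), (1.0, AC), (3.0, N2B27)])
        t_cross = 2.4999918254165273
        for joint in (2.0, 1.0 + 1e-9, t_cross):
            eps = 1e-9
            grid = [max(joint - eps, 0.0), min(joint + eps, 6.0)]
            traj = simulate_protocol(protocol, params, output_grid=grid)
            assert np.max(np.abs(traj.states[1] - traj.states[0])) < 1e-6

    def test_monotonicity_properties(self, rng):
        """p nonincreasing; n, m and s nondecreasing, for random models."""
        for _ in range(15):
            params = random_params(rng)
            protocol = random_protocol(rng)
            grid = np.linspace(0, protocol.total_duration, 40)
            traj = simulate_protocol(protocol, params, output_grid=grid)
            assert np.all(np.diff(traj.p) <= 1e-12)
            assert np.all(np.diff(traj.n) >= -1e-12)
            assert np.all(np.diff(traj.m) >= -1e-12)
            assert np.all(np.diff(traj.signal) >= -1e-12)
            assert np.max(np.abs(traj.states.sum(axis=1) - 1.0)) < 1e-9


class TestNumericOracle:
    def test_constant_trajectory_when_frozen(self, n2b27_6d):
        params = RateParameters(lambda_D=0.0, lambda_N=0.5, theta=0.5)
        traj = numeric_oracle(n2b27_6d, params, output_grid=[0, 2, 4, 6])
        assert np.allclose(traj.states, [[1, 0, 0, 0]] * 4, atol=1e-12)

    def test_single_segment_matches_segment_solution(self, params, n2b27_6d):
        from fatekinetics import RateRegime, constant_rate_segment, PopulationState

        traj = numeric_oracle(n2b27_6d, params, output_grid=[6.0])
        regime = RateRegime(params.lambda_D, params.lambda_N, 0.0)
        end = constant_rate_segment(PopulationState.pluripotent(), regime, 6.0)
        assert np.max(np.abs(traj.states[-1] - end.as_array())) < 1e-8

    def test_trajectory_csv_roundtrip(self, params, n2b27_6d, tmp_path):
        import pandas as pd

        traj = simulate_protocol(n2b27_6d, params, output_grid=[0, 3, 6])
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        frame = pd.read_csv(path)
        assert list(frame.columns) == [
            "time_day", "p", "d", "n", "m", "signal", "regime_label",
        ]
        assert np.allclose(frame[["p", "d", "n", "m"]].to_numpy(), traj.states)
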