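"""Unit and property tests for the three-state resource synapse."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import recursion_amplitudes, rk4_relax, rk4_train_states, stationary_recursion_fixed_point
from schaffer.stp import (
    STPParams,
    STPState,
    apply_spike,
    epsc_trace,
    initial_state,
    propagate,
    relax,
    train_amplitudes,
)


class TestInitialState:
    def test_full_recovered_pool(self):
        s = initial_state()
        assert (s.x, s.y, s.z, s.p, s.t) == (1.0, 0.0, 0.0, 0.0, 0.0)

    def test_initial_state_is_fixed_point_of_relax(self, control_params):
        s = relax(initial_state(), 123.4, control_params)
        assert (s.x, s.y, s.z, s.p) == (1.0, 0.0, 0.0, 0.0)


class TestRelax:
    def test_zero_interval_is_identity(self, control_params):
        s = STPState(x=0.5, y=0.2, z=0.3, p=0.4, t=7.0)
        assert relax(s, 0.0, control_params) == s

    def test_negative_interval_rejected(self, control_params):
        with pytest.raises(ValueError):
            relax(initial_state(), -1.0, control_params)

    def test_inactive_pool_recovery_matches_closed_form(self, control_params):
        # z decays as z0 * exp(-dt/tau_rec) when y = 0
        s = STPState(x=0.85, y=0.0, z=0.15, p=0.15, t=0.0)
        out = relax(s, 10.0, control_params)
        assert out.z == pytest.approx(0.15 * math.exp(-10.0 / 50.0), abs=1e-12)
        assert out.x == pytest.approx(1.0 - out.z, abs=1e-12)
        assert out.x == pytest.approx(0.8772, abs=5e-5)

    def test_facilitation_decay(self, control_params):
        s = STPState(x=0.85, y=0.0, z=0.15, p=0.15, t=0.0)
        out = relax(s, 10.0, control_params)
        assert out.p == pytest.approx(0.15 * math.exp(-10.0 / 200.0), abs=1e-12)
        assert out.p == pytest.approx(0.14268, abs=5e-6)

    @pytest.mark.parametrize("dt", [0.5, 3.0, 25.0, 200.0])
    def test_matches_fine_step_integration(self, abeta_params, dt):
        s = STPState(x=0.3, y=0.36, z=0.34, p=0.5, t=0.0)
        out = relax(s, dt, abeta_params)
        y, z, p = rk4_relax(s.y, s.z, s.p, dt, abeta_params.tau_in, abeta_params.tau_rec, abeta_params.tau_facil)
        assert out.y == pytest.approx(y, abs=1e-9)
        assert out.z == pytest.approx(z, abs=1e-9)
        assert out.p == pytest.approx(p, abs=1e-9)

    def test_equal_time_constants_degenerate_limit(self):
        # tau_in == tau_rec invokes the t*exp(-t/tau) particular solution;
        # it must be the continuous limit of nearby parameter values.
        s = STPState(x=0.4, y=0.4, z=0.2, p=0.1, t=0.0)
        exact = relax(s, 7.0, STPParams(U=0.2, tau_in=20.0, tau_rec=20.0))
        near = relax(s, 7.0, STPParams(U=0.2, tau_in=20.0, tau_rec=20.0 + 1e-7))
        assert exact.z == pytest.approx(near.z, abs=1e-7)
        assert exact.x == pytest.approx(near.x, abs=1e-7)


class TestApplySpike:
    def test_first_spike_releases_U(self, control_params):
        out, delta = apply_spike(initial_state(), control_params)
        assert out.p == pytest.approx(0.15)
        assert delta == pytest.approx(0.15)
        assert out.x == pytest.approx(0.85)

    def test_full_release_when_U_is_one(self):
        out, delta = apply_spike(initial_state(), STPParams(U=1.0))
        assert (out.p, delta, out.x) == (1.0, 1.0, 0.0)

    def test_second_spike_of_100hz_train_matches_integration(self, control_params):
        state = initial_state()
        state, _ = apply_spike(state, control_params)
        state = relax(state, 10.0, control_params)
        assert state.p == pytest.approx(0.14268, abs=5e-6)
        state, delta = apply_spike(state, control_params)
        assert state.p == pytest.approx(0.27128, abs=5e-6)
        # oracle: fixed-step integration of the full kinetics; released = p+ * x-
        oracle = rk4_train_states(control_params, [0.0, 10.0])
        x_pre, p_pre = oracle[1, 0], oracle[1, 3]
        p_plus = p_pre + 0.15 * (1 - p_pre)
        assert delta == pytest.approx(p_plus * x_pre, abs=1e-6)


class TestEpscTrace:
    def test_no_spikes_gives_zero_trace(self, control_params):
        t, i = epsc_trace(control_params, [], sample_step=0.1, duration_ms=20.0)
        assert np.all(i == 0.0)

    def test_single_spike_peak_near_A_times_U(self):
        params = STPParams(U=0.15, A=100.0)
        t, i = epsc_trace(params, [0.0], sample_step=0.01)
        assert i.max() == pytest.approx(15.0, rel=1e-3)

    def test_trace_jumps_only_at_spike_times(self, control_params):
        t, i = epsc_trace(control_params, [5.0, 15.0], sample_step=0.01, duration_ms=30.0)
        jumps = np.diff(i)
        up = np.where(jumps > 1e-3)[0]
        assert np.allclose(t[up + 1], [5.0, 15.0], atol=0.02)
        # strictly decreasing elsewhere after the first spike
        after = (t[:-1] > 5.0) & ~np.isin(np.arange(len(jumps)), up)
        assert np.all(jumps[after] <= 0)

    def test_unsorted_spikes_rejected(self, control_params):
        with pytest.raises(ValueError):
            epsc_trace(control_params, [5.0, 3.0], sample_step=0.1)
        with pytest.raises(ValueError):
            epsc_trace(control_params, [3.0, 3.0], sample_step=0.1)

    def test_inward_convention_flips_sign(self, control_params):
        _, pos = epsc_trace(control_params, [0.0], sample_step=0.1, duration_ms=5.0)
        _, neg = epsc_trace(control_params, [0.0], sample_step=0.1, duration_ms=5.0, inward_negative=True)
        assert np.allclose(pos, -neg)


class TestTrainAmplitudes:
    def test_single_pulse_normalizes_to_one(self, control_params):
        amps, norm = train_amplitudes(control_params, 1, 100.0)
        assert norm.tolist() == [1.0]

    @pytest.mark.parametrize(
        "U, expected",
        [
            (0.15, [1.0, 1.59, 1.73, 1.63, 1.46]),
            (0.36, [1.0, 1.13, 0.84, 0.62, 0.54]),
        ],
    )
    def test_five_pulse_100hz_matches_recursion_oracle(self, U, expected):
        params = STPParams(U=U)
        oracle = recursion_amplitudes(U, 50.0, 200.0, 5, 100.0)
        assert np.allclose(oracle, expected, atol=5e-3)
        _, norm = train_amplitudes(params, 5, 100.0)
        assert np.allclose(norm, oracle, rtol=0.05)

    def test_facilitation_only_limit_non_decreasing(self):
        # near-instant recovery and inactivation: amplitudes follow p_n / U
        params = STPParams(U=0.15, tau_in=1e-3, tau_rec=1e-2, tau_facil=200.0)
        _, norm = train_amplitudes(params, 8, 100.0)
        assert np.all(np.diff(norm) >= -1e-9)
        p, expected = 0.0, []
        for _ in range(8):
            p = p + 0.15 * (1 - p)
            expected.append(p / 0.15)
            p *= math.exp(-10.0 / 200.0)
        assert np.allclose(norm, expected, rtol=1e-3)

    def test_depression_only_limit_non_increasing(self):
        params = STPParams(U=0.36, tau_in=1.0, tau_rec=50.0, tau_facil=1e-3)
        _, norm = train_amplitudes(params, 8, 100.0)
        assert np.all(np.diff(norm) <= 1e-9)

    @pytest.mark.parametrize("U", [0.15, 0.36])
    def test_stationary_amplitude_converges_to_fixed_point(self, U):
        params = STPParams(U=U, tau_in=1e-3)
        _, norm = train_amplitudes(params, 200, 100.0)
        p_star, x_star = stationary_recursion_fixed_point(U, 50.0, 200.0, 100.0)
        assert norm[-1] == pytest.approx(p_star * x_star / U, rel=0.01)

    def test_invalid_protocol_rejected(self, control_params):
        with pytest.raises(ValueError):
            train_amplitudes(control_params, 0, 100.0)
        with pytest.raises(ValueError):
            train_amplitudes(control_params, 5, 0.0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    U=st.floats(0.01, 1.0),
    tau_in=st.floats(0.1, 20.0),
    tau_rec=st.floats(1.0, 500.0),
    tau_facil=st.floats(1.0, 1000.0),
    isis=st.lists(st.floats(0.01, 300.0), min_size=1, max_size=20),
)
def test_resource_conservation_under_arbitrary_event_sequences(U, tau_in, tau_rec, tau_facil, isis):
    """x + y + z stays 1 (to 1e-9) and p stays in [0, 1] through any
    alternation of relaxations and spikes."""
    params = STPParams(U=U, tau_in=tau_in, tau_rec=tau_rec, tau_facil=tau_facil)
    state = initial_state()
    for dt in isis:
        state = relax(state, dt, params)
        assert abs(state.x + state.y + state.z - 1.0) < 1e-9
        state, _ = apply_spike(state, params)
        assert abs(state.x + state.y + state.z - 1.0) < 1e-9
        assert 0.0 <= state.p <= 1.0
        assert min(state.x, state.y, state.z) >= -1e-12


def test_propagate_matches_stepwise_composition(control_params):
    times = np.array([0.0, 7.0, 19.0, 21.0, 80.0])
    out = propagate(control_params, times)
    state = initial_state()
    for i, t in enumerate(times):
        state = relax(state, t - state.t, control_params)
        assert out["x_pre"][i] == pytest.approx(state.x, abs=1e-12)
        state, delta = apply_spike(state, control_params)
        assert out["released"][i] == pytest.approx(delta, abs=1e-12)
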