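"""STDP rule checks against the analytic fixed point and hand-computed updates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wtcrl.dynamics import Clock, SynapseParams, TraceState, update_traces
from wtcrl.plasticity import (
    HomeostasisParams,
    PlasticState,
    STDPParams,
    equilibrium_weight,
    homeostasis_step,
    init_lateral_weights,
    stdp_on_post,
    stdp_on_pre,
)

PARAMS = STDPParams()  # reference values: 0.004 / 0.024 / 0.2 / 0.1
SYN = SynapseParams(tau_f=2.8, tau_x=1.3, tau_y=4.3)


def make_state(w0=0.5, m=1, n=1):
    return PlasticState(W=np.full((m, n), float(w0)), traces=TraceState.zeros(n, m))


def run_clamped_pairing(delta_t_ms, n_pairs=2500, w0=0.5, period_ms=15.0, dt=0.1):
    """Drive one synapse with pre→post pairs at a fixed lag; return the weight.

    Uses the real trace dynamics and both rule cases, one pair per
    ``period_ms`` window (long enough that traces from one pair have decayed
    below the eligibility threshold before the next).
    """
    state = make_state(w0)
    clock = Clock(dt=dt)
    lag_steps = round(delta_t_ms / dt)
    period_steps = round(period_ms / dt)
    no_spike = np.array([False])
    spike = np.array([True])
    for _ in range(n_pairs):
        for step in range(period_steps):
            clock.tick()
            pre = spike if step == 0 else no_spike
            post = spike if step == lag_steps else no_spike
            update_traces(state.traces, SYN, pre, post, clock)
            stdp_on_post(state, PARAMS, post)
            stdp_on_pre(state, PARAMS, pre)
    return state.W[0, 0]


def run_anticausal_pairing(lag_ms, n_pairs=300, w0=0.8, period_ms=15.0, dt=0.1):
    """Post→pre pairs: the presynaptic spike arrives ``lag_ms`` after the post."""
    state = make_state(w0)
    clock = Clock(dt=dt)
    lag_steps = round(lag_ms / dt)
    period_steps = round(period_ms / dt)
    no_spike = np.array([False])
    spike = np.array([True])
    for _ in range(n_pairs):
        for step in range(period_steps):
            clock.tick()
            post = spike if step == 0 else no_spike
            pre = spike if step == lag_steps else no_spike
            update_traces(state.traces, SYN, pre, post, clock)
            stdp_on_post(state, PARAMS, post)
            stdp_on_pre(state, PARAMS, pre)
    return state.W[0, 0]


class TestCausalCase:
    def test_hand_computed_update(self):
        """x=0.5, w=0.3: dw = 0.004 * (1 - 0.5 - 0.3 + 0.2) = +0.0016."""
        state = make_state(0.3)
        state.traces.x[0] = 0.5
        stdp_on_post(state, PARAMS, np.array([True]))
        assert state.W[0, 0] == pytest.approx(0.3016, abs=1e-12)

    def test_subthreshold_trace_is_ineligible(self):
        state = make_state(0.3)
        state.traces.x[0] = 0.05
        stdp_on_post(state, PARAMS, np.array([True]))
        assert state.W[0, 0] == 0.3

    def test_no_post_spike_no_update(self):
        state = make_state(0.3)
        state.traces.x[0] = 0.5
        stdp_on_post(state, PARAMS, np.array([False]))
        assert state.W[0, 0] == 0.3

    def test_disabled_state_frozen(self):
        state = make_state(0.3)
        state.enabled = False
        state.traces.x[0] = 0.5
        stdp_on_post(state, PARAMS, np.array([True]))
        assert state.W[0, 0] == 0.3

    @pytest.mark.parametrize("delta_t", [0.0, 0.5, 1.0, 2.0])
    def test_pairing_converges_to_analytic_fixed_point(self, delta_t):
        w = run_clamped_pairing(delta_t)
        assert w == pytest.approx(equilibrium_weight(delta_t), abs=1e-3)

    def test_simultaneous_pair_converges_to_offset(self):
        """At lag 0 the trace reads 1, so the weight settles at w_offset = 0.2."""
        assert run_clamped_pairing(0.0) == pytest.approx(0.2, abs=1e-3)

    def test_eligibility_window_edge(self):
        """The causal case only triggers while x > eps: lag <= tau_x ln(1/eps) ~ 2.99 ms."""
        inside = run_clamped_pairing(2.9, n_pairs=200, w0=0.5)
        outside = run_clamped_pairing(3.1, n_pairs=200, w0=0.5)
        assert inside != 0.5  # updated
        assert outside == 0.5  # frozen: trace below eligibility threshold


class TestAntiCausalCase:
    def test_hand_computed_depression(self):
        state = make_state(0.5)
        state.traces.y[0] = 0.5
        stdp_on_pre(state, PARAMS, np.array([True]))
        assert state.W[0, 0] == pytest.approx(0.5 - 0.024 * 0.5, abs=1e-12)

    def test_simultaneous_spikes_no_depression(self):
        state = make_state(0.5)
        state.traces.y[0] = 1.0
        stdp_on_pre(state, PARAMS, np.array([True]))
        assert state.W[0, 0] == 0.5

    def test_subthreshold_post_trace_ineligible(self):
        state = make_state(0.5)
        state.traces.y[0] = 0.05
        stdp_on_pre(state, PARAMS, np.array([True]))
        assert state.W[0, 0] == 0.5

    def test_repeated_anticausal_pairing_drives_weight_to_zero(self):
        assert run_anticausal_pairing(5.0, n_pairs=300) == 0.0

    def test_anticausal_window_edge(self):
        """The anti-causal case triggers while y > eps: |lag| <= tau_y ln(1/eps) ~ 9.90 ms."""
        inside = run_anticausal_pairing(9.8, n_pairs=50, w0=0.8)
        outside = run_anticausal_pairing(10.0, n_pairs=50, w0=0.8)
        assert inside < 0.8
        assert outside == 0.8

    def test_case_order_irrelevant_for_simultaneous_spikes(self):
        """At lag 0 case 2's increment is exactly 0, so case order cannot matter."""
        spike = np.array([True])
        for order in ("post_first", "pre_first"):
            state = make_state(0.5)
            clock = Clock(dt=0.1)
            clock.tick()
            update_traces(state.traces, SYN, spike, spike, clock)
            if order == "post_first":
                stdp_on_post(state, PARAMS, spike)
                stdp_on_pre(state, PARAMS, spike)
            else:
                stdp_on_pre(state, PARAMS, spike)
                stdp_on_post(state, PARAMS, spike)
            # x = 1 at the post spike: dw1 = alpha+ * (1 - 1 - w + 0.2)
            assert state.W[0, 0] == pytest.approx(
                0.5 + 0.004 * (0.2 - 0.5), abs=1e-12
            ), order


class TestEquilibriumWeight:
    def test_zero_lag_gives_offset(self):
        assert equilibrium_weight(0.0) == pytest.approx(0.2)

    def test_large_lag_clips_at_one(self):
        assert equilibrium_weight(1e6) == 1.0

    def test_one_tau_lag(self):
        assert equilibrium_weight(1.3) == pytest.approx(1 - math.exp(-1) + 0.2, rel=1e-9)

    def test_negative_lag_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_weight(-0.1)


class TestBounds:
    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_weights_stay_in_unit_interval(self, seed):
        """Random spike bombardment never pushes weights outside [0, 1]."""
        rng = np.random.default_rng(seed)
        state = make_state(w0=0.5, m=3, n=5)
        state.W[:] = rng.uniform(0, 1, size=(3, 5))
        clock = Clock(dt=0.1)
        for _ in range(200):
            clock.tick()
            pre = rng.random(5) < 0.1
            post = rng.random(3) < 0.1
            update_traces(state.traces, SYN, pre, post, clock)
            stdp_on_post(state, PARAMS, post)
            stdp_on_pre(state, PARAMS, pre)
            assert np.all(state.W >= 0.0) and np.all(state.W <= 1.0)


class TestHomeostasis:
    HOMEO = HomeostasisParams(c_min=9.0, c_max=91.0, tau_w=100.0)

    def test_initial_lateral_weights(self):
        L = init_lateral_weights(4, self.HOMEO)
        off = ~np.eye(4, dtype=bool)
        assert np.all(L[off] == -9.0)
        assert np.all(np.diag(L) == 0.0)

    def test_relaxation_matches_closed_form_at_one_tau(self):
        """After tau_w ms the gap to -c_max has shrunk by a factor e."""
        L = init_lateral_weights(3, self.HOMEO)
        clock = Clock(dt=0.1)
        for _ in range(1000):  # 100 ms = tau_w
            clock.tick()
            homeostasis_step(L, self.HOMEO, clock)
        expected = -91.0 + (91.0 - 9.0) * math.exp(-1.0)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(L[off], expected, atol=0.05)
        assert np.all(np.diag(L) == 0.0)

    def test_asymptote_is_minus_c_max(self):
        L = init_lateral_weights(2, self.HOMEO)
        clock = Clock(dt=0.1)
        for _ in range(20000):  # 20 tau_w
            clock.tick()
            homeostasis_step(L, self.HOMEO, clock)
        assert L[0, 1] == pytest.approx(-91.0, abs=1e-3)

    def test_entries_confined_to_ramp_interval(self):
        L = init_lateral_weights(3, self.HOMEO)
        clock = Clock(dt=0.1)
        off = ~np.eye(3, dtype=bool)
        for _ in range(5000):
            clock.tick()
            homeostasis_step(L, self.HOMEO, clock)
            assert np.all(L[off] <= -9.0) and np.all(L[off] >= -91.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            HomeostasisParams(c_min=10.0, c_max=5.0, tau_w=1.0)
        with pytest.raises(ValueError):
            HomeostasisParams(c_min=1.0, c_max=2.0, tau_w=0.0)
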