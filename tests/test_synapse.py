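"""Endbulb depression models: recursion, steady states, depression level."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gbcsim import (DepressionSpec, SynapseParams, SynapseState,
                    conductance_trace, depression_level,
                    steady_state_strength, u_for_depression, update_on_spike)
from gbcsim.synapse import delivered_conductances


def iterate_events(params, times):
    """Reference path through the public single-event API."""
    state = SynapseState.initial(params)
    out = []
    for t in times:
        state, g = update_on_spike(state, params, t)
        out.append(g)
    return np.asarray(out)


# ----------------------------------------------------------------------
class TestRecursion:
    def test_zero_utilization_is_tonic(self):
        p = SynapseParams(kind="single_exp", w=7.0, u=0.0)
        times = np.cumsum(np.full(20, 1e-3))
        assert np.allclose(iterate_events(p, times), 7.0)

    def test_full_recovery_at_long_intervals(self):
        for kind in ("single_exp", "double_exp"):
            p = SynapseParams(kind=kind, w=5.0, u=0.6)
            # intervals of tens of seconds: >> both recovery constants
            g = iterate_events(p, np.array([30.0, 90.0, 200.0]))
            assert np.allclose(g, 5.0, rtol=1e-6)

    def test_first_event_delivers_w_exactly(self):
        p = SynapseParams(kind="double_exp", w=12.0, u=0.6)
        _, g = update_on_spike(SynapseState.initial(p), p, 0.0123)
        assert g == pytest.approx(12.0, rel=1e-12)

    def test_double_exp_with_k1_reduces_to_single_exp(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 0.5, 200))
        single = SynapseParams(kind="single_exp", w=9.0, u=0.5, tau=90.0)
        double = SynapseParams(kind="double_exp", w=9.0, u=0.5, k=1.0,
                               tau_f=90.0, tau_s=123.0)
        assert np.allclose(iterate_events(single, times),
                           iterate_events(double, times), rtol=1e-12)

    def test_periodic_train_converges_to_closed_form(self):
        """500 events at 300 Hz approach the fixed point of the recursion."""
        p = SynapseParams(kind="single_exp", w=10.0, u=0.6, tau=90.0)
        times = np.arange(1, 501) / 300.0
        g = iterate_events(p, times)
        e = math.exp(-(1000.0 / 300.0) / 90.0)
        closed = 10.0 * (1 - e) / (1 - (1 - 0.6) * e)
        assert g[-1] == pytest.approx(closed, rel=1e-9)

    def test_rejects_non_increasing_events(self):
        p = SynapseParams(kind="single_exp", w=1.0, u=0.2)
        state, _ = update_on_spike(SynapseState.initial(p), p, 0.01)
        with pytest.raises(ValueError):
            update_on_spike(state, p, 0.01)

    def test_vectorized_path_matches_event_api(self):
        rng = np.random.default_rng(3)
        times = np.sort(rng.uniform(0, 1.0, 300))
        for p in (SynapseParams(kind="single_exp", w=4.0, u=0.35),
                  SynapseParams.yang2009mean(w=4.0),
                  SynapseParams.tonic(w=4.0)):
            assert np.allclose(delivered_conductances(p, times),
                               iterate_events(p, times), rtol=1e-12)

    @given(u=st.floats(0.05, 0.95), scale=st.floats(0.5, 2.0))
    def test_conductance_nonincreasing_in_u_and_increasing_in_recovery(
            self, u, scale):
        times = np.arange(1, 40) / 300.0
        base = SynapseParams(kind="single_exp", w=5.0, u=u, tau=90.0)
        more_u = SynapseParams(kind="single_exp", w=5.0,
                               u=min(u + 0.04, 0.99), tau=90.0)
        faster = SynapseParams(kind="single_exp", w=5.0, u=u,
                               tau=90.0 / (1 + scale))
        g0 = iterate_events(base, times)
        assert np.all(iterate_events(more_u, times) <= g0 + 1e-12)
        assert np.all(iterate_events(faster, times) >= g0 - 1e-12)


# ----------------------------------------------------------------------
class TestSteadyState:
    def test_tonic_is_weight(self):
        assert steady_state_strength(SynapseParams.tonic(w=3.0), 123.0) == 3.0

    def test_vanishing_utilization_limit(self):
        p = SynapseParams(kind="single_exp", w=6.0, u=1e-9)
        for f in (10.0, 300.0):
            assert steady_state_strength(p, f) == pytest.approx(6.0, rel=1e-6)

    @pytest.mark.parametrize("f", [50.0, 300.0])
    def test_matches_long_iteration_oracle(self, f):
        p = SynapseParams(kind="single_exp", w=10.0, u=0.6, tau=90.0)
        n = int(10 * 90e-3 * f) + 50
        g = iterate_events(p, np.arange(1, n + 1) / f)
        assert steady_state_strength(p, f) == pytest.approx(g[-1], rel=1e-9)

    def test_double_exp_fixed_point_is_self_consistent(self):
        p = SynapseParams.yang2009mean(w=10.0)
        for f in (50.0, 100.0, 300.0):
            s = steady_state_strength(p, f)
            times = np.arange(1, 3000) / f
            g = iterate_events(p, times)
            assert g[-1] == pytest.approx(s, rel=1e-8)

    @given(u=st.floats(0.05, 0.9))
    def test_strictly_decreasing_in_rate(self, u):
        p = SynapseParams(kind="single_exp", w=5.0, u=u, tau=90.0)
        rates = [20.0, 50.0, 120.0, 300.0]
        vals = [steady_state_strength(p, f) for f in rates]
        assert all(a > b for a, b in zip(vals, vals[1:]))


# ----------------------------------------------------------------------
class TestDepressionLevel:
    def test_tonic_and_zero_u_have_no_depression(self):
        assert depression_level(SynapseParams.tonic()) == 0.0
        assert depression_level(
            SynapseParams(kind="single_exp", u=0.0)) == 0.0

    def test_default_in_vitro_utilization_exceeds_sweep_range(self):
        """u=0.6 with 90 ms recovery gives ~80% depression (> the 0-70% sweep)."""
        p = SynapseParams(kind="single_exp", w=1.0, u=0.6, tau=90.0)
        e50 = math.exp(-20.0 / 90.0)
        e300 = math.exp(-(1000.0 / 300.0) / 90.0)
        s50 = (1 - e50) / (1 - 0.4 * e50)
        s300 = (1 - e300) / (1 - 0.4 * e300)
        expected = (1 - s300 / s50) * 100
        x = depression_level(p)
        assert x == pytest.approx(expected, abs=1e-9)
        assert 75.0 < x < 85.0

    def test_u_for_zero_depression(self):
        assert u_for_depression(0.0) == 0.0

    @pytest.mark.parametrize("x", [10.0, 30.0, 65.0])
    def test_roundtrip_identity(self, x):
        u = u_for_depression(x)
        p = SynapseParams(kind="single_exp", w=1.0, u=u, tau=90.0)
        assert depression_level(p) == pytest.approx(x, abs=0.01)

    def test_unattainable_level_raises(self):
        with pytest.raises(ValueError):
            u_for_depression(95.0)
        with pytest.raises(ValueError):
            u_for_depression(-1.0)

    def test_forward_simulation_of_two_rate_protocol(self):
        """u from a 10% target reproduces 10% in the 50->300 Hz protocol."""
        u = u_for_depression(10.0)
        p = SynapseParams(kind="single_exp", w=1.0, u=u, tau=90.0)
        t_low = np.arange(1, int(0.5 * 50) + 1) / 50.0
        t_high = 0.5 + np.arange(1, int(0.5 * 300) + 1) / 300.0
        g = iterate_events(p, np.concatenate([t_low, t_high]))
        s50 = g[len(t_low) - 1]
        s300 = g[-1]
        assert (1 - s300 / s50) * 100 == pytest.approx(10.0, abs=0.5)

    @given(st.floats(0.02, 0.9))
    def test_monotone_in_u(self, u):
        lo = SynapseParams(kind="single_exp", w=1.0, u=u * 0.9, tau=90.0)
        hi = SynapseParams(kind="single_exp", w=1.0, u=u, tau=90.0)
        assert depression_level(hi) > depression_level(lo)

    def test_yang_normalized_sequences_order_by_rate(self):
        """In-vitro-fitted synapse depresses more at higher stimulation rates."""
        p = SynapseParams.yang2009mean(w=1.0)
        seqs = {}
        for f in (100.0, 200.0, 333.0):
            seqs[f] = iterate_events(p, np.arange(1, 31) / f)
        # normalized (first pulse = w = 1) sequences, compare from pulse 2 on
        assert np.all(seqs[200.0][1:] <= seqs[100.0][1:] + 1e-12)
        assert np.all(seqs[333.0][1:] <= seqs[200.0][1:] + 1e-12)


# ----------------------------------------------------------------------
class TestConductanceTrace:
    def test_single_event_decay(self):
        t = np.array([0.0, 0.1e-3, 0.2e-3, 0.4e-3]) + 1e-3
        g = conductance_trace([1e-3], [10.0], t, g_decay_tau=0.2)
        assert np.allclose(g, 10.0 * np.exp(-(t - 1e-3) / 0.2e-3))

    def test_linearity_of_simultaneous_events(self):
        t = np.linspace(0, 5e-3, 200)
        one = conductance_trace([1e-3], [10.0], t)
        two = conductance_trace([1e-3, 1e-3], [5.0, 5.0], t)
        assert np.allclose(one, two)

    def test_periodic_train_matches_geometric_summation(self):
        """Peak after n events follows the geometric series of decayed peaks."""
        f, g0, tau = 300.0, 10.0, 2.0  # slow decay so summation is non-trivial
        events = np.arange(20) / f
        t = events.copy()  # sample exactly at event times (peaks)
        got = conductance_trace(events, np.full(20, g0), t, g_decay_tau=tau)
        rho = math.exp(-(1.0 / f) / (tau * 1e-3))
        expected = g0 * (1 - rho ** np.arange(1, 21)) / (1 - rho)
        assert np.allclose(got, expected, rtol=1e-10)

    def test_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            conductance_trace([0.0, 1.0], [1.0], np.array([0.0]))


class TestParamValidation:
    def test_u_out_of_range(self):
        with pytest.raises(ValueError):
            SynapseParams(kind="single_exp", u=1.5)

    def test_full_depletion_rejected_for_depressing_kinds(self):
        with pytest.raises(ValueError):
            SynapseParams(kind="single_exp", u=1.0)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            SynapseParams(kind="triple_exp")
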