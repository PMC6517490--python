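"""Single neuron-element semantics: multi-synapse accumulation and
decay, NMDA voltage dependence, STP recurrences and quantization, and
the LIF-with-SFA membrane."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biohybrid.core import (MultiSynapseState, decay_conductance,
                            inject_event, nmda_factor, quantize_stp,
                            simulate_single_neuron, step_neuron,
                            stp_on_spike, stp_rest_state, synaptic_efficacy,
                            fresh_neuron_state)
from biohybrid.params import (MultiSynapseParams, NeuronParams, STPParams,
                              DEFAULT_NMDA_PWL, default_synapses)


class TestMultiSynapse:
    @pytest.mark.parametrize("g0,eff,quantum,expected", [
        (0.0, 10, 0.5, 5.0),          # linear definition
        (5.0, 10, 0.5, 10.0),         # two simultaneous events superpose
        (3.0, 0, 0.5, 3.0),           # zero efficacy leaves conductance
    ])
    def test_inject_linear_superposition(self, g0, eff, quantum, expected):
        out = inject_event(MultiSynapseState(g0), eff, quantum)
        assert out.conductance == pytest.approx(expected)

    def test_inject_rejects_negative_efficacy(self):
        with pytest.raises(ValueError):
            inject_event(MultiSynapseState(0.0), -1, 0.5)

    @pytest.mark.parametrize("g0,dt,tau,expected", [
        (7.0, 5.0, 5.0, 7.0 * math.exp(-1.0)),  # one time constant
        (7.0, 0.0, 5.0, 7.0),                   # identity at dt=0
        (0.0, 123.0, 5.0, 0.0),                 # zero stays zero
    ])
    def test_decay(self, g0, dt, tau, expected):
        assert decay_conductance(MultiSynapseState(g0), dt, tau).conductance \
            == pytest.approx(expected)

    @given(st.lists(st.tuples(st.floats(0, 100), st.integers(0, 63)),
                    min_size=1, max_size=8))
    @settings(deadline=None, max_examples=50)
    def test_event_train_matches_closed_form(self, raw):
        """Interleaved inject/decay over disjoint intervals equals the
        closed form g(t) = sum_i a_i exp(-(t - t_i)/tau)."""
        tau, quantum = 5.0, 0.5
        evs = sorted((t, e) for t, e in raw)
        state, t_prev = MultiSynapseState(0.0), 0.0
        for t, eff in evs:
            state = decay_conductance(state, t - t_prev, tau)
            state = inject_event(state, eff, quantum)
            t_prev = t
        t_end = t_prev + 3.0
        state = decay_conductance(state, t_end - t_prev, tau)
        closed = sum(e * quantum * math.exp(-(t_end - t) / tau)
                     for t, e in evs)
        assert state.conductance == pytest.approx(closed, rel=1e-9, abs=1e-12)


class TestNMDA:
    def test_breakpoint_and_interpolation(self):
        pwl = ((-80.0, 0.0), (-40.0, 0.2), (0.0, 0.6))
        assert nmda_factor(-40.0, pwl) == pytest.approx(0.2)
        # midway between factors 0.2 and 0.6 -> 0.4
        assert nmda_factor(-20.0, pwl) == pytest.approx(0.4)

    def test_saturation_outside_range(self):
        assert nmda_factor(40.0, DEFAULT_NMDA_PWL) == pytest.approx(1.0)
        assert nmda_factor(-120.0, DEFAULT_NMDA_PWL) == pytest.approx(0.0)

    def test_unordered_breakpoints_rejected(self):
        with pytest.raises(ValueError):
            nmda_factor(-50.0, ((-40.0, 0.5), (-80.0, 0.0)))
        with pytest.raises(ValueError):
            MultiSynapseParams(kind="NMDA", nmda_pwl=((-40., .5), (-80., 0.)))


class TestSTP:
    def test_rest_state_is_fixed_point(self):
        p = STPParams(mode="combined")
        s = stp_rest_state(p)
        far = stp_on_spike(s, p, t=0.0)  # infinitely long silence
        assert far.u == pytest.approx(p.U + p.U * (1 - p.U))  # one spike applied
        # recovery alone (before the spike update) returns u=U, x=1:
        s2 = stp_on_spike(stp_rest_state(STPParams(mode="depression")),
                          STPParams(mode="depression"), t=0.0)
        assert s2.x == pytest.approx(1.0 - STPParams().U)

    def test_depression_weakens_second_release(self):
        p = STPParams(mode="depression", U=0.4, rec_tau=300.0)
        s0 = stp_rest_state(p)
        s1 = stp_on_spike(s0, p, t=0.0)
        first = s1.u * s1.x
        s2 = stp_on_spike(s1, p, t=10.0)  # dt << rec_tau
        assert s2.u * s2.x < first

    def test_facilitation_increases_u(self):
        p = STPParams(mode="facilitation", U=0.2, facil_tau=530.0)
        s1 = stp_on_spike(stp_rest_state(p), p, t=0.0)
        s2 = stp_on_spike(s1, p, t=5.0)  # dt << facil_tau
        assert s2.u > s1.u

    def test_static_mode_holds_u_times_x(self):
        p = STPParams(mode="static", U=0.7)
        s = stp_on_spike(stp_rest_state(p), p, t=3.0)
        assert s.u * s.x == pytest.approx(0.7)

    def test_rejects_time_reversal(self):
        p = STPParams(mode="depression")
        s = stp_on_spike(stp_rest_state(p), p, t=10.0)
        with pytest.raises(ValueError):
            stp_on_spike(s, p, t=5.0)

    @given(st.lists(st.floats(0.1, 50.0), min_size=1, max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_quantized_state_matches_bruteforce(self, gaps):
        """After every update the transmitted 6-bit state equals
        round(u*x*63) recomputed from the continuous variables."""
        p = STPParams(mode="combined", U=0.3)
        s, t = stp_rest_state(p), 0.0
        for gap in gaps:
            t += gap
            s = stp_on_spike(s, p, t)
            assert 0.0 <= s.u <= 1.0 and 0.0 <= s.x <= 1.0
            assert s.quantized_state == quantize_stp(s.u * s.x, 64)


class TestEfficacy:
    @pytest.mark.parametrize("w,q,expected", [
        (63, 63, 3969), (0, 17, 0), (32, 16, 512)])
    def test_product(self, w, q, expected):
        assert synaptic_efficacy(w, q) == expected

    @pytest.mark.parametrize("w,q", [(-1, 0), (64, 0), (0, 64), (0, -2)])
    def test_range_check(self, w, q):
        with pytest.raises(ValueError):
            synaptic_efficacy(w, q)


class TestMembrane:
    def test_leak_only_relaxation_is_monotone(self):
        params = NeuronParams()
        syn = default_synapses()
        stp = STPParams()
        state = fresh_neuron_state(params, stp)
        state.voltage = -60.0
        vs = []
        for i in range(500):
            state, spiked = step_neuron(state, params, syn, stp, i * params.dt)
            assert not spiked
            vs.append(state.voltage)
        diffs = np.diff([-60.0] + vs)
        assert np.all(diffs <= 1e-12)
        assert vs[-1] == pytest.approx(params.leak_reversal, abs=0.5)

    def test_above_threshold_spikes_and_resets(self):
        params = NeuronParams()
        syn = default_synapses()
        stp = STPParams()
        state = fresh_neuron_state(params, stp)
        state.voltage = params.threshold + 1.0
        state, spiked = step_neuron(state, params, syn, stp, 0.0)
        assert spiked
        assert state.voltage == params.reset
        assert state.sfa_conductance == pytest.approx(
            params.sfa_increment * math.exp(-params.dt / params.sfa_tau))

    def test_sfa_lengthens_interspike_intervals(self):
        """Constant strong drive with SFA: ISIs are non-decreasing over
        the first spikes (adaptation)."""
        params = NeuronParams(sfa_increment=30.0)
        syn = default_synapses()
        stp = STPParams()
        # steady excitatory drive on the background slot
        events = [(t, 1, 3969) for t in np.arange(0.0, 400.0, 1.0)]
        spikes, _ = simulate_single_neuron(params, syn, stp, events, 400.0)
        assert len(spikes) >= 4
        isis = np.diff(spikes)[:4]
        assert np.all(np.diff(isis) >= -params.dt / 2)

    def test_voltage_bounded_under_random_bombardment(self, rng):
        params = NeuronParams()
        syn = default_synapses()
        stp = STPParams()
        events = [(float(t), int(k), int(e)) for t, k, e in zip(
            np.sort(rng.uniform(0, 200, 300)), rng.integers(0, 5, 300),
            rng.integers(0, 3970, 300))]
        _, trace = simulate_single_neuron(params, syn, stp, events, 200.0)
        lo = min([params.sfa_reversal, params.reset]
                 + [s.reversal for s in syn])
        hi = max([params.threshold] + [s.reversal for s in syn])
        assert trace.min() >= lo - 1e-9
        assert trace.max() <= hi + 1e-9

    def test_halving_dt_barely_moves_spike_times(self):
        """Convergence sanity: spike times of a driven neuron change by
        less than one coarse step when dt is halved."""
        syn = default_synapses()
        stp = STPParams()
        # three suprathreshold impulse volleys (events on all AMPA slots)
        events = [(t, k, 9000) for t in (5.0, 35.0, 65.0) for k in (0, 1, 2)]
        coarse, _ = simulate_single_neuron(
            NeuronParams(dt=0.1), syn, stp, events, 100.0)
        fine, _ = simulate_single_neuron(
            NeuronParams(dt=0.05), syn, stp, events, 100.0)
        assert len(coarse) == len(fine) == 3
        assert np.max(np.abs(np.array(coarse) - np.array(fine))) <= 0.1 + 1e-9

    def test_param_invariants_enforced(self):
        with pytest.raises(ValueError):
            NeuronParams(threshold=-70.0, reset=-55.0)
        with pytest.raises(ValueError):
            NeuronParams(dt=5.0, refractory=2.0)
        with pytest.raises(ValueError):
            STPParams(U=0.0)
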