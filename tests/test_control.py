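"""Controller and estimator semantics, open-loop calibration, and
closed-loop orchestration basics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biohybrid.control import (ControllerState, EstimatorState,
                               calibrate_baseline, controller_output,
                               run_closed_loop, update_estimate)
from biohybrid.culture import CultureSurrogate
from biohybrid.network import HardwareNetwork
from biohybrid.params import (ControlGains, CultureParams, DetectorParams,
                              NetworkConfig, NeuronParams)


def explicit_weighted_sum(s, t, tau, p0):
    """Independent oracle for the recursion: the explicit exponentially
    weighted sum over the full response history."""
    p = p0
    total = 0.0
    t_prev = 0.0
    # expand: P_n = sum_k (1-e^{-dt_k/tau}) prod_{j>k} e^{-dt_j/tau} s_k
    #         + prod_j e^{-dt_j/tau} * p0
    weights = []
    for k in range(len(s)):
        dt = t[k] - (t[k - 1] if k else 0.0)
        weights.append(1.0 - math.exp(-dt / tau))
    acc = 0.0
    for k in range(len(s)):
        w = weights[k]
        for j in range(k + 1, len(s)):
            dtj = t[j] - t[j - 1]
            w *= math.exp(-dtj / tau)
        acc += w * s[k]
    tail = p0
    for j in range(len(s)):
        dtj = t[j] - (t[j - 1] if j else 0.0)
        tail *= math.exp(-dtj / tau)
    return acc + tail


class TestEstimator:
    def test_zero_gap_leaves_estimate(self):
        s = EstimatorState(p_hat=0.4, t_last=10.0)
        out = update_estimate(s, 1, 10.0)
        assert out.p_hat == pytest.approx(0.4)

    def test_long_gap_forgets_history(self):
        s = EstimatorState(p_hat=0.1, t_last=0.0, tau=250.0)
        out = update_estimate(s, 1, 1e6)
        assert out.p_hat == pytest.approx(1.0)

    def test_single_step_one_tau(self):
        # p=0, s=1, dt = tau = 250 s -> 1 - 1/e
        s = EstimatorState(p_hat=0.0, t_last=0.0, tau=250.0)
        out = update_estimate(s, 1, 250.0)
        assert out.p_hat == pytest.approx(1.0 - math.exp(-1.0), abs=1e-12)

    def test_rejects_time_reversal_and_bad_s(self):
        s = EstimatorState(p_hat=0.5, t_last=100.0)
        with pytest.raises(ValueError):
            update_estimate(s, 1, 50.0)
        with pytest.raises(ValueError):
            update_estimate(s, 2, 200.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=100)
    def test_recursion_equals_explicit_sum(self, seed):
        """Oracle equivalence on random schedules to 1e-12; the
        estimate stays in [0, 1] throughout."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 40))
        gaps = rng.uniform(0.01, 600.0, n)
        t = np.cumsum(gaps)
        s = rng.integers(0, 2, n)
        p0 = float(rng.uniform(0, 1))
        state = EstimatorState(p_hat=p0, t_last=0.0, tau=250.0)
        for sk, tk in zip(s, t):
            state = update_estimate(state, int(sk), float(tk))
            assert 0.0 <= state.p_hat <= 1.0
        oracle = explicit_weighted_sum(list(s), list(t), 250.0, p0)
        assert state.p_hat == pytest.approx(oracle, abs=1e-12)


class TestController:
    def test_zero_error_returns_baseline(self):
        gains = ControlGains(a_baseline=500.0)
        state = ControllerState()
        for _ in range(10):
            amp, state = controller_output(state, gains, 0.0)
            assert amp == 500.0

    def test_hand_computed_first_step(self):
        # 500 + 400*0.5 + 80*0.5 = 740 mV
        gains = ControlGains(g_p=400.0, g_i=80.0, g_d=0.0, a_baseline=500.0)
        amp, _ = controller_output(ControllerState(), gains, 0.5)
        assert amp == pytest.approx(740.0)

    def test_derivative_term(self):
        gains = ControlGains(g_p=0.0, g_i=0.0, g_d=100.0, a_baseline=500.0)
        state = ControllerState(last_error=0.2)
        amp, _ = controller_output(state, gains, 0.5)
        assert amp == pytest.approx(500.0 + 100.0 * 0.3)

    @pytest.mark.parametrize("err,rail", [(1.0, 1150.0), (-1.0, 100.0)])
    def test_saturation_rails(self, err, rail):
        gains = ControlGains(a_baseline=500.0)
        state = ControllerState()
        amps = []
        for _ in range(50):
            amp, state = controller_output(state, gains, err)
            amps.append(amp)
        assert amps[-1] == rail
        assert all(100.0 <= a <= 1150.0 for a in amps)

    def test_integral_keeps_growing_under_saturation(self):
        gains = ControlGains(a_baseline=500.0)
        state = ControllerState()
        for _ in range(50):
            _, state = controller_output(state, gains, 1.0)
        assert state.error_sum == pytest.approx(50.0)

    def test_error_sum_clamp(self):
        gains = ControlGains(a_baseline=500.0, error_sum_clamp=3.0)
        state = ControllerState()
        for _ in range(50):
            _, state = controller_output(state, gains, 1.0)
        assert state.error_sum == pytest.approx(3.0)


class TestCalibration:
    def _factory(self, **kw):
        params = CultureParams(**kw)
        return lambda seed: CultureSurrogate(params, seed=seed)

    def test_half_probability_lands_near_midpoint(self):
        a = calibrate_baseline(self._factory(), 0.5,
                               np.arange(200.0, 1001.0, 100.0),
                               n_trials=200, seed=0)
        assert abs(a - 600.0) <= 100.0  # within one grid step of a50

    def test_boundary_targets(self):
        grid = [100.0, 400.0, 700.0, 1000.0]
        lo = calibrate_baseline(self._factory(), 0.0, grid, n_trials=60,
                                seed=1)
        hi = calibrate_baseline(self._factory(), 1.0, grid, n_trials=60,
                                seed=2)
        assert lo == 100.0
        assert hi == 1000.0


class TestClosedLoop:
    def test_zero_gains_hold_baseline(self, scaled_config):
        """All gains zero: constant-baseline open-loop stimulation."""
        net = HardwareNetwork(scaled_config, seed=0,
                              neuron=NeuronParams(dt=0.5))
        culture = CultureSurrogate(CultureParams(), seed=10)
        gains = ControlGains(g_p=0.0, g_i=0.0, g_d=0.0, a_baseline=600.0)
        rec = run_closed_loop(net, culture, gains, DetectorParams(),
                              schedule=lambda t: 0.5, duration_s=60.0,
                              seed=0)
        assert np.all(rec.stimuli["amplitude_mv"].to_numpy() == 600.0)
        assert len(rec.stimuli) == 30
        # estimates remain probabilities
        assert rec.stimuli["p_hat_hardware"].between(0, 1).all()

    def test_estimator_converges_to_surrogate_probability(self):
        """Surrogate and estimator are mutually consistent: under long
        stationary stimulation the estimate matches the logistic
        response probability within +-0.05 (no hardware in the loop:
        the culture side is read directly)."""
        from biohybrid.control import EstimatorState, update_estimate
        from biohybrid.culture import StimulusEvent, respond_probability
        from biohybrid.detection import classify_evoked, detect_bursts
        params = CultureParams()
        culture = CultureSurrogate(params, seed=4)
        det = DetectorParams()
        amp = 700.0
        est = EstimatorState(p_hat=0.5, t_last=0.0, tau=250.0)
        hits = []
        for i in range(900):
            t = i * 2000.0
            table = culture.generate_response(StimulusEvent(t, amp),
                                              horizon=2000.0)
            bursts = classify_evoked(
                detect_bursts(table, 60, det, t0=t, t_end=t + 2000.0),
                [t], det)
            s = int(any(b.evoked for b in bursts))
            est = update_estimate(est, s, (i + 1) * 2.0)
            hits.append(s)
        target = respond_probability(amp, params)
        assert est.p_hat == pytest.approx(target, abs=0.05)
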