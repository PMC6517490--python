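"""Closed-loop machinery: response-probability estimation, PID
stimulation control, and the experiment orchestrator that couples the
culture surrogate to the hardware network.

The controlled variable is the probability that a stimulus evokes a
network synchronization.  It is estimated online from the binary
response indicators s_n by the exponentially-weighted recursion

    p_n = (1 - exp(-(t_n - t_{n-1}) / tau)) * s_n
          + exp(-(t_n - t_{n-1}) / tau) * p_{n-1},          tau ~ 250 s,

and regulated by a PID law on the error e_n = P*_n - p_n:

    A_n = A_baseline + g_P e_n + g_I sum_i e_i + g_D (e_n - e_{n-1}),

clamped to the stimulator range [100, 1150] mV.  The integral keeps
accumulating while the output is clamped (no anti-windup by default),
so control is only maintained while the commanded amplitude stays
inside the range.

In the default circuit (mirroring the indirect-control experiments) the
controller reads the *hardware* network's responses while the computed
stimulus is applied to the *culture*: the hardware is controlled
indirectly through the biological side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import events as ev
from .culture import CultureSurrogate, StimulusEvent
from .detection import (classify_evoked, detect_bursts, recruitment_order)
from .network import HardwareNetwork
from .params import ControlGains, DetectorParams

__all__ = [
    "EstimatorState",
    "ControllerState",
    "update_estimate",
    "controller_output",
    "calibrate_baseline",
    "run_closed_loop",
    "ExperimentRecord",
]


@dataclass
class EstimatorState:
    """Exponentially-weighted response-probability estimate."""

    p_hat: float = 0.0
    t_last: float = 0.0  # s
    tau: float = 250.0   # s

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_hat <= 1.0:
            raise ValueError("p_hat must lie in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


@dataclass
class ControllerState:
    """PID accumulators and the target schedule."""

    error_sum: float = 0.0
    last_error: float = 0.0
    target_schedule: object = None  # callable t_s -> desired probability


def update_estimate(state: EstimatorState, s_n: int,
                    t_n: float) -> EstimatorState:
    """Advance the estimate to the response ``s_n`` (0 or 1) of the
    stimulus delivered at ``t_n`` seconds."""
    if s_n not in (0, 1):
        raise ValueError("s_n must be 0 or 1")
    if t_n < state.t_last:
        raise ValueError("stimulus times must be non-decreasing")
    w = math.exp(-(t_n - state.t_last) / state.tau)
    return EstimatorState(p_hat=(1.0 - w) * float(s_n) + w * state.p_hat,
                          t_last=t_n, tau=state.tau)


def controller_output(state: ControllerState, gains: ControlGains,
                      e_n: float) -> tuple[float, ControllerState]:
    """One PID update: returns the clamped stimulation amplitude (mV)
    and the new controller state.  The integral of the error continues
    to accumulate even while the output is clamped."""
    error_sum = state.error_sum + e_n
    if gains.error_sum_clamp is not None:
        c = gains.error_sum_clamp
        error_sum = min(max(error_sum, -c), c)
    raw = (gains.a_baseline + gains.g_p * e_n + gains.g_i * error_sum
           + gains.g_d * (e_n - state.last_error))
    amplitude = min(max(raw, gains.a_min), gains.a_max)
    new = ControllerState(error_sum=error_sum, last_error=e_n,
                          target_schedule=state.target_schedule)
    return amplitude, new


def calibrate_baseline(make_culture, desired_p: float, amplitude_grid,
                       n_trials: int = 100, seed: int = 0,
                       stim_period_s: float = 2.0,
                       detector: DetectorParams | None = None) -> float:
    """Open-loop calibration of the baseline amplitude prior to an
    experiment: stimulate a fresh surrogate ``n_trials`` times at each
    grid amplitude, burst-detect the responses, and return the
    amplitude whose empirical evoked-response rate is closest to
    ``desired_p``.  ``make_culture`` is a factory taking a seed and
    returning a fresh surrogate (each amplitude is probed on an
    independent culture)."""
    grid = list(amplitude_grid)
    if any(not 100.0 <= a <= 1150.0 for a in grid):
        raise ValueError("amplitude grid must lie within [100, 1150] mV")
    detector = detector if detector is not None else DetectorParams()
    period_ms = stim_period_s * 1000.0
    best_a, best_gap = grid[0], float("inf")
    for j, a in enumerate(grid):
        culture = make_culture(seed + j)
        n_active = culture.params.n_electrodes
        hits = 0
        for i in range(n_trials):
            t = i * period_ms
            table = culture.generate_response(
                StimulusEvent(time=t, amplitude=a), horizon=period_ms)
            bursts = detect_bursts(table, n_active, detector, t0=t,
                                   t_end=t + period_ms)
            bursts = classify_evoked(bursts, [t], detector)
            hits += int(any(b.evoked for b in bursts))
        gap = abs(hits / n_trials - desired_p)
        if gap < best_gap - 1e-12:
            best_a, best_gap = a, gap
    return float(best_a)


@dataclass
class ExperimentRecord:
    """Everything a coupled run produces.

    ``stimuli`` has one row per stimulus: time_s, amplitude_mv, target,
    s_culture, s_hardware, p_hat_culture, p_hat_hardware,
    latency_culture_ms, latency_hardware_ms.  Spike tables hold the
    culture events and the 60-channel hardware readout; ``*_orders``
    hold (stimulus_time_s, recruitment order) of each evoked burst.
    """

    stimuli: pd.DataFrame
    culture_events: pd.DataFrame
    hardware_readout: pd.DataFrame
    culture_orders: list = field(default_factory=list)
    hardware_orders: list = field(default_factory=list)

    def summary(self) -> dict:
        df = self.stimuli
        return {
            "n_stimuli": int(len(df)),
            "mean_amplitude_mv": float(df["amplitude_mv"].mean()),
            "mean_p_hat_hardware": float(df["p_hat_hardware"].mean()),
            "mean_p_hat_culture": float(df["p_hat_culture"].mean()),
            "response_rate_culture": float(df["s_culture"].mean()),
            "response_rate_hardware": float(df["s_hardware"].mean()),
        }

    def to_hdf5(self, path) -> None:
        import h5py
        ev.write_hdf5(self.culture_events, path, group="culture_spikes")
        ev.write_hdf5(self.hardware_readout, path, group="hardware_spikes")
        with h5py.File(path, "a") as fh:
            if "stimuli" in fh:
                del fh["stimuli"]
            g = fh.create_group("stimuli")
            for col in self.stimuli.columns:
                g.create_dataset(col, data=self.stimuli[col].to_numpy(float))


def run_closed_loop(hardware: HardwareNetwork, culture: CultureSurrogate,
                    gains: ControlGains, detector: DetectorParams,
                    schedule, stim_period_s: float = 2.0,
                    duration_s: float = 600.0, loop_delay_ms: float = 1.0,
                    estimator_tau_s: float = 250.0,
                    s_source: str = "hardware", seed: int = 0,
                    order_depth: int = 5) -> ExperimentRecord:
    """Run the coupled experiment.

    At every stimulus tick: (1) the controller computes the amplitude
    from the current estimate and target; (2) the pulse is applied to
    the culture surrogate; (3) the culture spikes (after the transport
    delay) are injected into the hardware network through the culture
    input routing; (4) both sides' activity is burst-detected on their
    60 channels and the evoked indicator s_n extracted; (5) the
    estimator of the configured ``s_source`` side feeds the controller.
    ``schedule`` maps time (s) to the desired response probability.
    """
    if s_source not in ("hardware", "culture"):
        raise ValueError("s_source must be 'hardware' or 'culture'")
    n_ticks = int(round(duration_s / stim_period_s))
    period_ms = stim_period_s * 1000.0
    target0 = float(schedule(0.0))
    est_hw = EstimatorState(p_hat=target0, t_last=0.0, tau=estimator_tau_s)
    est_cu = EstimatorState(p_hat=target0, t_last=0.0, tau=estimator_tau_s)
    ctrl = ControllerState(target_schedule=schedule)

    rows = []
    cul_tables, hw_tables = [], []
    cul_orders, hw_orders = [], []
    n_active = culture.params.n_electrodes  # "all electrodes" convention

    for n in range(n_ticks):
        t_s = n * stim_period_s
        t_ms = n * period_ms
        target = float(schedule(t_s))
        p_ctrl = est_hw.p_hat if s_source == "hardware" else est_cu.p_hat
        e_n = target - p_ctrl
        amplitude, ctrl = controller_output(ctrl, gains, e_n)

        stim = StimulusEvent(time=t_ms, amplitude=amplitude)
        cul = culture.generate_response(stim, horizon=period_ms)

        # transport to the hardware side (~1 ms loop delay)
        delayed = cul.copy()
        delayed["time_ms"] = delayed["time_ms"] + loop_delay_ms
        hw_spikes, _ = hardware.run(period_ms, culture_events=delayed)
        hw_read = hardware.readout(hw_spikes)
        hw_read = hw_read.assign(source_tag="hardware")

        s_side = {}
        for side, table in (("culture", cul), ("hardware", hw_read)):
            bursts = detect_bursts(table, n_active, detector, t0=t_ms,
                                   t_end=t_ms + period_ms)
            bursts = classify_evoked(bursts, [t_ms], detector)
            evoked = [b for b in bursts if b.evoked]
            s_side[side] = (1 if evoked else 0,
                            evoked[0].latency if evoked else None)
            if evoked:
                b = recruitment_order(table, evoked[0], detector,
                                      depth=order_depth)
                (cul_orders if side == "culture" else hw_orders).append(
                    (t_s, b.recruitment_order))

        t_next = (n + 1) * stim_period_s
        est_hw = update_estimate(est_hw, s_side["hardware"][0], t_next)
        est_cu = update_estimate(est_cu, s_side["culture"][0], t_next)

        rows.append({
            "n": n, "time_s": t_s, "amplitude_mv": amplitude,
            "target": target,
            "s_culture": s_side["culture"][0],
            "s_hardware": s_side["hardware"][0],
            "p_hat_culture": est_cu.p_hat,
            "p_hat_hardware": est_hw.p_hat,
            "latency_culture_ms": s_side["culture"][1],
            "latency_hardware_ms": s_side["hardware"][1],
        })
        cul_tables.append(cul)
        hw_tables.append(hw_read)

    return ExperimentRecord(
        stimuli=pd.DataFrame(rows),
        culture_events=ev.concat_tables(cul_tables),
        hardware_readout=ev.concat_tables(hw_tables),
        culture_orders=cul_orders,
        hardware_orders=hw_orders,
    )
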