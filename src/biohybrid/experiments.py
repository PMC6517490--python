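"""Canned closed-loop experiment designs.

Three designs mirror the coupling studies this package re-creates:

* :func:`sinusoidal_tracking` — the controller steers the coupled
  system along a slow sinusoidal response-probability target (default
  0.3–0.9, 900-s period over a 30-min run);
* :func:`two_level` — indirect control at a high then a low activity
  level (default 0.8 / 0.2, 10 min per block), the setting in which
  latency, burst-rate and propagation-path effects appear;
* :func:`population_spike_run` — the hardware network alone under its
  Poisson background, exhibiting the spontaneous population-spike
  regime.

All use the degree-preserving scaled hardware network (288 neurons,
p = 0.07, mean recurrent out-degree ~20) at dt = 0.5 ms by default,
which preserves the full system's dynamical regime at desk-scale cost;
pass ``scale=1`` for the full 2880-neuron system.

The tracking and two-level controllers enable the documented
``error_sum_clamp`` (±3): the τ = 250 s estimator makes peak targets
transiently infeasible, and an unclamped integral would wind up during
those episodes and drive the amplitude rail-to-rail (the controller
default leaves the clamp off, reproducing the deployed behavior).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .control import ExperimentRecord, calibrate_baseline, run_closed_loop
from .culture import CultureSurrogate
from .network import HardwareNetwork
from .params import (ControlGains, CultureParams, DetectorParams,
                     NetworkConfig, NeuronParams)

__all__ = [
    "scaled_hardware",
    "sinusoidal_tracking",
    "two_level",
    "TwoLevelResult",
    "population_spike_run",
]


def scaled_hardware(seed: int, scale: int = 10, dt: float = 0.5,
                    config: NetworkConfig | None = None) -> HardwareNetwork:
    """Hardware network at the given scale-down factor (1 = full)."""
    if config is None:
        config = NetworkConfig() if scale == 1 else NetworkConfig.scaled(scale)
    return HardwareNetwork(config, seed=seed, neuron=NeuronParams(dt=dt))


def _gains(culture_params: CultureParams, desired_p: float, seed: int,
           n_trials: int = 60) -> ControlGains:
    baseline = calibrate_baseline(
        lambda s: CultureSurrogate(culture_params, seed=s), desired_p,
        np.arange(200.0, 1001.0, 50.0), n_trials=n_trials, seed=seed + 900)
    return ControlGains(a_baseline=baseline, error_sum_clamp=3.0)


def sinusoidal_tracking(seed: int, duration_s: float = 1800.0,
                        period_s: float = 900.0, low: float = 0.3,
                        high: float = 0.9, stim_period_s: float = 2.0,
                        scale: int = 10) -> ExperimentRecord:
    """Closed-loop tracking of a sinusoidal response-probability target
    (culture stimulated, hardware read — the indirect circuit)."""
    mid, amp = (high + low) / 2.0, (high - low) / 2.0
    hardware = scaled_hardware(seed, scale=scale)
    culture_params = CultureParams()
    culture = CultureSurrogate(culture_params, seed=seed + 100)
    gains = _gains(culture_params, mid, seed)
    schedule = lambda t: mid + amp * math.sin(2.0 * math.pi * t / period_s)
    return run_closed_loop(hardware, culture, gains, DetectorParams(),
                           schedule, stim_period_s=stim_period_s,
                           duration_s=duration_s, seed=seed)


@dataclass
class TwoLevelResult:
    record: ExperimentRecord
    block_s: float
    high: float
    low: float

    def block_mask(self, label: str):
        t = self.record.stimuli["time_s"]
        return t < self.block_s if label == "high" else t >= self.block_s


def two_level(seed: int, block_s: float = 600.0, high: float = 0.8,
              low: float = 0.2, stim_period_s: float = 2.0,
              scale: int = 10) -> TwoLevelResult:
    """Two-level indirect control: high activity level for one block,
    then low, while the hardware follows only through the coupling."""
    hardware = scaled_hardware(seed, scale=scale)
    culture_params = CultureParams()
    culture = CultureSurrogate(culture_params, seed=seed + 100)
    gains = _gains(culture_params, (high + low) / 2.0, seed)
    schedule = lambda t: high if t < block_s else low
    record = run_closed_loop(hardware, culture, gains, DetectorParams(),
                             schedule, stim_period_s=stim_period_s,
                             duration_s=2.0 * block_s, seed=seed)
    return TwoLevelResult(record=record, block_s=block_s, high=high, low=low)


def population_spike_run(seed: int, duration_s: float = 300.0,
                         scale: int = 10):
    """Spontaneous regime: the hardware network under its 25-source
    10-Hz Poisson background, no culture input.  Returns the spike
    table and the population-average rate trace."""
    hardware = scaled_hardware(seed, scale=scale)
    return hardware.run(duration_s * 1000.0)
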