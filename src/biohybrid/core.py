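"""Discrete-time emulation of a single neuron element.

One neuron element comprises a leaky integrate-and-fire membrane with
spike-frequency adaptation (SFA), five conductance-based multi-synapses
at its input, and four digital short-term-plasticity (STP) channels at
its output.  A multi-synapse accumulates the inputs of many presynaptic
connections linearly: each event re-triggers the instantaneous
conductance increase on the accumulated value, which then decays
exponentially.  Each output spike updates all four STP channels, whose
quantized (6-bit) u*x state is transmitted with the spike and
multiplied with the 6-bit routing weight at the receiving synapse.

This module is the scalar reference implementation; the vectorized
network stepper in :mod:`biohybrid.kernels` reproduces it exactly and
is tested against it.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .params import MultiSynapseParams, NeuronParams, STPParams

__all__ = [
    "MultiSynapseState",
    "STPState",
    "NeuronState",
    "inject_event",
    "decay_conductance",
    "nmda_factor",
    "stp_on_spike",
    "stp_rest_state",
    "synaptic_efficacy",
    "step_neuron",
    "simulate_single_neuron",
]


@dataclass
class MultiSynapseState:
    conductance: float = 0.0  # nS, accumulated value

    def __post_init__(self) -> None:
        if self.conductance < 0:
            raise ValueError("conductance must be >= 0")


@dataclass
class STPState:
    u: float          # facilitation variable
    x: float          # resource variable
    quantized_state: int
    last_spike_time: float = -np.inf  # ms


@dataclass
class NeuronState:
    voltage: float
    refractory_until: float = -np.inf  # ms
    sfa_conductance: float = 0.0       # nS
    synapse_states: list = field(default_factory=list)  # 5 x MultiSynapseState
    stp_states: list = field(default_factory=list)      # 4 x STPState

    def __post_init__(self) -> None:
        if len(self.synapse_states) != 5 or len(self.stp_states) != 4:
            raise ValueError("a neuron has exactly 5 multi-synapses and 4 STP channels")


def fresh_neuron_state(params: NeuronParams, stp: STPParams) -> NeuronState:
    return NeuronState(
        voltage=params.leak_reversal,
        synapse_states=[MultiSynapseState() for _ in range(5)],
        stp_states=[stp_rest_state(stp) for _ in range(4)],
    )


def inject_event(state: MultiSynapseState, efficacy: int,
                 quantum: float) -> MultiSynapseState:
    """Add one synaptic input of integer ``efficacy`` to the accumulated
    conductance (``quantum`` converts efficacy units to nS).
    Simultaneous events superpose linearly."""
    if efficacy < 0:
        raise ValueError("efficacy must be >= 0")
    return MultiSynapseState(state.conductance + efficacy * quantum)


def decay_conductance(state: MultiSynapseState, dt: float,
                      decay_tau: float) -> MultiSynapseState:
    """Exponential decay of the accumulated conductance over ``dt`` ms."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    return MultiSynapseState(state.conductance * math.exp(-dt / decay_tau))


def nmda_factor(voltage: float, nmda_pwl) -> float:
    """Piecewise-linear voltage dependence of the NMDA conductance,
    saturated at the end factors outside the breakpoint range."""
    if not nmda_pwl:
        raise ValueError("nmda_pwl breakpoints required")
    volts = np.array([v for v, _ in nmda_pwl])
    facts = np.array([f for _, f in nmda_pwl])
    if np.any(np.diff(volts) <= 0):
        raise ValueError("nmda_pwl voltages must be strictly increasing")
    return float(np.interp(voltage, volts, facts))


def quantize_stp(value: float, quant_levels: int = 64) -> int:
    """Map the continuous u*x in [0, 1] to its transmitted integer
    state, rounding half-up (round(u*x*(levels-1)))."""
    return int(math.floor(value * (quant_levels - 1) + 0.5))


def stp_rest_state(params: STPParams) -> STPState:
    """The fixed point reached after a long silent period: u = U, x = 1."""
    q = quantize_stp(params.U, params.quant_levels)
    return STPState(u=params.U, x=1.0, quantized_state=q)


def stp_on_spike(state: STPState, params: STPParams, t: float) -> STPState:
    """Advance an STP channel to a presynaptic spike at time ``t``.

    Continuous recovery over the silent interval (u relaxes toward U
    with facil_tau, x toward 1 with rec_tau) is applied first, then the
    spike itself: facilitating channels increment u by U*(1-u);
    depressing channels deplete x by the released fraction u.  The
    quantized state transmitted with the spike is round(u*x*(levels-1))
    after the full update.  Static channels hold u*x = U.
    """
    if t < state.last_spike_time:
        raise ValueError("spike times must be non-decreasing")
    if params.mode == "static":
        return STPState(u=params.U, x=1.0,
                        quantized_state=quantize_stp(params.U, params.quant_levels),
                        last_spike_time=t)
    dt = t - state.last_spike_time
    fac = math.exp(-dt / params.facil_tau) if math.isfinite(dt) else 0.0
    rec = math.exp(-dt / params.rec_tau) if math.isfinite(dt) else 0.0
    u = params.U + (state.u - params.U) * fac
    x = 1.0 - (1.0 - state.x) * rec
    if params.mode in ("facilitation", "combined"):
        u = u + params.U * (1.0 - u)
    if params.mode in ("depression", "combined"):
        x = x * (1.0 - u)
    return STPState(u=u, x=x, quantized_state=quantize_stp(u * x, params.quant_levels),
                    last_spike_time=t)


def synaptic_efficacy(weight: int, stp_quantized: int) -> int:
    """On-chip product of the 6-bit routing weight and the 6-bit STP
    state; scaled to nS by the target multi-synapse's quantum."""
    if not 0 <= weight <= 63:
        raise ValueError("weight outside 6-bit range")
    if not 0 <= stp_quantized <= 63:
        raise ValueError("stp state outside 6-bit range")
    return weight * stp_quantized


def _membrane_bounds(params: NeuronParams, synapses) -> tuple[float, float]:
    revs = [params.leak_reversal, params.sfa_reversal, params.reset]
    revs += [s.reversal for s in synapses]
    return min(revs), max(revs + [params.threshold])


def step_neuron(state: NeuronState, params: NeuronParams,
                synapses, stp: STPParams, t: float):
    """One forward-Euler step of the membrane at time ``t`` (grid of dt).

    During refractoriness the voltage is held at reset.  Otherwise
    C dV/dt = -g_leak (V - E_leak) - sum_k g_k f_k(V) (V - E_k)
              - g_sfa (V - E_sfa),
    with f_k the piecewise-linear NMDA factor (1 for non-NMDA slots).
    All conductances then decay by their exponential factor.  A
    threshold crossing emits a spike, resets the membrane, starts the
    refractory period, increments the self-triggered SFA conductance,
    and updates the four STP channels.

    Returns ``(new_state, spiked)``.
    """
    dt = params.dt
    v = state.voltage
    refractory = t < state.refractory_until - 1e-12
    if refractory:
        v = params.reset
    else:
        current = params.leak_conductance * (params.leak_reversal - v)
        current += state.sfa_conductance * (params.sfa_reversal - v)
        for syn, sp in zip(state.synapse_states, synapses):
            f = nmda_factor(v, sp.nmda_pwl) if sp.kind == "NMDA" else 1.0
            current += syn.conductance * f * (sp.reversal - v)
        v = v + dt / (1000.0 * params.capacitance) * current
        lo, hi = _membrane_bounds(params, synapses)
        v = min(max(v, lo), hi)

    spiked = (not refractory) and v >= params.threshold
    new = NeuronState(
        voltage=v,
        refractory_until=state.refractory_until,
        sfa_conductance=state.sfa_conductance,
        synapse_states=list(state.synapse_states),
        stp_states=list(state.stp_states),
    )
    if spiked:
        new.voltage = params.reset
        new.refractory_until = t + params.refractory
        new.sfa_conductance += params.sfa_increment
        new.stp_states = [stp_on_spike(s, stp, t) for s in new.stp_states]
    new.synapse_states = [
        decay_conductance(s, dt, sp.decay_tau)
        for s, sp in zip(new.synapse_states, synapses)
    ]
    new.sfa_conductance *= math.exp(-dt / params.sfa_tau)
    return new, spiked


def simulate_single_neuron(params: NeuronParams, synapses, stp: STPParams,
                           events, duration: float):
    """Reference single-neuron simulation on the fixed dt grid.

    ``events`` is an iterable of ``(time_ms, synapse_index, efficacy)``;
    events are aligned to the grid (floor) and simultaneous events are
    summed before the membrane update.  Returns the list of spike times
    and the voltage trace (one sample per step, post-update).
    """
    dt = params.dt
    n_steps = int(round(duration / dt))
    by_step: dict[int, list] = {}
    for ev_t, k, eff in events:
        by_step.setdefault(int(ev_t / dt), []).append((k, eff))
    state = fresh_neuron_state(params, stp)
    spikes, trace = [], np.empty(n_steps)
    for s in range(n_steps):
        t = s * dt
        for k, eff in by_step.get(s, ()):
            state.synapse_states[k] = inject_event(
                state.synapse_states[k], eff, synapses[k].quantum)
        state, spiked = step_neuron(state, params, synapses, stp, t)
        if spiked:
            spikes.append(t)
        trace[s] = state.voltage
    return spikes, trace
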