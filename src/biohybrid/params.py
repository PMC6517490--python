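"""Parameter dataclasses for every component of the biohybrid simulator.

All quantities carry the units used throughout the package: time in ms
(except the controller/estimator layer, which follows the convention of
expressing stimulus times and the estimation time constant in seconds),
voltage in mV, conductance in nS, capacitance in nF.

Every dataclass validates its invariants on construction and can be
round-tripped through YAML via :func:`dump_config` / :func:`load_config`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import yaml

__all__ = [
    "NeuronParams",
    "MultiSynapseParams",
    "STPParams",
    "PopulationSpec",
    "CultureInputSpec",
    "NetworkConfig",
    "DetectorParams",
    "ControlGains",
    "CultureParams",
    "default_synapses",
    "default_config",
    "dump_config",
    "load_config",
]

SYNAPSE_KINDS = ("AMPA", "NMDA", "GABA", "SFA-self")
STP_MODES = ("static", "facilitation", "depression", "combined")


@dataclass
class NeuronParams:
    """Leaky integrate-and-fire neuron with spike-frequency adaptation.

    The SFA conductance is an inhibitory conductance triggered by the
    neuron's own spikes: each spike increments it by ``sfa_increment``
    and it decays with ``sfa_tau`` toward zero, pulling the membrane
    toward ``sfa_reversal``.
    """

    capacitance: float = 1.0        # nF
    leak_conductance: float = 140.0  # nS
    leak_reversal: float = -70.0   # mV
    threshold: float = -55.0       # mV
    reset: float = -70.0           # mV
    refractory: float = 2.0        # ms
    sfa_increment: float = 10.0    # nS added per output spike
    sfa_tau: float = 1000.0        # ms ("timescales in the order of 1 s")
    sfa_reversal: float = -80.0    # mV
    dt: float = 0.1                # ms, fixed integration grid

    def __post_init__(self) -> None:
        if self.capacitance <= 0 or self.sfa_tau <= 0:
            raise ValueError("capacitance and time constants must be > 0")
        if self.threshold <= self.reset:
            raise ValueError("threshold must exceed reset")
        if not (0 < self.dt <= self.refractory):
            raise ValueError("require 0 < dt <= refractory")


@dataclass
class MultiSynapseParams:
    """One of the five conductance-based multi-synapses of a neuron.

    Many presynaptic connections share the circuit: every input event
    re-triggers the instantaneous conductance increase on the
    accumulated value, which then decays exponentially.  NMDA-type
    synapses additionally scale their current by a piecewise-linear
    voltage-dependence (``nmda_pwl``) approximating the Mg2+ block,
    saturated outside the breakpoint range.
    """

    kind: str = "AMPA"
    reversal: float = 0.0   # mV
    decay_tau: float = 5.0  # ms
    quantum: float = 0.0    # nS per unit of integer efficacy
    nmda_pwl: tuple = ()    # ((voltage mV, factor), ...) for kind == NMDA

    def __post_init__(self) -> None:
        if self.kind not in SYNAPSE_KINDS:
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be > 0")
        if self.quantum < 0:
            raise ValueError("quantum must be >= 0")
        self.nmda_pwl = tuple((float(v), float(f)) for v, f in self.nmda_pwl)
        if self.kind == "NMDA":
            if not self.nmda_pwl:
                raise ValueError("NMDA synapse requires nmda_pwl breakpoints")
            volts = [v for v, _ in self.nmda_pwl]
            if any(b <= a for a, b in zip(volts, volts[1:])):
                raise ValueError("nmda_pwl voltages must be strictly increasing")
            if any(not 0.0 <= f <= 1.0 for _, f in self.nmda_pwl):
                raise ValueError("nmda_pwl factors must lie in [0, 1]")
        elif self.nmda_pwl:
            raise ValueError("nmda_pwl only valid for NMDA synapses")


#: default 3-segment approximation of the NMDA Mg2+-block sigmoid
DEFAULT_NMDA_PWL = ((-80.0, 0.0), (-40.0, 0.5), (0.0, 1.0))


@dataclass
class STPParams:
    """Presynaptic short-term plasticity channel (Tsodyks–Markram family).

    ``mode`` selects one of the four hardware flavors.  ``U`` is the
    baseline utilization, ``facil_tau``/``rec_tau`` the facilitation and
    resource-recovery time constants.  The running u*x product is
    quantized to ``quant_levels`` states (6 bits in hardware) each time
    it is transmitted.
    """

    mode: str = "static"
    U: float = 0.4
    facil_tau: float = 530.0  # ms
    rec_tau: float = 300.0    # ms
    quant_levels: int = 64

    def __post_init__(self) -> None:
        if self.mode not in STP_MODES:
            raise ValueError(f"unknown STP mode {self.mode!r}")
        if not 0 < self.U <= 1:
            raise ValueError("U must lie in (0, 1]")
        if self.facil_tau <= 0 or self.rec_tau <= 0:
            raise ValueError("STP time constants must be > 0")
        if self.quant_levels < 2:
            raise ValueError("quant_levels must be >= 2")


@dataclass
class PopulationSpec:
    """A population and its projection: size N, pairwise connection
    probability p, and maximum synaptic conductance g (the conductance
    delivered by a full 6-bit weight x 6-bit STP-state product)."""

    N: int
    p: float
    g: float  # nS
    rate: float = 0.0  # Hz, for Poisson source populations

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.g < 0 or self.rate < 0:
            raise ValueError("g and rate must be >= 0")


@dataclass
class CultureInputSpec:
    """Projection of the 60 MEA channels into the hardware network."""

    n_channels: int = 60
    coupling_fraction: float = 0.2  # fraction of the network each channel targets
    g: float = 20.0                 # nS at full weight

    def __post_init__(self) -> None:
        if self.n_channels < 0:
            raise ValueError("n_channels must be >= 0")
        if not 0.0 <= self.coupling_fraction <= 1.0:
            raise ValueError("coupling_fraction must lie in [0, 1]")
        if self.g < 0:
            raise ValueError("g must be >= 0")


@dataclass
class NetworkConfig:
    """Structure of the full hardware system.

    Defaults replicate the deployed system: 9 chips x 10 groups x 32
    neurons = 2880 neurons configured as one excitatory recurrent
    population (p = 0.007, i.e. ~20 recurrent targets per neuron),
    driven by 25 Poisson background sources at 10 Hz (p = 0.3,
    g = 20 nS) and by the 60 culture channels.
    """

    n_chips: int = 9
    groups_per_chip: int = 10
    neurons_per_group: int = 32
    recurrent: PopulationSpec = field(
        default_factory=lambda: PopulationSpec(N=2880, p=0.007, g=25.0))
    background: PopulationSpec = field(
        default_factory=lambda: PopulationSpec(N=25, p=0.3, g=20.0, rate=10.0))
    culture_inputs: CultureInputSpec = field(default_factory=CultureInputSpec)
    max_entries_per_source: int = 3400  # FPGA routing-table capacity per STP output

    def __post_init__(self) -> None:
        if self.n_chips * self.groups_per_chip * self.neurons_per_group \
                != self.recurrent.N:
            raise ValueError(
                "n_chips * groups_per_chip * neurons_per_group must equal recurrent.N")

    @property
    def n_neurons(self) -> int:
        return self.recurrent.N

    @classmethod
    def scaled(cls, factor: int = 10, **overrides) -> "NetworkConfig":
        """Degree-preserving scaled-down system: N/factor neurons with
        p*factor, keeping the mean recurrent out-degree at ~20."""
        full = cls()
        n = full.recurrent.N // factor
        if full.groups_per_chip % factor == 0:
            chips, groups = full.n_chips, full.groups_per_chip // factor
        else:
            chips, groups = 1, 1
        per_group = n // (chips * groups)
        rec = PopulationSpec(N=n, p=min(1.0, full.recurrent.p * factor),
                             g=full.recurrent.g)
        kwargs = dict(n_chips=chips, groups_per_chip=groups,
                      neurons_per_group=per_group, recurrent=rec,
                      background=full.background,
                      culture_inputs=full.culture_inputs)
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class DetectorParams:
    """Spike and burst detection chain parameters."""

    sd_multiple: float = 6.0        # threshold = 6 x SD of the calibration trace
    calibration_window: float = 2000.0  # ms
    refractory: float = 6.0         # ms
    bin_width: float = 25.0         # ms
    active_fraction: float = 0.25   # burst threshold = ceil(fraction x active electrodes)
    evoked_window: tuple = (10.0, 800.0)  # ms after stimulation
    direct_exclusion: float = 15.0  # ms; direct electrical responses excluded

    def __post_init__(self) -> None:
        self.evoked_window = (float(self.evoked_window[0]),
                              float(self.evoked_window[1]))
        vals = (self.sd_multiple, self.calibration_window, self.refractory,
                self.bin_width, self.active_fraction, self.direct_exclusion)
        if any(v <= 0 for v in vals):
            raise ValueError("all detector parameters must be > 0")
        if not self.evoked_window[0] < self.evoked_window[1]:
            raise ValueError("evoked_window must be an increasing pair")


@dataclass
class ControlGains:
    """PID gains and amplitude limits of the stimulation controller."""

    g_p: float = 400.0        # mV per unit probability error
    g_i: float = 80.0         # mV per unit accumulated error
    g_d: float = 0.0          # mV per unit error difference
    a_baseline: float = 500.0  # mV
    a_min: float = 100.0      # mV
    a_max: float = 1150.0     # mV
    # optional symmetric clamp on the accumulated error; None (default)
    # reproduces the deployed controller, whose integral keeps growing
    # under saturation
    error_sum_clamp: float | None = None

    def __post_init__(self) -> None:
        if not self.a_min < self.a_max:
            raise ValueError("require a_min < a_max")
        if self.g_p < 0 or self.g_i < 0 or self.g_d < 0:
            raise ValueError("gains must be >= 0")
        if self.error_sum_clamp is not None and self.error_sum_clamp <= 0:
            raise ValueError("error_sum_clamp must be > 0 when set")


@dataclass
class CultureParams:
    """Statistical model of the in vitro MEA network surrogate.

    The probability that a voltage pulse of amplitude A evokes a network
    burst follows a logistic law with midpoint ``a50`` and slope ``k``;
    evoked-burst latency decreases linearly with amplitude
    (``latency_base`` - ``latency_gain`` * (A - a50), floored at 20 ms).
    Bursts recruit electrodes in one of two template orders, selected by
    the recent controlled activity level, with per-electrode jitter.
    """

    n_electrodes: int = 60
    spontaneous_burst_rate: float = 0.05  # Hz
    a50: float = 600.0        # mV, amplitude of half-maximal response
    k: float = 120.0          # mV, logistic slope
    latency_base: float = 120.0   # ms
    latency_gain: float = 0.08    # ms per mV
    latency_floor: float = 20.0   # ms
    latency_jitter: float = 10.0  # ms (sd)
    # burst profile
    spikes_per_electrode: float = 3.0  # mean spike count per electrode per burst
    recruit_spacing: float = 1.5       # ms between successive template electrodes
    recruit_jitter: float = 0.5        # ms (sd) on first-spike times
    burst_spread: float = 60.0         # ms over which follow-up spikes scatter
    direct_volley_size: int = 8        # spikes in the 0-15 ms direct response
    background_rate: float = 0.2       # Hz per electrode
    # regime-dependent propagation templates
    template_switch_threshold: float = 0.5  # on the internal activity-level estimate
    level_tau: float = 60.0                 # s, time constant of that estimate
    burst_refractory_tau: float = 500.0     # ms; 0 disables post-burst recovery
    noise_sd: float = 4.0      # uV, voltage-trace noise
    spike_amplitude: float = 10.0  # x noise_sd, planted waveform peak

    def __post_init__(self) -> None:
        if self.n_electrodes < 1:
            raise ValueError("n_electrodes must be >= 1")
        if not 100.0 <= self.a50 <= 1150.0:
            raise ValueError("a50 must lie within the stimulator range [100, 1150] mV")
        if self.k <= 0:
            raise ValueError("k must be > 0")
        for name in ("spontaneous_burst_rate", "background_rate",
                     "spikes_per_electrode", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.spike_amplitude < 8.0:
            raise ValueError("spike_amplitude must be >= 8 x noise sd")


def default_synapses(recurrent_g: float = 25.0, background_g: float = 20.0,
                     culture_g: float = 20.0) -> list[MultiSynapseParams]:
    """The five multi-synapse slots of every neuron in the default
    biomimetic network: three AMPA slots fed by the recurrent
    population, the Poisson background, and the culture channels, plus
    one NMDA and one GABA slot (configured but unrouted by default).

    The quantum converts the integer efficacy (6-bit weight x 6-bit STP
    state, max 63*63 = 3969) to nS so that a full product delivers the
    population's maximum conductance g.
    """
    full = 63 * 63
    return [
        MultiSynapseParams(kind="AMPA", reversal=0.0, decay_tau=5.0,
                           quantum=recurrent_g / full),
        MultiSynapseParams(kind="AMPA", reversal=0.0, decay_tau=5.0,
                           quantum=background_g / full),
        MultiSynapseParams(kind="AMPA", reversal=0.0, decay_tau=5.0,
                           quantum=culture_g / full),
        MultiSynapseParams(kind="NMDA", reversal=0.0, decay_tau=100.0,
                           quantum=0.0, nmda_pwl=DEFAULT_NMDA_PWL),
        MultiSynapseParams(kind="GABA", reversal=-75.0, decay_tau=10.0,
                           quantum=0.0),
    ]


# synapse slot indices used by the default network wiring
SLOT_RECURRENT = 0
SLOT_BACKGROUND = 1
SLOT_CULTURE = 2


def default_config() -> dict:
    """Full default configuration as a plain dict (YAML-serializable)."""
    return {
        "neuron": dataclasses.asdict(NeuronParams()),
        "synapses": [dataclasses.asdict(s) for s in default_synapses()],
        "stp": dataclasses.asdict(
            STPParams(mode="depression", U=0.4, rec_tau=500.0)),
        "network": dataclasses.asdict(NetworkConfig()),
        "detector": dataclasses.asdict(DetectorParams()),
        "control": dataclasses.asdict(ControlGains()),
        "culture": dataclasses.asdict(CultureParams()),
        "estimator_tau": 250.0,  # s
        "stim_period": 2.0,      # s
        "loop_delay": 1.0,       # ms, culture <-> hardware transport
    }


def dump_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
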