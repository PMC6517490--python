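"""Build and simulate the full hardware system.

The deployed system is nine chips of 10 groups x 32 neuron elements,
i.e. 2880 neurons configured as a single excitatory recurrent
population (connection probability 0.007, ~20 recurrent targets per
neuron), driven by 25 Poisson background sources at 10 Hz (p = 0.3,
g = 20 nS) and, in coupled experiments, by the 60 culture channels.
Directed connectivity lives in an FPGA-style routing table whose
entries carry a 6-bit weight, the source STP channel and the target
multi-synapse slot.

:class:`HardwareNetwork` drives the numba stepping kernel chunk by
chunk, so the closed-loop orchestrator can interleave culture input and
burst detection with the simulation while keeping all dynamical state.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import events as ev
from .core import _membrane_bounds, quantize_stp
from .kernels import STP_MODE_CODES, run_chunk
from .params import (SLOT_BACKGROUND, SLOT_CULTURE, SLOT_RECURRENT,
                     MultiSynapseParams, NetworkConfig, NeuronParams,
                     PopulationSpec, STPParams, default_synapses)

__all__ = [
    "RoutingTable",
    "build_recurrent_network",
    "attach_culture_inputs",
    "generate_background",
    "HardwareNetwork",
    "simulate",
    "sample_readout",
    "audit",
    "population_rate",
    "RateTrace",
]


@dataclass
class RoutingTable:
    """Directed synaptic links, mirroring the FPGA routing table.

    Recurrent entries have a neuron source and a source STP channel
    (0..3); external entries (background sources, culture channels) have
    ``stp_channel = -1`` and transmit at the full 6-bit STP state (63).
    """

    n_neurons: int
    source: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    stp_channel: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    target: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    target_synapse: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    weight: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    external: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    max_entries_per_source: int = 3400

    def __len__(self) -> int:
        return len(self.source)

    def _validate(self) -> None:
        if len(self.weight) and (self.weight.min() < 0 or self.weight.max() > 63):
            raise ValueError("weights must be in the 6-bit range 0..63")
        if len(self.target) and (self.target.min() < 0
                                 or self.target.max() >= self.n_neurons):
            raise ValueError("target neuron id out of range")
        rec = ~self.external
        if rec.any():
            # capacity: 3400 entries per (neuron, STP output)
            key = self.source[rec] * 4 + self.stp_channel[rec]
            counts = np.bincount(key)
            if counts.size and counts.max() > self.max_entries_per_source:
                raise ValueError("per-source routing capacity (3400) exceeded")

    def append(self, source, stp_channel, target, target_synapse, weight,
               external: bool) -> None:
        n = len(source)
        self.source = np.concatenate([self.source, np.asarray(source, np.int64)])
        self.stp_channel = np.concatenate(
            [self.stp_channel, np.asarray(stp_channel, np.int64)])
        self.target = np.concatenate([self.target, np.asarray(target, np.int64)])
        self.target_synapse = np.concatenate(
            [self.target_synapse, np.asarray(target_synapse, np.int64)])
        self.weight = np.concatenate([self.weight, np.asarray(weight, np.int64)])
        self.external = np.concatenate(
            [self.external, np.full(n, external, dtype=bool)])
        self._validate()

    def out_degree(self, external: bool = False) -> np.ndarray:
        """Out-degree per source id (recurrent neurons by default)."""
        mask = self.external == external
        n = self.n_neurons if not external else int(
            self.source[mask].max() + 1) if mask.any() else 0
        return np.bincount(self.source[mask], minlength=n)


def build_recurrent_network(spec: PopulationSpec, seed: int,
                            n_neurons: int | None = None,
                            max_entries_per_source: int = 3400) -> RoutingTable:
    """Random recurrent connectivity: each ordered pair of distinct
    neurons is connected independently with probability p.  There are no
    self-connections (self-influence is the dedicated SFA conductance).
    Entries are assigned round-robin across the four source STP channels
    and all target the excitatory recurrent multi-synapse slot."""
    n = n_neurons if n_neurons is not None else spec.N
    rng = np.random.default_rng(seed)
    table = RoutingTable(n_neurons=n,
                         max_entries_per_source=max_entries_per_source)
    sources, targets = [], []
    others = np.empty(n - 1, np.int64)
    for i in range(n):
        k = rng.binomial(n - 1, spec.p)
        if k == 0:
            continue
        others[:i] = np.arange(i)
        others[i:] = np.arange(i + 1, n)
        tgt = rng.choice(others, size=k, replace=False)
        sources.append(np.full(k, i, np.int64))
        targets.append(np.sort(tgt))
    if sources:
        src = np.concatenate(sources)
        tgt = np.concatenate(targets)
    else:
        src = tgt = np.empty(0, np.int64)
    stp_ch = np.arange(len(src), dtype=np.int64) % 4  # round-robin
    table.append(src, stp_ch, tgt,
                 np.full(len(src), SLOT_RECURRENT, np.int64),
                 np.full(len(src), 63, np.int64), external=False)
    return table


def attach_culture_inputs(table: RoutingTable, n_channels: int,
                          coupling_fraction: float, weight: int,
                          seed: int, target_synapse: int = SLOT_CULTURE,
                          channel_offset: int = 0) -> RoutingTable:
    """Connect each external culture channel to a random subset of
    ``coupling_fraction * n_neurons`` target neurons."""
    if not 0.0 <= coupling_fraction <= 1.0:
        raise ValueError("coupling_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_targets = int(round(coupling_fraction * table.n_neurons))
    if n_targets == 0 or n_channels == 0:
        return table
    sources, targets = [], []
    for c in range(n_channels):
        tgt = rng.choice(table.n_neurons, size=n_targets, replace=False)
        sources.append(np.full(n_targets, channel_offset + c, np.int64))
        targets.append(np.sort(tgt))
    src = np.concatenate(sources)
    tgt = np.concatenate(targets)
    table.append(src, np.full(len(src), -1, np.int64), tgt,
                 np.full(len(src), target_synapse, np.int64),
                 np.full(len(src), weight, np.int64), external=True)
    return table


def generate_background(n_sources: int, rate: float, duration: float,
                        seed: int, t0: float = 0.0) -> pd.DataFrame:
    """Independent homogeneous Poisson spike trains for the background
    stimulus (times in ms on [t0, t0 + duration))."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    times, chans = [], []
    for s in range(n_sources):
        k = rng.poisson(rate * duration / 1000.0)
        ts = np.sort(rng.uniform(t0, t0 + duration, size=k))
        times.append(ts)
        chans.append(np.full(k, s, np.int64))
    if not times:
        return ev.empty_table()
    return ev.event_table(np.concatenate(times), np.concatenate(chans),
                          "background")


@dataclass
class RateTrace:
    """Population-average firing rate, normalized to a single neuron."""

    times_ms: np.ndarray  # bin start times
    rate_hz: np.ndarray   # Hz per neuron
    bin_ms: float


def population_rate(spike_times_ms, n_neurons: int, duration_ms: float,
                    bin_ms: float = 25.0, t0: float = 0.0) -> RateTrace:
    n_bins = max(1, int(math.ceil(duration_ms / bin_ms)))
    edges = t0 + np.arange(n_bins + 1) * bin_ms
    counts, _ = np.histogram(np.asarray(spike_times_ms, float), bins=edges)
    rate = counts / (n_neurons * bin_ms / 1000.0)
    return RateTrace(times_ms=edges[:-1], rate_hz=rate, bin_ms=bin_ms)


def audit(config: NetworkConfig) -> dict:
    """Structural counts of the configured system."""
    n = config.n_neurons
    return {
        "neurons": n,
        "multi_synapses": 5 * n,
        "stp_channels": 4 * n,
        "chips": config.n_chips,
        "groups_per_chip": config.groups_per_chip,
        "neurons_per_group": config.neurons_per_group,
    }


def neuron_address(neuron_id: int, config: NetworkConfig) -> tuple[int, int, int]:
    """(chip, group, index) bookkeeping address of a neuron id."""
    per_chip = config.groups_per_chip * config.neurons_per_group
    chip, rest = divmod(neuron_id, per_chip)
    group, idx = divmod(rest, config.neurons_per_group)
    return chip, group, idx


class HardwareNetwork:
    """Stateful simulator of the configured hardware system.

    All randomness (connectivity, background playback, readout subset)
    derives from ``seed``; a given seed and call sequence reproduces
    spike tables bitwise.
    """

    CHUNK_MS = 2000.0

    def __init__(self, config: NetworkConfig, seed: int,
                 neuron: NeuronParams | None = None,
                 synapses: list[MultiSynapseParams] | None = None,
                 stp: STPParams | None = None,
                 n_readout: int = 60):
        self.config = config
        self.seed = int(seed)
        self.neuron = neuron if neuron is not None else NeuronParams()
        self.synapses = synapses if synapses is not None else default_synapses(
            recurrent_g=config.recurrent.g,
            background_g=config.background.g,
            culture_g=config.culture_inputs.g)
        if len(self.synapses) != 5:
            raise ValueError("exactly 5 multi-synapse slots required")
        # default STP parameterization shared by all four channels
        self.stp = stp if stp is not None else STPParams(
            mode="depression", U=0.4, rec_tau=500.0)

        n = config.n_neurons
        self.n_neurons = n
        self.n_background = config.background.N

        # connectivity
        self.table = build_recurrent_network(
            config.recurrent, seed, n_neurons=n,
            max_entries_per_source=config.max_entries_per_source)
        # background sources occupy external channels 0..n_background-1
        attach_culture_inputs(
            self.table, config.background.N, config.background.p,
            weight=63, seed=seed + 1, target_synapse=SLOT_BACKGROUND,
            channel_offset=0)
        # culture channels follow
        attach_culture_inputs(
            self.table, config.culture_inputs.n_channels,
            config.culture_inputs.coupling_fraction, weight=63,
            seed=seed + 2, target_synapse=SLOT_CULTURE,
            channel_offset=config.background.N)

        self._build_csr()

        if n < n_readout:
            raise ValueError("network smaller than the readout subset")
        rng = np.random.default_rng(seed + 3)
        self.readout_neurons = np.sort(rng.choice(n, size=n_readout,
                                                  replace=False))
        self.reset()

    # -- construction helpers -------------------------------------------------

    def _build_csr(self) -> None:
        t = self.table
        rec = ~t.external
        order = np.argsort(t.source[rec], kind="stable")
        self._r_targets = t.target[rec][order]
        self._r_tsyn = t.target_synapse[rec][order]
        self._r_weights = t.weight[rec][order]
        self._r_stpch = t.stp_channel[rec][order]
        self._r_indptr = np.searchsorted(
            t.source[rec][order], np.arange(self.n_neurons + 1)).astype(np.int64)

        ext = t.external
        n_ext = self.n_background + self.config.culture_inputs.n_channels
        order = np.argsort(t.source[ext], kind="stable")
        self._x_targets = t.target[ext][order]
        self._x_tsyn = t.target_synapse[ext][order]
        # external inputs carry no source STP: full 6-bit state
        self._x_eff = (t.weight[ext][order] * 63).astype(np.int64)
        self._x_indptr = np.searchsorted(
            t.source[ext][order], np.arange(n_ext + 1)).astype(np.int64)
        self._n_ext = n_ext

        syn = self.synapses
        self._syn_e = np.array([s.reversal for s in syn])
        self._syn_quant = np.array([s.quantum for s in syn])
        self._syn_is_nmda = np.array([s.kind == "NMDA" for s in syn])
        nmda = [s for s in syn if s.kind == "NMDA"]
        pwl = nmda[0].nmda_pwl if nmda else ((-80.0, 0.0), (0.0, 1.0))
        self._pwl_v = np.array([v for v, _ in pwl])
        self._pwl_f = np.array([f for _, f in pwl])
        self._stp_mode = np.full(4, STP_MODE_CODES[self.stp.mode], np.int64)
        self._stp_uu = np.full(4, self.stp.U)
        self._stp_ftau = np.full(4, self.stp.facil_tau)
        self._stp_rtau = np.full(4, self.stp.rec_tau)
        self._v_lo, self._v_hi = _membrane_bounds(self.neuron, syn)

    def reset(self) -> None:
        """Restore the initial dynamical state and clock (connectivity
        and readout subset are kept)."""
        n = self.n_neurons
        p = self.neuron
        self.V = np.full(n, p.leak_reversal)
        self.refrac_until = np.full(n, -np.inf)
        self.g_sfa = np.zeros(n)
        self.g_syn = np.zeros((n, 5))
        self.stp_u = np.full((n, 4), self.stp.U)
        self.stp_x = np.ones((n, 4))
        self.last_spike = np.full(n, -1e30)
        self._pend_ids = np.zeros(n, np.int64)
        self._pend_q = np.zeros((n, 4), np.int64)
        self._n_pend = 0
        self.time_ms = 0.0
        self._bg_rng = np.random.default_rng(self.seed + 4)

    # -- simulation -----------------------------------------------------------

    def _background_chunk(self, t0: float, duration: float):
        """Background playback for one chunk; draws are consumed
        source-by-source from a dedicated generator."""
        cfg = self.config.background
        times, chans = [], []
        for s in range(cfg.N):
            k = self._bg_rng.poisson(cfg.rate * duration / 1000.0)
            ts = np.sort(self._bg_rng.uniform(t0, t0 + duration, size=k))
            times.append(ts)
            chans.append(np.full(k, s, np.int64))
        return np.concatenate(times), np.concatenate(chans)

    def run(self, duration_ms: float, culture_events: pd.DataFrame | None = None,
            background: bool = True):
        """Advance the network by ``duration_ms``, injecting the given
        culture spike events (absolute times, channel 0..59).

        Returns ``(spikes, rate)``: the hardware spike event table and
        the population-average rate trace (25-ms bins, Hz per neuron).
        """
        dt = self.neuron.dt
        t_start = self.time_ms
        n_steps_total = int(round(duration_ms / dt))
        if culture_events is not None and len(culture_events):
            cul_t = culture_events["time_ms"].to_numpy(float)
            cul_c = culture_events["channel"].to_numpy(np.int64) + self.n_background
        else:
            cul_t = np.empty(0)
            cul_c = np.empty(0, np.int64)

        all_times, all_ids = [], []
        done = 0
        while done < n_steps_total:
            steps = min(n_steps_total - done, int(round(self.CHUNK_MS / dt)))
            t0 = t_start + done * dt
            chunk_ms = steps * dt
            if background and self.config.background.rate > 0:
                bg_t, bg_c = self._background_chunk(t0, chunk_ms)
            else:
                bg_t, bg_c = np.empty(0), np.empty(0, np.int64)
            m = (cul_t >= t0) & (cul_t < t0 + chunk_ms)
            ext_t = np.concatenate([bg_t, cul_t[m]])
            ext_c = np.concatenate([bg_c, cul_c[m]])
            ext_step = np.floor((ext_t - t0) / dt).astype(np.int64)
            np.clip(ext_step, 0, steps - 1, out=ext_step)
            order = np.argsort(ext_step, kind="stable")
            ext_step = ext_step[order]
            ext_c = ext_c[order]

            cap = self.n_neurons * (int(chunk_ms / self.neuron.refractory) + 2)
            out_step = np.empty(cap, np.int64)
            out_id = np.empty(cap, np.int64)
            n_out, self._n_pend = run_chunk(
                self.V, self.refrac_until, self.g_sfa, self.g_syn,
                self.stp_u, self.stp_x, self.last_spike,
                self._pend_ids, self._pend_q, self._n_pend,
                dt, self.neuron.capacitance, self.neuron.leak_conductance,
                self.neuron.leak_reversal, self.neuron.threshold,
                self.neuron.reset, self.neuron.refractory,
                self.neuron.sfa_increment, math.exp(-dt / self.neuron.sfa_tau),
                self.neuron.sfa_reversal, self._v_lo, self._v_hi,
                self._syn_e, np.exp(-dt / np.array([s.decay_tau for s in self.synapses])),
                self._syn_quant, self._syn_is_nmda, self._pwl_v, self._pwl_f,
                self._stp_mode, self._stp_uu, self._stp_ftau, self._stp_rtau,
                self.stp.quant_levels,
                self._r_indptr, self._r_targets, self._r_tsyn,
                self._r_weights, self._r_stpch,
                ext_step, ext_c,
                self._x_indptr, self._x_targets, self._x_tsyn, self._x_eff,
                t0, steps, out_step, out_id)
            all_times.append(t0 + out_step[:n_out] * dt)
            all_ids.append(out_id[:n_out])
            done += steps

        self.time_ms = t_start + n_steps_total * dt
        times = np.concatenate(all_times) if all_times else np.empty(0)
        ids = np.concatenate(all_ids) if all_ids else np.empty(0, np.int64)
        spikes = ev.event_table(times, ids, "hardware")
        rate = population_rate(times, self.n_neurons, duration_ms,
                               bin_ms=25.0, t0=t_start)
        return spikes, rate

    def readout(self, spikes: pd.DataFrame) -> pd.DataFrame:
        """Restrict a hardware spike table to the fixed 60-neuron
        readout subset, re-indexed as channels 0..59."""
        return sample_readout(spikes, subset=self.readout_neurons)


def sample_readout(spikes: pd.DataFrame, n_channels: int = 60,
                   seed: int | None = None, n_neurons: int | None = None,
                   subset: np.ndarray | None = None) -> pd.DataFrame:
    """Sample the hardware activity by a fixed subset of neurons,
    mirroring the 60-electrode recording of the culture.  Either pass
    an explicit ``subset`` of neuron ids or a ``seed`` (+ ``n_neurons``)
    from which the subset is drawn."""
    if subset is None:
        if seed is None or n_neurons is None:
            raise ValueError("provide either subset or (seed, n_neurons)")
        if n_neurons < n_channels:
            raise ValueError("network smaller than the readout subset")
        rng = np.random.default_rng(seed)
        subset = np.sort(rng.choice(n_neurons, size=n_channels, replace=False))
    subset = np.asarray(subset)
    idx = {int(nid): c for c, nid in enumerate(subset)}
    mask = spikes["channel"].isin(idx).to_numpy() if len(spikes) else \
        np.empty(0, bool)
    out = spikes.loc[mask].copy()
    if len(out):
        out["channel"] = out["channel"].map(idx).astype(np.int64)
    return out.reset_index(drop=True)


def simulate(network: HardwareNetwork, duration_ms: float,
             external_events: pd.DataFrame | None = None):
    """Run a fresh simulation of ``duration_ms`` from the initial state
    (deterministic given the network's seed)."""
    network.reset()
    return network.run(duration_ms, culture_events=external_events)
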