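"""Synthetic stand-in for the cultured MEA network.

Generates 60-channel spike trains with the statistical structure the
closed-loop experiments rely on:

* a voltage pulse of amplitude A evokes a network burst with logistic
  probability 1 / (1 + exp(-(A - a50)/k)), modulated by a short
  post-burst recovery (1 - exp(-dt/tau)) after each burst;
* evoked-burst latency decreases linearly with amplitude
  (latency_base - latency_gain * (A - a50), floored), with jitter;
* electrodes are recruited in one of two template orders, selected by
  the recent controlled activity level — so sustained high- and
  low-level control exercise different propagation paths;
* sparse per-electrode background spikes and Poisson-timed spontaneous
  bursts are always present;
* a voltage-trace synthesizer plants stereotyped biphasic spike
  waveforms in Gaussian noise to exercise the threshold detector.

This is a statistical surrogate, not a biophysical model: it provides
the amplitude-probability, amplitude-latency and path-switching laws
that a cultured network exhibits under this stimulation protocol,
nothing below that level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import events as ev
from .params import CultureParams

__all__ = [
    "StimulusEvent",
    "CultureSurrogate",
    "respond_probability",
    "synth_voltage_trace",
]


@dataclass
class StimulusEvent:
    """A monophasic 200-us square voltage pulse on one electrode."""

    time: float       # ms
    amplitude: float  # mV
    electrode: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude <= 1150.0:
            raise ValueError("amplitude outside the device range [0, 1150] mV")


def respond_probability(amplitude: float, params: CultureParams) -> float:
    """Logistic probability that a pulse of ``amplitude`` mV evokes a
    network burst (monotone increasing, 0.5 at a50)."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    return 1.0 / (1.0 + math.exp(-(amplitude - params.a50) / params.k))


class CultureSurrogate:
    """Stateful surrogate culture.

    State carried across stimuli: the time of the last burst (for the
    post-burst recovery of responsiveness) and an exponentially-weighted
    estimate of the recent evoked-response rate, which selects the
    active recruitment template (high-activity vs low-activity path).
    """

    def __init__(self, params: CultureParams, seed: int,
                 templates: tuple | None = None):
        self.params = params
        self.rng = np.random.default_rng(seed)
        if templates is None:
            t_rng = np.random.default_rng(seed + 1)
            a = t_rng.permutation(params.n_electrodes)
            b = t_rng.permutation(params.n_electrodes)
            # force the leading (recruitment-order) electrodes apart
            while len(set(a[:5]) & set(b[:5])):
                b = t_rng.permutation(params.n_electrodes)
            templates = (a, b)
        self.templates = (np.asarray(templates[0]), np.asarray(templates[1]))
        self.last_burst_time = -np.inf  # ms
        self.level_estimate = 0.0       # recent evoked-response rate

    # -- internal pieces ------------------------------------------------------

    def _recovery_factor(self, t: float) -> float:
        tau = self.params.burst_refractory_tau
        if tau <= 0 or not np.isfinite(self.last_burst_time):
            return 1.0
        return 1.0 - math.exp(-(t - self.last_burst_time) / tau)

    def active_template(self) -> np.ndarray:
        high = self.level_estimate >= self.params.template_switch_threshold
        return self.templates[0] if high else self.templates[1]

    def _burst_events(self, start: float) -> tuple[np.ndarray, np.ndarray]:
        """One network burst beginning at ``start``: electrodes fire in
        template order with jitter, then scatter follow-up spikes."""
        p = self.params
        order = self.active_template()
        first = start + np.arange(len(order)) * p.recruit_spacing
        if p.recruit_jitter > 0:
            first = first + self.rng.normal(0.0, p.recruit_jitter, len(order))
        times = [first]
        chans = [order.astype(np.int64)]
        extra = self.rng.poisson(max(p.spikes_per_electrode - 1.0, 0.0),
                                 len(order))
        for e, k in zip(order, extra):
            if k:
                times.append(first[np.where(order == e)[0][0]]
                             + self.rng.uniform(0.5, p.burst_spread, k))
                chans.append(np.full(k, e, np.int64))
        return np.concatenate(times), np.concatenate(chans)

    def _background(self, t0: float, duration: float):
        p = self.params
        lam = p.background_rate * p.n_electrodes * duration / 1000.0
        k = self.rng.poisson(lam)
        t = np.sort(self.rng.uniform(t0, t0 + duration, k))
        c = self.rng.integers(0, p.n_electrodes, k)
        return t, c

    # -- public operations ----------------------------------------------------

    def generate_response(self, stim: StimulusEvent,
                          horizon: float = 2000.0) -> pd.DataFrame:
        """Culture activity on [stim.time, stim.time + horizon).

        With probability respond_probability(A) (times the post-burst
        recovery factor) the culture emits a direct-response volley
        within 0-15 ms and a network burst at the amplitude-dependent
        latency; otherwise only background spikes.  The evoked-response
        level estimate and last-burst time are updated.
        """
        p = self.params
        t = stim.time
        prob = respond_probability(stim.amplitude, p) * self._recovery_factor(t)
        responded = bool(self.rng.random() < prob)
        times, chans = self._background(t, horizon)
        parts_t, parts_c = [times], [chans]
        if responded:
            volley_t = t + self.rng.uniform(1.0, 14.0, p.direct_volley_size)
            volley_c = self.rng.choice(p.n_electrodes, p.direct_volley_size,
                                       replace=False)
            latency = p.latency_base - p.latency_gain * (stim.amplitude - p.a50)
            latency += self.rng.normal(0.0, p.latency_jitter)
            latency = max(latency, p.latency_floor)
            bt, bc = self._burst_events(t + latency)
            parts_t += [volley_t, bt]
            parts_c += [volley_c.astype(np.int64), bc]
            self.last_burst_time = t + latency
        # level estimate tracks the evoked-response rate (EWMA, level_tau s)
        dt_s = 2.0 if not hasattr(self, "_t_prev") else max(
            (t - self._t_prev) / 1000.0, 0.0)
        self._t_prev = t
        w = 1.0 - math.exp(-dt_s / p.level_tau)
        self.level_estimate = w * (1.0 if responded else 0.0) \
            + (1.0 - w) * self.level_estimate
        all_t = np.concatenate(parts_t)
        all_c = np.concatenate(parts_c)
        keep = (all_t >= t) & (all_t < t + horizon)
        return ev.event_table(all_t[keep], all_c[keep], "culture")

    def generate_spontaneous(self, duration: float,
                             t0: float = 0.0) -> pd.DataFrame:
        """Unstimulated activity: Poisson-timed spontaneous bursts at
        ``spontaneous_burst_rate`` plus per-electrode background."""
        if duration <= 0:
            raise ValueError("duration must be > 0")
        p = self.params
        times, chans = self._background(t0, duration)
        parts_t, parts_c = [times], [chans]
        n_bursts = self.rng.poisson(p.spontaneous_burst_rate * duration / 1000.0)
        starts = np.sort(self.rng.uniform(t0, t0 + duration, n_bursts))
        for s in starts:
            bt, bc = self._burst_events(s)
            parts_t.append(bt)
            parts_c.append(bc)
            self.last_burst_time = s
        all_t = np.concatenate(parts_t)
        all_c = np.concatenate(parts_c)
        keep = (all_t >= t0) & (all_t < t0 + duration)
        return ev.event_table(all_t[keep], all_c[keep], "culture")


def synth_voltage_trace(events: pd.DataFrame, params: CultureParams,
                        fs: float = 16000.0, duration_ms: float | None = None,
                        seed: int = 0) -> np.ndarray:
    """Per-channel voltage traces (uV): Gaussian noise of sd
    ``noise_sd`` with a stereotyped biphasic extracellular waveform
    (peak ``spike_amplitude`` x noise sd, dominant negative phase)
    inserted at each event time.  Returns array (n_electrodes, samples).
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    if duration_ms is None:
        duration_ms = float(events["time_ms"].max()) + 10.0 if len(events) else 10.0
    n_samp = int(round(duration_ms * fs / 1000.0))
    rng = np.random.default_rng(seed)
    traces = rng.normal(0.0, params.noise_sd,
                        (params.n_electrodes, n_samp))
    # biphasic waveform: 0.3 ms negative lobe, 0.5 ms positive rebound
    tw = np.arange(int(round(0.9e-3 * fs))) / fs * 1000.0  # ms
    neg = -np.exp(-0.5 * ((tw - 0.15) / 0.08) ** 2)
    pos = 0.35 * np.exp(-0.5 * ((tw - 0.55) / 0.15) ** 2)
    wave = (neg + pos) * params.spike_amplitude * params.noise_sd
    for t, c in zip(events["time_ms"].to_numpy(float),
                    events["channel"].to_numpy(np.int64)):
        i0 = int(round(t * fs / 1000.0))
        seg = wave[: max(0, min(len(wave), n_samp - i0))]
        if i0 >= 0 and len(seg):
            traces[c, i0:i0 + len(seg)] += seg
    return traces
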