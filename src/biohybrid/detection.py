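"""Detection chain: threshold spike detection, binned network-burst
(synchronization) detection, evoked/spontaneous classification, and
recruitment-order extraction.

Spikes are detected per channel at negative-going crossings of
-6 x SD of a 2-s calibration window, with a 6-ms refractory period.
Network bursts are threshold crossings of the population spike count in
25-ms bins (threshold: ceil of 25% of the active electrodes); a burst's
amplitude is the maximal bin count of its supra-threshold run and its
detection time the start of the first such bin.  A burst is evoked if
it falls 10-800 ms after the most recent stimulus (each stimulus claims
at most one burst).  The propagation path of an evoked burst is the
order of first spikes per electrode after a 15-ms direct-response
exclusion window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import DetectorParams

__all__ = [
    "BurstEvent",
    "detect_spikes",
    "detect_bursts",
    "classify_evoked",
    "recruitment_order",
    "propagation_delays",
    "active_electrodes",
    "bursts_to_frame",
]


@dataclass
class BurstEvent:
    """A detected network synchronization event."""

    detection_time: float          # ms, start of the first supra-threshold bin
    amplitude: int                 # max summed spikes in a 25-ms bin
    end_time: float                # ms, end of the last supra-threshold bin
    evoked: bool = False
    stimulus_time: float | None = None
    latency: float | None = None   # ms, detection_time - stimulus_time
    recruitment_order: tuple = ()  # ordered electrode ids
    truncated: bool = False        # fewer responding electrodes than depth


def detect_spikes(traces: np.ndarray, params: DetectorParams,
                  fs: float = 16000.0) -> pd.DataFrame:
    """Threshold-crossing spike detection on (n_channels, n_samples)
    voltage traces.

    The threshold of each channel is ``sd_multiple`` x the SD of its
    first ``calibration_window`` ms; events are negative-going
    crossings, with subsequent crossings inside ``refractory`` ms
    suppressed.  Returns an event table.
    """
    traces = np.atleast_2d(np.asarray(traces, float))
    n_cal = int(round(params.calibration_window * fs / 1000.0))
    if traces.shape[1] < n_cal:
        raise ValueError("trace shorter than the calibration window")
    refrac_samp = int(round(params.refractory * fs / 1000.0))
    times, chans = [], []
    for c in range(traces.shape[0]):
        x = traces[c]
        thr = -params.sd_multiple * float(np.std(x[:n_cal]))
        if thr == 0.0:
            continue
        crossing = np.flatnonzero((x[1:] < thr) & (x[:-1] >= thr)) + 1
        last = -refrac_samp - 1
        for i in crossing:
            if i - last > refrac_samp:
                times.append(i / fs * 1000.0)
                chans.append(c)
                last = i
    from . import events as ev
    return ev.event_table(times, chans, "culture")


def active_electrodes(events: pd.DataFrame, n_electrodes: int,
                      window_ms: float | None = None) -> int:
    """Number of active electrodes (>= 1 spike within the calibration
    epoch, or the whole table if no window is given)."""
    df = events
    if window_ms is not None and len(df):
        df = df[df["time_ms"] < window_ms]
    return int(df["channel"].nunique())


def detect_bursts(events: pd.DataFrame, n_active_electrodes: int,
                  params: DetectorParams, t0: float = 0.0,
                  t_end: float | None = None) -> list[BurstEvent]:
    """Binned burst detection on an event table.

    Bins of ``bin_width`` ms are anchored at ``t0`` (recording start);
    a burst spans a maximal run of bins whose summed spike count is
    >= ceil(active_fraction x n_active_electrodes).
    """
    if n_active_electrodes < 1:
        raise ValueError("n_active_electrodes must be >= 1")
    threshold = math.ceil(params.active_fraction * n_active_electrodes)
    if not len(events):
        return []
    t = events["time_ms"].to_numpy(float)
    if t_end is None:
        t_end = t.max() + params.bin_width
    n_bins = max(1, int(math.ceil((t_end - t0) / params.bin_width)))
    edges = t0 + np.arange(n_bins + 1) * params.bin_width
    counts, _ = np.histogram(t, bins=edges)
    supra = counts >= threshold
    bursts: list[BurstEvent] = []
    i = 0
    while i < n_bins:
        if supra[i]:
            j = i
            while j + 1 < n_bins and supra[j + 1]:
                j += 1
            bursts.append(BurstEvent(
                detection_time=float(edges[i]),
                amplitude=int(counts[i:j + 1].max()),
                end_time=float(edges[j + 1])))
            i = j + 1
        else:
            i += 1
    return bursts


def classify_evoked(bursts: list[BurstEvent], stimuli,
                    params: DetectorParams) -> list[BurstEvent]:
    """Mark bursts evoked by the most recent stimulus.

    A burst is evoked iff its detection time lies in
    (stim + evoked_window[0], stim + evoked_window[1]] for the most
    recent preceding stimulus; each stimulus claims at most the first
    such burst (the binary response indicator s_i).  Latency is filled
    for evoked bursts.  ``stimuli`` is a time-sorted sequence of
    stimulus times (ms) or of objects with a ``time`` attribute.
    """
    stim_times = np.array([getattr(s, "time", s) for s in stimuli], float)
    if len(stim_times) and np.any(np.diff(stim_times) < 0):
        raise ValueError("stimuli must be time-sorted")
    lo, hi = params.evoked_window
    claimed: set[int] = set()
    out = []
    for b in sorted(bursts, key=lambda b: b.detection_time):
        evoked, stim_t, latency = False, None, None
        if len(stim_times):
            k = int(np.searchsorted(stim_times, b.detection_time,
                                    side="right")) - 1
            if k >= 0 and k not in claimed:
                dt = b.detection_time - stim_times[k]
                if lo < dt <= hi:
                    evoked, stim_t, latency = True, float(stim_times[k]), dt
                    claimed.add(k)
        out.append(BurstEvent(
            detection_time=b.detection_time, amplitude=b.amplitude,
            end_time=b.end_time, evoked=evoked, stimulus_time=stim_t,
            latency=latency, recruitment_order=b.recruitment_order,
            truncated=b.truncated))
    return out


def recruitment_order(events: pd.DataFrame, burst: BurstEvent,
                      params: DetectorParams, depth: int = 5) -> BurstEvent:
    """Propagation path of an evoked burst: electrodes ordered by their
    first spike after ``stimulus_time + direct_exclusion`` (direct
    electrical responses excluded), truncated to ``depth``.  Ties are
    broken by ascending electrode id.  Returns the burst with its
    ``recruitment_order`` filled (``truncated`` set when fewer than
    ``depth`` electrodes responded)."""
    if burst.stimulus_time is None:
        raise ValueError("recruitment order requires an associated stimulus")
    start = burst.stimulus_time + params.direct_exclusion
    df = events[(events["time_ms"] > start)
                & (events["time_ms"] <= burst.end_time)]
    order: list[int] = []
    if len(df):
        firsts = df.groupby("channel")["time_ms"].min()
        ranked = sorted(firsts.items(), key=lambda kv: (kv[1], kv[0]))
        order = [int(c) for c, _ in ranked[:depth]]
    burst.recruitment_order = tuple(order)
    burst.truncated = len(order) < depth
    return burst


def propagation_delays(events: pd.DataFrame, order,
                       after_ms: float | None = None) -> list[float]:
    """Successive differences of the first-spike times of the ordered
    electrodes (|order| - 1 inter-spike intervals of the recruitment)."""
    order = list(order)
    if not order:
        raise ValueError("order must be non-empty")
    df = events
    if after_ms is not None:
        df = df[df["time_ms"] > after_ms]
    firsts = df.groupby("channel")["time_ms"].min()
    t = [float(firsts[c]) for c in order]
    return [t[i + 1] - t[i] for i in range(len(t) - 1)]


def bursts_to_frame(bursts: list[BurstEvent]) -> pd.DataFrame:
    """Serialize a burst list to a DataFrame (one row per burst)."""
    return pd.DataFrame([{
        "detection_time_ms": b.detection_time,
        "amplitude": b.amplitude,
        "end_time_ms": b.end_time,
        "evoked": b.evoked,
        "stimulus_time_ms": b.stimulus_time,
        "latency_ms": b.latency,
        "recruitment_order": ",".join(str(c) for c in b.recruitment_order),
    } for b in bursts])
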