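"""Post-hoc analysis of coupled runs.

Covers the propagation-path similarity analysis (pairwise Levenshtein
distance between the first-five recruitment orders of consecutive
evoked bursts), per-activity-level burst statistics with a Welch t
comparison, and population-spike detection on rate traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import RateTrace

__all__ = [
    "levenshtein",
    "path_similarity_matrix",
    "PathDistanceMatrix",
    "LevelBlock",
    "level_statistics",
    "detect_population_spikes",
]


def levenshtein(a, b) -> int:
    """Edit distance between two id sequences (unit-cost insertions,
    deletions and substitutions).  Identical orders give 0; length-5
    orders with no ids in common give 5."""
    a, b = list(a), list(b)
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


@dataclass
class PathDistanceMatrix:
    """Pairwise Levenshtein distances between recruitment orders, in
    chronological order (the Fig-style similarity image)."""

    orders: list
    distances: np.ndarray
    times: np.ndarray | None = None  # chronological timestamps, if known

    def block_means(self, labels) -> dict:
        """Mean distance within and between groups of orders.

        ``labels`` assigns a hashable group label to each order; the
        diagonal is excluded.  Returns {"within": .., "between": ..}.
        """
        labels = np.asarray(labels)
        d = self.distances
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(len(labels), dtype=bool)
        within = d[same & off]
        between = d[~same]
        return {"within": float(within.mean()) if within.size else math.nan,
                "between": float(between.mean()) if between.size else math.nan}


def path_similarity_matrix(orders, depth: int = 5,
                           times=None) -> PathDistanceMatrix:
    """Pairwise Levenshtein distance matrix across all recruitment
    orders (each truncated to ``depth``), chronology preserved."""
    orders = [tuple(o)[:depth] for o in orders]
    n = len(orders)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = levenshtein(orders[i], orders[j])
    return PathDistanceMatrix(orders=orders, distances=d,
                              times=None if times is None else np.asarray(times))


@dataclass
class LevelBlock:
    """One controlled activity-level epoch of a two-level experiment."""

    label: str    # "high" | "low"
    start: float  # s
    end: float    # s
    bursts: dict = field(default_factory=dict)  # side -> list of BurstEvent

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("require start < end")


def _block_features(bursts, start_s: float, end_s: float) -> dict:
    lat = np.array([b.latency for b in bursts if b.latency is not None])
    amp = np.array([b.amplitude for b in bursts], float)
    dur_s = end_s - start_s
    return {
        "n_bursts": len(bursts),
        "burst_rate_hz": len(bursts) / dur_s,
        "latency_mean_ms": float(lat.mean()) if lat.size else math.nan,
        "latency_sd_ms": float(lat.std(ddof=1)) if lat.size > 1 else math.nan,
        "amplitude_mean": float(amp.mean()) if amp.size else math.nan,
        "amplitude_sd": float(amp.std(ddof=1)) if amp.size > 1 else math.nan,
        "_latencies": lat,
        "_amplitudes": amp,
    }


def level_statistics(blocks: list[LevelBlock]) -> pd.DataFrame:
    """Per-block, per-side burst statistics plus a Welch two-sample t
    comparison of each feature between the first two non-empty blocks
    of different labels.

    Returns a tidy frame with one row per (block, side); the Welch
    t statistic and p-value for latency and amplitude are attached to
    the frame's ``attrs["welch"]`` as {side: {feature: (t, p)}}.
    """
    rows = []
    per_side: dict = {}
    for blk in blocks:
        for side, bursts in blk.bursts.items():
            if not bursts:
                rows.append({"label": blk.label, "side": side,
                             "excluded_empty": True})
                continue
            feats = _block_features(bursts, blk.start, blk.end)
            per_side.setdefault(side, {}).setdefault(blk.label, feats)
            row = {k: v for k, v in feats.items() if not k.startswith("_")}
            row.update({"label": blk.label, "side": side,
                        "excluded_empty": False})
            rows.append(row)
    welch = {}
    for side, by_label in per_side.items():
        labels = list(by_label)
        if len(labels) < 2:
            continue
        a, b = by_label[labels[0]], by_label[labels[1]]
        welch[side] = {}
        for feat in ("_latencies", "_amplitudes"):
            x, y = a[feat], b[feat]
            if len(x) > 1 and len(y) > 1:
                t, p = stats.ttest_ind(x, y, equal_var=False)
                welch[side][feat.strip("_")] = (float(t), float(p))
    df = pd.DataFrame(rows)
    df.attrs["welch"] = welch
    return df


def detect_population_spikes(trace: RateTrace, ratio: float = 5.0,
                             min_rate_hz: float = 10.0,
                             n_iter: int = 5) -> dict:
    """Identify discrete population spikes in a population-rate trace.

    The baseline is estimated iteratively as the mean rate of non-peak
    bins; peak bins must exceed both ``ratio`` x baseline and the
    absolute synchronization floor ``min_rate_hz`` (10 Hz per neuron in
    a 25-ms bin corresponds to a quarter of the population firing
    together, keeping stray single spikes on a silent background from
    counting as events).  Contiguous supra-threshold runs are merged
    into single population spikes.  Returns peak times, per-peak
    amplitudes, the baseline, and the peak-to-baseline ratio."""
    r = np.asarray(trace.rate_hz, float)
    baseline = r.mean() if r.size else 0.0
    peaks = np.zeros(len(r), dtype=bool)
    for _ in range(n_iter):
        thr = max(ratio * baseline, min_rate_hz)
        peaks = r > thr
        rest = r[~peaks]
        new_base = rest.mean() if rest.size else baseline
        if math.isclose(new_base, baseline, rel_tol=1e-9, abs_tol=1e-12):
            break
        baseline = new_base
    peak_times, peak_amps = [], []
    i = 0
    while i < len(r):
        if peaks[i]:
            j = i
            while j + 1 < len(r) and peaks[j + 1]:
                j += 1
            k = i + int(np.argmax(r[i:j + 1]))
            peak_times.append(float(trace.times_ms[k]))
            peak_amps.append(float(r[k]))
            i = j + 1
        else:
            i += 1
    peak_amps = np.array(peak_amps)
    return {
        "n_peaks": len(peak_times),
        "peak_times_ms": np.array(peak_times),
        "peak_rates_hz": peak_amps,
        "baseline_hz": float(baseline),
        "min_peak_ratio": float(peak_amps.min() / baseline)
        if len(peak_amps) and baseline > 0 else math.inf if len(peak_amps) else 0.0,
    }
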