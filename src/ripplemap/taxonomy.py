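"""Memory vs non-memory ripple classification and content comparison.

A post-training ripple is memory-associated when the memory assembly's
activation strength exceeds median + 2 s.d. in any bin intersecting
(onset, onset + 150 ms]; the rest are non-memory.  Content differences are
quantified per dCA1 unit by |M-N|/(M+N) rate-contrast scores (with
split-half controls), an amplitude-threshold selectivity index, and
up/none/down grouping of peri-ripple response differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.stats import ranksums

from .core import ActivationTrace, RippleEvent, SpikeData
from .memory import (
    ModulationResult,
    modulation_from_z,
    peri_event_histogram,
    zscore_against_baseline,
)

log = logging.getLogger(__name__)


def classify_ripples(
    ripples: Sequence[RippleEvent],
    memory_trace: Optional[ActivationTrace],
    window_ms: float = 150.0,
    threshold_sd: float = 2.0,
) -> list[RippleEvent]:
    """Label each ripple memory/non_memory from the memory-assembly trace.

    Threshold = median + ``threshold_sd`` x s.d. of the activation strength;
    a ripple is memory-associated when any supra-threshold bin intersects
    the half-open window (onset, onset + window_ms].  With no memory
    assembly available all ripples stay unlabeled (warning).
    """
    if memory_trace is None:
        log.warning("no memory assembly supplied; ripples left unlabeled")
        return [replace(r, label="unlabeled") for r in ripples]
    s = memory_trace.strength
    thr = float(np.median(s)) + threshold_sd * float(s.std())
    hi = np.flatnonzero(s > thr)
    bin_s = memory_trace.bin_s
    starts = memory_trace.t0 + hi * bin_s  # supra-threshold bin starts
    w = window_ms / 1000.0

    out = []
    for r in ripples:
        # bin [b, b+bin_s) intersects (onset, onset+w] iff b < onset+w and b+bin_s > onset
        lo = np.searchsorted(starts, r.onset_s - bin_s, side="right")
        hit = False
        for b in starts[lo:]:
            if b >= r.onset_s + w:
                break
            if b + bin_s > r.onset_s:
                hit = True
                break
        out.append(replace(r, label="memory" if hit else "non_memory"))
    return out


@dataclass
class RipplePropertyComparison:
    median_amplitude: dict[str, float]
    iqr_amplitude: dict[str, tuple[float, float]]
    median_duration_ms: dict[str, float]
    iqr_duration_ms: dict[str, tuple[float, float]]
    p_amplitude: Optional[float]
    p_duration: Optional[float]
    n: dict[str, int]


def compare_ripple_properties(
    labeled: Sequence[RippleEvent], min_per_class: int = 5
) -> RipplePropertyComparison:
    """Medians/IQRs and two-sided rank-sum p for amplitude and duration,
    memory vs non-memory.  With < ``min_per_class`` events in either class
    the p-values are None (summaries still reported)."""
    amp = {"memory": [], "non_memory": []}
    dur = {"memory": [], "non_memory": []}
    for r in labeled:
        if r.label in amp:
            amp[r.label].append(r.amplitude_sd)
            dur[r.label].append(r.duration_ms)

    def summarize(d):
        med, iqr = {}, {}
        for k, v in d.items():
            arr = np.asarray(v)
            if arr.size:
                med[k] = float(np.median(arr))
                iqr[k] = (float(np.percentile(arr, 25)), float(np.percentile(arr, 75)))
            else:
                med[k] = float("nan")
                iqr[k] = (float("nan"), float("nan"))
        return med, iqr

    med_a, iqr_a = summarize(amp)
    med_d, iqr_d = summarize(dur)
    ok = all(len(v) >= min_per_class for v in amp.values())
    p_a = float(ranksums(amp["memory"], amp["non_memory"]).pvalue) if ok else None
    p_d = float(ranksums(dur["memory"], dur["non_memory"]).pvalue) if ok else None
    return RipplePropertyComparison(
        median_amplitude=med_a,
        iqr_amplitude=iqr_a,
        median_duration_ms=med_d,
        iqr_duration_ms=iqr_d,
        p_amplitude=p_a,
        p_duration=p_d,
        n={k: len(v) for k, v in amp.items()},
    )


def _pooled_rate(
    spike_times: np.ndarray, onsets: np.ndarray, window_ms: float
) -> float:
    """Total spikes within +/-window of onsets over total window time."""
    w = window_ms / 1000.0
    ts = np.sort(spike_times)
    n = 0
    for o in onsets:
        lo, hi = np.searchsorted(ts, [o - w, o + w])
        n += hi - lo
    total = 2 * w * len(onsets)
    return n / total if total > 0 else float("nan")


def contrast_score(a: float, b: float) -> float:
    """|a - b| / (a + b); NaN when both are zero."""
    if a + b == 0:
        return float("nan")
    return abs(a - b) / (a + b)


@dataclass
class RippleContentScores:
    unit_id: int
    m_hz: float
    n_hz: float
    m_n: float
    m1_m2: float
    n1_n2: float
    group: str  # up | none | down


def _split_halves(onsets: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random equal halves; with an odd count one random event is dropped."""
    idx = rng.permutation(onsets.size)
    if onsets.size % 2:
        idx = idx[:-1]
    half = idx.size // 2
    return onsets[idx[:half]], onsets[idx[half:]]


def response_difference_group(
    spike_times: np.ndarray,
    memory_onsets: np.ndarray,
    non_memory_onsets: np.ndarray,
    window_ms: float = 500.0,
    bin_ms: float = 5.0,
    smooth_sd_ms: float = 15.0,
    baseline_ms: tuple[float, float] = (300.0, 500.0),
    z_threshold: float = 3.3,
    n_consecutive: int = 3,
    test_window_ms: float = 150.0,
) -> ModulationResult:
    """Up/none/down grouping of the (memory - non-memory) peri-ripple rate
    difference, z-scored against baseline lags, using the same
    consecutive-bin rule as ripple modulation."""
    kw = dict(window_ms=window_ms, bin_ms=bin_ms, smooth_sd_ms=smooth_sd_ms,
              baseline_ms=baseline_ms)
    peh_m = peri_event_histogram(spike_times, memory_onsets, **kw)
    peh_n = peri_event_histogram(spike_times, non_memory_onsets, **kw)
    diff = peh_m.smoothed_hz - peh_n.smoothed_hz
    diff_raw = peh_m.rate_hz - peh_n.rate_hz
    z, _, _ = zscore_against_baseline(
        diff,
        peh_m.lag_centers_ms,
        baseline_ms,
        raw=diff_raw,
        sigma_bins=smooth_sd_ms / bin_ms,
    )
    return modulation_from_z(
        z, peh_m.lag_centers_ms, z_threshold, n_consecutive, test_window_ms
    )


def firing_difference_scores(
    dca1_spikes: SpikeData,
    labeled: Sequence[RippleEvent],
    split_seed: int = 0,
    window_ms: float = 100.0,
) -> list[RippleContentScores]:
    """Per-unit M|N, M1|M2, N1|N2 contrast scores plus up/none/down group.

    Rates are pooled (total spikes / total window time) in +/-``window_ms``
    of ripple onsets.  Units silent in all windows are excluded.
    """
    mem = np.array([r.onset_s for r in labeled if r.label == "memory"])
    non = np.array([r.onset_s for r in labeled if r.label == "non_memory"])
    if mem.size < 2 or non.size < 2:
        raise ValueError("need >= 2 ripples in each class")
    rng = np.random.default_rng(split_seed)
    out = []
    for uid in dca1_spikes.unit_ids("dCA1"):
        ts = dca1_spikes.times[uid]
        m = _pooled_rate(ts, mem, window_ms)
        n = _pooled_rate(ts, non, window_ms)
        if m + n == 0:
            log.warning("unit %d silent in all ripple windows; excluded", uid)
            continue
        m1, m2 = _split_halves(mem, rng)
        n1, n2 = _split_halves(non, rng)
        group = response_difference_group(ts, mem, non)
        out.append(
            RippleContentScores(
                unit_id=uid,
                m_hz=m,
                n_hz=n,
                m_n=contrast_score(m, n),
                m1_m2=contrast_score(
                    _pooled_rate(ts, m1, window_ms), _pooled_rate(ts, m2, window_ms)
                ),
                n1_n2=contrast_score(
                    _pooled_rate(ts, n1, window_ms), _pooled_rate(ts, n2, window_ms)
                ),
                group=group.direction,
            )
        )
    return out


def selectivity_index(
    labeled: Sequence[RippleEvent], threshold_sd: float
) -> Optional[float]:
    """S = M/(M+N) where M (N) is the percentage of memory (non-memory)
    ripples whose amplitude exceeds ``threshold_sd``.  None when no ripple
    in either class exceeds the threshold, or a class is empty."""
    mem = [r.amplitude_sd for r in labeled if r.label == "memory"]
    non = [r.amplitude_sd for r in labeled if r.label == "non_memory"]
    if not mem or not non:
        raise ValueError("both ripple classes must be non-empty")
    m = 100.0 * np.mean(np.asarray(mem) > threshold_sd)
    n = 100.0 * np.mean(np.asarray(non) > threshold_sd)
    if m + n == 0:
        return None
    return float(m / (m + n))


@dataclass
class UnitRippleProfile:
    unit_id: int
    z_memory: np.ndarray
    z_non_memory: np.ndarray
    group: str
    peak_rate_memory_hz: float
    peak_rate_non_memory_hz: float
    peak_latency_memory_ms: float
    peak_latency_non_memory_ms: float


def population_peri_ripple_profiles(
    dca1_spikes: SpikeData,
    labeled: Sequence[RippleEvent],
    window_ms: float = 500.0,
    bin_ms: float = 5.0,
    smooth_sd_ms: float = 15.0,
) -> list[UnitRippleProfile]:
    """Per-unit smoothed z-traces around each ripple class, the up/none/down
    group from the class difference, and per-class peak rate/latency."""
    mem = np.array([r.onset_s for r in labeled if r.label == "memory"])
    non = np.array([r.onset_s for r in labeled if r.label == "non_memory"])
    if mem.size == 0 or non.size == 0:
        raise ValueError("need ripples in both classes")
    kw = dict(window_ms=window_ms, bin_ms=bin_ms, smooth_sd_ms=smooth_sd_ms)
    out = []
    for uid in dca1_spikes.unit_ids("dCA1"):
        ts = dca1_spikes.times[uid]
        peh_m = peri_event_histogram(ts, mem, **kw)
        peh_n = peri_event_histogram(ts, non, **kw)
        group = response_difference_group(ts, mem, non, **kw)
        km = int(np.argmax(peh_m.smoothed_hz))
        kn = int(np.argmax(peh_n.smoothed_hz))
        out.append(
            UnitRippleProfile(
                unit_id=uid,
                z_memory=peh_m.z,
                z_non_memory=peh_n.z,
                group=group.direction,
                peak_rate_memory_hz=float(peh_m.smoothed_hz[km]),
                peak_rate_non_memory_hz=float(peh_n.smoothed_hz[kn]),
                peak_latency_memory_ms=float(peh_m.lag_centers_ms[km]),
                peak_latency_non_memory_ms=float(peh_n.lag_centers_ms[kn]),
            )
        )
    return out
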