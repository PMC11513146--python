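"""Ripple-band event detection from LFP, offline and as a causal stream.

Offline detection band-passes 100-250 Hz with a zero-phase FIR filter,
takes the Hilbert-magnitude envelope, smooths it with a 4-ms Gaussian and
thresholds the z-scored envelope (5 s.d. peak, 1 s.d. boundaries, >20 ms
duration).  The streaming variant uses a causal Butterworth filter and
emits triggers on first threshold crossing, for closed-loop simulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .core import Epoch, LfpTrace, RippleEvent

log = logging.getLogger(__name__)

RIPPLE_BAND = (100.0, 250.0)


def _bandpass_fir(x: np.ndarray, fs: float, band=RIPPLE_BAND) -> np.ndarray:
    numtaps = int(0.25 * fs) | 1  # ~250 ms, odd: ~13 Hz transition band
    taps = signal.firwin(numtaps, band, pass_zero=False, fs=fs)
    return signal.filtfilt(taps, 1.0, x)


def ripple_envelope(
    lfp: LfpTrace,
    band: tuple[float, float] = RIPPLE_BAND,
    smooth_sd_ms: float = 4.0,
    method: str = "hilbert",
) -> np.ndarray:
    """Smoothed ripple-band envelope, same length as the input.

    Parameters
    ----------
    method
        ``"hilbert"`` (magnitude of the analytic signal, default) or
        ``"rectify"`` (absolute value of the filtered trace).
    """
    x = lfp.samples
    bad = np.flatnonzero(~np.isfinite(x))
    if bad.size:
        raise ValueError(f"non-finite LFP sample at index {bad[0]}")
    filt = _bandpass_fir(x, lfp.fs, band)
    if method == "hilbert":
        env = np.abs(signal.hilbert(filt))
    elif method == "rectify":
        env = np.abs(filt)
    else:
        raise ValueError(f"unknown envelope method {method!r}")
    sigma = smooth_sd_ms / 1000.0 * lfp.fs
    return gaussian_filter1d(env, sigma)


def envelope_stats(
    envelope: np.ndarray, mask: Optional[np.ndarray] = None
) -> tuple[float, float]:
    """Mean and s.d. of the envelope, optionally over a sample mask."""
    env = envelope if mask is None else envelope[mask]
    if env.size == 0:
        raise ValueError("no samples to compute envelope statistics")
    return float(env.mean()), float(env.std())


def detect_ripples(
    envelope: np.ndarray,
    fs: float,
    peak_threshold_sd: float = 5.0,
    boundary_sd: float = 1.0,
    min_duration_ms: float = 20.0,
    t0: float = 0.0,
    stats: Optional[tuple[float, float]] = None,
    stats_mask: Optional[np.ndarray] = None,
) -> list[RippleEvent]:
    """Threshold the z-scored envelope into discrete ripple events.

    A candidate is a contiguous run above ``boundary_sd`` whose maximum
    exceeds ``peak_threshold_sd``; onset/offset are the boundary crossings,
    so overlapping candidates are merged by construction (the run keeps the
    larger peak).  Events whose duration does not exceed ``min_duration_ms``
    are dropped.  ``stats`` (mean, sd) or ``stats_mask`` restrict the
    normalization, e.g. to slow-wave-sleep samples.
    """
    if peak_threshold_sd <= boundary_sd:
        raise ValueError("peak_threshold_sd must exceed boundary_sd")
    envelope = np.asarray(envelope, dtype=float)
    if envelope.size == 0:
        return []
    if stats is None:
        stats = envelope_stats(envelope, stats_mask)
    mean, sd = stats
    if sd <= 0:
        return []
    z = (envelope - mean) / sd

    above = z > boundary_sd
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        stops = np.r_[stops, above.size]

    events = []
    for i0, i1 in zip(starts, stops):
        seg = z[i0:i1]
        k = int(np.argmax(seg))
        if seg[k] < peak_threshold_sd:
            continue
        dur_ms = (i1 - i0) / fs * 1000.0
        if dur_ms <= min_duration_ms:
            continue
        events.append(
            RippleEvent(
                onset_s=t0 + i0 / fs,
                peak_s=t0 + (i0 + k) / fs,
                offset_s=t0 + i1 / fs,
                amplitude_sd=float(seg[k]),
            )
        )
    return events


@dataclass
class TriggerResult:
    """Output of the causal closed-loop trigger simulation."""

    trigger_times: np.ndarray  # stimulation onset times (incl. delay)
    detection_times: np.ndarray  # causal threshold-crossing times
    trigger_sd: float
    delay_ms: float
    pulse_ms: float


def streaming_trigger(
    lfp: LfpTrace,
    trigger_sd: float = 8.0,
    pulse_ms: float = 150.0,
    delay_ms: float = 0.0,
    refractory_ms: float = 200.0,
    smooth_ms: float = 4.0,
    stats: Optional[tuple[float, float]] = None,
) -> TriggerResult:
    """Causal ripple trigger: 4th-order Butterworth band-pass, rectified
    envelope with a causal moving-average, threshold at ``trigger_sd``.

    No future samples are used by the filters; the reported detection time
    is the first sample at which the causal envelope crosses threshold.
    ``delay_ms`` is added to every trigger (delayed-stimulation control).
    """
    sos = signal.butter(4, RIPPLE_BAND, btype="bandpass", fs=lfp.fs, output="sos")
    filt = signal.sosfilt(sos, lfp.samples)
    n_avg = max(1, int(round(smooth_ms / 1000.0 * lfp.fs)))
    env = signal.lfilter(np.ones(n_avg) / n_avg, 1.0, np.abs(filt))
    if stats is None:
        stats = float(env.mean()), float(env.std())
    mean, sd = stats
    thr = mean + trigger_sd * sd

    crossings = np.flatnonzero((env[1:] >= thr) & (env[:-1] < thr)) + 1
    refractory_n = int(round(refractory_ms / 1000.0 * lfp.fs))
    kept = []
    last = -np.inf
    for c in crossings:
        if c - last >= refractory_n:
            kept.append(c)
            last = c
    det = lfp.t0 + np.asarray(kept, dtype=float) / lfp.fs
    return TriggerResult(
        trigger_times=det + delay_ms / 1000.0,
        detection_times=det,
        trigger_sd=trigger_sd,
        delay_ms=delay_ms,
        pulse_ms=pulse_ms,
    )


def trigger_latencies(
    trigger_times: np.ndarray,
    reference_onsets: np.ndarray,
    max_lag_s: float = 0.5,
) -> np.ndarray:
    """Latency of each trigger after the nearest preceding reference onset.

    Triggers with no reference within ``max_lag_s`` before them are dropped.
    """
    refs = np.sort(np.asarray(reference_onsets, dtype=float))
    out = []
    for t in np.asarray(trigger_times, dtype=float):
        i = np.searchsorted(refs, t, side="right") - 1
        if i >= 0 and t - refs[i] <= max_lag_s:
            out.append(t - refs[i])
    return np.asarray(out)


def detect_sws(
    lfp: LfpTrace,
    ripples: Sequence[RippleEvent],
    window_s: float = 2.0,
    min_duration_s: float = 10.0,
    median_factor: float = 0.5,
    delta_band: tuple[float, float] = (1.0, 4.0),
) -> list[tuple[float, float]]:
    """Heuristic slow-wave-sleep intervals: delta-band power above a fraction
    of its session median, with at least one ripple event inside.

    This is a declared heuristic (no published algorithm): delta power is
    averaged in ``window_s`` windows; windows above ``median_factor`` x the
    session median are merged into candidate intervals; candidates shorter
    than ``min_duration_s`` or containing no ripple are discarded.
    """
    sos = signal.butter(2, delta_band, btype="bandpass", fs=lfp.fs, output="sos")
    delta = signal.sosfiltfilt(sos, lfp.samples)
    power = delta**2
    n_win = max(1, int(round(window_s * lfp.fs)))
    n_full = power.size // n_win
    if n_full == 0:
        return []
    win_power = power[: n_full * n_win].reshape(n_full, n_win).mean(axis=1)
    thr = median_factor * float(np.median(win_power))
    active = win_power > thr

    ripple_peaks = np.asarray([r.peak_s for r in ripples])
    intervals = []
    i = 0
    while i < n_full:
        if not active[i]:
            i += 1
            continue
        j = i
        while j < n_full and active[j]:
            j += 1
        start = lfp.t0 + i * n_win / lfp.fs
        stop = lfp.t0 + j * n_win / lfp.fs
        if stop - start >= min_duration_s and np.any(
            (ripple_peaks >= start) & (ripple_peaks < stop)
        ):
            intervals.append((start, stop))
        i = j
    return intervals


def sws_sample_mask(lfp: LfpTrace, intervals: Sequence[tuple[float, float]]) -> np.ndarray:
    """Boolean per-sample mask of the given intervals."""
    mask = np.zeros(lfp.samples.size, dtype=bool)
    for start, stop in intervals:
        i0 = max(0, int(np.ceil((start - lfp.t0) * lfp.fs)))
        i1 = min(mask.size, int(np.ceil((stop - lfp.t0) * lfp.fs)))
        mask[i0:i1] = True
    return mask


def detect_ripples_in_epoch(
    lfp: LfpTrace,
    epoch: Epoch,
    peak_threshold_sd: float = 5.0,
    boundary_sd: float = 1.0,
    min_duration_ms: float = 20.0,
    sws_intervals: Optional[Sequence[tuple[float, float]]] = None,
    method: str = "hilbert",
) -> list[RippleEvent]:
    """Convenience wrapper: envelope + detection within one epoch, with the
    normalization statistics restricted to SWS samples when provided."""
    sub = lfp.slice(epoch.start_s, epoch.end_s)
    env = ripple_envelope(sub, method=method)
    mask = None
    if sws_intervals is not None:
        mask = sws_sample_mask(sub, sws_intervals)
        if not mask.any():
            mask = None
    return detect_ripples(
        env,
        sub.fs,
        peak_threshold_sd=peak_threshold_sd,
        boundary_sd=boundary_sd,
        min_duration_ms=min_duration_ms,
        t0=sub.t0,
        stats_mask=mask,
    )
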