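"""Occupancy/rate maps and spatial information content.

Rate maps use 1x1 cm bins: spike-count and occupancy-time maps are each
Gaussian-smoothed (kernel full width ~5 bins) and divided; unvisited bins
are masked.  Spatial information is sum_i p_i (l_i/l) log2(l_i/l) in
bits/spike, and units enter further analysis only when their peak binned
rate exceeds 0.4 Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import ranksums

from .core import PositionTrace

log = logging.getLogger(__name__)

# "filter width, 5 bins" read as kernel full width ~5 bins
FWHM_TO_SIGMA = 1.0 / 2.355


@dataclass
class RateMap:
    """Smoothed firing-rate map with occupancy probabilities."""

    rate_hz: np.ndarray  # NaN where unvisited
    occupancy_p: np.ndarray  # sums to 1 over visited bins
    visited: np.ndarray  # bool mask
    bin_cm: float

    @property
    def mean_rate_hz(self) -> float:
        v = self.visited
        return float(np.sum(self.occupancy_p[v] * self.rate_hz[v]))

    @property
    def peak_rate_hz(self) -> float:
        v = self.visited
        return float(np.nanmax(self.rate_hz[v])) if v.any() else float("nan")


def build_rate_map(
    spike_times: np.ndarray,
    position: PositionTrace,
    arena_cm: tuple[float, float],
    bin_cm: float = 1.0,
    smooth_width_bins: float = 5.0,
    smooth_sigma_bins: Optional[float] = None,
    smooth_order: str = "before_division",
) -> RateMap:
    """Rate map on a [0, W) x [0, H) cm grid, half-open 1-cm bins anchored
    at the arena corner.

    ``smooth_order='before_division'`` smooths count and occupancy maps
    separately then divides (numerically stable default);
    ``'after_division'`` divides raw maps then smooths the rate.
    """
    w_cm, h_cm = arena_cm
    nx, ny = int(np.floor(w_cm / bin_cm)), int(np.floor(h_cm / bin_cm))
    if nx < 2 or ny < 2:
        raise ValueError("arena must span at least 2x2 bins")
    if position.fs < 10:
        raise ValueError("position must be sampled at >= 10 Hz")
    sigma = smooth_sigma_bins
    if sigma is None:
        sigma = smooth_width_bins * FWHM_TO_SIGMA

    xe = np.arange(nx + 1) * bin_cm
    ye = np.arange(ny + 1) * bin_cm
    dt = np.empty_like(position.t)
    dt[:-1] = np.diff(position.t)
    dt[-1] = dt[-2] if dt.size > 1 else 0.0
    occ_s, _, _ = np.histogram2d(position.x, position.y, bins=(xe, ye), weights=dt)
    if occ_s.sum() <= 0:
        raise ValueError("zero occupancy everywhere")

    ts = np.asarray(spike_times, dtype=float)
    ts = ts[(ts >= position.t[0]) & (ts <= position.t[-1])]
    sx = np.interp(ts, position.t, position.x)
    sy = np.interp(ts, position.t, position.y)
    counts, _, _ = np.histogram2d(sx, sy, bins=(xe, ye))

    visited = occ_s > 0
    if smooth_order == "before_division":
        sm_counts = gaussian_filter(counts, sigma)
        sm_occ = gaussian_filter(occ_s, sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(sm_occ > 0, sm_counts / np.maximum(sm_occ, 1e-12), np.nan)
    elif smooth_order == "after_division":
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(visited, counts / np.maximum(occ_s, 1e-12), 0.0)
        rate = gaussian_filter(raw, sigma)
    else:
        raise ValueError(f"unknown smooth_order {smooth_order!r}")
    rate = np.where(visited, rate, np.nan)
    p = np.where(visited, occ_s / occ_s.sum(), 0.0)
    return RateMap(rate_hz=rate, occupancy_p=p, visited=visited, bin_cm=bin_cm)


def spatial_information(rate_map: RateMap) -> float:
    """Information content in bits/spike; NaN when the mean rate is zero.

    Convention: bins with zero rate contribute zero (0 log 0 = 0).
    """
    lam = rate_map.mean_rate_hz
    if not lam > 0:
        return float("nan")
    v = rate_map.visited
    p = rate_map.occupancy_p[v]
    li = rate_map.rate_hz[v]
    pos = li > 0
    ratio = li[pos] / lam
    return float(np.sum(p[pos] * ratio * np.log2(ratio)))


def place_cell_filter(
    maps: dict[int, RateMap], peak_threshold_hz: float = 0.4
) -> list[int]:
    """Unit ids whose peak binned rate strictly exceeds the threshold."""
    return sorted(
        uid for uid, m in maps.items() if m.peak_rate_hz > peak_threshold_hz
    )


@dataclass
class SubgroupComparison:
    median_a: float
    median_b: float
    p_value: Optional[float]
    n_a: int
    n_b: int


def compare_subgroups(
    si_a: Sequence[float], si_b: Sequence[float], min_per_group: int = 5
) -> SubgroupComparison:
    """Two-sided rank-sum comparison of spatial information between unit
    subgroups (e.g. higher- vs lower-weight); p is None for small groups."""
    a = np.asarray([s for s in si_a if np.isfinite(s)])
    b = np.asarray([s for s in si_b if np.isfinite(s)])
    p = None
    if a.size >= min_per_group and b.size >= min_per_group:
        p = float(ranksums(a, b).pvalue)
    return SubgroupComparison(
        median_a=float(np.median(a)) if a.size else float("nan"),
        median_b=float(np.median(b)) if b.size else float("nan"),
        p_value=p,
        n_a=int(a.size),
        n_b=int(b.size),
    )
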