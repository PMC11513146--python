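"""Lag-shifted Poisson-GLM decoding of ripple-locked target activity.

Predictors are dCA1 population spike counts in four 100-ms windows around
each ripple onset; the target (a BLA unit's spikes or an assembly's
activation events) is counted in the same windows shifted by +35 ms.
Ripples are split into equal train/test halves; prediction power is the
Pearson correlation between predicted and observed test counts, compared
to a null from refitting on ripple-permuted targets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import pearsonr, spearmanr
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import PoissonRegressor

from .core import SpikeData
from .memory import peri_event_histogram

log = logging.getLogger(__name__)

_DEFAULT_SOURCE_WINDOWS = ((-300, -200), (-200, -100), (-100, 0), (0, 100))


@dataclass(frozen=True)
class WindowSchedule:
    """Paired 100-ms count windows with a fixed source->target lag."""

    lag_ms: float = 35.0
    source_windows_ms: tuple[tuple[float, float], ...] = _DEFAULT_SOURCE_WINDOWS

    def __post_init__(self):
        for w0, w1 in self.source_windows_ms:
            if w1 <= w0:
                raise ValueError("window bounds out of order")

    @property
    def target_windows_ms(self) -> tuple[tuple[float, float], ...]:
        return tuple(
            (w0 + self.lag_ms, w1 + self.lag_ms) for w0, w1 in self.source_windows_ms
        )

    @property
    def n_windows(self) -> int:
        return len(self.source_windows_ms)


def counts_in_windows(
    times: np.ndarray, onsets: np.ndarray, window_ms: tuple[float, float]
) -> np.ndarray:
    """Event count in [onset + w0, onset + w1) per onset."""
    ts = np.sort(np.asarray(times, dtype=float))
    w0, w1 = window_ms[0] / 1000.0, window_ms[1] / 1000.0
    onsets = np.asarray(onsets, dtype=float)
    lo = np.searchsorted(ts, onsets + w0, side="left")
    hi = np.searchsorted(ts, onsets + w1, side="left")
    return (hi - lo).astype(float)


def extract_ripple_counts(
    dca1_spikes: SpikeData,
    target_times: np.ndarray,
    ripple_onsets: np.ndarray,
    schedule: WindowSchedule = WindowSchedule(),
) -> tuple[list[np.ndarray], list[np.ndarray], list[int]]:
    """Per window pair: X (ripples x dCA1 units) and y (ripples,).

    Every ripple is one sample; overlapping ripple windows are kept as
    independent samples.  Returns (X per window, y per window, unit order).
    """
    unit_ids = dca1_spikes.unit_ids("dCA1")
    if not unit_ids:
        raise ValueError("no dCA1 units")
    Xs, ys = [], []
    for src, tgt in zip(schedule.source_windows_ms, schedule.target_windows_ms):
        X = np.column_stack(
            [counts_in_windows(dca1_spikes.times[u], ripple_onsets, src) for u in unit_ids]
        )
        y = counts_in_windows(target_times, ripple_onsets, tgt)
        Xs.append(X)
        ys.append(y)
    return Xs, ys, unit_ids


@dataclass
class FittedGlm:
    coef: np.ndarray
    intercept: float
    alpha: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.exp(np.clip(X @ self.coef + self.intercept, -30, 30))


def fit_glm(
    X: np.ndarray, y: np.ndarray, alpha: float = 1e-4, max_iter: int = 1000
) -> FittedGlm:
    """Poisson GLM (log link) with a small L2 ridge for separability.

    On non-convergence the ridge is increased 10x, up to 3 times.
    """
    if np.any(y < 0):
        raise ValueError("target counts must be non-negative")
    if X.shape[0] < X.shape[1] / 2:
        log.warning("few samples (%d) for %d predictors", X.shape[0], X.shape[1])
    a = alpha
    for _ in range(4):
        model = PoissonRegressor(alpha=a, max_iter=max_iter)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            model.fit(X, y)
        if not any(issubclass(w.category, ConvergenceWarning) for w in caught):
            return FittedGlm(coef=model.coef_.copy(), intercept=float(model.intercept_), alpha=a)
        a *= 10
    raise RuntimeError("Poisson GLM failed to converge even with inflated ridge")


def _correlate(pred: np.ndarray, real: np.ndarray, method: str) -> float:
    if np.ptp(real) == 0 or np.ptp(pred) < 1e-12 * (1 + np.abs(pred).max()):
        return float("nan")
    if method == "pearson":
        return float(pearsonr(pred, real).statistic)
    if method == "spearman":
        return float(spearmanr(pred, real).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


@dataclass
class DecodingResult:
    """Per-window decoding scores with their permutation nulls."""

    r: list[float]
    null_r: list[np.ndarray]  # per window, n_shuffles values
    coefficients: list[np.ndarray]
    n_train: int
    n_test: int
    schedule: WindowSchedule = field(default_factory=WindowSchedule)

    def null_percentile(self, q: float = 97.5) -> list[float]:
        return [
            float(np.nanpercentile(nr, q))
            if nr.size and not np.all(np.isnan(nr))
            else float("nan")
            for nr in self.null_r
        ]

    def significant(self, q: float = 97.5) -> list[bool]:
        return [
            (not np.isnan(r)) and r > p
            for r, p in zip(self.r, self.null_percentile(q))
        ]


def decode_and_score(
    dca1_spikes: SpikeData,
    target_times: np.ndarray,
    ripple_onsets: np.ndarray,
    schedule: WindowSchedule = WindowSchedule(),
    split_seed: int = 0,
    n_shuffles: int = 100,
    alpha: float = 1e-4,
    correlation: str = "pearson",
) -> DecodingResult:
    """Equal-split train/test GLM decoding per window pair.

    The null permutes target counts across ripples (seeded) and repeats
    the identical fit/score procedure.
    """
    onsets = np.asarray(ripple_onsets, dtype=float)
    if onsets.size < 20:
        raise ValueError("need at least 20 ripples")
    rng = np.random.default_rng(split_seed)
    Xs, ys, _ = extract_ripple_counts(dca1_spikes, target_times, onsets, schedule)

    n = onsets.size
    perm = rng.permutation(n)
    train_idx, test_idx = perm[: n // 2], perm[n // 2 :]

    rs, nulls, coefs = [], [], []
    for X, y in zip(Xs, ys):
        model = fit_glm(X[train_idx], y[train_idx], alpha=alpha)
        r = _correlate(model.predict(X[test_idx]), y[test_idx], correlation)
        null = np.empty(n_shuffles)
        for s in range(n_shuffles):
            yp = y[rng.permutation(n)]
            m = fit_glm(X[train_idx], yp[train_idx], alpha=alpha)
            null[s] = _correlate(m.predict(X[test_idx]), yp[test_idx], correlation)
        rs.append(r)
        nulls.append(null)
        coefs.append(model.coef)
    return DecodingResult(
        r=rs,
        null_r=nulls,
        coefficients=coefs,
        n_train=train_idx.size,
        n_test=test_idx.size,
        schedule=schedule,
    )


def rank_units_by_target_correlation(
    dca1_spikes: SpikeData,
    target_times: np.ndarray,
    window_ms: float = 500.0,
) -> list[int]:
    """dCA1 unit ids ordered by their peri-target cross-correlogram peak
    (descending), the ranking used for the top/bottom weight split."""
    scored = []
    for uid in dca1_spikes.unit_ids("dCA1"):
        peh = peri_event_histogram(
            dca1_spikes.times[uid], target_times, window_ms=window_ms
        )
        scored.append((float(peh.z.max()), uid))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [uid for _, uid in scored]


def weight_split_decoding(
    dca1_spikes: SpikeData,
    target_times: np.ndarray,
    ripple_onsets: np.ndarray,
    schedule: WindowSchedule = WindowSchedule(),
    split_seed: int = 0,
    n_shuffles: int = 100,
    alpha: float = 1e-4,
) -> dict[str, DecodingResult]:
    """Decode separately with the top and bottom halves of dCA1 units ranked
    by peri-target cross-correlation.  With an odd unit count the middle
    unit goes to the bottom half (logged)."""
    order = rank_units_by_target_correlation(dca1_spikes, target_times)
    half = len(order) // 2
    if len(order) % 2:
        log.info("odd unit count: middle unit %d assigned to bottom half", order[half])
    top, bottom = order[:half], order[half:]
    out = {}
    for name, ids in (("top", top), ("bottom", bottom)):
        out[name] = decode_and_score(
            dca1_spikes.select(ids),
            target_times,
            ripple_onsets,
            schedule=schedule,
            split_seed=split_seed,
            n_shuffles=n_shuffles,
            alpha=alpha,
        )
    return out
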