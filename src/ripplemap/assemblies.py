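"""Cell-assembly extraction from binned population spikes.

Spike counts are binned (25 ms) and z-scored per unit; the number of
co-activation patterns is the count of correlation-matrix eigenvalues above
the Marchenko-Pastur bound for uncorrelated data; FastICA on the projection
into the significant principal subspace yields the assembly weight vectors.
Activation strength is the projection of each z-scored population vector
onto an assembly pattern (zero-diagonal quadratic form by default, linear
optional); activation events are bins exceeding mean + 5 s.d.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .core import ActivationTrace, AssemblyPattern, Epoch, SpikeData

log = logging.getLogger(__name__)


@dataclass
class BinnedMatrix:
    """Units x bins matrix of z-scored spike counts on a fixed bin grid."""

    z: np.ndarray  # kept-units x bins, row mean ~0, sd ~1
    counts: np.ndarray  # raw counts, same shape
    bin_ms: float
    t0: float
    unit_ids: np.ndarray  # kept unit ids, aligned with rows
    excluded_ids: np.ndarray  # zero-variance units dropped before z-scoring

    @property
    def n_units(self) -> int:
        return self.z.shape[0]

    @property
    def n_bins(self) -> int:
        return self.z.shape[1]

    @property
    def bin_s(self) -> float:
        return self.bin_ms / 1000.0

    @property
    def bin_centers(self) -> np.ndarray:
        return self.t0 + (np.arange(self.n_bins) + 0.5) * self.bin_s


def bin_and_zscore(
    spikes: SpikeData,
    epoch: Epoch,
    bin_ms: float = 25.0,
    min_bins: int = 100,
) -> BinnedMatrix:
    """Bin spike counts on a grid anchored at the epoch start and z-score
    each unit's row.  Units with zero count variance are excluded (z-score
    undefined) and reported in ``excluded_ids``.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    bin_s = bin_ms / 1000.0
    n_bins = int(np.floor(epoch.duration_s / bin_s))
    if n_bins < min_bins:
        raise ValueError(
            f"epoch {epoch.name!r} has {n_bins} bins; need >= {min_bins}"
        )
    edges = epoch.start_s + np.arange(n_bins + 1) * bin_s
    ids = np.asarray(spikes.unit_ids())
    counts = np.empty((ids.size, n_bins))
    for i, uid in enumerate(ids):
        counts[i], _ = np.histogram(spikes.times[uid], bins=edges)

    sd = counts.std(axis=1)
    keep = sd > 0
    if not np.all(keep):
        log.warning(
            "excluding %d zero-variance unit(s) before z-scoring: %s",
            (~keep).sum(),
            ids[~keep].tolist(),
        )
    kept = counts[keep]
    z = (kept - kept.mean(axis=1, keepdims=True)) / kept.std(axis=1, keepdims=True)
    return BinnedMatrix(
        z=z,
        counts=kept,
        bin_ms=bin_ms,
        t0=epoch.start_s,
        unit_ids=ids[keep],
        excluded_ids=ids[~keep],
    )


def marchenko_pastur_bound(n_units: int, n_bins: int) -> float:
    """Largest eigenvalue of a random correlation matrix: (1 + sqrt(n/B))^2."""
    if n_bins <= n_units:
        raise ValueError("need n_bins > n_units for a valid bound")
    q = n_units / n_bins
    return (1.0 + np.sqrt(q)) ** 2


# Tracy-Widom (beta=1) quantiles for the finite-size edge correction
_TW1_QUANTILES = {0.95: 0.9793, 0.99: 2.0234, 0.999: 3.2724}


def significance_threshold(
    n_units: int, n_bins: int, edge_quantile: Optional[float] = 0.99
) -> float:
    """Analytic eigenvalue threshold for uncorrelated data.

    ``edge_quantile=None`` returns the asymptotic Marchenko-Pastur edge
    (1 + sqrt(n/B))^2.  At finite size the largest null eigenvalue
    fluctuates around that edge (Tracy-Widom) and exceeds it for a few
    percent of draws, so by default the threshold is the Johnstone
    finite-size centering plus the TW1 quantile:
    mu + sigma * tw1(edge_quantile), with
    mu = (sqrt(n-1/2) + sqrt(B-1/2))^2 / B and
    sigma = (sqrt(n-1/2) + sqrt(B-1/2)) / B *
    (1/sqrt(n-1/2) + 1/sqrt(B-1/2))^(1/3).
    """
    if edge_quantile is None:
        return marchenko_pastur_bound(n_units, n_bins)
    if n_bins <= n_units:
        raise ValueError("need n_bins > n_units for a valid bound")
    if edge_quantile not in _TW1_QUANTILES:
        raise ValueError(f"edge_quantile must be one of {sorted(_TW1_QUANTILES)}")
    a, b = np.sqrt(n_units - 0.5), np.sqrt(n_bins - 0.5)
    mu = (a + b) ** 2 / n_bins
    sigma = (a + b) / n_bins * (1 / a + 1 / b) ** (1 / 3)
    return float(mu + sigma * _TW1_QUANTILES[edge_quantile])


def _correlation_eigh(mat: BinnedMatrix) -> tuple[np.ndarray, np.ndarray]:
    corr = mat.z @ mat.z.T / mat.n_bins
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


def count_significant_components(
    mat: BinnedMatrix, edge_quantile: Optional[float] = 0.99
) -> int:
    """Number of correlation eigenvalues strictly above the uncorrelated-data
    threshold (finite-size-corrected MP edge; see significance_threshold)."""
    lam_max = significance_threshold(mat.n_units, mat.n_bins, edge_quantile)
    evals, _ = _correlation_eigh(mat)
    return int(np.sum(evals > lam_max))


def extract_assembly_patterns(
    mat: BinnedMatrix,
    n_components: Optional[int] = None,
    seed: int = 0,
    max_iter: int = 500,
    retries: int = 3,
) -> list[AssemblyPattern]:
    """Assembly weight vectors via PCA-subspace FastICA.

    The z-matrix is projected onto the top ``n_components`` principal
    directions (default: the significant-component count); FastICA unmixes
    the projected signals; each unmixing direction is mapped back to unit
    space, normalized to unit length and sign-fixed.  Patterns are ordered
    by explained variance, descending.  Deterministic given ``seed``;
    non-convergence retries with a shifted seed and errors out after
    ``retries`` attempts.
    """
    if n_components is None:
        n_components = count_significant_components(mat)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    _, evecs = _correlation_eigh(mat)
    V = evecs[:, :n_components]  # units x k
    proj = V.T @ mat.z  # k x bins

    last_err: Optional[Exception] = None
    for attempt in range(retries):
        ica = FastICA(
            n_components=n_components,
            random_state=seed + attempt,
            max_iter=max_iter,
            whiten="unit-variance",
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            try:
                ica.fit(proj.T)
            except Exception as err:  # pragma: no cover - sklearn internal
                last_err = err
                continue
            if any(issubclass(w.category, ConvergenceWarning) for w in caught):
                last_err = RuntimeError("FastICA did not converge")
                continue
        raw = ica.components_ @ V.T  # k x units
        patterns = []
        for row in raw:
            patterns.append(
                AssemblyPattern(weights=row, unit_ids=mat.unit_ids.copy())
            )
        # order by variance the pattern explains in the binned data
        var = [np.var(p.weights @ mat.z) for p in patterns]
        order = np.argsort(var)[::-1]
        out = []
        for new_id, k in enumerate(order):
            p = patterns[k]
            p.id = new_id
            out.append(p)
        return out
    raise RuntimeError(f"FastICA failed after {retries} attempts: {last_err}")


def activation_strength(
    pattern: AssemblyPattern,
    mat: BinnedMatrix,
    mode: str = "quadratic",
    threshold_sd: float = 5.0,
) -> ActivationTrace:
    """Per-bin activation strength of one assembly.

    ``quadratic``: R(t) = z_t' P z_t with P = w w' and zeroed diagonal,
    which is insensitive to any single unit firing alone.  ``linear``:
    R(t) = w . z_t.
    """
    if pattern.weights.size != mat.n_units or not np.array_equal(
        pattern.unit_ids, mat.unit_ids
    ):
        raise ValueError("pattern and matrix unit indexing differ")
    w = pattern.weights
    if mode == "quadratic":
        lin = w @ mat.z
        strength = lin**2 - (w**2) @ (mat.z**2)
    elif mode == "linear":
        strength = w @ mat.z
    else:
        raise ValueError(f"unknown activation mode {mode!r}")
    return ActivationTrace(
        strength=strength, bin_s=mat.bin_s, t0=mat.t0, threshold_sd=threshold_sd
    )


def surrogate_activation_null(
    pattern: AssemblyPattern,
    mat: BinnedMatrix,
    n_surrogates: int = 500,
    seed: int = 0,
    mode: str = "quadratic",
    threshold_sd: float = 5.0,
    shuffle: str = "circular",
) -> np.ndarray:
    """Null distribution of activation-event rates from shuffled matrices.

    Each surrogate destroys co-activation while preserving per-unit
    statistics: ``circular`` rolls each row by an independent random offset
    (keeps autocorrelation); ``permute`` independently permutes each row's
    bins.  Each surrogate's strength trace is thresholded at the *real*
    trace's mean + ``threshold_sd`` x s.d. (a fixed yardstick, so rates are
    directly comparable to the real event rate); returns one event rate
    (Hz) per surrogate.
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    if shuffle not in ("circular", "permute"):
        raise ValueError(f"unknown shuffle {shuffle!r}")
    rng = np.random.default_rng(seed)
    real = activation_strength(pattern, mat, mode=mode, threshold_sd=threshold_sd)
    threshold = real.mean + threshold_sd * real.sd
    bin_s = mat.bin_s
    n, B = mat.z.shape
    rates = np.empty(n_surrogates)
    cols = np.arange(B)
    for s in range(n_surrogates):
        if shuffle == "circular":
            shifts = rng.integers(0, B, size=n)
            idx = (cols[None, :] - shifts[:, None]) % B
            zs = np.take_along_axis(mat.z, idx, axis=1)
        else:
            zs = np.empty_like(mat.z)
            for i in range(n):
                zs[i] = mat.z[i, rng.permutation(B)]
        sur = BinnedMatrix(
            z=zs,
            counts=mat.counts,
            bin_ms=mat.bin_ms,
            t0=mat.t0,
            unit_ids=mat.unit_ids,
            excluded_ids=mat.excluded_ids,
        )
        strength = activation_strength(pattern, sur, mode=mode).strength
        rates[s] = float(np.count_nonzero(strength > threshold)) / (B * bin_s)
    return rates


@dataclass
class AssemblyMatch:
    index_a: int
    index_b: int
    similarity: float  # |cosine|


def match_assemblies(
    patterns_a: Sequence[AssemblyPattern],
    patterns_b: Sequence[AssemblyPattern],
) -> tuple[list[AssemblyMatch], list[int], list[int]]:
    """Greedy one-to-one pairing by absolute cosine similarity.

    Returns (matches, unmatched indices in a, unmatched indices in b).
    """
    if not patterns_a or not patterns_b:
        return [], list(range(len(patterns_a))), list(range(len(patterns_b)))
    sim = np.abs(
        np.array([[a.weights @ b.weights for b in patterns_b] for a in patterns_a])
    )
    matches = []
    free_a = set(range(len(patterns_a)))
    free_b = set(range(len(patterns_b)))
    work = sim.copy()
    while free_a and free_b:
        i, j = np.unravel_index(np.argmax(work), work.shape)
        if work[i, j] < 0:
            break
        matches.append(AssemblyMatch(int(i), int(j), float(sim[i, j])))
        free_a.discard(int(i))
        free_b.discard(int(j))
        work[i, :] = -1.0
        work[:, j] = -1.0
    return matches, sorted(free_a), sorted(free_b)
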