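"""Shared domain types for the analysis pipeline.

All times are seconds from session start; LFP amplitudes are microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

REGIONS = ("dCA1", "BLA")

SLEEP_EPOCHS = ("pre_sleep", "post_sleep")
EPOCH_ORDER = ("pre_sleep", "training", "post_sleep", "test")


@dataclass(frozen=True)
class Epoch:
    """A labeled, half-open time interval [start_s, end_s)."""

    name: str
    start_s: float
    end_s: float

    def __post_init__(self):
        if not self.end_s > self.start_s:
            raise ValueError(f"epoch {self.name!r}: end_s must exceed start_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t: np.ndarray | float) -> np.ndarray | bool:
        return (np.asarray(t) >= self.start_s) & (np.asarray(t) < self.end_s)


def validate_epochs(epochs: Sequence[Epoch]) -> None:
    """Require ordered, non-overlapping epochs."""
    for a, b in zip(epochs, epochs[1:]):
        if b.start_s < a.end_s:
            raise ValueError(
                f"epochs {a.name!r} and {b.name!r} overlap or are out of order"
            )


def epoch_by_name(epochs: Sequence[Epoch], name: str) -> Epoch:
    for e in epochs:
        if e.name == name:
            return e
    raise KeyError(f"no epoch named {name!r}")


@dataclass
class SpikeData:
    """Sorted spike timestamps per unit, with a region label per unit.

    ``times`` maps unit id -> strictly non-decreasing float array (seconds);
    ``regions`` maps unit id -> one of :data:`REGIONS`.
    """

    times: dict[int, np.ndarray]
    regions: dict[int, str]

    def __post_init__(self):
        for uid, ts in self.times.items():
            ts = np.asarray(ts, dtype=float)
            if ts.ndim != 1:
                raise ValueError(f"unit {uid}: spike times must be 1-D")
            if ts.size > 1 and np.any(np.diff(ts) < 0):
                raise ValueError(f"unit {uid}: spike times are not sorted")
            self.times[uid] = ts
        for uid, region in self.regions.items():
            if region not in REGIONS:
                raise ValueError(
                    f"unit {uid}: unknown region label {region!r} "
                    f"(expected one of {REGIONS})"
                )
        if set(self.times) != set(self.regions):
            raise ValueError("times and regions must cover the same unit ids")

    def unit_ids(self, region: Optional[str] = None) -> list[int]:
        if region is None:
            return sorted(self.times)
        return sorted(u for u, r in self.regions.items() if r == region)

    def select(self, unit_ids: Iterable[int]) -> "SpikeData":
        ids = list(unit_ids)
        return SpikeData(
            times={u: self.times[u] for u in ids},
            regions={u: self.regions[u] for u in ids},
        )

    def region(self, region: str) -> "SpikeData":
        return self.select(self.unit_ids(region))

    def restrict(self, start_s: float, end_s: float) -> "SpikeData":
        """Spikes within [start_s, end_s), keeping all units."""
        out = {}
        for uid, ts in self.times.items():
            lo, hi = np.searchsorted(ts, [start_s, end_s])
            out[uid] = ts[lo:hi]
        return SpikeData(times=out, regions=dict(self.regions))

    def merge(self, other: "SpikeData") -> "SpikeData":
        if set(self.times) & set(other.times):
            raise ValueError("unit id collision when merging SpikeData")
        return SpikeData(
            times={**self.times, **other.times},
            regions={**self.regions, **other.regions},
        )

    @property
    def n_units(self) -> int:
        return len(self.times)


@dataclass
class LfpTrace:
    """A single-channel LFP trace sampled at a constant rate."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    units: str = "uV"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("LFP samples must be 1-D")
        if self.fs < 1000:
            raise ValueError(f"fs must be >= 1000 Hz, got {self.fs}")

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def slice(self, start_s: float, end_s: float) -> "LfpTrace":
        i0 = max(0, int(np.ceil((start_s - self.t0) * self.fs)))
        i1 = min(self.samples.size, int(np.ceil((end_s - self.t0) * self.fs)))
        return replace(self, samples=self.samples[i0:i1], t0=self.t0 + i0 / self.fs)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


RIPPLE_LABELS = ("unlabeled", "memory", "non_memory")


@dataclass
class RippleEvent:
    """One detected ripple with its envelope-derived geometry."""

    onset_s: float
    peak_s: float
    offset_s: float
    amplitude_sd: float
    label: str = "unlabeled"

    def __post_init__(self):
        if not (self.onset_s <= self.peak_s <= self.offset_s):
            raise ValueError("ripple must satisfy onset <= peak <= offset")
        if self.label not in RIPPLE_LABELS:
            raise ValueError(f"unknown ripple label {self.label!r}")

    @property
    def duration_ms(self) -> float:
        return 1000.0 * (self.offset_s - self.onset_s)


@dataclass
class AssemblyPattern:
    """Unit-norm weight vector over units plus its high-weight member set.

    Members are the indices whose weight exceeds the pattern mean by more
    than 2 s.d. of the pattern's weights (one-sided rule).
    """

    weights: np.ndarray
    unit_ids: np.ndarray
    id: int = 0
    member_sd: float = 2.0

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.unit_ids = np.asarray(self.unit_ids)
        if self.weights.shape != self.unit_ids.shape:
            raise ValueError("weights and unit_ids must align")
        nrm = np.linalg.norm(self.weights)
        if nrm == 0:
            raise ValueError("zero weight vector")
        self.weights = self.weights / nrm
        # sign convention: largest-magnitude entry positive
        k = int(np.argmax(np.abs(self.weights)))
        if self.weights[k] < 0:
            self.weights = -self.weights

    @property
    def member_indices(self) -> np.ndarray:
        """Positions (into weights) of member units."""
        w = self.weights
        return np.flatnonzero(w > w.mean() + self.member_sd * w.std())

    @property
    def members(self) -> frozenset:
        """Unit ids of members."""
        return frozenset(self.unit_ids[self.member_indices].tolist())


@dataclass
class ActivationTrace:
    """Per-bin assembly activation strength with supra-threshold events."""

    strength: np.ndarray
    bin_s: float
    t0: float
    threshold_sd: float = 5.0

    def __post_init__(self):
        self.strength = np.asarray(self.strength, dtype=float)

    @property
    def bin_centers(self) -> np.ndarray:
        return self.t0 + (np.arange(self.strength.size) + 0.5) * self.bin_s

    @property
    def mean(self) -> float:
        return float(self.strength.mean())

    @property
    def sd(self) -> float:
        return float(self.strength.std())

    @property
    def event_mask(self) -> np.ndarray:
        return self.strength > self.mean + self.threshold_sd * self.sd

    @property
    def event_times(self) -> np.ndarray:
        """Centers of supra-threshold bins."""
        return self.bin_centers[self.event_mask]

    @property
    def event_rate_hz(self) -> float:
        return float(self.event_mask.sum()) / (self.strength.size * self.bin_s)


@dataclass
class SessionBundle:
    """Everything one recording session contributes to the pipeline."""

    spikes: SpikeData
    epochs: list[Epoch]
    lfp: Optional[LfpTrace] = None
    shock_times: np.ndarray = field(default_factory=lambda: np.array([]))
    position: Optional["PositionTrace"] = None
    truth: Optional[dict] = None

    def __post_init__(self):
        validate_epochs(self.epochs)
        self.shock_times = np.asarray(self.shock_times, dtype=float)
        end = max(e.end_s for e in self.epochs)
        for uid, ts in self.spikes.times.items():
            if ts.size and (ts[0] < 0 or ts[-1] > end):
                raise ValueError(f"unit {uid}: spikes outside session bounds")

    def epoch(self, name: str) -> Epoch:
        return epoch_by_name(self.epochs, name)

    def has_epoch(self, name: str) -> bool:
        return any(e.name == name for e in self.epochs)


@dataclass
class PositionTrace:
    """2-D position samples at a constant rate (cm)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have equal shapes")
        if self.t.size >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError("position timestamps must be strictly increasing")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))
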