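"""Synthetic sessions with known ground truth.

Generates the full session layout used throughout the tests: pre-training
sleep, training (with shocks), post-training sleep and a test epoch; an LFP
with 1/f + delta background and injected ripple bursts; a BLA population
with planted co-activating assemblies (optionally yoked to a fraction of
ripples at a fixed lag, post-training only); a dCA1 population with
per-ripple participation; a GLM-coupled BLA target unit; and a random-walk
trajectory with place-field-modulated units.

All outputs are pure functions of the configuration and its seed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    Epoch,
    LfpTrace,
    PositionTrace,
    SessionBundle,
    SpikeData,
)
from .decoding import WindowSchedule, counts_in_windows
from .ripples import ripple_envelope

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssemblySpec:
    """One planted BLA assembly.

    ``members`` are BLA-local indices (0-based).  During each 25-ms
    activation window every member's rate is multiplied by ``gain``.
    ``yoked_fraction`` of ripples in ``yoked_epochs`` trigger an activation
    ``lag_ms`` after ripple onset; other sleep epochs get independent
    Poisson activations at ``event_rate_hz``.  ``shock_gain`` multiplies
    member baseline rates after the first shock of the training epoch.
    """

    members: tuple[int, ...]
    event_rate_hz: float = 0.3
    gain: float = 8.0
    yoked_fraction: float = 0.0
    lag_ms: float = 35.0
    shock_gain: float = 1.0
    yoked_epochs: tuple[str, ...] = ("post_sleep",)

    def __post_init__(self):
        if self.gain < 1:
            raise ValueError("gain < 1 would invert the planted structure")
        if self.event_rate_hz < 0 or not (0 <= self.yoked_fraction <= 1):
            raise ValueError("invalid assembly rates")
        if self.lag_ms < 0:
            raise ValueError("lag_ms must be >= 0")


@dataclass
class SessionConfig:
    """Parameters of one synthetic session; the seed fully determines it."""

    epoch_durations: dict[str, float] = field(
        default_factory=lambda: {
            "pre_sleep": 600.0,
            "training": 1800.0,
            "post_sleep": 600.0,
            "test": 300.0,
        }
    )
    n_dca1: int = 25
    n_bla: int = 30
    dca1_rate_hz: float = 2.0
    bla_rate_hz: float = 5.0
    assembly_specs: tuple[AssemblySpec, ...] = ()
    event_window_ms: float = 25.0
    # ripples
    ripple_rate_hz: float = 0.45  # events/s during sleep epochs
    ripple_amp_sd: tuple[float, float] = (9.0, 2.0)  # mean, sd (s.d. units)
    ripple_dur_ms: tuple[float, float] = (60.0, 10.0)
    ripple_freq_range: tuple[float, float] = (120.0, 220.0)  # inside the band
    min_ripple_gap_s: float = 0.5
    n_ripples_per_epoch: Optional[int] = None  # exact count override
    # dCA1 ripple participation
    dca1_ripple_gain: float = 3.0
    # LFP
    lfp_fs: float = 2000.0
    pink_sd_uv: float = 50.0
    delta_amp_uv: float = 120.0
    delta_hz: float = 2.0
    # coupling (GLM target)
    coupling_weights: Optional[np.ndarray] = None
    coupling_intercept: float = -1.0
    lag_ms: float = 35.0
    # shocks: every 3 min starting at 3 min into training
    shock_interval_s: float = 180.0
    n_shocks: int = 10
    # arena / trajectory
    arena_cm: tuple[float, float] = (50.0, 50.0)
    position_fs: float = 50.0
    seed: int = 0

    def __post_init__(self):
        for name, d in self.epoch_durations.items():
            if d <= 0:
                raise ValueError(f"epoch {name!r} duration must be positive")
        for r in (self.dca1_rate_hz, self.bla_rate_hz, self.ripple_rate_hz):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if self.lag_ms < 0:
            raise ValueError("lag_ms must be >= 0")
        if self.lfp_fs < 1000:
            raise ValueError("lfp_fs < 1000 Hz cannot represent 250 Hz ripples")

    def epochs(self) -> list[Epoch]:
        out, t = [], 0.0
        for name in ("pre_sleep", "training", "post_sleep", "test"):
            if name in self.epoch_durations:
                d = self.epoch_durations[name]
                out.append(Epoch(name, t, t + d))
                t += d
        return out

    def sleep_epochs(self) -> list[Epoch]:
        return [e for e in self.epochs() if e.name in ("pre_sleep", "post_sleep")]

    @property
    def session_end_s(self) -> float:
        return sum(self.epoch_durations.values())

    def shock_times(self) -> np.ndarray:
        epochs = {e.name: e for e in self.epochs()}
        if "training" not in epochs:
            return np.array([])
        tr = epochs["training"]
        times = tr.start_s + self.shock_interval_s * np.arange(1, self.n_shocks + 1)
        return times[times < tr.end_s]

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator per named stage, derived from the seed.

        Uses a stable digest of the stream name (process-independent).
        """
        key = int.from_bytes(hashlib.sha256(stream.encode()).digest()[:4], "little")
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(key,))
        )


@dataclass
class RippleTruth:
    onset_s: float
    peak_s: float
    offset_s: float
    amplitude_sd: float
    epoch: str


def _pink_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def _draw_event_times(
    epoch: Epoch,
    rate_hz: float,
    rng: np.random.Generator,
    min_gap_s: float,
    margin_s: float = 1.0,
    n_exact: Optional[int] = None,
) -> np.ndarray:
    """Well-separated random event times inside an epoch."""
    usable = epoch.duration_s - 2 * margin_s
    if usable <= min_gap_s:
        return np.array([])
    slots = np.arange(epoch.start_s + margin_s, epoch.end_s - margin_s, min_gap_s)
    n = n_exact if n_exact is not None else rng.poisson(rate_hz * usable)
    n = min(n, slots.size)
    if n == 0:
        return np.array([])
    chosen = np.sort(rng.choice(slots.size, size=n, replace=False))
    jitter = rng.random(n) * 0.5 * min_gap_s
    return slots[chosen] + jitter


def generate_lfp(cfg: SessionConfig) -> tuple[LfpTrace, list[RippleTruth]]:
    """Session LFP: 1/f background, delta during sleep, injected ripples.

    Ripple bursts are in-band sinusoids under a Gaussian amplitude envelope;
    their peak size is calibrated in s.d. of the background ripple-band
    envelope so detection thresholds are directly interpretable.  Returns
    the exact injected (onset, peak, offset) times.
    """
    rng = cfg.rng("lfp")
    n = int(round(cfg.session_end_s * cfg.lfp_fs))
    t = np.arange(n) / cfg.lfp_fs
    x = cfg.pink_sd_uv * _pink_noise(n, cfg.lfp_fs, rng)
    for e in cfg.sleep_epochs():
        sel = slice(int(e.start_s * cfg.lfp_fs), int(e.end_s * cfg.lfp_fs))
        phase = rng.random() * 2 * np.pi
        x[sel] += cfg.delta_amp_uv * np.sin(2 * np.pi * cfg.delta_hz * t[sel] + phase)

    # baseline ripple-band envelope statistics over sleep epochs
    bg = LfpTrace(samples=x.copy(), fs=cfg.lfp_fs)
    env = ripple_envelope(bg)
    sleep_mask = np.zeros(n, dtype=bool)
    for e in cfg.sleep_epochs():
        sleep_mask[int(e.start_s * cfg.lfp_fs) : int(e.end_s * cfg.lfp_fs)] = True
    if not sleep_mask.any():
        sleep_mask[:] = True
    mu_b = float(env[sleep_mask].mean())
    sd_b = float(env[sleep_mask].std())

    truths: list[RippleTruth] = []
    if cfg.ripple_rate_hz > 0 or cfg.n_ripples_per_epoch:
        for e in cfg.sleep_epochs():
            peaks = _draw_event_times(
                e,
                cfg.ripple_rate_hz,
                rng,
                cfg.min_ripple_gap_s,
                n_exact=cfg.n_ripples_per_epoch,
            )
            for tc in peaks:
                amp_sd = max(3.0, rng.normal(*cfg.ripple_amp_sd))
                dur_s = max(0.03, rng.normal(*cfg.ripple_dur_ms) / 1000.0)
                freq = rng.uniform(*cfg.ripple_freq_range)
                sigma = dur_s / 4.0
                amp_uv = mu_b + amp_sd * sd_b
                i0 = max(0, int((tc - 4 * sigma) * cfg.lfp_fs))
                i1 = min(n, int((tc + 4 * sigma) * cfg.lfp_fs))
                tt = t[i0:i1] - tc
                x[i0:i1] += amp_uv * np.exp(-(tt**2) / (2 * sigma**2)) * np.cos(
                    2 * np.pi * freq * tt
                )
                # truth onset/offset: envelope crossing of mean + 1 s.d.
                ratio = amp_uv / max(mu_b + sd_b, 1e-12)
                half = sigma * np.sqrt(2 * np.log(ratio)) if ratio > 1 else dur_s / 2
                truths.append(
                    RippleTruth(
                        onset_s=tc - half,
                        peak_s=tc,
                        offset_s=tc + half,
                        amplitude_sd=amp_sd,
                        epoch=e.name,
                    )
                )
    truths.sort(key=lambda r: r.onset_s)
    return LfpTrace(samples=x, fs=cfg.lfp_fs), truths


def _poisson_train(
    rate_hz: float, start_s: float, end_s: float, rng: np.random.Generator
) -> np.ndarray:
    dur = end_s - start_s
    if rate_hz <= 0 or dur <= 0:
        return np.array([])
    n = rng.poisson(rate_hz * dur)
    return np.sort(start_s + rng.random(n) * dur)


@dataclass
class AssemblyTruth:
    member_ids: frozenset
    event_times: np.ndarray
    yoked_event_times: np.ndarray
    spec: Optional[AssemblySpec] = None


def generate_assembly_spikes(
    cfg: SessionConfig,
    ripple_truths: Sequence[RippleTruth] = (),
) -> tuple[SpikeData, list[AssemblyTruth]]:
    """BLA population with planted co-activating assemblies.

    Non-members fire homogeneous Poisson at baseline.  Within each
    activation window (``event_window_ms``) member rates are multiplied by
    the assembly gain.  Yoking to ripples applies only in the spec's
    ``yoked_epochs``; shock-activated members get ``shock_gain`` x baseline
    from the first shock to the end of training.
    """
    rng = cfg.rng("bla")
    epochs = cfg.epochs()
    end = cfg.session_end_s
    ids = [cfg.n_dca1 + i for i in range(cfg.n_bla)]
    member_shock_gain = {i: 1.0 for i in range(cfg.n_bla)}
    for spec in cfg.assembly_specs:
        for m in spec.members:
            if not 0 <= m < cfg.n_bla:
                raise ValueError(f"assembly member index {m} out of range")
            member_shock_gain[m] = max(member_shock_gain[m], spec.shock_gain)

    shock = cfg.shock_times()
    training = next((e for e in epochs if e.name == "training"), None)
    times = {}
    for i, uid in enumerate(ids):
        ts = _poisson_train(cfg.bla_rate_hz, 0.0, end, rng)
        g = member_shock_gain[i]
        if g > 1 and shock.size and training is not None:
            extra = _poisson_train(
                (g - 1) * cfg.bla_rate_hz, float(shock.min()), training.end_s, rng
            )
            ts = np.sort(np.concatenate([ts, extra]))
        times[uid] = ts

    win = cfg.event_window_ms / 1000.0
    truths = []
    for spec in cfg.assembly_specs:
        all_events, yoked_events = [], []
        for e in [ep for ep in epochs if ep.name in ("pre_sleep", "post_sleep")]:
            if spec.yoked_fraction > 0 and e.name in spec.yoked_epochs:
                onsets = np.array(
                    [r.onset_s for r in ripple_truths if r.epoch == e.name]
                )
                k = int(round(spec.yoked_fraction * onsets.size))
                if k:
                    sel = np.sort(rng.choice(onsets.size, size=k, replace=False))
                    yk = onsets[sel] + spec.lag_ms / 1000.0
                    yk = yk[yk + win < e.end_s]
                    yoked_events.append(yk)
                    all_events.append(yk)
            indep = _poisson_train(spec.event_rate_hz, e.start_s, e.end_s - win, rng)
            all_events.append(indep)
        events = np.sort(np.concatenate(all_events)) if all_events else np.array([])
        yoked = np.sort(np.concatenate(yoked_events)) if yoked_events else np.array([])
        extra_rate = (spec.gain - 1.0) * cfg.bla_rate_hz
        for m in spec.members:
            uid = ids[m]
            extras = []
            for t0 in events:
                k = rng.poisson(extra_rate * win)
                if k:
                    extras.append(t0 + rng.random(k) * win)
            if extras:
                times[uid] = np.sort(np.concatenate([times[uid], *extras]))
        truths.append(
            AssemblyTruth(
                member_ids=frozenset(ids[m] for m in spec.members),
                event_times=events,
                yoked_event_times=yoked,
                spec=spec,
            )
        )
    return SpikeData(times=times, regions={u: "BLA" for u in ids}), truths


def generate_dca1_spikes(
    cfg: SessionConfig,
    ripple_truths: Sequence[RippleTruth] = (),
    ripple_window_ms: tuple[float, float] = (-100.0, 100.0),
) -> SpikeData:
    """dCA1 population: baseline Poisson plus heterogeneous per-ripple
    participation (exponential per-unit-per-ripple gain), which makes
    ripple-window population vectors informative for decoding."""
    rng = cfg.rng("dca1")
    end = cfg.session_end_s
    w0, w1 = ripple_window_ms[0] / 1000.0, ripple_window_ms[1] / 1000.0
    onsets = np.array([r.onset_s for r in ripple_truths])
    times = {}
    for uid in range(cfg.n_dca1):
        ts = [_poisson_train(cfg.dca1_rate_hz, 0.0, end, rng)]
        if onsets.size and cfg.dca1_ripple_gain > 0:
            gains = rng.exponential(1.0, size=onsets.size)
            lam = cfg.dca1_rate_hz * cfg.dca1_ripple_gain * gains * (w1 - w0)
            counts = rng.poisson(lam)
            for o, k in zip(onsets, counts):
                if k:
                    ts.append(o + w0 + rng.random(k) * (w1 - w0))
        times[uid] = np.sort(np.concatenate(ts))
    return SpikeData(times=times, regions={u: "dCA1" for u in range(cfg.n_dca1)})


def generate_coupled_population(
    cfg: SessionConfig,
    dca1_spikes: SpikeData,
    coupled_onsets: np.ndarray,
    uncoupled_onsets: np.ndarray = (),
    weights: Optional[np.ndarray] = None,
    schedule: Optional[WindowSchedule] = None,
    baseline_rate_hz: float = 2.0,
    unit_id: Optional[int] = None,
) -> np.ndarray:
    """One BLA target unit whose ripple-window counts follow a Poisson GLM.

    For each coupled ripple and window pair, the count in the lag-shifted
    target window is Poisson with log-rate intercept + weights . (dCA1
    counts in the source window).  Uncoupled ripples (e.g. pre-training
    sleep) use the intercept only (zero weights).  Outside ripple windows
    the unit is homogeneous Poisson at ``baseline_rate_hz``.
    """
    rng = cfg.rng(f"target{unit_id if unit_id is not None else ''}")
    if schedule is None:
        schedule = WindowSchedule(lag_ms=cfg.lag_ms)
    unit_ids = dca1_spikes.unit_ids("dCA1")
    if weights is None:
        weights = cfg.coupling_weights
    weights = np.asarray(weights, dtype=float)
    if weights.size != len(unit_ids):
        raise ValueError("coupling_weights length must equal n_dca1")

    coupled_onsets = np.asarray(coupled_onsets, dtype=float)
    uncoupled_onsets = np.asarray(uncoupled_onsets, dtype=float)
    all_onsets = np.concatenate([coupled_onsets, uncoupled_onsets])

    # baseline spikes outside the union of target windows
    ts = _poisson_train(baseline_rate_hz, 0.0, cfg.session_end_s, rng)
    tws = schedule.target_windows_ms
    lo = min(w[0] for w in tws) / 1000.0
    hi = max(w[1] for w in tws) / 1000.0
    if all_onsets.size:
        in_window = np.zeros(ts.size, dtype=bool)
        for o in all_onsets:
            i0, i1 = np.searchsorted(ts, [o + lo, o + hi])
            in_window[i0:i1] = True
        ts = ts[~in_window]

    spikes = [ts]
    for onsets, w in ((coupled_onsets, weights), (uncoupled_onsets, None)):
        if onsets.size == 0:
            continue
        for src, tgt in zip(schedule.source_windows_ms, tws):
            if w is not None:
                X = np.column_stack(
                    [counts_in_windows(dca1_spikes.times[u], onsets, src) for u in unit_ids]
                )
                lam = np.exp(np.clip(cfg.coupling_intercept + X @ w, -30, 10))
            else:
                lam = np.full(onsets.size, np.exp(cfg.coupling_intercept))
            counts = rng.poisson(lam)
            t0, t1 = tgt[0] / 1000.0, tgt[1] / 1000.0
            for o, k in zip(onsets, counts):
                if k:
                    spikes.append(o + t0 + rng.random(k) * (t1 - t0))
    return np.sort(np.concatenate(spikes))


@dataclass
class PlaceCellSpec:
    center_cm: tuple[float, float]
    sigma_cm: float
    peak_hz: float
    uniform: bool = False  # if True, fire position-independently at peak_hz


def generate_trajectory(
    cfg: SessionConfig,
    duration_s: float,
    t0: float = 0.0,
    speed_cm_s: float = 12.0,
    tau_s: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> PositionTrace:
    """Smoothed (Ornstein-Uhlenbeck velocity) random walk, reflected at the
    arena walls."""
    if rng is None:
        rng = cfg.rng("trajectory")
    w, h = cfg.arena_cm
    if w < 2 or h < 2:
        raise ValueError("arena smaller than 2x2 bins")
    dt = 1.0 / cfg.position_fs
    n = int(round(duration_s / dt))
    pos = np.empty((n, 2))
    p = np.array([w / 2, h / 2])
    v = np.zeros(2)
    sig = speed_cm_s * np.sqrt(2 * dt / tau_s)
    for i in range(n):
        v += -v * dt / tau_s + sig * rng.standard_normal(2)
        p = p + v * dt
        for d, lim in enumerate((w, h)):
            if p[d] < 0:
                p[d], v[d] = -p[d], -v[d]
            if p[d] > lim:
                p[d], v[d] = 2 * lim - p[d], -v[d]
        pos[i] = p
    t = t0 + np.arange(n) * dt
    return PositionTrace(t=t, x=pos[:, 0], y=pos[:, 1])


def generate_place_cell_spikes(
    cfg: SessionConfig,
    position: PositionTrace,
    specs: Sequence[PlaceCellSpec],
    rng: Optional[np.random.Generator] = None,
) -> list[np.ndarray]:
    """Inhomogeneous-Poisson spike trains with Gaussian spatial tuning (or
    position-independent for uniform specs), one per spec."""
    if rng is None:
        rng = cfg.rng("place")
    dt = np.median(np.diff(position.t))
    out = []
    for spec in specs:
        if spec.uniform:
            rate = np.full(position.t.size, spec.peak_hz)
        else:
            cx, cy = spec.center_cm
            d2 = (position.x - cx) ** 2 + (position.y - cy) ** 2
            rate = spec.peak_hz * np.exp(-d2 / (2 * spec.sigma_cm**2))
        counts = rng.poisson(rate * dt)
        idx = np.repeat(np.arange(counts.size), counts)
        out.append(np.sort(position.t[idx] + rng.random(idx.size) * dt))
    return out


def default_config(seed: int = 0) -> SessionConfig:
    """The strong-effect planted session used by the end-to-end oracles:
    four BLA assemblies, one of which is ripple-yoked post-training only
    (35-ms lag) and shock-activated, i.e. the planted memory assembly."""
    return SessionConfig(
        seed=seed,
        lfp_fs=1000.0,
        bla_rate_hz=5.0,
        assembly_specs=(
            AssemblySpec(
                members=(0, 1, 2, 3),
                event_rate_hz=0.05,
                gain=12.0,
                yoked_fraction=0.35,
                lag_ms=35.0,
                shock_gain=4.0,
            ),
            AssemblySpec(members=(4, 5, 6, 7), event_rate_hz=0.3, gain=12.0),
            AssemblySpec(members=(8, 9, 10, 11), event_rate_hz=0.3, gain=12.0),
            AssemblySpec(members=(12, 13, 14, 15, 16), event_rate_hz=0.3, gain=12.0),
        ),
    )


def make_default_session(seed: int = 0, with_position: bool = True) -> SessionBundle:
    """Generate the full default planted session as a SessionBundle.

    The ``truth`` dict records planted ripples, assemblies (index 0 is the
    planted memory assembly), dCA1 place-field centers and shock times.
    """
    cfg = default_config(seed)
    lfp, ripple_truths = generate_lfp(cfg)
    bla, assembly_truths = generate_assembly_spikes(cfg, ripple_truths)
    dca1 = generate_dca1_spikes(cfg, ripple_truths)

    position = None
    place_specs = []
    if with_position:
        test = next(e for e in cfg.epochs() if e.name == "test")
        rng = cfg.rng("place")
        position = generate_trajectory(cfg, test.duration_s, t0=test.start_s, rng=rng)
        w, h = cfg.arena_cm
        place_specs = [
            PlaceCellSpec(
                center_cm=(rng.uniform(0.1 * w, 0.9 * w), rng.uniform(0.1 * h, 0.9 * h)),
                sigma_cm=5.0,
                peak_hz=8.0,
            )
            for _ in range(cfg.n_dca1)
        ]
        trains = generate_place_cell_spikes(cfg, position, place_specs, rng=rng)
        for uid, extra in zip(range(cfg.n_dca1), trains):
            dca1.times[uid] = np.sort(np.concatenate([dca1.times[uid], extra]))

    truth = {
        "config": cfg,
        "ripples": ripple_truths,
        "assemblies": assembly_truths,
        "memory_assembly_index": 0,
        "place_specs": place_specs,
    }
    return SessionBundle(
        spikes=dca1.merge(bla),
        epochs=cfg.epochs(),
        lfp=lfp,
        shock_times=cfg.shock_times(),
        position=position,
        truth=truth,
    )
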