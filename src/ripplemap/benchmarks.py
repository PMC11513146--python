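"""From-scratch recomputation of the calibration/recovery benchmarks.

Each function generates its own synthetic inputs (seeded), runs the package
end to end and returns plain metric dicts.  The pytest acceptance suite
asserts the documented tolerances on these metrics; the acceptance script
prints them.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import wilcoxon

from .assemblies import (
    BinnedMatrix,
    bin_and_zscore,
    count_significant_components,
    extract_assembly_patterns,
)
from .core import Epoch, RippleEvent, SpikeData
from .decoding import (
    WindowSchedule,
    decode_and_score,
    extract_ripple_counts,
    fit_glm,
    weight_split_decoding,
)
from .memory import permutation_test_proportion
from .pipeline import RunConfig, run_pipeline
from .ripples import detect_ripples, ripple_envelope
from .spatial import RateMap, build_rate_map, spatial_information
from .synthetic import (
    AssemblySpec,
    PlaceCellSpec,
    RippleTruth,
    SessionConfig,
    _draw_event_times,
    generate_assembly_spikes,
    generate_coupled_population,
    generate_dca1_spikes,
    generate_lfp,
    generate_place_cell_spikes,
    generate_trajectory,
    make_default_session,
)

# ---------------------------------------------------------------- helpers


def _poisson_train(rate, T, rng, t0=0.0):
    n = rng.poisson(rate * T)
    return np.sort(t0 + rng.random(n) * T)


def _plan_ripples(cfg: SessionConfig, rng) -> list[RippleTruth]:
    """Ripple schedule without synthesizing an LFP (for spike-only stages)."""
    out = []
    for e in cfg.sleep_epochs():
        peaks = _draw_event_times(
            e, cfg.ripple_rate_hz, rng, cfg.min_ripple_gap_s,
            n_exact=cfg.n_ripples_per_epoch,
        )
        for tc in peaks:
            amp = max(3.0, rng.normal(*cfg.ripple_amp_sd))
            dur = max(0.03, rng.normal(*cfg.ripple_dur_ms) / 1000.0)
            out.append(
                RippleTruth(
                    onset_s=tc - dur / 2, peak_s=tc, offset_s=tc + dur / 2,
                    amplitude_sd=amp, epoch=e.name,
                )
            )
    out.sort(key=lambda r: r.onset_s)
    return out


# -------------------------------------------------- 1. MP-bound calibration


def mp_calibration(seed: int = 0, n_seeds: int = 100, n_units: int = 58,
                   n_bins: int = 10_000, rate: float = 0.125) -> dict:
    """Fraction of i.i.d. Poisson matrices with zero significant components."""
    zero = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        counts = rng.poisson(rate, size=(n_units, n_bins)).astype(float)
        z = counts - counts.mean(axis=1, keepdims=True)
        z /= z.std(axis=1, keepdims=True)
        mat = BinnedMatrix(
            z=z, counts=counts, bin_ms=25.0, t0=0.0,
            unit_ids=np.arange(n_units), excluded_ids=np.array([], dtype=int),
        )
        zero += count_significant_components(mat) == 0
    return {"fraction_zero": zero / n_seeds, "n_seeds": n_seeds}


# --------------------------------------------- 2. planted-assembly recovery


def planted_recovery(seed: int = 0, n_seeds: int = 20) -> dict:
    """Two disjoint planted assemblies (gain 8, 0.5 events/s, 20 min):
    fraction of seeds with both member sets recovered exactly."""
    perfect = 0
    for s in range(n_seeds):
        cfg = SessionConfig(
            seed=seed + s, n_bla=58, bla_rate_hz=5.0,
            epoch_durations={"post_sleep": 1200.0},
            assembly_specs=(
                AssemblySpec(members=(3, 7, 12), event_rate_hz=0.5, gain=8.0),
                AssemblySpec(members=(20, 21, 40, 41), event_rate_hz=0.5, gain=8.0),
            ),
        )
        spikes, truths = generate_assembly_spikes(cfg)
        mat = bin_and_zscore(spikes, cfg.epochs()[0])
        n = count_significant_components(mat)
        if n < 1:
            continue
        patterns = extract_assembly_patterns(mat, n, seed=0)
        found = {p.members for p in patterns}
        if all(t.member_ids in found for t in truths):
            perfect += 1
    return {"fraction_perfect": perfect / n_seeds, "n_seeds": n_seeds}


# --------------------------------------------------- 3. ripple detection


def ripple_detection_metrics(seed: int = 1) -> dict:
    """Precision/recall on 50 injected 12-s.d./60-ms ripples plus exact
    threshold monotonicity.  A detection matches an injection when their
    intervals overlap or their peaks are within 10 ms."""
    cfg = SessionConfig(
        seed=seed, lfp_fs=1000.0,
        epoch_durations={"pre_sleep": 100.0, "post_sleep": 100.0},
        ripple_amp_sd=(12.0, 0.0), ripple_dur_ms=(60.0, 0.0),
        n_ripples_per_epoch=25,
    )
    lfp, truths = generate_lfp(cfg)
    env = ripple_envelope(lfp)
    events = detect_ripples(env, lfp.fs, t0=lfp.t0)

    def matches(e, r):
        return (e.onset_s < r.offset_s and e.offset_s > r.onset_s) or abs(
            e.peak_s - r.peak_s
        ) < 0.01

    recall = float(np.mean([any(matches(e, r) for e in events) for r in truths]))
    precision = float(np.mean([any(matches(e, r) for r in truths) for e in events]))
    at3 = detect_ripples(env, lfp.fs, peak_threshold_sd=3.0, t0=lfp.t0)
    peaks3 = {round(e.peak_s, 6) for e in at3}
    monotone = all(round(e.peak_s, 6) in peaks3 for e in events)
    return {
        "precision": precision,
        "recall": recall,
        "monotone": bool(monotone),
        "n_injected": len(truths),
        "n_detected": len(events),
    }


# --------------------------------- 4. memory classification, end to end


def memory_classification_end_to_end(seed: int = 0) -> dict:
    """Full pipeline on the default planted session."""
    bundle = make_default_session(seed=seed)
    res = run_pipeline(bundle, RunConfig(seed=seed))
    memory = [ix for ix in res.memory_table if ix.is_memory]
    planted = bundle.truth["assemblies"][0].member_ids
    matches = False
    rmi = mai = float("nan")
    if len(memory) == 1:
        pat = next(p for p in res.patterns if p.id == memory[0].id)
        matches = pat.members == planted
        rmi, mai = memory[0].rmi, memory[0].mai
    others = [ix for ix in res.memory_table if not ix.is_memory]
    others_ok = sum(
        not (
            ix.rmi is not None and ix.mai is not None
            and ix.rmi > 1 and ix.mai > 2
        )
        for ix in others
    )
    return {
        "n_memory": len(memory),
        "matches_planted": bool(matches),
        "memory_rmi": rmi,
        "memory_mai": mai,
        "others_below_threshold_fraction": others_ok / len(others) if others else 1.0,
    }


# ----------------------------------------- 5. permutation-test calibration


def permutation_calibration(seed: int = 0, n_null: int = 200, n_power: int = 20) -> dict:
    """Type-I rate on exchangeable (shuffled-vs-shuffled) data and power on
    planted ripple-yoked coupling (3 yoked of 12 assemblies)."""
    T = 600.0

    def bursty(rng):
        centers = np.sort(rng.random(rng.poisson(0.08 * T)) * T)
        ev = [c + rng.normal(0, 0.010, rng.poisson(6.0)) for c in centers]
        return np.sort(np.concatenate(ev)) if ev else np.array([])

    rejections = 0
    for s in range(n_null):
        rng = np.random.default_rng(seed + 1000 + s)
        trains = [bursty(rng) for _ in range(12)]
        refs = np.sort(rng.random(150) * T)
        res = permutation_test_proportion(
            trains, refs, [(0.0, T)], n_shuffles=100, seed=seed + s
        )
        rejections += res.p_value < 0.05

    power_hits = 0
    for s in range(n_power):
        rng = np.random.default_rng(seed + s)
        ripples = np.sort(rng.random(300) * T)
        trains = [_poisson_train(2.0, T, rng) for _ in range(9)]
        for _ in range(3):
            sel = rng.choice(300, 100, replace=False)
            trains.append(
                np.sort(
                    np.concatenate(
                        [
                            ripples[sel] + 0.035 + rng.normal(0, 0.005, 100),
                            _poisson_train(1.5, T, rng),
                        ]
                    )
                )
            )
        res = permutation_test_proportion(
            trains, ripples, [(0.0, T)], n_shuffles=100, seed=seed + s
        )
        power_hits += res.p_value < 0.05
    return {
        "type_i_rate": rejections / n_null,
        "power": power_hits / n_power,
        "n_null": n_null,
        "n_power": n_power,
    }


# --------------------------------------------- 6. GLM pre/post dissociation


def _coupled_setup(seed: int, weights: np.ndarray, n_ripples: int = 250,
                   epoch_durations=None, baseline_rate: float = 2.0):
    cfg = SessionConfig(
        seed=seed, lfp_fs=1000.0, n_dca1=weights.size,
        epoch_durations=epoch_durations
        or {"pre_sleep": 600.0, "post_sleep": 600.0},
        n_ripples_per_epoch=n_ripples, coupling_intercept=-0.5,
    )
    truths = _plan_ripples(cfg, cfg.rng("ripple_plan"))
    dca1 = generate_dca1_spikes(cfg, truths)
    pre = np.array([r.onset_s for r in truths if r.epoch == "pre_sleep"])
    post = np.array([r.onset_s for r in truths if r.epoch == "post_sleep"])
    target = generate_coupled_population(
        cfg, dca1, coupled_onsets=post, uncoupled_onsets=pre,
        weights=weights, baseline_rate_hz=baseline_rate,
    )
    return cfg, dca1, pre, post, target


def glm_dissociation(seed: int = 0, n_seeds: int = 20, n_shuffles: int = 50) -> dict:
    """Decoding beats the shuffle null for post-sleep (coupling on) but not
    pre-sleep (coupling off); coefficient recovery slope at 500 ripples."""
    rng = np.random.default_rng(seed)
    w = rng.uniform(0.1, 0.4, 25)
    window = 3  # the (0,100) -> (35,135) pair, strongest planted coupling
    post_sig = pre_nonsig = 0
    for s in range(n_seeds):
        _, dca1, pre, post, target = _coupled_setup(seed + s, w)
        d_post = decode_and_score(
            dca1, target, post, split_seed=s, n_shuffles=n_shuffles
        )
        d_pre = decode_and_score(
            dca1, target, pre, split_seed=s, n_shuffles=n_shuffles
        )
        post_sig += d_post.significant()[window]
        pre_nonsig += not d_pre.significant()[window]

    _, dca1, _, post, target = _coupled_setup(seed + 777, w, n_ripples=500,
                                              epoch_durations={"post_sleep": 1200.0})
    Xs, ys, _ = extract_ripple_counts(dca1, target, post, WindowSchedule())
    model = fit_glm(Xs[window], ys[window])
    slope = float(np.polyfit(w, model.coef, 1)[0])
    return {
        "post_significant_fraction": post_sig / n_seeds,
        "pre_nonsignificant_fraction": pre_nonsig / n_seeds,
        "coefficient_slope": slope,
        "n_seeds": n_seeds,
    }


# ------------------------------------------------------- 7. weight split


def weight_split_contrast(seed: int = 0, n_seeds: int = 5, n_shuffles: int = 100) -> dict:
    """Broad coupling: both ranked halves decode above null.  Sparse
    coupling (half the units): only the top half does."""
    n_units = 24
    window = 3
    broad = np.full(n_units, 0.12)
    # sparse: only a third of the units coupled, with strong weights and a
    # quiet target baseline so the cross-correlation ranking separates them
    sparse = np.zeros(n_units)
    sparse[: n_units // 3] = 0.5

    def run(weights, s, baseline):
        cfg = SessionConfig(
            seed=s, lfp_fs=1000.0, n_dca1=n_units,
            epoch_durations={"post_sleep": 800.0},
            n_ripples_per_epoch=400, coupling_intercept=-1.0,
        )
        truths = _plan_ripples(cfg, cfg.rng("ripple_plan"))
        dca1 = generate_dca1_spikes(cfg, truths)
        post = np.array([r.onset_s for r in truths])
        target = generate_coupled_population(
            cfg, dca1, coupled_onsets=post, weights=weights,
            baseline_rate_hz=baseline,
        )
        ws = weight_split_decoding(
            dca1, target, post, split_seed=0, n_shuffles=n_shuffles
        )
        return {half: d.significant()[window] for half, d in ws.items()}

    broad_both = sparse_top = sparse_bottom_quiet = 0
    for s in range(n_seeds):
        rb = run(broad, seed + s, baseline=1.0)
        rs = run(sparse, seed + 100 + s, baseline=0.5)
        broad_both += rb["top"] and rb["bottom"]
        sparse_top += rs["top"]
        sparse_bottom_quiet += not rs["bottom"]
    return {
        "broad_both_fraction": broad_both / n_seeds,
        "sparse_top_fraction": sparse_top / n_seeds,
        "sparse_bottom_nonsig_fraction": sparse_bottom_quiet / n_seeds,
        "n_seeds": n_seeds,
    }


# --------------------------------------------------- 8. spatial information


def spatial_information_checks(seed: int = 3) -> dict:
    cfg = SessionConfig(seed=seed)
    pos = generate_trajectory(cfg, 600.0)
    specs = [
        PlaceCellSpec(center_cm=(25, 25), sigma_cm=3.0, peak_hz=20.0),
        PlaceCellSpec(center_cm=(25, 25), sigma_cm=15.0, peak_hz=3.2),
        PlaceCellSpec(center_cm=(0, 0), sigma_cm=1.0, peak_hz=2.0, uniform=True),
    ]
    tight, broad, uniform = (
        spatial_information(build_rate_map(ts, pos, arena_cm=cfg.arena_cm))
        for ts in generate_place_cell_spikes(cfg, pos, specs)
    )
    hand = RateMap(
        rate_hz=np.array([[2.0, 0.0]]),
        occupancy_p=np.array([[0.5, 0.5]]),
        visited=np.array([[True, True]]),
        bin_cm=1.0,
    )
    return {
        "uniform_si": float(uniform),
        "tight_si": float(tight),
        "broad_si": float(broad),
        "two_bin_si": float(spatial_information(hand)),
    }


# ------------------------------------------------------ 9. content scores


def content_score_checks(seed: int = 0) -> dict:
    from .taxonomy import firing_difference_scores, selectivity_index

    T = 2400.0
    rng = np.random.default_rng(seed)

    def ripple(onset, amp, label):
        return RippleEvent(
            onset_s=onset, peak_s=onset + 0.02, offset_s=onset + 0.05,
            amplitude_sd=amp, label=label,
        )

    # exchangeable null (3:1 class ratio equalizes m_n and m1_m2 variance)
    onsets = np.sort(rng.random(400) * T)
    labels = np.array(["memory"] * 300 + ["non_memory"] * 100)
    rng.shuffle(labels)
    labeled = [ripple(o, 6.0, l) for o, l in zip(onsets, labels)]
    spikes = SpikeData(
        times={u: _poisson_train(3.0, T, rng) for u in range(20)},
        regions={u: "dCA1" for u in range(20)},
    )
    scores = firing_difference_scores(spikes, labeled, split_seed=seed)
    mn = np.array([s.m_n for s in scores])
    m12 = np.array([s.m1_m2 for s in scores])

    def amp_set(mu_mem, mu_non, s):
        r = np.random.default_rng(s)
        mem = [ripple(i + r.random() * 0.2, max(3.1, r.normal(mu_mem, 2.0)), "memory")
               for i in range(200)]
        non = [ripple(300 + i + r.random() * 0.2, max(3.1, r.normal(mu_non, 2.0)), "non_memory")
               for i in range(2000)]
        return mem + non

    identical = amp_set(8.0, 8.0, seed + 1)
    enlarged = amp_set(10.0, 7.0, seed + 2)
    s_ident = [selectivity_index(identical, sd) for sd in (4.0, 6.0)]
    s_enl = [selectivity_index(enlarged, sd) for sd in (4.0, 6.0, 8.0)]
    return {
        "scores_in_unit_interval": bool(np.all((mn >= 0) & (mn <= 1))),
        "exchangeable_p": float(wilcoxon(mn, m12).pvalue),
        "selectivity_identical": [float(s) for s in s_ident],
        "selectivity_enlarged": [float(s) for s in s_enl],
        "selectivity_ordered": bool(s_enl[2] >= s_enl[1] >= s_enl[0]),
    }
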