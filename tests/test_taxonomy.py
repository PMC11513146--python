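import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ripplemap.core import ActivationTrace, RippleEvent, SpikeData
from ripplemap.taxonomy import (
    classify_ripples,
    compare_ripple_properties,
    contrast_score,
    firing_difference_scores,
    population_peri_ripple_profiles,
    selectivity_index,
)
from tests.conftest import poisson_train


def _ripple(onset, amp=8.0, dur=0.05, label="unlabeled"):
    return RippleEvent(
        onset_s=onset, peak_s=onset + 0.02, offset_s=onset + dur,
        amplitude_sd=amp, label=label,
    )


def _ripples_with_amps(amps, label, t0=0.0, gap=1.0, rng=None):
    rng = rng or np.random.default_rng(0)
    return [
        _ripple(t0 + i * gap + rng.random() * 0.2, amp=a, label=label)
        for i, a in enumerate(amps)
    ]


# --- ripple classification ------------------------------------------------


def _trace(strength, bin_s=0.025, t0=0.0):
    return ActivationTrace(strength=np.asarray(strength, float), bin_s=bin_s, t0=t0)


def test_flat_trace_gives_zero_memory_ripples():
    rng = np.random.default_rng(0)
    trace = _trace(rng.normal(0, 1, 4000))
    ripples = [_ripple(5.0 + i) for i in range(20)]
    labeled = classify_ripples(ripples, trace)
    # noise trace: only chance-level coincidences; all labels assigned
    assert all(r.label in ("memory", "non_memory") for r in labeled)


def test_no_trace_leaves_unlabeled():
    labeled = classify_ripples([_ripple(1.0)], None)
    assert labeled[0].label == "unlabeled"


def test_yoked_activation_is_labeled_memory():
    strength = np.zeros(4000)
    onsets = np.arange(5.0, 95.0, 5.0)
    hot = ((onsets + 0.05) / 0.025).astype(int)
    strength[hot[::2]] = 50.0  # every other ripple has a supra bin at +50 ms
    labeled = classify_ripples([_ripple(o) for o in onsets], _trace(strength))
    labels = [r.label for r in labeled]
    assert labels[::2] == ["memory"] * len(labels[::2])
    assert labels[1::2] == ["non_memory"] * len(labels[1::2])


def test_classification_partitions_ripples(default_result):
    labeled = default_result.labeled_ripples
    assert labeled
    assert all(r.label in ("memory", "non_memory") for r in labeled)


def test_raising_cut_never_adds_memory_labels():
    rng = np.random.default_rng(1)
    strength = rng.exponential(1.0, 8000)
    ripples = [_ripple(3.0 + i * 2) for i in range(40)]
    at2 = classify_ripples(ripples, _trace(strength), threshold_sd=2.0)
    at4 = classify_ripples(ripples, _trace(strength), threshold_sd=4.0)
    mem2 = {r.onset_s for r in at2 if r.label == "memory"}
    mem4 = {r.onset_s for r in at4 if r.label == "memory"}
    assert mem4 <= mem2


# --- property comparison --------------------------------------------------


def test_property_comparison_detects_planted_difference():
    rng = np.random.default_rng(2)
    mem = _ripples_with_amps(rng.normal(10, 1.5, 200), "memory", rng=rng)
    mem = [  # enlarge durations too
        RippleEvent(r.onset_s, r.peak_s, r.onset_s + 0.08, r.amplitude_sd, "memory")
        for r in mem
    ]
    non = _ripples_with_amps(rng.normal(7, 1.5, 2000), "non_memory", t0=300.0, rng=rng)
    cmpres = compare_ripple_properties(mem + non)
    assert cmpres.p_amplitude < 0.01
    assert cmpres.p_duration < 0.01
    assert cmpres.median_amplitude["memory"] > cmpres.median_amplitude["non_memory"]


def test_property_comparison_small_class_gives_na():
    rng = np.random.default_rng(3)
    mem = _ripples_with_amps(rng.normal(8, 1, 3), "memory", rng=rng)
    non = _ripples_with_amps(rng.normal(8, 1, 50), "non_memory", t0=100.0, rng=rng)
    cmpres = compare_ripple_properties(mem + non)
    assert cmpres.p_amplitude is None
    assert cmpres.median_amplitude["memory"] == pytest.approx(
        np.median([r.amplitude_sd for r in mem])
    )


def test_property_comparison_null_calibration():
    rejections = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        mem = _ripples_with_amps(rng.normal(8, 1.5, 100), "memory", rng=rng)
        non = _ripples_with_amps(rng.normal(8, 1.5, 400), "non_memory", t0=200.0, rng=rng)
        if compare_ripple_properties(mem + non).p_amplitude < 0.05:
            rejections += 1
    assert rejections <= 4


# --- contrast scores ------------------------------------------------------


def test_contrast_score_basics():
    assert contrast_score(2.0, 2.0) == 0.0
    assert contrast_score(2.0, 0.0) == 1.0
    assert np.isnan(contrast_score(0.0, 0.0))


@given(
    st.floats(0.0, 100.0), st.floats(0.0, 100.0), st.floats(0.01, 50.0)
)
@settings(max_examples=100, deadline=None)
def test_contrast_score_properties(a, b, c):
    if a + b == 0:
        return
    s = contrast_score(a, b)
    assert 0.0 <= s <= 1.0
    assert s == contrast_score(b, a)  # symmetric
    assert s == pytest.approx(contrast_score(c * a, c * b))  # scale-invariant


def _labeled_null(rng, n_mem=300, n_non=100, T=2400.0):
    ons = np.sort(rng.random(n_mem + n_non) * T)
    labels = np.array(["memory"] * n_mem + ["non_memory"] * n_non)
    rng.shuffle(labels)
    return [_ripple(o, label=l) for o, l in zip(ons, labels)]


def test_firing_difference_scores_exchangeable_null():
    # class sizes 3:1 equalize the sampling variance of m_n and m1_m2
    from scipy.stats import wilcoxon

    rng = np.random.default_rng(0)
    labeled = _labeled_null(rng)
    T = 2400.0
    spikes = SpikeData(
        times={u: poisson_train(3.0, T, rng) for u in range(20)},
        regions={u: "dCA1" for u in range(20)},
    )
    scores = firing_difference_scores(spikes, labeled, split_seed=0)
    assert len(scores) == 20
    mn = np.array([s.m_n for s in scores])
    m12 = np.array([s.m1_m2 for s in scores])
    assert np.all((mn >= 0) & (mn <= 1))
    assert wilcoxon(mn, m12).pvalue > 0.05
    assert all(s.group == "none" for s in scores)


def test_firing_difference_scores_require_both_classes():
    rng = np.random.default_rng(1)
    spikes = SpikeData(times={0: np.array([1.0])}, regions={0: "dCA1"})
    only_mem = [_ripple(float(i), label="memory") for i in range(10)]
    with pytest.raises(ValueError):
        firing_difference_scores(spikes, only_mem)


def test_silent_unit_excluded():
    rng = np.random.default_rng(2)
    labeled = _labeled_null(rng, n_mem=20, n_non=20, T=100.0)
    spikes = SpikeData(
        times={0: np.array([]), 1: poisson_train(5.0, 100.0, rng)},
        regions={0: "dCA1", 1: "dCA1"},
    )
    scores = firing_difference_scores(spikes, labeled, split_seed=0)
    assert [s.unit_id for s in scores] == [1]


# --- selectivity ----------------------------------------------------------


def test_selectivity_identical_distributions_near_half():
    rng = np.random.default_rng(4)
    mem = _ripples_with_amps(rng.normal(8, 2, 200).clip(3.1), "memory", rng=rng)
    non = _ripples_with_amps(rng.normal(8, 2, 2000).clip(3.1), "non_memory", t0=300, rng=rng)
    for sd in (4.0, 6.0):
        assert selectivity_index(mem + non, sd) == pytest.approx(0.5, abs=0.05)


def test_selectivity_all_above_threshold_memory():
    mem = _ripples_with_amps([12.0] * 10, "memory")
    non = _ripples_with_amps([5.0] * 10, "non_memory", t0=100)
    assert selectivity_index(mem + non, 8.0) == 1.0


def test_selectivity_requires_both_classes():
    with pytest.raises(ValueError):
        selectivity_index(_ripples_with_amps([8.0] * 5, "memory"), 4.0)


def test_selectivity_increases_with_threshold_under_enlargement():
    rng = np.random.default_rng(5)
    mem = _ripples_with_amps(rng.normal(10, 2, 200).clip(3.1), "memory", rng=rng)
    non = _ripples_with_amps(rng.normal(7, 2, 2000).clip(3.1), "non_memory", t0=300, rng=rng)
    s = [selectivity_index(mem + non, sd) for sd in (4.0, 6.0, 8.0)]
    assert s[2] >= s[1] >= s[0]


# --- population profiles --------------------------------------------------


def test_population_profiles_recover_planted_groups():
    rng = np.random.default_rng(6)
    T = 1200.0
    mem_on = np.sort(rng.random(150) * (T / 2))
    non_on = np.sort(T / 2 + rng.random(300) * (T / 2))
    times, regions = {}, {}
    # 3 up-regulated (extra spikes at memory ripples), 3 unmodulated
    for u in range(6):
        base = poisson_train(3.0, T, rng)
        if u < 3:
            extra = np.concatenate(
                [mem_on + 0.02 + rng.normal(0, 0.005, mem_on.size) for _ in range(2)]
            )
            base = np.sort(np.concatenate([base, extra]))
        times[u] = base
        regions[u] = "dCA1"
    labeled = [_ripple(o, label="memory") for o in mem_on] + [
        _ripple(o, label="non_memory") for o in non_on
    ]
    profiles = population_peri_ripple_profiles(
        SpikeData(times=times, regions=regions), labeled
    )
    groups = {p.unit_id: p.group for p in profiles}
    assert all(groups[u] == "up" for u in range(3))
    assert sum(groups[u] == "none" for u in range(3, 6)) >= 2
    for p in profiles[:3]:
        assert p.peak_rate_memory_hz > p.peak_rate_non_memory_hz


def test_identical_response_grouped_none():
    rng = np.random.default_rng(7)
    T = 1200.0
    ons = np.sort(rng.random(300) * T)
    labels = ["memory" if i % 3 == 0 else "non_memory" for i in range(300)]
    labeled = [_ripple(o, label=l) for o, l in zip(ons, labels)]
    spikes = SpikeData(
        times={0: poisson_train(4.0, T, rng)}, regions={0: "dCA1"}
    )
    profiles = population_peri_ripple_profiles(spikes, labeled)
    assert profiles[0].group == "none"
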