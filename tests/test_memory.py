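import numpy as np
import pytest

from ripplemap.memory import (
    MemoryIndices,
    ModulationResult,
    classify_memory_units,
    compute_mai,
    compute_rmi,
    is_ripple_modulated,
    modulation_from_z,
    peri_event_histogram,
    permutation_test_proportion,
    shuffle_reference_times,
)
from tests.conftest import poisson_train

T = 600.0


def _mk_peh(event_times, refs, **kw):
    return peri_event_histogram(np.asarray(event_times), np.asarray(refs), **kw)


# --- peri-event histogram -------------------------------------------------


def test_peh_requires_references():
    with pytest.raises(ValueError):
        peri_event_histogram(np.array([1.0]), np.array([]))


def test_peh_bin_count():
    peh = _mk_peh([1.0], [1.0])
    assert peh.lag_centers_ms.size == 200  # 2*500/5


def test_peh_doubling_references_is_identity():
    rng = np.random.default_rng(0)
    ev = poisson_train(3.0, T, rng)
    refs = np.sort(rng.random(50) * T)
    a = _mk_peh(ev, refs)
    b = _mk_peh(ev, np.sort(np.concatenate([refs, refs])))
    np.testing.assert_allclose(a.rate_hz, b.rate_hz)
    np.testing.assert_allclose(a.smoothed_hz, b.smoothed_hz)
    # the empirical-sd z is a pure function of the (duplicated) histogram
    a_emp = _mk_peh(ev, refs, baseline_sd="empirical")
    b_emp = _mk_peh(
        ev, np.sort(np.concatenate([refs, refs])), baseline_sd="empirical"
    )
    np.testing.assert_allclose(a_emp.z, b_emp.z)


def test_peh_null_calibration():
    spurious = 0
    high_z = 0
    for seed in range(60):
        rng = np.random.default_rng(seed)
        peh = _mk_peh(poisson_train(2.0, T, rng), np.sort(rng.random(200) * T))
        spurious += bool(is_ripple_modulated(peh))
        high_z += np.abs(peh.z[np.abs(peh.lag_centers_ms) <= 150]).max() >= 3.3
    assert spurious <= 3  # modulation rule false-positive rate ~<=5%
    assert high_z <= 9  # isolated high-z bins are slightly more common


def test_peh_planted_lag_peak():
    rng = np.random.default_rng(1)
    refs = np.sort(rng.random(200) * T)
    sel = rng.choice(refs.size, 80, replace=False)
    ev = np.sort(
        np.concatenate(
            [refs[sel] + 0.035 + rng.normal(0, 0.005, 80), poisson_train(1.0, T, rng)]
        )
    )
    peh = _mk_peh(ev, refs)
    peak_lag = peh.lag_centers_ms[np.argmax(peh.smoothed_hz)]
    assert 20 <= peak_lag <= 50


# --- modulation rule ------------------------------------------------------


def _flat_peh():
    rng = np.random.default_rng(3)
    return _mk_peh(poisson_train(2.0, T, rng), np.sort(rng.random(100) * T))


def test_all_zero_z_is_none():
    peh = _flat_peh()
    peh.z[:] = 0.0
    assert is_ripple_modulated(peh).direction == "none"


def test_two_isolated_bins_insufficient():
    peh = _flat_peh()
    peh.z[:] = 0.0
    peh.z[100] = 5.0
    peh.z[102] = 5.0
    assert is_ripple_modulated(peh).direction == "none"


def test_three_consecutive_bins_trigger_up():
    peh = _flat_peh()
    peh.z[:] = 0.0
    peh.z[100:103] = 3.3
    res = is_ripple_modulated(peh)
    assert res.direction == "up"
    assert res.first_lag_ms is not None


def test_down_modulation_and_up_precedence():
    peh = _flat_peh()
    peh.z[:] = 0.0
    peh.z[95:98] = -4.0
    assert is_ripple_modulated(peh).direction == "down"
    peh.z[100:103] = 4.0
    assert is_ripple_modulated(peh).direction == "up"


def test_runs_outside_test_window_ignored():
    peh = _flat_peh()
    peh.z[:] = 0.0
    peh.z[:3] = 9.0  # lag ~ -500 ms
    assert is_ripple_modulated(peh).direction == "none"


def test_modulation_reproducible_from_z_trace():
    peh = _flat_peh()
    direct = is_ripple_modulated(peh)
    rebuilt = modulation_from_z(peh.z, peh.lag_centers_ms)
    assert direct == rebuilt


# --- RMI / MAI ------------------------------------------------------------


def _peh_with_peak(peak_hz, rng_seed=0):
    """Synthetic PEH whose smoothed peak in (0, 150] ms is ~peak_hz."""
    rng = np.random.default_rng(rng_seed)
    refs = np.sort(rng.random(200) * T)
    n_lock = int(peak_hz * 200 * 0.05)
    ev = np.sort(refs[rng.choice(200, min(n_lock, 200), replace=True)] + 0.05)
    return _mk_peh(ev, refs)


def test_rmi_formula():
    pre = _flat_peh()
    post = _flat_peh()
    pre.smoothed_hz[:] = 0.0
    post.smoothed_hz[:] = 0.0
    sel_pre = (pre.lag_centers_ms > 0) & (pre.lag_centers_ms <= 150)
    pre.smoothed_hz[sel_pre] = 4.0
    post.smoothed_hz[sel_pre] = 12.0
    assert compute_rmi(pre, post, baseline_hz=2.0) == pytest.approx(4.0)


def test_rmi_equal_peaks_is_zero():
    peh = _flat_peh()
    assert compute_rmi(peh, peh, baseline_hz=1.5) == pytest.approx(0.0)


def test_rmi_zero_baseline_undefined():
    peh = _flat_peh()
    assert compute_rmi(peh, peh, baseline_hz=0.0) is None


def test_mai_formula():
    # 2 Hz before the shock at 180 s, 6 Hz after, within a 1800-s epoch
    rng = np.random.default_rng(2)
    pre = poisson_train(2.0, 180.0, rng)
    post = 180.0 + poisson_train(6.0, 1620.0, rng)
    mai = compute_mai(np.concatenate([pre, post]), [180.0], 0.0, 1800.0)
    assert mai == pytest.approx(3.0, rel=0.15)


def test_mai_stationary_near_one():
    ok = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        mai = compute_mai(poisson_train(2.0, 1800.0, rng), [180.0], 0.0, 1800.0)
        ok += 0.7 <= mai <= 1.4
    assert ok >= 18


def test_mai_no_shocks_undefined():
    assert compute_mai(np.array([1.0, 2.0]), [], 0.0, 1800.0) is None


def test_mai_zero_pre_rate_undefined():
    assert compute_mai(np.array([500.0, 600.0]), [180.0], 0.0, 1800.0) is None


# --- classification -------------------------------------------------------


def _ix(rmi, mai, pre="none", post="up"):
    return MemoryIndices(
        id=0, rmi=rmi, mai=mai,
        pre_modulation=ModulationResult(pre),
        post_modulation=ModulationResult(post),
    )


def test_classification_strict_boundaries():
    assert not classify_memory_units([_ix(1.0, 3.0)])[0].is_memory  # rmi not > 1
    assert not classify_memory_units([_ix(2.0, 2.0)])[0].is_memory  # mai not > 2
    assert classify_memory_units([_ix(1.01, 2.01)])[0].is_memory


def test_classification_requires_post_only_modulation():
    assert not classify_memory_units([_ix(3.0, 3.0, pre="up")])[0].is_memory
    assert not classify_memory_units([_ix(3.0, 3.0, post="none")])[0].is_memory
    assert not classify_memory_units([_ix(3.0, 3.0, post="down")])[0].is_memory
    assert classify_memory_units([_ix(3.0, 3.0, pre="down")])[0].is_memory


def test_classification_undefined_indices_never_memory():
    assert not classify_memory_units([_ix(None, 3.0)])[0].is_memory
    assert not classify_memory_units([_ix(3.0, None)])[0].is_memory


# --- permutation test -----------------------------------------------------


def test_shuffle_preserves_count_and_intervals():
    rng = np.random.default_rng(0)
    refs = shuffle_reference_times(100, [(0.0, 10.0), (50.0, 60.0)], rng)
    assert refs.size == 100
    assert np.all(((refs >= 0) & (refs < 10)) | ((refs >= 50) & (refs < 60)))
    assert np.all(np.diff(refs) >= 0)


def test_permutation_requires_ripples():
    with pytest.raises(ValueError):
        permutation_test_proportion([np.array([1.0])], np.arange(5), [(0.0, T)])


def test_permutation_no_modulation_p_is_one():
    # empty event trains -> nothing modulated anywhere -> p = 1
    trains = [np.array([]) for _ in range(3)]
    rng = np.random.default_rng(0)
    res = permutation_test_proportion(
        trains, np.sort(rng.random(50) * T), [(0.0, T)], n_shuffles=5, seed=0
    )
    assert res.p_value == 1.0
    assert res.real_proportion == 0.0


def test_permutation_power_on_planted_coupling():
    hits = 0
    for seed in range(5):
        rng = np.random.default_rng(seed)
        ripples = np.sort(rng.random(300) * T)
        trains = [poisson_train(2.0, T, rng) for _ in range(9)]
        for _ in range(3):
            sel = rng.choice(300, 100, replace=False)
            trains.append(
                np.sort(
                    np.concatenate(
                        [
                            ripples[sel] + 0.035 + rng.normal(0, 0.005, 100),
                            poisson_train(1.5, T, rng),
                        ]
                    )
                )
            )
        res = permutation_test_proportion(
            trains, ripples, [(0.0, T)], n_shuffles=50, seed=seed
        )
        hits += res.p_value < 0.05
    assert hits >= 4
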