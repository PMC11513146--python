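import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ripplemap.assemblies import (
    BinnedMatrix,
    activation_strength,
    bin_and_zscore,
    count_significant_components,
    extract_assembly_patterns,
    marchenko_pastur_bound,
    match_assemblies,
    significance_threshold,
    surrogate_activation_null,
)
from ripplemap.core import AssemblyPattern, Epoch, SpikeData


def _poisson_matrix(n, b, rate=0.125, seed=0):
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate, size=(n, b)).astype(float)
    z = counts - counts.mean(axis=1, keepdims=True)
    z /= z.std(axis=1, keepdims=True)
    return BinnedMatrix(
        z=z, counts=counts, bin_ms=25.0, t0=0.0,
        unit_ids=np.arange(n), excluded_ids=np.array([], dtype=int),
    )


# --- binning -------------------------------------------------------------


def test_bin_count_arithmetic():
    rng = np.random.default_rng(0)
    spikes = SpikeData(
        times={0: np.sort(rng.random(200) * 10.0)}, regions={0: "BLA"}
    )
    mat = bin_and_zscore(spikes, Epoch("e", 0.0, 10.0), bin_ms=25.0)
    assert mat.n_bins == 400


def test_zero_variance_unit_excluded():
    # one spike per bin exactly -> zero variance -> excluded
    regular = np.arange(0.0125, 10.0, 0.025)
    rng = np.random.default_rng(1)
    spikes = SpikeData(
        times={0: regular, 1: np.sort(rng.random(300) * 10.0)},
        regions={0: "BLA", 1: "BLA"},
    )
    mat = bin_and_zscore(spikes, Epoch("e", 0.0, 10.0))
    assert 0 in mat.excluded_ids
    assert mat.unit_ids.tolist() == [1]


def test_rows_are_zscored():
    mat = _poisson_matrix(10, 10_000)
    np.testing.assert_allclose(mat.z.mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(mat.z.std(axis=1), 1.0, atol=1e-12)


def test_short_epoch_rejected():
    spikes = SpikeData(times={0: np.array([0.1])}, regions={0: "BLA"})
    with pytest.raises(ValueError, match="bins"):
        bin_and_zscore(spikes, Epoch("e", 0.0, 1.0))


# --- Marchenko-Pastur -----------------------------------------------------


def test_mp_bound_closed_form():
    assert marchenko_pastur_bound(100, 400) == pytest.approx(2.25)


def test_mp_bound_invalid_shape():
    with pytest.raises(ValueError):
        marchenko_pastur_bound(100, 100)


@given(st.integers(10, 200))
@settings(max_examples=25, deadline=None)
def test_mp_bound_limit_to_one(n):
    # q -> 0 => bound -> 1
    assert marchenko_pastur_bound(n, 10_000_000) == pytest.approx(1.0, abs=0.02)


@given(st.integers(10, 100), st.integers(500, 5000))
@settings(max_examples=25, deadline=None)
def test_corrected_threshold_above_raw_bound(n, b):
    assert significance_threshold(n, b) > marchenko_pastur_bound(n, b)


def test_null_matrix_has_no_significant_components():
    hits = sum(
        count_significant_components(_poisson_matrix(58, 10_000, seed=s)) > 0
        for s in range(20)
    )
    assert hits <= 1


def test_duplicated_row_adds_component():
    mat = _poisson_matrix(20, 5000, seed=3)
    base = count_significant_components(mat)
    z2 = np.vstack([mat.z, mat.z[0]])
    dup = BinnedMatrix(
        z=z2, counts=np.vstack([mat.counts, mat.counts[0]]),
        bin_ms=25.0, t0=0.0, unit_ids=np.arange(21),
        excluded_ids=np.array([], dtype=int),
    )
    assert count_significant_components(dup) >= base + 1


# --- pattern extraction ---------------------------------------------------


def test_planted_patterns_recovered(planted_two_assemblies):
    cfg, spikes, truths = planted_two_assemblies
    mat = bin_and_zscore(spikes, cfg.epochs()[0])
    n = count_significant_components(mat)
    assert n == 2
    patterns = extract_assembly_patterns(mat, n, seed=0)
    found = {p.members for p in patterns}
    assert {t.member_ids for t in truths} == found


def test_patterns_unit_norm_and_sign_convention(planted_two_assemblies):
    cfg, spikes, truths = planted_two_assemblies
    mat = bin_and_zscore(spikes, cfg.epochs()[0])
    for p in extract_assembly_patterns(mat, 2, seed=0):
        assert np.linalg.norm(p.weights) == pytest.approx(1.0)
        k = np.argmax(np.abs(p.weights))
        assert p.weights[k] > 0


def test_extraction_deterministic(planted_two_assemblies):
    cfg, spikes, truths = planted_two_assemblies
    mat = bin_and_zscore(spikes, cfg.epochs()[0])
    a = extract_assembly_patterns(mat, 2, seed=5)
    b = extract_assembly_patterns(mat, 2, seed=5)
    for pa, pb in zip(a, b):
        np.testing.assert_array_equal(pa.weights, pb.weights)


def test_permutation_equivariance(planted_two_assemblies):
    cfg, spikes, truths = planted_two_assemblies
    mat = bin_and_zscore(spikes, cfg.epochs()[0])
    rng = np.random.default_rng(0)
    perm = rng.permutation(mat.n_units)
    permuted = BinnedMatrix(
        z=mat.z[perm], counts=mat.counts[perm], bin_ms=mat.bin_ms,
        t0=mat.t0, unit_ids=mat.unit_ids[perm], excluded_ids=mat.excluded_ids,
    )
    pats_a = extract_assembly_patterns(mat, 2, seed=0)
    pats_b = extract_assembly_patterns(permuted, 2, seed=0)
    # member sets (by unit id) are permutation-invariant
    assert {p.members for p in pats_a} == {p.members for p in pats_b}


# --- activation strength --------------------------------------------------


def _one_hot_pattern(n, k):
    w = np.zeros(n)
    w[k] = 1.0
    return AssemblyPattern(weights=w, unit_ids=np.arange(n))


def test_activation_zero_vector_bins():
    mat = _poisson_matrix(5, 2000, seed=2)
    mat.z[:, 10] = 0.0
    pat = AssemblyPattern(weights=np.ones(5), unit_ids=np.arange(5))
    for mode in ("quadratic", "linear"):
        tr = activation_strength(pat, mat, mode=mode)
        assert tr.strength[10] == pytest.approx(0.0)


def test_one_hot_quadratic_strength_is_zero():
    mat = _poisson_matrix(5, 2000, seed=2)
    tr = activation_strength(_one_hot_pattern(5, 2), mat, mode="quadratic")
    np.testing.assert_allclose(tr.strength, 0.0, atol=1e-12)


def test_quadratic_ignores_solo_firing():
    # a huge solo deflection of one unit does not move the quadratic strength
    mat = _poisson_matrix(6, 2000, seed=4)
    pat = AssemblyPattern(weights=np.ones(6), unit_ids=np.arange(6))
    base = activation_strength(pat, mat, mode="quadratic").strength.copy()
    mat.z[3, 100] += 50.0
    bumped = activation_strength(pat, mat, mode="quadratic").strength
    # only cross terms with unit 3 change; the pure z_3^2 term is removed
    expected_delta = 2 * 50.0 * (pat.weights[3] * (pat.weights @ mat.z[:, 100] - pat.weights[3] * mat.z[3, 100]))
    assert bumped[100] - base[100] == pytest.approx(expected_delta, rel=1e-6)


def test_dimension_mismatch_rejected():
    mat = _poisson_matrix(5, 2000)
    with pytest.raises(ValueError, match="unit indexing"):
        activation_strength(_one_hot_pattern(6, 0), mat)


def test_planted_event_bins_have_high_strength(planted_two_assemblies):
    cfg, spikes, truths = planted_two_assemblies
    mat = bin_and_zscore(spikes, cfg.epochs()[0])
    patterns = extract_assembly_patterns(mat, 2, seed=0)
    by_members = {p.members: p for p in patterns}
    for t in truths:
        tr = activation_strength(by_members[t.member_ids], mat)
        in_event = np.zeros(mat.n_bins, dtype=bool)
        idx = ((t.event_times - mat.t0) / mat.bin_s).astype(int)
        in_event[np.clip(idx, 0, mat.n_bins - 1)] = True
        assert tr.strength[in_event].mean() > 5 * abs(tr.strength[~in_event].mean())


# --- surrogates -----------------------------------------------------------


def test_surrogate_contract_length():
    mat = _poisson_matrix(8, 2000, seed=5)
    pat = AssemblyPattern(weights=np.ones(8), unit_ids=np.arange(8))
    null = surrogate_activation_null(pat, mat, n_surrogates=1, seed=0)
    assert null.shape == (1,)


def test_planted_event_rate_beats_surrogate_null(planted_two_assemblies):
    cfg, spikes, truths = planted_two_assemblies
    mat = bin_and_zscore(spikes, cfg.epochs()[0])
    patterns = extract_assembly_patterns(mat, 2, seed=0)
    tr = activation_strength(patterns[0], mat)
    null = surrogate_activation_null(patterns[0], mat, n_surrogates=100, seed=0)
    assert tr.event_rate_hz > np.percentile(null, 97.5)


def test_surrogate_null_covers_independent_data():
    covered = 0
    for seed in range(10):
        mat = _poisson_matrix(10, 4000, rate=1.0, seed=100 + seed)
        pat = AssemblyPattern(weights=np.ones(10), unit_ids=np.arange(10))
        real = activation_strength(pat, mat).event_rate_hz
        null = surrogate_activation_null(pat, mat, n_surrogates=60, seed=seed)
        lo, hi = np.percentile(null, [2.5, 97.5])
        covered += lo <= real <= hi
    assert covered >= 8


# --- matching -------------------------------------------------------------


def _random_patterns(n_units, k, seed):
    rng = np.random.default_rng(seed)
    return [
        AssemblyPattern(weights=rng.standard_normal(n_units), unit_ids=np.arange(n_units), id=i)
        for i in range(k)
    ]


def test_match_identity():
    pats = _random_patterns(20, 3, 0)
    matches, ua, ub = match_assemblies(pats, pats)
    assert not ua and not ub
    for m in matches:
        assert m.index_a == m.index_b
        assert m.similarity == pytest.approx(1.0)


def test_match_sign_flip_absolute():
    pats = _random_patterns(20, 2, 1)
    flipped = [
        AssemblyPattern(weights=-p.weights, unit_ids=p.unit_ids) for p in pats
    ]
    matches, _, _ = match_assemblies(pats, flipped)
    for m in matches:
        assert m.similarity == pytest.approx(1.0)


def test_split_half_stability():
    from ripplemap.synthetic import AssemblySpec, SessionConfig, generate_assembly_spikes

    cfg = SessionConfig(
        seed=13, n_bla=58, bla_rate_hz=5.0,
        epoch_durations={"post_sleep": 1600.0},
        assembly_specs=(
            AssemblySpec(members=(3, 7, 12), event_rate_hz=0.6, gain=10.0),
            AssemblySpec(members=(20, 21, 40, 41), event_rate_hz=0.6, gain=10.0),
        ),
    )
    spikes, _ = generate_assembly_spikes(cfg)
    m1 = bin_and_zscore(spikes, Epoch("h1", 0.0, 800.0))
    m2 = bin_and_zscore(spikes, Epoch("h2", 800.0, 1600.0))
    p1 = extract_assembly_patterns(m1, 2, seed=0)
    p2 = extract_assembly_patterns(m2, 2, seed=0)
    matches, _, _ = match_assemblies(p1, p2)
    assert np.mean([m.similarity for m in matches]) >= 0.8
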