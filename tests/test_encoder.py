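"""Encoding model: storage semantics, kernel maths, intensity formulas."""

import numpy as np
import pytest

from replaydecoder.encoder import EncodingModel, FrozenModelError

SQRT_2PI = np.sqrt(2 * np.pi)


def brute_force_density(marks, bins, sigma, n_bins, query):
    """Naive double loop over stored marks x position bins: the KDE oracle."""
    out = np.zeros(n_bins)
    for m, b in zip(marks, bins):
        a2 = float(np.sum((np.asarray(m) - np.asarray(query)) ** 2))
        w = np.exp(-a2 / (2 * sigma**2)) / (sigma * SQRT_2PI)
        out[b] += w
    return out / len(marks)


def filled_model(rng, n_stored=50, n_bins=10, dim=3, sigma=2.0):
    model = EncodingModel(0, n_bins, dim, sigma=sigma)
    marks = rng.normal(0, 5, (n_stored, dim))
    bins = rng.integers(0, n_bins, n_stored)
    for m, b in zip(marks, bins):
        model.add_spike(m, int(b))
    for b in range(n_bins):
        model.add_occupancy(b, 1.0)
    return model, marks, bins


def test_add_spike_stores_pairs_and_histogram(rng):
    model, marks, bins = filled_model(rng, n_stored=200)
    assert model.n_stored == 200
    expected = np.bincount(bins, minlength=10) / 200
    np.testing.assert_allclose(model.ground_dist, expected)


def test_wrong_mark_dimension_rejected():
    model = EncodingModel(0, 5, 2)
    with pytest.raises(ValueError, match="shape"):
        model.add_spike([1.0, 2.0, 3.0], 0)


def test_freeze_semantics(rng):
    model, *_ = filled_model(rng)
    q = rng.normal(0, 5, 3)
    before = model.joint_mark_density(q)
    model.freeze()
    model.freeze()  # idempotent
    assert model.frozen
    with pytest.raises(FrozenModelError):
        model.add_spike(np.zeros(3), 0)
    np.testing.assert_array_equal(before, model.joint_mark_density(q))


def test_freeze_empty_model_errors():
    with pytest.raises(ValueError):
        EncodingModel(0, 5, 2).freeze()


def test_kernel_weight_at_zero_distance_is_gaussian_peak():
    model = EncodingModel(0, 5, 2, sigma=1.0)
    model.add_spike([3.0, 4.0], 1)
    w = model.kernel_weights([3.0, 4.0])
    assert w[0] == pytest.approx(1 / SQRT_2PI)
    assert w[0] == pytest.approx(0.398942, abs=1e-6)


def test_kernel_weight_1d_example():
    """Stored mark 100, query 120, sigma=20: a^2=400, w = 0.012099."""
    model = EncodingModel(0, 5, 1, sigma=20.0)
    model.add_spike([100.0], 0)
    w = model.kernel_weights([120.0])
    expected = np.exp(-400 / (2 * 400)) / (20 * SQRT_2PI)
    assert w[0] == pytest.approx(expected, rel=1e-12)
    assert w[0] == pytest.approx(0.012099, abs=1e-6)


def test_kernel_weights_shift_invariant(rng):
    model, marks, _ = filled_model(rng)
    shifted = EncodingModel(0, 10, 3, sigma=2.0)
    for m, b in zip(marks, model._bins):
        shifted.add_spike(np.asarray(m) + 7.5, b)
    q = rng.normal(0, 5, 3)
    np.testing.assert_allclose(
        model.kernel_weights(q), shifted.kernel_weights(q + 7.5), rtol=1e-12
    )


def test_kernel_weights_decrease_with_distance():
    model = EncodingModel(0, 5, 1, sigma=3.0)
    for v in (0.0, 1.0, 2.0, 5.0, 10.0):
        model.add_spike([v], 0)
    w = model.kernel_weights([0.0])
    assert np.all(np.diff(w) < 0)
    assert w[0] == pytest.approx(1 / (3.0 * SQRT_2PI))


def test_sigma_must_be_positive():
    with pytest.raises(ValueError):
        EncodingModel(0, 5, 1, sigma=0.0)


def test_density_equal_weight_histogram():
    model = EncodingModel(0, 5, 1, sigma=1.0)
    model.add_spike([0.0], 0)
    model.add_spike([0.0], 1)
    d = model.joint_mark_density([0.0])
    w = 1 / SQRT_2PI
    np.testing.assert_allclose(d, [w / 2, w / 2, 0, 0, 0])


def test_density_single_spike_all_mass_at_its_bin():
    model = EncodingModel(0, 4, 2, sigma=1.0)
    model.add_spike([1.0, 1.0], 2)
    d = model.joint_mark_density([0.0, 0.0])
    assert d[2] > 0 and np.all(d[[0, 1, 3]] == 0)


def test_density_matches_brute_force_oracle(rng):
    """Vectorized estimate == naive double loop, 1e-10 relative."""
    n_bins, dim, sigma = 25, 4, 20.0
    model = EncodingModel(0, n_bins, dim, sigma=sigma)
    marks = rng.uniform(50, 400, (1000, dim))
    bins = rng.integers(0, n_bins, 1000)
    for m, b in zip(marks, bins):
        model.add_spike(m, int(b))
    for q in rng.uniform(50, 400, (20, dim)):
        got = model.joint_mark_density(q)
        expected = brute_force_density(marks, bins, sigma, n_bins, q)
        np.testing.assert_allclose(got, expected, rtol=1e-10, atol=1e-300)


def test_ground_intensity_constant_when_ratios_cancel():
    """Uniform occupancy and uniform spike positions: ground == mu everywhere."""
    n_bins = 8
    model = EncodingModel(0, n_bins, 1, sigma=1.0, occupancy_smoothing_bins=0.0)
    for i in range(2 * n_bins):
        model.add_spike([float(i)], i % n_bins)
    for b in range(n_bins):
        model.add_occupancy(b, 0.5)  # 4 s total encoding time
    model.freeze()
    mu = 2 * n_bins / 4.0
    np.testing.assert_allclose(model.ground_intensity(), mu, rtol=1e-9)


def test_jmi_zero_where_density_zero(rng):
    model = EncodingModel(0, 6, 2, sigma=1.0, occupancy_smoothing_bins=0.0)
    model.add_spike([0.0, 0.0], 3)
    for b in range(6):
        model.add_occupancy(b, 1.0)
    model.freeze()
    res = model.intensities([0.0, 0.0])
    assert res.jmi[3] > 0
    assert np.all(res.jmi[[0, 1, 2, 4, 5]] == 0)


def test_intensities_match_direct_formula(rng):
    """jmi = mu p(x,m)/pi, ground = mu p(x)/pi, re-evaluated independently."""
    n_bins, dim, sigma = 12, 3, 5.0
    model = EncodingModel(0, n_bins, dim, sigma=sigma,
                          occupancy_smoothing_bins=0.0, occupancy_floor=1e-12)
    marks = rng.normal(0, 10, (80, dim))
    bins = rng.integers(0, n_bins, 80)
    occ = rng.uniform(0.5, 2.0, n_bins)
    for m, b in zip(marks, bins):
        model.add_spike(m, int(b))
    for b, dwell in enumerate(occ):
        model.add_occupancy(b, float(dwell))
    model.freeze()
    q = rng.normal(0, 10, dim)
    res = model.intensities(q)
    pi = occ / occ.sum() + 1e-12
    mu = 80 / occ.sum()
    p_x = np.bincount(bins, minlength=n_bins) / 80
    p_xm = brute_force_density(marks, bins, sigma, n_bins, q)
    np.testing.assert_allclose(res.ground, mu * p_x / pi, rtol=1e-10)
    np.testing.assert_allclose(res.jmi, mu * p_xm / pi, rtol=1e-10)


def test_latency_style_inputs_give_uniform_ground():
    """Identical marks with cyclic positions 0..max_bin-1 spread the ground
    process uniformly over those bins."""
    max_bin, n_marks = 10, 1000
    model = EncodingModel(0, max_bin, 4, sigma=20.0)
    marks = np.ones((n_marks, 4))
    for i in range(n_marks):
        model.add_spike(marks[i], i % max_bin)
    np.testing.assert_allclose(model.ground_dist, 1.0 / max_bin)


def test_query_cost_scales_sublinearly_in_mark_dimension(rng):
    """Raising D from 1 to 16 must not cost 16x per query (vectorized KDE)."""
    import time

    def timed(dim):
        model = EncodingModel(0, 20, dim, sigma=20.0)
        marks = rng.uniform(0, 300, (5000, dim))
        bins = rng.integers(0, 20, 5000)
        for m, b in zip(marks, bins):
            model.add_spike(m, int(b))
        queries = rng.uniform(0, 300, (100, dim))
        model.joint_mark_density(queries[0])  # warm the cache
        t0 = time.perf_counter()
        for q in queries:
            model.joint_mark_density(q)
        return time.perf_counter() - t0

    t1 = min(timed(1) for _ in range(3))
    t16 = min(timed(16) for _ in range(3))
    assert t16 / t1 < 16.0


def test_hdf5_roundtrip(tmp_path, rng):
    model, *_ = filled_model(rng)
    model.freeze()
    q = rng.normal(0, 5, 3)
    model.to_hdf5(tmp_path / "model.h5")
    loaded = EncodingModel.from_hdf5(tmp_path / "model.h5",
                                     "encoding_model/group_0")
    assert loaded.frozen and loaded.n_stored == model.n_stored
    np.testing.assert_array_equal(model.joint_mark_density(q),
                                  loaded.joint_mark_density(q))
    res_a, res_b = model.intensities(q), loaded.intensities(q)
    np.testing.assert_array_equal(res_a.jmi, res_b.jmi)
    np.testing.assert_array_equal(res_a.ground, res_b.ground)
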