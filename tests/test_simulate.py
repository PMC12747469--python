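"""Synthetic fixtures: kinematics, Poisson spiking, mark clusters, LFP."""

import numpy as np
import pytest
from scipy import signal

from replaydecoder.simulate import (
    SimConfig,
    cluster_centers,
    default_geometry,
    path_position,
    simulate_lfp,
    simulate_spikes,
    simulate_trajectory,
    tuning_curve,
)


def test_zero_duration_gives_empty_streams():
    df, truth = simulate_trajectory(SimConfig(duration_s=0.0))
    assert len(df) == 0 and len(truth.frame_bin) == 0


def test_traversal_kinematics():
    """A run from the center (102.5 cm) to an arm tip covers 102.5 cm at the
    configured speed."""
    sim = SimConfig(duration_s=30.0, run_speed_cm_s=25.0, pause_center_s=2.0)
    geom = default_geometry()
    t = np.linspace(0, 30, 3001)
    s = path_position(sim, t, geom)
    # first leg: flat at center during the pause, then linear to the arm tip
    assert np.allclose(s[t <= 2.0], 102.5)
    run = (t > 2.0) & (t < 2.0 + 102.5 / 25.0)
    ds = np.diff(s[run]) / np.diff(t[run])
    assert np.allclose(ds, 25.0, atol=1e-6)
    assert s.max() == pytest.approx(205.0)


def test_occupancy_matches_schedule_dwell_fractions():
    """Long-session bin occupancy equals dwell time from the leg schedule."""
    sim = SimConfig(duration_s=300.0)
    df, truth = simulate_trajectory(sim)
    # moving frames spread uniformly over the track; paused frames pile up
    # at the center and the two tips
    moving = truth.frame_speed > 4.0
    occ = np.bincount(truth.frame_bin[moving], minlength=41) / moving.sum()
    # uniform dwell over bins while moving (constant speed): ~1/41 each
    np.testing.assert_allclose(occ, 1 / 41, atol=0.35 / 41)
    paused_bins = set(np.unique(truth.frame_bin[~moving]))
    assert paused_bins <= {0, 20, 21, 40}  # tips and the central box


def test_no_rate_no_spikes():
    sim = SimConfig(duration_s=20.0, peak_rate_hz=0.0, baseline_rate_hz=0.0)
    df, _ = simulate_spikes(sim)
    assert len(df) == 0


def test_homogeneous_rate_poisson_count_within_3_sigma():
    """With flat tuning the count is Poisson(n_cells * rate * T)."""
    sim = SimConfig(duration_s=100.0, peak_rate_hz=0.0, baseline_rate_hz=20.0,
                    n_groups=1, cells_per_group=1, seed=123)
    df, _ = simulate_spikes(sim)
    expected = 20.0 * 100.0
    assert abs(len(df) - expected) <= 3 * np.sqrt(expected)


def test_rate_recovery_from_long_run():
    """Empirical spike rate vs position recovers the Gaussian tuning curve."""
    sim = SimConfig(duration_s=600.0, n_groups=1, cells_per_group=1,
                    baseline_rate_hz=0.5, peak_rate_hz=30.0,
                    field_width_cm=12.0, seed=7)
    geom = default_geometry()
    df, truth = simulate_spikes(sim, geom)
    # dwell time per 5 cm of path, from the trajectory truth
    edges = np.arange(0, 206, 5.0)
    dwell, _ = np.histogram(truth.frame_s_cm, bins=edges)
    dwell = dwell / sim.camera_hz
    s_spk = path_position(sim, truth.spike_times_s, geom)
    counts, _ = np.histogram(s_spk, bins=edges)
    with np.errstate(invalid="ignore"):
        rate = counts / dwell
    # locate the field: the single cell's center is where the rate peaks
    centers = (edges[:-1] + edges[1:]) / 2
    c_hat = centers[np.nanargmax(rate)]
    expected = tuning_curve(sim, np.array([c_hat]), centers)[0]
    ok = dwell > 5.0
    err = np.abs(rate[ok] - expected[ok])
    sigma = np.sqrt(expected[ok] / dwell[ok])  # Poisson binning error
    assert np.mean(err <= 3 * sigma + 1.0) > 0.9


def test_marks_cluster_around_separated_centers(rng):
    sim = SimConfig(duration_s=60.0, seed=4)
    df, truth = simulate_spikes(sim)
    mark_cols = [f"mark_{d}" for d in range(sim.mark_dim)]
    marks = df[mark_cols].to_numpy()
    for cell in np.unique(truth.spike_cell):
        sel = truth.spike_cell == cell
        if sel.sum() < 30:
            continue
        spread = marks[sel].std(axis=0)
        np.testing.assert_allclose(spread, sim.mark_sd, rtol=0.35)
    # empirical cluster means within one group stay well separated
    g0 = df["electrode_group_id"].to_numpy() == 0
    cells0 = np.unique(truth.spike_cell[g0])
    means = [marks[g0 & (truth.spike_cell == c)].mean(axis=0) for c in cells0]
    for i in range(len(means)):
        for j in range(i + 1, len(means)):
            assert np.linalg.norm(means[i] - means[j]) > 0.8 * sim.cluster_separation


def test_cluster_center_generation_enforces_separation(rng):
    sim = SimConfig()
    centers = cluster_centers(sim, rng)
    for g in range(sim.n_groups):
        for i in range(sim.cells_per_group):
            for j in range(i + 1, sim.cells_per_group):
                d = np.linalg.norm(centers[g, i] - centers[g, j])
                assert d >= sim.cluster_separation


def test_lfp_truth_lists_every_injection():
    sim = SimConfig(duration_s=60.0, n_ripples=5, seed=2)
    lfp, intervals = simulate_lfp(sim)
    assert len(intervals) == 5
    assert len(lfp) == int(60.0 * sim.fs_lfp)
    assert all(b - a == pytest.approx(sim.ripple_dur_s) for a, b in intervals)


def test_no_injbecomes_pure_noise():
    sim = SimConfig(duration_s=20.0, n_ripples=0, seed=2)
    _, intervals = simulate_lfp(sim)
    assert intervals == []


def test_burst_band_power_exceeds_background():
    """Ripple-band power inside injected windows beats background by far
    more than the amplitude factor squared would suggest for 1/f noise."""
    sim = SimConfig(duration_s=60.0, n_ripples=5, seed=8, ripple_free_start_s=12.0)
    lfp, intervals = simulate_lfp(sim)
    x = lfp["value"].to_numpy()
    sos = signal.butter(4, (150, 250), btype="bandpass", fs=sim.fs_lfp,
                        output="sos")
    band = signal.sosfiltfilt(sos, x)
    fs = sim.fs_lfp
    in_power, out_power = [], []
    mask = np.zeros(len(x), bool)
    for a, b in intervals:
        mask[int(a * fs): int(b * fs)] = True
    in_power = np.mean(band[mask] ** 2)
    out_power = np.mean(band[~mask] ** 2)
    assert in_power / out_power > sim.ripple_amp_rms**2


def test_fixed_seed_reproduces_fixtures_bit_for_bit(tmp_path):
    from replaydecoder.simulate import simulate_session

    sim = SimConfig(duration_s=15.0, task1_end_s=10.0, seed=21, n_ripples=2)
    paths_a, truth_a = simulate_session(sim, tmp_path / "a")
    paths_b, truth_b = simulate_session(sim, tmp_path / "b")
    for k in paths_a:
        assert paths_a[k].read_bytes() == paths_b[k].read_bytes()
    np.testing.assert_array_equal(truth_a.spike_cell, truth_b.spike_cell)
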