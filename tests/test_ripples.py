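"""Ripple detection: filter stages, z-scoring, onset/offset state machine."""

import numpy as np
import pytest
from scipy import signal

from replaydecoder.ripples import (
    RippleConfig,
    RippleDetector,
    StreamingSOS,
    consensus_intervals,
    lfp_deadline_us,
    power_lowpass_sos,
    ripple_bandpass_sos,
)
from replaydecoder.simulate import SimConfig, simulate_lfp


def test_deadline_at_1500_hz_is_667_us():
    assert round(lfp_deadline_us(1500.0)) == 667


def test_config_validation():
    with pytest.raises(ValueError):
        RippleConfig(band=(150.0, 800.0))  # above Nyquist at 1500 Hz
    with pytest.raises(ValueError):
        RippleConfig(z_threshold=1.0, z_end_threshold=2.0)


def test_zero_input_zero_output():
    det = RippleDetector(RippleConfig())
    filtered = det.filter_ripple_band(np.zeros(100))
    assert np.all(filtered == 0)
    assert np.all(det.power_estimate(filtered) == 0)


def test_inband_sine_passes_out_of_band_attenuated():
    cfg = RippleConfig()
    fs = cfg.fs_lfp
    t = np.arange(int(fs * 4)) / fs

    def steady_gain(freq):
        det = RippleDetector(cfg)
        y = det.filter_ripple_band(np.sin(2 * np.pi * freq * t))
        return np.abs(y[-1500:]).max()

    # analytic gain of the chosen causal filter at each frequency
    sos = ripple_bandpass_sos(cfg)
    w, h = signal.sosfreqz(sos, worN=[10.0, 200.0], fs=fs)
    assert steady_gain(200.0) == pytest.approx(np.abs(h[1]), rel=0.02)
    assert steady_gain(10.0) == pytest.approx(np.abs(h[0]), rel=0.1)
    assert np.abs(h[1]) > 0.9 and np.abs(h[0]) < 1e-3


def test_streaming_chunks_equal_whole_trace(rng):
    """Any chunking of the input gives sample-identical output."""
    cfg = RippleConfig()
    x = rng.normal(0, 1, 6000)
    whole = RippleDetector(cfg)
    y_whole = whole.power_estimate(whole.filter_ripple_band(x))
    chunked = RippleDetector(cfg)
    cuts = np.sort(rng.integers(1, len(x), 25))
    pieces = np.split(x, cuts)
    y_chunks = np.concatenate(
        [chunked.power_estimate(chunked.filter_ripple_band(p)) for p in pieces]
    )
    np.testing.assert_array_equal(y_whole, y_chunks)


def test_envelope_of_constant_sinusoid_settles_near_half_squared_amplitude():
    cfg = RippleConfig()
    fs = cfg.fs_lfp
    t = np.arange(int(fs * 5)) / fs
    amp = 3.0
    det = RippleDetector(cfg)
    env = det.power_estimate(det.filter_ripple_band(amp * np.sin(2 * np.pi * 200 * t)))
    sos = ripple_bandpass_sos(cfg)
    _, h = signal.sosfreqz(sos, worN=[200.0], fs=fs)
    expected = (amp * np.abs(h[0])) ** 2 / 2  # mean of sin^2 = A^2/2, LP DC gain 1
    assert np.mean(env[-1500:]) == pytest.approx(expected, rel=0.02)


def test_envelope_sign_flip_invariant(rng):
    x = rng.normal(0, 1, 3000)
    a, b = RippleDetector(RippleConfig()), RippleDetector(RippleConfig())
    ya = a.power_estimate(a.filter_ripple_band(x))
    yb = b.power_estimate(b.filter_ripple_band(-x))
    np.testing.assert_allclose(ya, yb, atol=1e-12)


def test_zscore_baseline_identities(rng):
    cfg = RippleConfig(baseline_window_s=1.0)
    det = RippleDetector(cfg)
    base = rng.uniform(1.0, 3.0, int(cfg.fs_lfp * cfg.baseline_window_s))
    det.zscore(base)
    m, s = base.mean(), base.std()
    assert det.zscore(np.array([m]))[0] == pytest.approx(0.0, abs=1e-9)
    assert det.zscore(np.array([m + 3 * s]))[0] == pytest.approx(3.0, abs=1e-9)


def test_zscore_matches_offline_recomputation(rng):
    cfg = RippleConfig(baseline_window_s=2.0)
    det = RippleDetector(cfg)
    n_base = int(cfg.fs_lfp * cfg.baseline_window_s)
    env = rng.uniform(0.5, 1.5, n_base + 4000)
    z_stream = np.concatenate([det.zscore(c) for c in np.array_split(env, 13)])
    base = env[:n_base]
    z_offline = (env - base.mean()) / base.std()
    np.testing.assert_allclose(z_stream[n_base:], z_offline[n_base:], atol=1e-9)
    assert np.all(np.isnan(z_stream[:n_base]))


def test_zscore_degenerate_baseline_errors():
    cfg = RippleConfig(baseline_window_s=0.01)
    det = RippleDetector(cfg)
    with pytest.raises(ValueError, match="degenerate"):
        det.zscore(np.ones(100))


def test_state_machine_single_event():
    """z = [0,0,4,5,4,0] with thresholds 3/1 opens at index 2, closes at 5."""
    cfg = RippleConfig(z_threshold=3.0, z_end_threshold=1.0)
    det = RippleDetector(cfg, group_id=7)
    events = det.detect(np.array([0, 0, 4, 5, 4, 0.0]), np.arange(6))
    assert len(events) == 1
    ev = events[0]
    assert (ev.start_timestamp, ev.end_timestamp) == (2, 5)
    assert ev.peak_z == 5.0 and ev.group_id == 7


def test_no_events_below_threshold():
    det = RippleDetector(RippleConfig(z_threshold=3.0))
    assert det.detect(np.full(100, 2.9), np.arange(100)) == []


def test_event_open_across_chunks():
    det = RippleDetector(RippleConfig(z_threshold=3.0, z_end_threshold=1.0))
    assert det.detect(np.array([0.0, 4.0]), [0, 1]) == []
    assert det.in_event
    events = det.detect(np.array([6.0, 0.5]), [2, 3])
    assert len(events) == 1 and events[0].peak_z == 6.0


def test_injected_bursts_detected_with_accurate_onsets():
    """Every injected burst is found within 20 ms; matched no-injection
    trace yields nothing at the separable threshold."""
    sim = SimConfig(duration_s=60.0, n_ripples=6, seed=5, ripple_free_start_s=12.0)
    lfp, intervals = simulate_lfp(sim)
    cfg = RippleConfig(z_threshold=25.0)
    det = RippleDetector(cfg)
    events = det.process(lfp["timestamp"].to_numpy(), lfp["value"].to_numpy())
    assert len(events) == len(intervals) == 6
    for ev, (on, _off) in zip(events, intervals):
        onset_err_ms = abs(ev.start_timestamp / sim.clock_hz - on) * 1000
        assert onset_err_ms <= 20.0
        assert ev.peak_z >= cfg.z_threshold
    # matched trace, no injections
    quiet, _ = simulate_lfp(SimConfig(duration_s=60.0, n_ripples=0, seed=5))
    det2 = RippleDetector(cfg)
    assert det2.process(quiet["timestamp"].to_numpy(),
                        quiet["value"].to_numpy()) == []


def test_streaming_detection_equals_offline(rng):
    """Event boundaries identical for chunked and whole-trace processing."""
    sim = SimConfig(duration_s=40.0, n_ripples=3, seed=9, ripple_free_start_s=12.0)
    lfp, _ = simulate_lfp(sim)
    ts, vals = lfp["timestamp"].to_numpy(), lfp["value"].to_numpy()
    cfg = RippleConfig(z_threshold=25.0)
    whole = RippleDetector(cfg).process(ts, vals)
    det = RippleDetector(cfg)
    cuts = np.sort(rng.integers(1, len(ts), 40))
    chunked = []
    for isl, vsl in zip(np.split(ts, cuts), np.split(vals, cuts)):
        chunked.extend(det.process(isl, vsl))
    assert [(e.start_timestamp, e.end_timestamp) for e in whole] == [
        (e.start_timestamp, e.end_timestamp) for e in chunked
    ]


def test_consensus_requires_n_channels():
    from replaydecoder.ripples import RippleEvent

    evs = {
        0: [RippleEvent(0, 10, 30, 5.0)],
        1: [RippleEvent(1, 20, 40, 5.0)],
        2: [RippleEvent(2, 100, 110, 5.0)],
    }
    assert consensus_intervals(evs, 2) == [(20, 30)]
    assert consensus_intervals(evs, 3) == []
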