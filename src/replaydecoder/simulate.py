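"""Ground-truthed synthetic sessions for the decoder.

The generator emulates the statistical structure the clusterless decoder
assumes, on a two-arm maze:

* a trajectory over a C-shaped track (two central-box segments plus one
  segment per arm, 205 cm / 41 five-cm bins by default) with
  piecewise-constant-speed traversals alternating between the arms and
  pauses at the arm ends and central box;
* place-cell spiking: each cell is an inhomogeneous Poisson process with a
  Gaussian tuning curve over linearized position (sampled by
  Lewis-Shedler thinning), and each spike carries a D-dimensional mark
  drawn from that cell's Gaussian amplitude cluster — the waveform-feature
  clusters a clusterless decoder relies on;
* LFP: 1/f-shaped background noise at 1,500 Hz with ripple-band
  (200 Hz) amplitude-modulated bursts injected at known times.

Everything is driven by one seeded generator, so a fixed seed reproduces
the session bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal.windows import tukey

from .linearization import TrackGeometry, linearize, to_bin

__all__ = ["SimConfig", "GroundTruth", "default_geometry",
           "simulate_trajectory", "simulate_spikes", "simulate_lfp",
           "simulate_session"]


def default_geometry() -> TrackGeometry:
    """Two-arm maze: central box (two segments) + two 75 cm arms, 205 cm.

    Segments are ordered and oriented along the linear path coordinate s
    (arm-2 tip -> central box -> arm-1 tip), so the global bin index is
    monotone in s and |bin difference| x bin size equals distance along
    the track.
    """
    return TrackGeometry(
        segments=(
            ((0.0, 75.0), (0.0, 0.0)),   # arm 2 (tip -> box)
            ((0.0, 0.0), (25.0, 0.0)),   # central box, half A
            ((25.0, 0.0), (55.0, 0.0)),  # central box, half B
            ((55.0, 0.0), (55.0, 75.0)),  # arm 1 (box -> tip)
        ),
        bins_per_segment=(15, 5, 6, 15),
        bin_size_cm=5.0,
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic session."""

    duration_s: float = 600.0
    task1_end_s: float = 300.0
    clock_hz: int = 30_000
    camera_hz: float = 30.0
    cm_per_pixel: float = 0.5
    # behaviour
    run_speed_cm_s: float = 25.0
    pause_center_s: float = 2.0
    pause_arm_s: float = 1.0
    # place-modulated units.  Each simulated unit stands for a multiunit
    # amplitude cluster, not a sorted single cell: clusterless decoding
    # operates on every threshold crossing, and per-tetrode multiunit rates
    # in CA1 during running reach tens to hundreds of Hz.
    n_groups: int = 8
    cells_per_group: int = 3
    field_width_cm: float = 8.0
    peak_rate_hz: float = 80.0
    baseline_rate_hz: float = 1.0
    # marks (tetrode peak amplitudes, ADC units)
    mark_dim: int = 4
    mark_sd: float = 20.0
    cluster_separation: float = 100.0  # 5 x mark_sd: well-separated clusters
    mark_range: tuple[float, float] = (100.0, 350.0)
    # LFP
    fs_lfp: float = 1500.0
    n_ripples: int = 10
    ripple_amp_rms: float = 6.0      # burst amplitude as multiple of noise RMS
    ripple_dur_s: float = 0.08
    ripple_freq_hz: float = 200.0
    ripple_free_start_s: float = 15.0  # leave the baseline window clean
    seed: int = 0


@dataclass
class GroundTruth:
    """Per-stream truth parallel to the emitted samples."""

    frame_times_s: np.ndarray
    frame_s_cm: np.ndarray
    frame_bin: np.ndarray
    frame_speed: np.ndarray
    spike_cell: np.ndarray          # cell index per emitted spike
    spike_times_s: np.ndarray
    ripple_intervals_s: list[tuple[float, float]]
    track_length_cm: float = 205.0


# --------------------------------------------------------------- trajectory

def _schedule(sim: SimConfig, track_len: float) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear knots (t, s) of the linear path coordinate."""
    center = track_len / 2.0
    v = sim.run_speed_cm_s
    knots_t, knots_s = [0.0], [center]
    t, s = 0.0, center
    targets = [track_len, center, 0.0, center]  # arm1, box, arm2, box
    pauses = [sim.pause_arm_s, sim.pause_center_s] * 2
    i = 0
    # initial center pause
    t += sim.pause_center_s
    knots_t.append(t)
    knots_s.append(s)
    while t < sim.duration_s:
        tgt = targets[i % 4]
        t += abs(tgt - s) / v
        s = tgt
        knots_t.append(t)
        knots_s.append(s)
        t += pauses[i % 4]
        knots_t.append(t)
        knots_s.append(s)
        i += 1
    return np.asarray(knots_t), np.asarray(knots_s)


def _s_to_xy(s: np.ndarray, track_len: float = 205.0) -> np.ndarray:
    """Linear path coordinate -> 2D cm on the default C-shaped track."""
    s = np.asarray(s, float)
    x = np.empty_like(s)
    y = np.empty_like(s)
    arm = 75.0
    box = track_len - 2 * arm  # 55
    a2 = s < arm
    bx = (s >= arm) & (s < arm + box)
    a1 = s >= arm + box
    x[a2], y[a2] = 0.0, arm - s[a2]
    x[bx], y[bx] = s[bx] - arm, 0.0
    x[a1], y[a1] = box, s[a1] - (arm + box)
    return np.column_stack([x, y])


def path_position(sim: SimConfig, t: np.ndarray,
                  geometry: TrackGeometry) -> np.ndarray:
    """Linear path coordinate s(t) in cm."""
    track_len = geometry.total_bins * geometry.bin_size_cm
    kt, ks = _schedule(sim, track_len)
    return np.interp(np.asarray(t, float), kt, ks)


def simulate_trajectory(
    sim: SimConfig, geometry: TrackGeometry | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Camera samples (CSV dialect) + per-frame ground truth."""
    geometry = geometry or default_geometry()
    track_len = geometry.total_bins * geometry.bin_size_cm
    n_frames = int(np.floor(sim.duration_s * sim.camera_hz))
    t = np.arange(n_frames) / sim.camera_hz
    s = path_position(sim, t, geometry)
    xy = _s_to_xy(s, track_len)
    seg = np.empty(n_frames, dtype=np.int64)
    norm = np.empty(n_frames)
    bins = np.empty(n_frames, dtype=np.int64)
    for i in range(n_frames):
        seg[i], norm[i] = linearize(xy[i], geometry)
        bins[i] = to_bin(seg[i], norm[i], geometry)
    speed = np.abs(np.gradient(s, t)) if n_frames > 1 else np.zeros(n_frames)
    pix = xy / sim.cm_per_pixel
    df = pd.DataFrame(
        {
            "timestamp": np.round(t * sim.clock_hz).astype(np.int64),
            "segment": seg,
            "norm_pos": norm,
            "x": pix[:, 0],
            "y": pix[:, 1],
            "x2": pix[:, 0] + 2.0,  # second LED, fixed offset
            "y2": pix[:, 1],
        }
    )
    truth = GroundTruth(
        frame_times_s=t,
        frame_s_cm=s,
        frame_bin=bins,
        frame_speed=speed,
        spike_cell=np.empty(0, np.int64),
        spike_times_s=np.empty(0),
        ripple_intervals_s=[],
        track_length_cm=track_len,
    )
    return df, truth


# ------------------------------------------------------------------- spikes

def cluster_centers(sim: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Mark-cluster centers, min pairwise separation enforced per group."""
    lo, hi = sim.mark_range
    centers = np.empty((sim.n_groups, sim.cells_per_group, sim.mark_dim))
    for g in range(sim.n_groups):
        placed: list[np.ndarray] = []
        while len(placed) < sim.cells_per_group:
            c = rng.uniform(lo, hi, sim.mark_dim)
            if all(
                np.linalg.norm(c - p) >= sim.cluster_separation for p in placed
            ):
                placed.append(c)
        centers[g] = placed
    return centers


def tuning_curve(sim: SimConfig, centers_cm: np.ndarray, s_cm) -> np.ndarray:
    """Gaussian place-field rate for each cell at path positions s."""
    s = np.atleast_1d(np.asarray(s_cm, float))
    d2 = (s[None, :] - centers_cm[:, None]) ** 2
    return sim.baseline_rate_hz + sim.peak_rate_hz * np.exp(
        -d2 / (2.0 * sim.field_width_cm**2)
    )


def simulate_spikes(
    sim: SimConfig,
    geometry: TrackGeometry | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Place-cell spikes with Gaussian mark clusters + trajectory truth.

    Spike times are sampled per cell by thinning a homogeneous Poisson
    process at the cell's peak rate against its tuning curve evaluated at
    the true trajectory.
    """
    geometry = geometry or default_geometry()
    rng = rng if rng is not None else np.random.default_rng(sim.seed)
    _, truth = simulate_trajectory(sim, geometry)
    track_len = truth.track_length_cm
    n_cells = sim.n_groups * sim.cells_per_group
    # place fields evenly spaced with jitter, covering the full track
    spacing = track_len / n_cells
    jitter = rng.uniform(-spacing / 4, spacing / 4, n_cells)
    field_centers = (np.arange(n_cells) + 0.5) * spacing + jitter
    rng.shuffle(field_centers)  # decorrelate field order from group order
    marks_centers = cluster_centers(sim, rng)

    lam_max = sim.baseline_rate_hz + sim.peak_rate_hz
    rows = []
    cell_ids = []
    for cell in range(n_cells):
        n_cand = rng.poisson(lam_max * sim.duration_s)
        t_cand = np.sort(rng.uniform(0.0, sim.duration_s, n_cand))
        s_cand = path_position(sim, t_cand, geometry)
        rate = tuning_curve(sim, field_centers[[cell]], s_cand)[0]
        keep = rng.uniform(0, lam_max, n_cand) < rate
        t_spk = t_cand[keep]
        g, c = divmod(cell, sim.cells_per_group)
        marks = marks_centers[g, c] + rng.normal(
            0.0, sim.mark_sd, (len(t_spk), sim.mark_dim)
        )
        for t, m in zip(t_spk, marks):
            rows.append((int(round(t * sim.clock_hz)), g, *m, t))
            cell_ids.append(cell)
    cols = ["timestamp", "electrode_group_id"] + [
        f"mark_{d}" for d in range(sim.mark_dim)
    ] + ["_t"]
    df = pd.DataFrame(rows, columns=cols)
    cell_arr = np.asarray(cell_ids, np.int64)
    order = np.argsort(df["timestamp"].to_numpy(), kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    truth.spike_cell = cell_arr[order]
    truth.spike_times_s = df.pop("_t").to_numpy()
    df["timestamp"] = df["timestamp"].astype(np.int64)
    df["electrode_group_id"] = df["electrode_group_id"].astype(np.int64)
    return df, truth


# --------------------------------------------------------------------- LFP

def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-shaped Gaussian noise, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / np.sqrt(np.mean(x**2))


def ripple_times(sim: SimConfig, rng: np.random.Generator,
                 t_start: float | None = None) -> np.ndarray:
    """Non-overlapping burst onset times, clear of the baseline window."""
    t0 = sim.ripple_free_start_s if t_start is None else t_start
    t1 = sim.duration_s - 2 * sim.ripple_dur_s
    if sim.n_ripples == 0:
        return np.empty(0)
    slots = np.linspace(t0, t1, sim.n_ripples, endpoint=False)
    gap = (t1 - t0) / max(sim.n_ripples, 1)
    jit = rng.uniform(0.0, max(gap - 2 * sim.ripple_dur_s, 0.0), sim.n_ripples)
    return slots + jit


def simulate_lfp(
    sim: SimConfig,
    rng: np.random.Generator | None = None,
    onsets_s: np.ndarray | None = None,
    group_id: int = 0,
) -> tuple[pd.DataFrame, list[tuple[float, float]]]:
    """Background 1/f noise + ripple-band bursts at known times.

    Bursts are sinusoids at ``ripple_freq_hz`` under a fast-attack Tukey
    envelope (10 ms tapers — in vivo ripples start abruptly), with peak
    amplitude ``ripple_amp_rms`` times the background RMS (1.0).  Returns
    the long-format LFP frame and the injected (start, end) intervals in
    seconds.
    """
    rng = rng if rng is not None else np.random.default_rng(sim.seed)
    n = int(np.floor(sim.duration_s * sim.fs_lfp))
    t = np.arange(n) / sim.fs_lfp
    x = _pink_noise(n, rng)
    if onsets_s is None:
        onsets_s = ripple_times(sim, rng)
    intervals = []
    n_burst = int(round(sim.ripple_dur_s * sim.fs_lfp))
    win = tukey(n_burst, 0.25)
    for on in onsets_s:
        i0 = int(round(on * sim.fs_lfp))
        if i0 + n_burst > n:
            continue
        phase = rng.uniform(0, 2 * np.pi)
        tt = np.arange(n_burst) / sim.fs_lfp
        x[i0 : i0 + n_burst] += (
            sim.ripple_amp_rms
            * win
            * np.sin(2 * np.pi * sim.ripple_freq_hz * tt + phase)
        )
        intervals.append((on, on + sim.ripple_dur_s))
    ticks_per_sample = sim.clock_hz / sim.fs_lfp
    df = pd.DataFrame(
        {
            "timestamp": np.round(np.arange(n) * ticks_per_sample).astype(np.int64),
            "group_id": np.full(n, group_id, np.int64),
            "value": x,
        }
    )
    return df, intervals


# ------------------------------------------------------------------ session

def simulate_session(
    sim: SimConfig,
    out_dir: str | Path,
    geometry: TrackGeometry | None = None,
) -> tuple[dict[str, Path], GroundTruth]:
    """Write a complete CSV session (spikes, LFP, position) + return truth."""
    geometry = geometry or default_geometry()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(sim.seed)
    pos_df, _ = simulate_trajectory(sim, geometry)
    spikes_df, truth = simulate_spikes(sim, geometry, rng)
    lfp_df, intervals = simulate_lfp(sim, rng)
    truth.ripple_intervals_s = intervals
    paths = {
        "spikes": out_dir / "spikes.csv",
        "lfp": out_dir / "lfp.csv",
        "position": out_dir / "position.csv",
    }
    spikes_df.to_csv(paths["spikes"], index=False)
    lfp_df.to_csv(paths["lfp"], index=False)
    pos_df.to_csv(paths["position"], index=False)
    return paths, truth
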