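"""Single-process streaming-replay orchestrator.

The live multi-process deployment (acquisition, ripple, encoder, decoder and
coordinator processes exchanging messages) is re-expressed here as one
deterministic event loop over the merged, timestamp-ordered sample stream.
Stage boundaries mirror the process decomposition so a parallel port stays
straightforward:

* position samples update the running-speed estimate and the animal's
  linearized bin; during task 1 (encoding) movement-period frames
  accumulate occupancy;
* spikes during task 1 with concurrent speed >= ``vel_thresh`` are stored
  in their group's encoding model; all models freeze at the task boundary;
* LFP keeps the decoder clock: every time LFP time crosses a dt boundary
  the pending chunk feeds the ripple detectors and a decoder step fires —
  spikes inside the step's half-open collection window contribute their
  joint mark intensities to the clusterless likelihood, the posterior is
  updated, and (in task 2) the remote-representation detector is stepped.

Results stream to a binary record file (decoder output, likelihoods,
ripples, representation events, dropped spikes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SessionConfig
from .decoder import bin_window, likelihood, predict, update
from .encoder import EncodingModel
from .events import RepresentationDetector
from .linearization import SpeedEstimator, distance_to_segments, to_bin
from .records import BinaryRecordWriter, RecordSchema, read_records
from .ripples import RippleDetector
from .sources import (
    LFPCSVSource,
    LFPHDF5Source,
    PositionCSVSource,
    PositionHDF5Source,
    SpikeCSVSource,
    SpikeHDF5Source,
    merge_streams,
)
from .types import LFPSample, PositionSample, SpikeEvent

__all__ = ["SessionReport", "run_session", "decode_offline", "RECORD_IDS"]

logger = logging.getLogger(__name__)

RECORD_IDS = {
    "DECODER_OUTPUT": 1,
    "LIKELIHOOD_OUTPUT": 2,
    "RIPPLE_OUTPUT": 3,
    "EVENT_OUTPUT": 4,
    "DROPPED_SPIKES": 5,
}


@dataclass
class SessionReport:
    """Bookkeeping of one replay run."""

    n_posterior_records: int = 0
    n_warmup_bins: int = 0
    spikes_ingested_task1: int = 0
    spikes_encoded: int = 0
    spikes_skipped_immobile: int = 0
    spikes_ingested_task2: int = 0
    spikes_decoded: int = 0
    spikes_dropped: int = 0
    spikes_pending_end: int = 0  # windows never closed before the stream ended
    n_ripples: int = 0
    n_events: int = 0
    events: list = field(default_factory=list)
    groups_active: tuple = ()
    encoding_time_s: float = 0.0
    output_path: str = ""


def _open_sources(config: SessionConfig):
    def pick(path, csv_cls, h5_cls):
        p = Path(path)
        cls = h5_cls if p.suffix in (".h5", ".hdf5") else csv_cls
        return cls(p)

    spikes = pick(config.spikes_path, SpikeCSVSource, SpikeHDF5Source)
    lfp = pick(config.lfp_path, LFPCSVSource, LFPHDF5Source)
    position = pick(config.position_path, PositionCSVSource, PositionHDF5Source)
    for g in config.electrode_groups:
        spikes.register_group(g)
        lfp.register_group(g)
    lfp.register_group(0)
    for s in (spikes, lfp, position):
        s.activate()
    return spikes, lfp, position


def _register_schemas(writer: BinaryRecordWriter, n_bins: int) -> None:
    writer.register(RecordSchema(
        RECORD_IDS["DECODER_OUTPUT"],
        ("bin_timestamp_l", "bin_timestamp_r", "velocity", "mapped_pos",
         "spike_count", "task_state", "dropped_spikes", "vel_thresh",
         "frozen_model") + tuple(f"post_{i}" for i in range(n_bins)),
        "qqdqqqqd?" + "d" * n_bins,
    ))
    writer.register(RecordSchema(
        RECORD_IDS["LIKELIHOOD_OUTPUT"],
        ("bin_timestamp_l", "bin_timestamp_r", "spike_count")
        + tuple(f"lk_{i}" for i in range(n_bins)),
        "qqq" + "d" * n_bins,
    ))
    writer.register(RecordSchema(
        RECORD_IDS["RIPPLE_OUTPUT"],
        ("group_id", "start_timestamp", "end_timestamp", "peak_z"),
        "qqqd",
    ))
    writer.register(RecordSchema(
        RECORD_IDS["EVENT_OUTPUT"],
        ("timestamp", "target_frac", "offtarget_frac", "distance_cm",
         "n_groups"),
        "qdddq",
    ))
    writer.register(RecordSchema(
        RECORD_IDS["DROPPED_SPIKES"],
        ("timestamp", "elec_grp_id", "real_bin", "late_bin"),
        "qiii",
    ))


def run_session(config: SessionConfig) -> SessionReport:
    """Replay a session deterministically; returns the report.

    The record file at ``config.output_path`` (plus its schema sidecar) is
    bit-identical across reruns with the same inputs and configuration.
    """
    geometry = config.geometry()
    grid = geometry.grid()
    n_bins = grid.n_bins
    dconf = config.decoder_config()
    dt_ticks = config.dt_ms * config.clock_hz / 1000.0
    delay_ticks = config.dt_delay_ms * config.clock_hz / 1000.0
    task1_end_ticks = config.task1_end_s * config.clock_hz

    spikes_src, lfp_src, pos_src = _open_sources(config)
    report = SessionReport(output_path=str(config.output_path))

    encoders = {
        g: EncodingModel(
            g, n_bins, config.encoder.mark_dim,
            sigma=config.encoder.sigma,
            occupancy_smoothing_bins=config.encoder.occupancy_smoothing_bins,
            occupancy_floor=config.encoder.occupancy_floor,
        )
        for g in config.electrode_groups
    }
    speed = SpeedEstimator(config.cm_per_pixel, config.clock_hz,
                           config.speed_window_s, config.camera_hz)
    ripple_detectors: dict[int, RippleDetector] = {}
    event_det = RepresentationDetector(config.event, config.clock_hz)
    # spatial specificity is judged over the whole target/off-target arms
    ev_bins = set(config.event.target_bins) | set(config.event.offtarget_bins)
    arm_segs = {int(grid.bin_segment[b]) for b in ev_bins}
    specific_bins = np.asarray(
        sorted(b for b in range(n_bins) if int(grid.bin_segment[b]) in arm_segs),
        dtype=np.int64,
    )

    frozen = False
    ground_vectors: dict[int, np.ndarray] = {}
    cur_bin = 0
    cur_speed = 0.0
    cur_xy_cm = np.zeros(2)
    dwell = 1.0 / config.camera_hz
    pending: list[SpikeEvent] = []  # arrive in timestamp order
    lfp_ts_buf: list[int] = []
    lfp_val_buf: list[np.ndarray] = []
    lfp_gids: list[int] = []
    t0 = None
    next_boundary = None
    posterior = np.full(n_bins, 1.0 / n_bins)
    last_window_hi = -np.inf

    def freeze_all() -> None:
        nonlocal frozen, ground_vectors
        active = {}
        for g, m in encoders.items():
            if m.n_stored == 0:
                logger.warning("group %d stored no spikes; excluded", g)
                continue
            m.freeze()
            active[g] = m
        if not active:
            # degenerate but well-defined: every bin's likelihood is the
            # empty product == 1, so the posterior follows the prior
            logger.warning("no electrode group stored any encoding spikes")
        ground_vectors = {g: m.ground_intensity() for g, m in active.items()}
        report.groups_active = tuple(sorted(active))
        report.encoding_time_s = max(
            (m.encoding_time_s for m in active.values()), default=0.0
        )
        frozen = True

    def flush_ripples() -> None:
        if not lfp_ts_buf:
            return
        ts = np.asarray(lfp_ts_buf, np.int64)
        vals = np.asarray(lfp_val_buf)
        lfp_ts_buf.clear()
        lfp_val_buf.clear()
        for ch, gid in enumerate(lfp_gids):
            det = ripple_detectors.get(gid)
            if det is None:
                det = ripple_detectors[gid] = RippleDetector(config.ripple, gid)
            for ev in det.process(ts, vals[:, ch]):
                writer.write_record(
                    RECORD_IDS["RIPPLE_OUTPUT"], ev.group_id,
                    ev.start_timestamp, ev.end_timestamp, ev.peak_z,
                )
                report.n_ripples += 1

    with BinaryRecordWriter(config.output_path) as writer:
        _register_schemas(writer, n_bins)

        def decoder_step(t_curr_ticks: float) -> None:
            nonlocal posterior, last_window_hi
            lo = t_curr_ticks - delay_ticks - dt_ticks
            hi = t_curr_ticks - delay_ticks
            if lo < t0:
                report.n_warmup_bins += 1
                # consume nothing: spikes before the first full window are
                # outside any decodable bin
                return
            last_window_hi = hi
            in_window: list[SpikeEvent] = []
            while pending and pending[0].timestamp <= hi:
                s = pending.pop(0)
                if s.timestamp > lo:
                    in_window.append(s)
                else:
                    report.spikes_dropped += 1
                    writer.write_record(
                        RECORD_IDS["DROPPED_SPIKES"], s.timestamp,
                        s.electrode_group_id, int(lo // dt_ticks),
                        int(s.timestamp // dt_ticks),
                    )
            spike_count = len(in_window)
            task_state = 2 if frozen else 1
            if frozen:
                group_results = {
                    g: (gv, []) for g, gv in ground_vectors.items()
                }
                specific_groups: set[int] = set()
                for s in in_window:
                    g = s.electrode_group_id
                    if g not in group_results:
                        continue
                    res = encoders[g].intensities(s.mark_from_waveform())
                    group_results[g][1].append(res.jmi)
                    tot = res.jmi.sum()
                    if tot > 0 and (
                        res.jmi[specific_bins].sum() / tot
                        > config.event.specificity_frac
                    ):
                        specific_groups.add(g)
                    report.spikes_decoded += 1
                like = likelihood(group_results, dconf)
            else:
                like = np.ones(n_bins)
                specific_groups = set()
            prior = predict(posterior, dconf.transition)
            state = update(prior, like, (lo, hi), spike_count)
            posterior = state.posterior
            writer.write_record(
                RECORD_IDS["DECODER_OUTPUT"],
                int(round(lo)), int(round(hi)), cur_speed, cur_bin,
                spike_count, task_state, report.spikes_dropped,
                config.vel_thresh_cm_s, frozen,
                *posterior.tolist(),
            )
            writer.write_record(
                RECORD_IDS["LIKELIHOOD_OUTPUT"],
                int(round(lo)), int(round(hi)), spike_count,
                *state.likelihood.tolist(),
            )
            report.n_posterior_records += 1
            if frozen:
                dist = distance_to_segments(
                    cur_xy_cm, geometry, config.center_segments
                )
                ev = event_det.step(
                    posterior, specific_groups, dist, int(round(t_curr_ticks))
                )
                if ev is not None:
                    writer.write_record(
                        RECORD_IDS["EVENT_OUTPUT"], ev.trigger_timestamp,
                        ev.target_fraction, ev.offtarget_fraction,
                        ev.animal_distance_cm, len(ev.contributing_groups),
                    )
                    report.n_events += 1

        for sample in merge_streams(lfp_src, pos_src, spikes_src):
            ts = sample.timestamp
            if not frozen and ts >= task1_end_ticks:
                freeze_all()
            if isinstance(sample, LFPSample):
                if t0 is None:
                    t0 = ts
                    next_boundary = t0 + dt_ticks
                    lfp_gids = list(sample.electrode_group_ids)
                lfp_ts_buf.append(ts)
                lfp_val_buf.append(sample.values)
                while ts >= next_boundary:
                    flush_ripples()
                    decoder_step(next_boundary)
                    next_boundary += dt_ticks
            elif isinstance(sample, PositionSample):
                cur_speed = speed.update(ts, sample.x, sample.y)
                cur_bin = to_bin(sample.segment, sample.norm_pos, geometry)
                cur_xy_cm = np.array([sample.x, sample.y]) * config.cm_per_pixel
                if not frozen and cur_speed >= config.vel_thresh_cm_s:
                    for m in encoders.values():
                        m.add_occupancy(cur_bin, dwell)
            else:  # SpikeEvent
                if not frozen:
                    report.spikes_ingested_task1 += 1
                    if cur_speed >= config.vel_thresh_cm_s:
                        enc = encoders.get(sample.electrode_group_id)
                        if enc is not None:
                            enc.add_spike(sample.mark_from_waveform(), cur_bin)
                            report.spikes_encoded += 1
                        else:
                            report.spikes_skipped_immobile += 1
                    else:
                        report.spikes_skipped_immobile += 1
                else:
                    report.spikes_ingested_task2 += 1
                    if sample.timestamp <= last_window_hi:
                        report.spikes_dropped += 1
                        writer.write_record(
                            RECORD_IDS["DROPPED_SPIKES"], sample.timestamp,
                            sample.electrode_group_id,
                            int(last_window_hi // dt_ticks),
                            int(sample.timestamp // dt_ticks),
                        )
                    else:
                        pending.append(sample)
        flush_ripples()

    if t0 is None:
        raise RuntimeError("input streams contained no LFP samples")
    if not frozen:
        raise RuntimeError("inputs ended before the task 1 boundary")
    report.spikes_pending_end = len(pending)
    report.events = list(event_det.events)
    return report


def decode_offline(
    records_path: str | Path,
    truth_times_s: np.ndarray | None = None,
    truth_bins: np.ndarray | None = None,
    clock_hz: float = 30_000.0,
    bin_size_cm: float = 5.0,
) -> pd.DataFrame:
    """Summarize a record file: MAP bin per time bin, error vs truth.

    When fixture truth (frame times in seconds + true bins) is supplied,
    an ``error_cm`` column gives |MAP bin - true bin| * bin size, with the
    true bin taken from the last camera frame at or before each decoding
    window's right edge.  Uniform posteriors tie-break to the lowest bin
    index and are flagged.
    """
    tables = read_records(records_path)
    dec = tables[RECORD_IDS["DECODER_OUTPUT"]]
    post_cols = [c for c in dec.columns if c.startswith("post_")]
    post = dec[post_cols].to_numpy()
    out = pd.DataFrame(
        {
            "bin_timestamp_l": dec["bin_timestamp_l"],
            "bin_timestamp_r": dec["bin_timestamp_r"],
            "spike_count": dec["spike_count"],
            "task_state": dec["task_state"],
            "map_bin": post.argmax(axis=1),
            "map_prob": post.max(axis=1),
            "velocity": dec["velocity"],
            "uniform_flag": np.isclose(post.max(axis=1), 1.0 / post.shape[1]),
        }
    )
    if truth_times_s is not None and truth_bins is not None:
        t_right = dec["bin_timestamp_r"].to_numpy() / clock_hz
        idx = np.searchsorted(truth_times_s, t_right, side="right") - 1
        idx = np.clip(idx, 0, len(truth_bins) - 1)
        out["true_bin"] = np.asarray(truth_bins)[idx]
        out["error_cm"] = np.abs(out["map_bin"] - out["true_bin"]) * bin_size_cm
    return out
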