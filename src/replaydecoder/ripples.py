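"""Online sharp-wave-ripple (SWR) detection from streamed LFP.

Processing chain per channel, all causal and stateful so that chunked
streaming is sample-exact with whole-trace filtering:

1. band-pass the raw LFP to the ripple band (default 150-250 Hz, causal
   Butterworth IIR),
2. estimate ripple power by low-pass filtering the squared band signal,
3. z-score the power against a baseline mean/sd estimated over an initial
   window and then frozen (optionally updated with a slow exponential),
4. a two-threshold state machine: an event opens when z crosses
   ``z_threshold`` (typically >= 3) and closes when z falls below
   ``z_end_threshold`` (default 0, i.e. return to baseline power).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = ["RippleConfig", "RippleEvent", "StreamingSOS", "RippleDetector",
           "consensus_intervals", "lfp_deadline_us"]


def lfp_deadline_us(fs_lfp: float) -> float:
    """Per-sample real-time processing budget in microseconds.

    Every LFP sample must be handled in under one sampling interval,
    1 / fs_lfp; at 1,500 Hz that is 667 us.
    """
    if fs_lfp <= 0:
        raise ValueError("sampling rate must be positive")
    return 1e6 / fs_lfp


@dataclass(frozen=True)
class RippleConfig:
    fs_lfp: float = 1500.0
    band: tuple[float, float] = (150.0, 250.0)
    band_order: int = 2
    power_lowpass_hz: float = 50.0
    power_order: int = 2
    z_threshold: float = 3.0
    z_end_threshold: float = 0.0
    baseline_window_s: float = 10.0
    baseline_decay: float = 0.0  # 0 = frozen after the window; else per-sample EMA rate

    def __post_init__(self) -> None:
        low, high = self.band
        nyq = self.fs_lfp / 2.0
        if not 0 < low < high < nyq:
            raise ValueError(
                f"band {self.band} must satisfy 0 < low < high < Nyquist ({nyq})"
            )
        if not 0 < self.power_lowpass_hz < nyq:
            raise ValueError("power low-pass cutoff outside (0, Nyquist)")
        if self.z_threshold < self.z_end_threshold:
            raise ValueError("z_threshold must be >= z_end_threshold")


@dataclass(frozen=True)
class RippleEvent:
    """One detected ripple on one channel (timestamps in clock ticks)."""

    group_id: int
    start_timestamp: int
    end_timestamp: int
    peak_z: float


def ripple_bandpass_sos(config: RippleConfig) -> np.ndarray:
    return signal.butter(
        config.band_order, config.band, btype="bandpass", fs=config.fs_lfp,
        output="sos",
    )


def power_lowpass_sos(config: RippleConfig) -> np.ndarray:
    return signal.butter(
        config.power_order, config.power_lowpass_hz, btype="lowpass",
        fs=config.fs_lfp, output="sos",
    )


class StreamingSOS:
    """Causal second-order-sections filter with state carried across chunks."""

    def __init__(self, sos: np.ndarray):
        self.sos = sos
        self._zi = np.zeros((sos.shape[0], 2))

    def process(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, float))
        y, self._zi = signal.sosfilt(self.sos, x, zi=self._zi)
        return y


class RippleDetector:
    """Streaming SWR detector for a single LFP channel."""

    def __init__(self, config: RippleConfig, group_id: int = 0):
        self.config = config
        self.group_id = int(group_id)
        self._bp = StreamingSOS(ripple_bandpass_sos(config))
        self._lp = StreamingSOS(power_lowpass_sos(config))
        self._baseline_n_target = int(round(config.baseline_window_s * config.fs_lfp))
        self._baseline_sum = 0.0
        self._baseline_sumsq = 0.0
        self._baseline_n = 0
        self._mean: float | None = None
        self._sd: float | None = None
        self.in_event = False
        self._event_start = 0
        self._event_peak = -np.inf
        self.last_z = float("nan")

    # ------------------------------------------------------------ stage ops
    def filter_ripple_band(self, samples) -> np.ndarray:
        """Causal ripple-band filtering, one output per input sample."""
        return self._bp.process(samples)

    def power_estimate(self, filtered) -> np.ndarray:
        """Causal low-pass of the squared band signal (power proxy)."""
        return self._lp.process(np.asarray(filtered, float) ** 2)

    @property
    def baseline_ready(self) -> bool:
        return self._mean is not None

    def _update_baseline(self, envelope: np.ndarray) -> None:
        cfg = self.config
        if self._mean is None:
            take = envelope[: self._baseline_n_target - self._baseline_n]
            self._baseline_sum += take.sum()
            self._baseline_sumsq += (take**2).sum()
            self._baseline_n += len(take)
            if self._baseline_n >= self._baseline_n_target:
                mean = self._baseline_sum / self._baseline_n
                var = self._baseline_sumsq / self._baseline_n - mean**2
                sd = float(np.sqrt(max(var, 0.0)))
                if sd == 0.0:
                    raise ValueError("degenerate baseline: sd of power is zero")
                self._mean, self._sd = float(mean), sd
        elif cfg.baseline_decay > 0:
            a = cfg.baseline_decay
            for e in envelope:
                self._mean = (1 - a) * self._mean + a * float(e)

    def zscore(self, envelope) -> np.ndarray:
        """Z-score power samples; NaN while the baseline window is filling."""
        envelope = np.atleast_1d(np.asarray(envelope, float))
        n_before = self._baseline_n_target - self._baseline_n if self._mean is None else 0
        self._update_baseline(envelope)
        z = np.full(len(envelope), np.nan)
        if self._mean is not None:
            start = min(n_before, len(envelope))
            z[start:] = (envelope[start:] - self._mean) / self._sd
        return z

    def detect(self, z, timestamps) -> list[RippleEvent]:
        """Run the onset/offset state machine over z samples."""
        cfg = self.config
        z = np.atleast_1d(np.asarray(z, float))
        timestamps = np.atleast_1d(np.asarray(timestamps))
        events: list[RippleEvent] = []
        for zi, ts in zip(z, timestamps):
            if np.isnan(zi):
                continue
            if not self.in_event:
                if zi >= cfg.z_threshold:
                    self.in_event = True
                    self._event_start = int(ts)
                    self._event_peak = float(zi)
            else:
                self._event_peak = max(self._event_peak, float(zi))
                if zi < cfg.z_end_threshold:
                    self.in_event = False
                    events.append(
                        RippleEvent(
                            self.group_id, self._event_start, int(ts),
                            self._event_peak,
                        )
                    )
                    self._event_peak = -np.inf
        self.last_z = float(z[-1]) if len(z) else self.last_z
        return events

    def process(self, timestamps, values) -> list[RippleEvent]:
        """Full chain over one chunk; returns events closed in this chunk."""
        filtered = self.filter_ripple_band(values)
        env = self.power_estimate(filtered)
        z = self.zscore(env)
        return self.detect(z, timestamps)


def consensus_intervals(
    events_per_channel: dict[int, list[RippleEvent]], n_required: int
) -> list[tuple[int, int]]:
    """Intervals where >= ``n_required`` channels are simultaneously in-event.

    Optional n-of-m consensus over independently detected channels; the
    default pipeline treats channels independently.
    """
    edges: list[tuple[int, int]] = []
    for evs in events_per_channel.values():
        for ev in evs:
            edges.append((ev.start_timestamp, +1))
            edges.append((ev.end_timestamp, -1))
    edges.sort()
    out, depth, start = [], 0, None
    for t, d in edges:
        depth += d
        if depth >= n_required and start is None:
            start = t
        elif depth < n_required and start is not None:
            out.append((start, t))
            start = None
    return out
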