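"""Track linearization: 2D positions -> 1D binned coordinate, plus speed.

The track is described by user-defined line segments (endpoints in cm).
A 2D point is assigned to the segment minimizing clamped point-to-segment
distance, with a normalized coordinate in [0, 1] along that segment.  Each
segment spans an integer number of fixed-width bins (default 5 cm); bins
are 0-based and laid out contiguously in segment order, so the full grid
covers ``sum(bins_per_segment)`` bins.  Bin intervals are half-open
[left, right); ``norm_pos == 1`` clamps to the segment's last bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TrackGeometry", "PositionGrid", "linearize", "to_bin",
           "estimate_speed", "SpeedEstimator"]


@dataclass(frozen=True)
class TrackGeometry:
    """Segmented track layout.

    ``segments`` is a sequence of ((x1, y1), (x2, y2)) endpoint pairs in cm;
    ``bins_per_segment`` gives how many ``bin_size_cm`` bins each spans.
    Segment lengths must agree with bins * bin_size within one bin.
    """

    segments: tuple
    bins_per_segment: tuple
    bin_size_cm: float = 5.0

    def __post_init__(self) -> None:
        segs = tuple(
            (np.asarray(a, float), np.asarray(b, float)) for a, b in self.segments
        )
        object.__setattr__(self, "segments", segs)
        object.__setattr__(self, "bins_per_segment", tuple(int(n) for n in self.bins_per_segment))
        if len(segs) == 0:
            raise ValueError("geometry needs at least one segment")
        if len(segs) != len(self.bins_per_segment):
            raise ValueError("one bins_per_segment entry per segment")
        if self.total_bins < 1:
            raise ValueError("total bin count must be >= 1")
        for i, ((a, b), nb) in enumerate(zip(segs, self.bins_per_segment)):
            length = float(np.linalg.norm(b - a))
            if abs(length - nb * self.bin_size_cm) > self.bin_size_cm:
                raise ValueError(
                    f"segment {i}: length {length:.1f} cm inconsistent with "
                    f"{nb} x {self.bin_size_cm} cm bins"
                )

    @property
    def total_bins(self) -> int:
        return int(sum(self.bins_per_segment))

    @property
    def bin_offsets(self) -> np.ndarray:
        """First bin index of each segment."""
        return np.concatenate([[0], np.cumsum(self.bins_per_segment)[:-1]]).astype(int)

    def grid(self) -> "PositionGrid":
        bin_seg = np.repeat(
            np.arange(len(self.segments)), self.bins_per_segment
        )
        return PositionGrid(self.total_bins, self.bin_size_cm, bin_seg)


@dataclass(frozen=True)
class PositionGrid:
    """Linearized 1D support: ``n_bins`` bins of ``bin_size_cm`` each."""

    n_bins: int
    bin_size_cm: float
    bin_segment: np.ndarray = field(default=None, repr=False)

    def centers_cm(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_size_cm


def linearize(point_2d, geometry: TrackGeometry) -> tuple[int, float]:
    """Nearest segment (clamped projection) and normalized position on it."""
    p = np.asarray(point_2d, float)
    if not np.all(np.isfinite(p)):
        raise ValueError("point must be finite")
    best = (np.inf, -1, 0.0)
    for i, (a, b) in enumerate(geometry.segments):
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
        d = float(np.linalg.norm(p - (a + t * ab)))
        if d < best[0]:
            best = (d, i, t)
    return best[1], best[2]


def to_bin(segment_id: int, norm_pos: float, geometry: TrackGeometry) -> int:
    """Global bin index for a (segment, normalized position) pair."""
    if not 0 <= segment_id < len(geometry.segments):
        raise ValueError(f"unknown segment {segment_id}")
    if not 0.0 <= norm_pos <= 1.0:
        raise ValueError(f"norm_pos {norm_pos} outside [0, 1]")
    nb = geometry.bins_per_segment[segment_id]
    local = min(int(np.floor(norm_pos * nb)), nb - 1)
    return int(geometry.bin_offsets[segment_id] + local)


def distance_to_segments(point_2d, geometry: TrackGeometry,
                         segment_ids=None) -> float:
    """Min clamped distance (cm) from a point to a subset of segments."""
    p = np.asarray(point_2d, float)
    ids = range(len(geometry.segments)) if segment_ids is None else segment_ids
    best = np.inf
    for i in ids:
        a, b = geometry.segments[i]
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
        best = min(best, float(np.linalg.norm(p - (a + t * ab))))
    return best


def estimate_speed(positions_cm: np.ndarray, dt: float,
                   smooth_window_s: float = 0.25) -> np.ndarray:
    """Boxcar-smoothed finite-difference speed (cm/s) for a 2D trace.

    ``positions_cm`` has shape (n, 2), sampled every ``dt`` seconds.  The
    speed at sample i is |x_i - x_{i-1}| / dt (first sample repeats the
    second), then smoothed with a centered boxcar of ``smooth_window_s``.
    """
    pos = np.atleast_2d(np.asarray(positions_cm, float))
    if len(pos) < 2:
        raise ValueError("need at least two position samples")
    step = np.linalg.norm(np.diff(pos, axis=0), axis=1) / dt
    raw = np.concatenate([[step[0]], step])
    w = max(1, int(round(smooth_window_s / dt)))
    kernel = np.ones(w) / w
    pad = np.pad(raw, (w // 2, w - 1 - w // 2), mode="edge")
    return np.convolve(pad, kernel, mode="valid")


class SpeedEstimator:
    """Streaming running-speed estimate from camera samples.

    Causal variant of :func:`estimate_speed`: instantaneous speed from the
    last pair of samples, averaged over a trailing boxcar window.
    """

    def __init__(self, cm_per_pixel: float, clock_hz: float,
                 smooth_window_s: float = 0.25, camera_hz: float = 30.0):
        self.cm_per_pixel = cm_per_pixel
        self.clock_hz = clock_hz
        self._maxlen = max(1, int(round(smooth_window_s * camera_hz)))
        self._last: tuple[int, np.ndarray] | None = None
        self._recent: list[float] = []

    def update(self, timestamp: int, x_pix: float, y_pix: float) -> float:
        p = np.array([x_pix, y_pix], float) * self.cm_per_pixel
        if self._last is None:
            self._last = (timestamp, p)
            return 0.0
        t0, p0 = self._last
        dt = (timestamp - t0) / self.clock_hz
        if dt > 0:
            self._recent.append(float(np.linalg.norm(p - p0)) / dt)
            if len(self._recent) > self._maxlen:
                self._recent.pop(0)
            self._last = (timestamp, p)
        return float(np.mean(self._recent)) if self._recent else 0.0
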