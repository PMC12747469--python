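"""Sample objects carried by the streaming data paths.

Three kinds of samples flow through the system: threshold-crossing spike
events (with either a raw waveform snippet or a precomputed mark vector of
waveform features), LFP samples, and camera position samples that arrive
already linearized to a track segment.  Timestamps are integer ticks of the
acquisition clock (e.g. 30 kHz); the optional ``t_send``/``t_recv``
nanosecond wall-clock stamps are diagnostic pass-throughs only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["SpikeEvent", "LFPSample", "PositionSample"]


@dataclass(slots=True)
class SpikeEvent:
    """A single threshold-crossing event on one electrode group.

    Exactly one of ``waveform`` (shape ``(n_channels, n_samples)``, ADC
    units) or ``mark`` (length-D feature vector, typically per-channel peak
    amplitudes) may be omitted.  ``mark_from_waveform`` derives the default
    mark — the per-channel peak amplitude — when only a snippet is present.
    """

    timestamp: int
    electrode_group_id: int
    waveform: Optional[np.ndarray] = None
    mark: Optional[np.ndarray] = None
    t_send: Optional[int] = None
    t_recv: Optional[int] = None

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise ValueError("spike timestamp must be non-negative")
        if self.waveform is None and self.mark is None:
            raise ValueError("spike needs a waveform or a mark vector")
        if self.mark is not None:
            self.mark = np.asarray(self.mark, dtype=float)
            if self.mark.ndim != 1 or self.mark.size < 1:
                raise ValueError("mark must be a vector with D >= 1")
        if self.waveform is not None:
            self.waveform = np.atleast_2d(np.asarray(self.waveform, dtype=float))

    def mark_from_waveform(self) -> np.ndarray:
        """Return the mark, computing per-channel peak amplitude if needed."""
        if self.mark is not None:
            return self.mark
        return self.waveform.max(axis=1)


@dataclass(slots=True)
class LFPSample:
    """One LFP time point, possibly carrying several electrode groups."""

    timestamp: int
    electrode_group_ids: list[int] = field(default_factory=list)
    values: np.ndarray = None
    t_send: Optional[int] = None
    t_recv: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if len(self.values) != len(self.electrode_group_ids):
            raise ValueError("one LFP value per listed electrode group")


@dataclass(slots=True)
class PositionSample:
    """One camera frame, already assigned to a track segment.

    ``norm_pos`` is the normalized coordinate along that segment in [0, 1];
    ``(x, y)`` and ``(x2, y2)`` are the two tracked points in pixels (e.g.
    red and green LEDs).
    """

    timestamp: int
    segment: int
    norm_pos: float
    x: float = 0.0
    y: float = 0.0
    x2: float = 0.0
    y2: float = 0.0
    t_recv: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.norm_pos <= 1.0:
            raise ValueError(f"norm_pos {self.norm_pos} outside [0, 1]")
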