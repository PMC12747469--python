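"""Remote-representation detection from recent decoded posteriors.

Every posterior update, the trailing ``dt_event`` (default 36 ms) of
posteriors is averaged and renormalized.  A remote representation fires
when, simultaneously (strict comparisons, as configured):

* more than ``target_frac`` (default 40%) of the averaged distribution
  lies in the target region,
* less than ``offtarget_frac`` (default 20%) lies in the off-target region,
* the animal is within ``center_radius_cm`` (default 17 cm) of the central
  box, and
* at least ``min_active_groups`` (default 2) electrode groups showed
  spatially specific activity in the window (a spike whose joint mark
  intensity concentrates in the target/off-target arms).

A refractory period (default 3 s, the reward-collection window) suppresses
retriggering.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = ["EventConfig", "RepresentationEvent", "window_average",
           "region_fractions", "evaluate", "RepresentationDetector"]


@dataclass(frozen=True)
class EventConfig:
    dt_event_ms: float = 36.0
    dt_ms: float = 6.0
    target_bins: tuple = ()
    offtarget_bins: tuple = ()
    target_frac: float = 0.40
    offtarget_frac: float = 0.20
    center_radius_cm: float = 17.0
    min_active_groups: int = 2
    refractory_s: float = 3.0
    specificity_frac: float = 0.50  # JMI mass in target+offtarget arms

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_bins", tuple(int(b) for b in self.target_bins))
        object.__setattr__(self, "offtarget_bins", tuple(int(b) for b in self.offtarget_bins))
        if set(self.target_bins) & set(self.offtarget_bins):
            raise ValueError("target and off-target bin sets must be disjoint")
        if not 0 < self.target_frac <= 1:
            raise ValueError("target_frac must be in (0, 1]")
        if self.dt_event_ms < self.dt_ms:
            raise ValueError("dt_event must be >= dt")

    @property
    def n_window(self) -> int:
        return int(round(self.dt_event_ms / self.dt_ms))


@dataclass(frozen=True)
class RepresentationEvent:
    trigger_timestamp: int
    target_fraction: float
    offtarget_fraction: float
    animal_distance_cm: float
    contributing_groups: frozenset[int]


def window_average(recent_posteriors, config: EventConfig):
    """Mean of the last dt_event/dt posteriors, renormalized; None if the
    window is not yet full."""
    n = config.n_window
    posts = list(recent_posteriors)[-n:]
    if len(posts) < n:
        return None
    avg = np.mean(np.asarray(posts, float), axis=0)
    return avg / avg.sum()


def region_fractions(distribution, config: EventConfig) -> tuple[float, float]:
    """Posterior mass in the target and off-target bin sets."""
    d = np.asarray(distribution, float)
    t = float(d[list(config.target_bins)].sum()) if config.target_bins else 0.0
    o = float(d[list(config.offtarget_bins)].sum()) if config.offtarget_bins else 0.0
    return t, o


def evaluate(
    averaged,
    animal_distance_cm: float,
    active_groups,
    config: EventConfig,
    timestamp: int = 0,
):
    """Apply the four gates to an averaged distribution; event or None.

    Comparisons are strict for the fraction gates (> 40%, < 20%) and
    inclusive for the spatial gate (<= 17 cm) and the group count (>= 2),
    as stated.
    """
    if averaged is None:
        return None
    target_f, offtarget_f = region_fractions(averaged, config)
    groups = frozenset(active_groups)
    if (
        target_f > config.target_frac
        and offtarget_f < config.offtarget_frac
        and animal_distance_cm <= config.center_radius_cm
        and len(groups) >= config.min_active_groups
    ):
        return RepresentationEvent(
            trigger_timestamp=int(timestamp),
            target_fraction=target_f,
            offtarget_fraction=offtarget_f,
            animal_distance_cm=float(animal_distance_cm),
            contributing_groups=groups,
        )
    return None


class RepresentationDetector:
    """Stateful wrapper: posterior ring buffer, group activity, refractory."""

    def __init__(self, config: EventConfig, clock_hz: float):
        self.config = config
        self.clock_hz = clock_hz
        self._posteriors: deque = deque(maxlen=config.n_window)
        self._window_groups: deque = deque(maxlen=config.n_window)
        self._last_trigger: int | None = None
        self.events: list[RepresentationEvent] = []
        self._callbacks = []

    def add_trigger_callback(self, fn) -> None:
        """Hook where hardware (reward, cue) integration would attach."""
        self._callbacks.append(fn)

    def step(self, posterior, specific_groups, animal_distance_cm: float,
             timestamp: int):
        """Feed one posterior + that bin's spatially specific groups."""
        self._posteriors.append(np.asarray(posterior, float))
        self._window_groups.append(frozenset(specific_groups))
        avg = window_average(self._posteriors, self.config)
        if avg is None:
            return None
        if self._last_trigger is not None:
            elapsed = (timestamp - self._last_trigger) / self.clock_hz
            if elapsed < self.config.refractory_s:
                return None
        active = frozenset().union(*self._window_groups)
        ev = evaluate(avg, animal_distance_cm, active, self.config, timestamp)
        if ev is not None:
            self._last_trigger = timestamp
            self.events.append(ev)
            for fn in self._callbacks:
                fn(ev)
        return ev
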