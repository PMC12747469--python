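"""Session configuration: YAML <-> dataclass plumbing and defaults."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .decoder import DecoderConfig, TransitionModel
from .events import EventConfig
from .linearization import TrackGeometry
from .ripples import RippleConfig

__all__ = ["SessionConfig", "default_session_config", "load_config",
           "dump_config"]


@dataclass(frozen=True)
class EncoderSettings:
    sigma: float = 20.0
    mark_dim: int = 4
    occupancy_smoothing_bins: float = 1.0
    occupancy_floor: float = 1e-12


@dataclass(frozen=True)
class SessionConfig:
    """Everything a replay run needs; sub-configs mirror the stage modules."""

    # inputs / outputs (CSV or HDF5 by extension)
    spikes_path: str = ""
    lfp_path: str = ""
    position_path: str = ""
    output_path: str = "records.bin"
    # track
    segments: tuple = (
        ((0.0, 75.0), (0.0, 0.0)),   # arm 2 (tip -> box)
        ((0.0, 0.0), (25.0, 0.0)),   # central box, half A
        ((25.0, 0.0), (55.0, 0.0)),  # central box, half B
        ((55.0, 0.0), (55.0, 75.0)),  # arm 1 (box -> tip)
    )
    bins_per_segment: tuple = (15, 5, 6, 15)
    bin_size_cm: float = 5.0
    center_segments: tuple = (1, 2)  # segments forming the central box
    # clocks & behaviour
    clock_hz: int = 30_000
    camera_hz: float = 30.0
    cm_per_pixel: float = 0.5
    vel_thresh_cm_s: float = 4.0
    speed_window_s: float = 0.25
    # task schedule (encoding task 1 -> feedback task 2)
    task1_end_s: float = 300.0
    # electrode groups
    electrode_groups: tuple = tuple(range(8))
    # stages
    encoder: EncoderSettings = field(default_factory=EncoderSettings)
    dt_ms: float = 6.0
    dt_delay_ms: float = 30.0
    transition: str = "uniform"
    transition_sd_bins: float = 1.0
    ripple: RippleConfig = field(default_factory=RippleConfig)
    event: EventConfig = field(default_factory=lambda: EventConfig(
        target_bins=tuple(range(36, 41)),   # tip of arm 1
        offtarget_bins=tuple(range(0, 5)),  # tip of arm 2
    ))
    seed: int = 0

    def geometry(self) -> TrackGeometry:
        return TrackGeometry(self.segments, self.bins_per_segment, self.bin_size_cm)

    def decoder_config(self) -> DecoderConfig:
        n_bins = int(sum(self.bins_per_segment))
        return DecoderConfig(
            dt_ms=self.dt_ms,
            dt_delay_ms=self.dt_delay_ms,
            n_bins=n_bins,
            transition=TransitionModel(self.transition, n_bins,
                                       self.transition_sd_bins),
        )


def default_session_config() -> SessionConfig:
    return SessionConfig()


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(x) for x in obj]
    return obj


def _build(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name == "encoder":
            v = EncoderSettings(**v)
        elif f.name == "ripple":
            v = RippleConfig(**{**v, "band": tuple(v.get("band", (150.0, 250.0)))})
        elif f.name == "event":
            v = EventConfig(**{
                **v,
                "target_bins": tuple(v.get("target_bins", ())),
                "offtarget_bins": tuple(v.get("offtarget_bins", ())),
            })
        elif f.name in ("segments",):
            v = tuple(tuple(tuple(p) for p in seg) for seg in v)
        elif f.name in ("bins_per_segment", "electrode_groups",
                        "center_segments"):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path: str | Path) -> SessionConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _build(SessionConfig, data)


def dump_config(config: SessionConfig) -> str:
    return yaml.safe_dump(_to_plain(config), sort_keys=False)
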