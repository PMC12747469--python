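"""Pluggable replay data sources and the timestamp-ordered merge.

A live acquisition stream is replaced here by file-backed sources that
honour the same contract a live receiver would: a source is *registered*
for one or more electrode groups, *activated*, and then iterated —
``next(source)`` returns the next sample in timestamp order, or ``None``
when the source is deactivated or exhausted.  CSV (human-readable fixtures)
and HDF5 (large sessions) dialects implement the same contract.

``merge_streams`` interleaves several sources into one globally
non-decreasing stream.  Ties at equal ticks break deterministically:
LFP before position before spikes, stable within a type.
"""

from __future__ import annotations

import heapq
import itertools
from abc import ABC, abstractmethod
from pathlib import Path
from typing import Iterator, Optional

import h5py
import numpy as np
import pandas as pd

from .types import LFPSample, PositionSample, SpikeEvent

__all__ = [
    "DataSource",
    "SpikeCSVSource",
    "LFPCSVSource",
    "PositionCSVSource",
    "SpikeHDF5Source",
    "LFPHDF5Source",
    "PositionHDF5Source",
    "merge_streams",
    "next_sample",
    "write_session_hdf5",
]

# merge priority at equal timestamps
_TYPE_RANK = {LFPSample: 0, PositionSample: 1, SpikeEvent: 2}


class ConfigurationError(ValueError):
    pass


class ParseError(ValueError):
    pass


class DataSource(ABC):
    """Contract shared by all replay sources."""

    def __init__(self) -> None:
        self._groups: set[int] = set()
        self._active = False
        self._iter: Optional[Iterator] = None

    def register_group(self, group_id: int) -> None:
        self._groups.add(int(group_id))

    @property
    def needs_groups(self) -> bool:
        return True

    def activate(self) -> None:
        if self.needs_groups and not self._groups:
            raise ConfigurationError(
                f"{type(self).__name__} activated with no registered "
                "electrode groups"
            )
        self._active = True
        if self._iter is None:
            self._iter = self._make_iter()

    def deactivate(self) -> None:
        self._active = False

    @abstractmethod
    def _make_iter(self) -> Iterator:
        ...

    def __iter__(self):
        return self

    def __next__(self):
        if not self._active:
            return None
        try:
            return next(self._iter)
        except StopIteration:
            return None


def next_sample(source: DataSource):
    """Next sample in timestamp order, or None when deactivated/exhausted."""
    return next(source)


def _numeric(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based numbering
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ParseError(f"{path}:{line}: malformed row")
    return out


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")


class SpikeCSVSource(DataSource):
    """Columns: ``timestamp,electrode_group_id,mark_0..mark_{D-1}``."""

    def __init__(self, path: str | Path):
        super().__init__()
        self.path = Path(path)

    def _make_iter(self) -> Iterator[SpikeEvent]:
        df = pd.read_csv(self.path)
        _require_columns(df, ["timestamp", "electrode_group_id", "mark_0"], self.path)
        df = _numeric(df, self.path)
        mark_cols = sorted(
            (c for c in df.columns if c.startswith("mark_")),
            key=lambda c: int(c.split("_")[1]),
        )
        ts = df["timestamp"].to_numpy(np.int64)
        gid = df["electrode_group_id"].to_numpy(np.int64)
        unknown = set(np.unique(gid)) - self._groups
        if unknown:
            raise ConfigurationError(
                f"{self.path}: spikes from unregistered electrode groups "
                f"{sorted(unknown)}"
            )
        marks = df[mark_cols].to_numpy(float)
        order = np.argsort(ts, kind="stable")
        return (
            SpikeEvent(int(ts[i]), int(gid[i]), mark=marks[i]) for i in order
        )


class LFPCSVSource(DataSource):
    """Long-format columns ``timestamp,group_id,value``; rows sharing a
    timestamp are combined into one multi-group :class:`LFPSample`."""

    def __init__(self, path: str | Path):
        super().__init__()
        self.path = Path(path)

    def _make_iter(self) -> Iterator[LFPSample]:
        df = pd.read_csv(self.path)
        _require_columns(df, ["timestamp", "group_id", "value"], self.path)
        df = _numeric(df, self.path)
        gid = df["group_id"].to_numpy(np.int64)
        unknown = set(np.unique(gid)) - self._groups
        if unknown:
            raise ConfigurationError(
                f"{self.path}: LFP from unregistered electrode groups "
                f"{sorted(unknown)}"
            )
        wide = df.pivot_table(
            index="timestamp", columns="group_id", values="value", sort=True
        )
        gids = [int(g) for g in wide.columns]
        ts = wide.index.to_numpy(np.int64)
        vals = wide.to_numpy(float)
        return (
            LFPSample(int(ts[i]), gids, vals[i]) for i in range(len(ts))
        )


class PositionCSVSource(DataSource):
    """Columns: ``timestamp,segment,norm_pos,x,y,x2,y2``."""

    def __init__(self, path: str | Path):
        super().__init__()
        self.path = Path(path)

    @property
    def needs_groups(self) -> bool:
        return False

    def _make_iter(self) -> Iterator[PositionSample]:
        df = pd.read_csv(self.path)
        cols = ["timestamp", "segment", "norm_pos", "x", "y", "x2", "y2"]
        _require_columns(df, cols, self.path)
        df = _numeric(df, self.path)
        arr = df[cols].to_numpy(float)
        order = np.argsort(arr[:, 0], kind="stable")
        return (
            PositionSample(
                int(a[0]), int(a[1]), float(a[2]), *map(float, a[3:7])
            )
            for a in arr[order]
        )


def write_session_hdf5(
    path: str | Path,
    spikes: pd.DataFrame | None = None,
    lfp: pd.DataFrame | None = None,
    position: pd.DataFrame | None = None,
) -> None:
    """Write the CSV-dialect DataFrames as HDF5 datasets per stream."""
    with h5py.File(path, "w") as f:
        if spikes is not None:
            g = f.create_group("spikes")
            g.create_dataset("timestamp", data=spikes["timestamp"].to_numpy(np.int64))
            g.create_dataset(
                "electrode_group_id",
                data=spikes["electrode_group_id"].to_numpy(np.int64),
            )
            mark_cols = sorted(
                (c for c in spikes.columns if c.startswith("mark_")),
                key=lambda c: int(c.split("_")[1]),
            )
            g.create_dataset("marks", data=spikes[mark_cols].to_numpy(float))
        if lfp is not None:
            g = f.create_group("lfp")
            for col in ("timestamp", "group_id"):
                g.create_dataset(col, data=lfp[col].to_numpy(np.int64))
            g.create_dataset("value", data=lfp["value"].to_numpy(float))
        if position is not None:
            g = f.create_group("position")
            for col in ("timestamp", "segment"):
                g.create_dataset(col, data=position[col].to_numpy(np.int64))
            for col in ("norm_pos", "x", "y", "x2", "y2"):
                g.create_dataset(col, data=position[col].to_numpy(float))


def _h5_frame(path: Path, group: str, int_cols: list[str], float_cols: list[str]):
    with h5py.File(path, "r") as f:
        if group not in f:
            raise ParseError(f"{path}: missing HDF5 group '{group}'")
        g = f[group]
        data = {c: np.asarray(g[c], np.int64) for c in int_cols}
        data.update({c: np.asarray(g[c], float) for c in float_cols})
        marks = np.asarray(g["marks"], float) if "marks" in g else None
    return data, marks


class SpikeHDF5Source(DataSource):
    def __init__(self, path: str | Path):
        super().__init__()
        self.path = Path(path)

    def _make_iter(self) -> Iterator[SpikeEvent]:
        data, marks = _h5_frame(
            self.path, "spikes", ["timestamp", "electrode_group_id"], []
        )
        ts, gid = data["timestamp"], data["electrode_group_id"]
        unknown = set(np.unique(gid)) - self._groups
        if unknown:
            raise ConfigurationError(
                f"{self.path}: spikes from unregistered electrode groups "
                f"{sorted(unknown)}"
            )
        order = np.argsort(ts, kind="stable")
        return (
            SpikeEvent(int(ts[i]), int(gid[i]), mark=marks[i]) for i in order
        )


class LFPHDF5Source(DataSource):
    def __init__(self, path: str | Path):
        super().__init__()
        self.path = Path(path)

    def _make_iter(self) -> Iterator[LFPSample]:
        data, _ = _h5_frame(self.path, "lfp", ["timestamp", "group_id"], ["value"])
        df = pd.DataFrame(data)
        unknown = set(df["group_id"].unique()) - self._groups
        if unknown:
            raise ConfigurationError(
                f"{self.path}: LFP from unregistered electrode groups "
                f"{sorted(unknown)}"
            )
        wide = df.pivot_table(
            index="timestamp", columns="group_id", values="value", sort=True
        )
        gids = [int(g) for g in wide.columns]
        ts = wide.index.to_numpy(np.int64)
        vals = wide.to_numpy(float)
        return (LFPSample(int(ts[i]), gids, vals[i]) for i in range(len(ts)))


class PositionHDF5Source(DataSource):
    def __init__(self, path: str | Path):
        super().__init__()
        self.path = Path(path)

    @property
    def needs_groups(self) -> bool:
        return False

    def _make_iter(self) -> Iterator[PositionSample]:
        data, _ = _h5_frame(
            self.path,
            "position",
            ["timestamp", "segment"],
            ["norm_pos", "x", "y", "x2", "y2"],
        )
        ts = data["timestamp"]
        order = np.argsort(ts, kind="stable")
        return (
            PositionSample(
                int(ts[i]),
                int(data["segment"][i]),
                float(data["norm_pos"][i]),
                float(data["x"][i]),
                float(data["y"][i]),
                float(data["x2"][i]),
                float(data["y2"][i]),
            )
            for i in order
        )


def merge_streams(*sources: DataSource):
    """Yield samples from all sources in global timestamp order.

    Ties at equal ticks: LFP, then position, then spikes; stable within
    each type.  Sources must already be activated.
    """
    seq = itertools.count()

    def keyed(src):
        while True:
            s = next(src)
            if s is None:
                return
            yield (s.timestamp, _TYPE_RANK[type(s)], next(seq)), s

    merged = heapq.merge(*(keyed(s) for s in sources), key=lambda kv: kv[0])
    for _, sample in merged:
        yield sample
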