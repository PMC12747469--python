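"""Per-electrode-group clusterless encoding model.

During the learning phase no model fitting happens: every accepted spike's
mark vector m (typically per-channel peak amplitudes) is simply stored
together with the position bin x where it occurred.  After learning, the
joint density p(x, m) is estimated lazily for each decoding-time mark by a
Gaussian product kernel in mark space: each stored mark m_o gets weight

    w_o = (1 / (sigma * sqrt(2*pi))) * exp(-a_o^2 / (2 sigma^2)),
    a_o^2 = sum_d (m_{o,d} - m_d)^2,

and p(x, m) is the weighted histogram of the stored position bins divided
by the number of stored marks.  The two intensity functions follow:

    jmi(x)    = mu * p(x, m) / pi(x)      (joint mark intensity, spikes/s)
    ground(x) = mu * p(x)    / pi(x)      (ground process intensity)

where pi(x) is the occupancy (normalized distribution of positions visited
during encoding, lightly smoothed), p(x) the normalized histogram of stored
spike positions, and mu the group's mean firing rate (stored spikes divided
by encoding movement time).  A small additive floor regularizes pi before
division.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = ["EncodingModel", "IntensityResult"]

_SQRT_2PI = float(np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class IntensityResult:
    """Joint mark intensity and ground process intensity over bins."""

    jmi: np.ndarray
    ground: np.ndarray


class FrozenModelError(RuntimeError):
    pass


class EncodingModel:
    """Stored-sample encoding model for one electrode group.

    Parameters
    ----------
    group_id : electrode group identifier.
    n_bins : number of linearized position bins.
    n_mark_dims : mark dimensionality D (e.g. 4 for tetrode peak amplitudes).
    sigma : Gaussian kernel bandwidth in mark units (ADC amplitude).
    occupancy_smoothing_bins : sd of the Gaussian smoother applied to the
        occupancy histogram, in bins.
    occupancy_floor : additive floor applied to pi(x) before division.
    """

    def __init__(
        self,
        group_id: int,
        n_bins: int,
        n_mark_dims: int,
        sigma: float = 20.0,
        occupancy_smoothing_bins: float = 1.0,
        occupancy_floor: float = 1e-12,
    ):
        if sigma <= 0:
            raise ValueError("kernel bandwidth sigma must be positive")
        if n_mark_dims < 1:
            raise ValueError("mark dimensionality must be >= 1")
        self.group_id = int(group_id)
        self.n_bins = int(n_bins)
        self.n_mark_dims = int(n_mark_dims)
        self.sigma = float(sigma)
        self.occupancy_smoothing_bins = float(occupancy_smoothing_bins)
        self.occupancy_floor = float(occupancy_floor)
        self.frozen = False
        self._marks: list[np.ndarray] = []
        self._bins: list[int] = []
        self._occ_counts = np.zeros(n_bins)
        self.encoding_time_s: float = 0.0
        # finalized arrays (valid when _cache_n == stored count)
        self._marks_arr = np.empty((0, n_mark_dims))
        self._bins_arr = np.empty(0, dtype=np.int64)
        self._cache_n = 0
        self._final = None  # (occupancy, floored occupancy)
        self._ground_cache = None

    # ------------------------------------------------------------------ learn
    @property
    def n_stored(self) -> int:
        return len(self._bins)

    def add_spike(self, mark, position_bin: int) -> None:
        """Store one (mark, position-bin) pair. Model must not be frozen."""
        if self.frozen:
            raise FrozenModelError("cannot add spikes to a frozen model")
        mark = np.asarray(mark, float)
        if mark.shape != (self.n_mark_dims,):
            raise ValueError(
                f"mark has shape {mark.shape}, expected ({self.n_mark_dims},)"
            )
        if not 0 <= position_bin < self.n_bins:
            raise ValueError(f"position bin {position_bin} out of range")
        self._marks.append(mark)
        self._bins.append(int(position_bin))
        self._final = None

    def add_occupancy(self, position_bin: int, dwell_s: float) -> None:
        """Accumulate occupancy: the animal spent ``dwell_s`` in this bin."""
        if self.frozen:
            raise FrozenModelError("cannot add occupancy to a frozen model")
        self._occ_counts[position_bin] += dwell_s
        self.encoding_time_s += dwell_s
        self._final = None

    def freeze(self) -> "EncodingModel":
        """Finalize the stored set; idempotent. Empty models cannot freeze."""
        if self.n_stored == 0:
            raise ValueError("cannot freeze a model with no stored spikes")
        if not self.frozen:
            self._materialize()
            self._finalize()
            self.frozen = True
        return self

    # ------------------------------------------------------------ finalization
    def _materialize(self) -> None:
        if self._cache_n != self.n_stored:
            self._marks_arr = np.asarray(self._marks, float).reshape(
                self.n_stored, self.n_mark_dims
            )
            self._bins_arr = np.asarray(self._bins, dtype=np.int64)
            self._cache_n = self.n_stored

    def _finalize(self) -> None:
        """Finalize the occupancy-dependent quantities (pi and its floor)."""
        if self._final is not None:
            return
        self._materialize()
        occ = self._occ_counts.copy()
        if occ.sum() <= 0:
            raise ValueError("all-zero occupancy: no encoding positions seen")
        if self.occupancy_smoothing_bins > 0:
            occ = gaussian_filter1d(
                occ, self.occupancy_smoothing_bins, mode="constant"
            )
        occupancy = occ / occ.sum()
        pi_reg = occupancy + self.occupancy_floor
        self._final = (occupancy, pi_reg)

    @property
    def occupancy(self) -> np.ndarray:
        self._finalize()
        return self._final[0]

    @property
    def ground_dist(self) -> np.ndarray:
        """Normalized histogram of stored spike positions, p_i(x)."""
        if self.n_stored == 0:
            raise ValueError("model has no stored spikes")
        if self._ground_cache is None or len(self._ground_cache[1]) != self.n_stored:
            self._materialize()
            g = np.bincount(self._bins_arr, minlength=self.n_bins).astype(float)
            self._ground_cache = (g / g.sum(), self._bins_arr)
        return self._ground_cache[0]

    @property
    def mean_rate(self) -> float:
        if self.encoding_time_s > 0:
            return self.n_stored / self.encoding_time_s
        return float(self.n_stored)  # standalone use: rate scale free

    # ------------------------------------------------------------------ query
    def kernel_weights(self, query_mark) -> np.ndarray:
        """Gaussian kernel weight of every stored mark for a query mark."""
        if self.n_stored == 0:
            raise ValueError("model has no stored spikes")
        q = np.asarray(query_mark, float)
        if q.shape != (self.n_mark_dims,):
            raise ValueError(
                f"query mark has shape {q.shape}, expected ({self.n_mark_dims},)"
            )
        self._materialize()
        diff = self._marks_arr - q
        a2 = np.einsum("ij,ij->i", diff, diff)
        return np.exp(-a2 / (2.0 * self.sigma**2)) / (self.sigma * _SQRT_2PI)

    def joint_mark_density(self, query_mark) -> np.ndarray:
        """Estimate p(x, m) at the query mark: weighted histogram over bins."""
        w = self.kernel_weights(query_mark)
        hist = np.bincount(self._bins_arr, weights=w, minlength=self.n_bins)
        return hist / self.n_stored

    def intensities(self, query_mark) -> IntensityResult:
        """Joint mark intensity and ground process intensity at a mark."""
        self._finalize()
        _, pi_reg = self._final
        mu = self.mean_rate
        jmi = mu * self.joint_mark_density(query_mark) / pi_reg
        ground = mu * self.ground_dist / pi_reg
        return IntensityResult(jmi=jmi, ground=ground)

    def ground_intensity(self) -> np.ndarray:
        """Ground process intensity (spikes/s) over bins; mark-independent."""
        self._finalize()
        _, pi_reg = self._final
        return self.mean_rate * self.ground_dist / pi_reg

    # ------------------------------------------------------------ persistence
    def to_hdf5(self, path: str | Path, group: str | None = None) -> None:
        self._materialize()
        with h5py.File(path, "a") as f:
            name = group or f"encoding_model/group_{self.group_id}"
            if name in f:
                del f[name]
            g = f.create_group(name)
            g.attrs.update(
                group_id=self.group_id,
                n_bins=self.n_bins,
                n_mark_dims=self.n_mark_dims,
                sigma=self.sigma,
                occupancy_smoothing_bins=self.occupancy_smoothing_bins,
                occupancy_floor=self.occupancy_floor,
                frozen=self.frozen,
                encoding_time_s=self.encoding_time_s,
            )
            g.create_dataset("marks", data=self._marks_arr)
            g.create_dataset("bins", data=self._bins_arr)
            g.create_dataset("occupancy_counts", data=self._occ_counts)

    @classmethod
    def from_hdf5(cls, path: str | Path, group: str) -> "EncodingModel":
        with h5py.File(path, "r") as f:
            g = f[group]
            model = cls(
                int(g.attrs["group_id"]),
                int(g.attrs["n_bins"]),
                int(g.attrs["n_mark_dims"]),
                sigma=float(g.attrs["sigma"]),
                occupancy_smoothing_bins=float(g.attrs["occupancy_smoothing_bins"]),
                occupancy_floor=float(g.attrs["occupancy_floor"]),
            )
            marks = np.asarray(g["marks"], float)
            bins = np.asarray(g["bins"], np.int64)
            model._marks = list(marks)
            model._bins = [int(b) for b in bins]
            model._occ_counts = np.asarray(g["occupancy_counts"], float)
            model.encoding_time_s = float(g.attrs["encoding_time_s"])
            if bool(g.attrs["frozen"]):
                model.freeze()
        return model
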