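"""Recursive Bayesian state-space update over linearized position bins.

Each decoder step k covers a half-open time window of width dt, shifted
``dt_delay`` behind the wall-clock trigger time to let spikes arrive and
have their joint mark intensity estimated:

    window(t_curr) = (t_curr - dt_delay - dt,  t_curr - dt_delay]

The clusterless likelihood for the spikes in that window is a product over
electrode groups i and over spikes j within each group,

    L(x) = prod_i [ prod_j jmi_i(x, m_j) * dt ] * exp(-ground_i(x) * dt),

with a group contributing only its no-spike factor exp(-ground_i(x) * dt)
when it emitted nothing in the window.  The product is accumulated in log
space and exponentiated after max-subtraction, since raw products underflow
for many electrode groups.  The one-step prior comes from a row-stochastic
transition model (uniform, identity, or Gaussian random walk), and the
posterior is prior x likelihood, renormalized.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DecoderConfig",
    "TransitionModel",
    "PosteriorState",
    "bin_window",
    "likelihood",
    "predict",
    "update",
]

logger = logging.getLogger(__name__)


class TransitionModel:
    """Row-stochastic movement prior p(x_k | x_{k-1}) on the bin grid.

    kinds: ``uniform`` (non-informative, the configuration used for
    closed-loop detection), ``identity`` (frozen state), ``random_walk``
    (discretized Gaussian step with sd ``sd_bins``).
    """

    KINDS = ("uniform", "identity", "random_walk")

    def __init__(self, kind: str, n_bins: int, sd_bins: float = 1.0):
        if kind not in self.KINDS:
            raise ValueError(f"unknown transition kind {kind!r}")
        self.kind = kind
        self.n_bins = int(n_bins)
        self.sd_bins = float(sd_bins)
        self._matrix: np.ndarray | None = None

    @property
    def matrix(self) -> np.ndarray:
        if self._matrix is None:
            n = self.n_bins
            if self.kind == "uniform":
                m = np.full((n, n), 1.0 / n)
            elif self.kind == "identity":
                m = np.eye(n)
            else:
                idx = np.arange(n)
                d2 = (idx[:, None] - idx[None, :]) ** 2
                m = np.exp(-d2 / (2.0 * self.sd_bins**2))
                m /= m.sum(axis=1, keepdims=True)
            self._matrix = m
        return self._matrix


@dataclass(frozen=True)
class DecoderConfig:
    """Time-bin geometry and transition model of the decoder."""

    dt_ms: float = 6.0
    dt_delay_ms: float = 30.0
    n_bins: int = 41
    transition: TransitionModel | None = None

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ValueError("dt must be positive")
        if self.dt_delay_ms < 0:
            raise ValueError("dt_delay must be non-negative")
        if self.transition is None:
            object.__setattr__(
                self, "transition", TransitionModel("uniform", self.n_bins)
            )

    @property
    def dt_s(self) -> float:
        """Bin width in seconds; the Delta multiplying intensities."""
        return self.dt_ms / 1000.0


@dataclass
class PosteriorState:
    """Posterior over bins for one time bin, plus its raw evidence."""

    posterior: np.ndarray
    likelihood: np.ndarray
    bin_timestamps: tuple[float, float]  # (left, right], window bounds
    spike_count: int = 0

    def map_bin(self) -> int:
        return int(np.argmax(self.posterior))


def bin_window(t_curr: float, config: DecoderConfig) -> tuple[float, float]:
    """Half-open spike-collection window (lower, upper] for a step at t_curr.

    Units of ``t_curr`` must match ``dt_ms``/``dt_delay_ms`` (ms here; the
    session loop converts clock ticks before calling).
    """
    upper = t_curr - config.dt_delay_ms
    return upper - config.dt_ms, upper


def likelihood(
    group_results: Mapping[int, tuple[np.ndarray, Sequence[np.ndarray]]],
    config: DecoderConfig,
) -> np.ndarray:
    """Per-bin clusterless likelihood for one time bin.

    ``group_results`` maps each active electrode group to
    ``(ground_intensity_vector, [jmi_vector_per_spike])``.  Returned vector
    is the log-space product exponentiated after max-subtraction, so it is
    scaled to max 1 (the posterior is scale invariant); all zeros only if
    every bin has zero evidence.
    """
    dt = config.dt_s
    log_l = np.zeros(config.n_bins)
    with np.errstate(divide="ignore"):
        for ground, jmis in group_results.values():
            ground = np.asarray(ground, float)
            if np.any(ground < 0):
                raise ValueError("negative ground process intensity")
            log_l -= ground * dt
            for jmi in jmis:
                jmi = np.asarray(jmi, float)
                if np.any(jmi < 0):
                    raise ValueError("negative joint mark intensity")
                log_l += np.log(jmi * dt)
    m = log_l.max()
    if not np.isfinite(m):
        return np.zeros(config.n_bins)
    return np.exp(log_l - m)


def predict(prev_posterior: np.ndarray, transition: TransitionModel) -> np.ndarray:
    """One-step prediction p(x_k) = sum p(x_k | x_{k-1}) p(x_{k-1} | data)."""
    prev = np.asarray(prev_posterior, float)
    m = transition.matrix
    rowsums = m.sum(axis=1)
    if np.any(np.abs(rowsums - 1.0) > 1e-12):
        raise ValueError("transition rows must sum to 1")
    prior = m.T @ prev
    return prior / prior.sum()


def update(
    prior: np.ndarray,
    like: np.ndarray,
    bin_timestamps: tuple[float, float] = (0.0, 0.0),
    spike_count: int = 0,
) -> PosteriorState:
    """Posterior ~ prior * likelihood, renormalized.

    Degenerate all-zero evidence falls back to the prior with a warning.
    """
    prior = np.asarray(prior, float)
    like = np.asarray(like, float)
    post = prior * like
    total = post.sum()
    if total <= 0:
        warnings.warn("all-zero posterior product; falling back to prior")
        post = prior.copy()
        like = np.ones_like(prior)
        total = post.sum()
    return PosteriorState(
        posterior=post / total,
        likelihood=like,
        bin_timestamps=tuple(bin_timestamps),
        spike_count=spike_count,
    )
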