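"""Memoryless Bayesian population decoding of position.

Given per-unit rate maps lambda_i(b) on a common spatial grid and spike
counts n_i observed in a window of length tau, the posterior under a
Poisson likelihood and a uniform spatial prior is

    P(b) propto prod_i lambda_i(b)^{n_i} * exp(-tau * sum_i lambda_i(b)),

computed in log space and normalised.  Rates are floored at a small
epsilon so bins where a firing unit's map is exactly zero do not produce
-inf log-likelihoods.  Windows with zero spikes are flagged rather than
filled with a uniform posterior: a uniform frame would corrupt the
step-distance criteria used by trajectory analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .maps import RateMap


@dataclass
class EncodingModel:
    """Per-unit rates on a common flattened grid, floored at ``epsilon``."""

    rates: np.ndarray          # (n_units, n_bins) Hz, >= epsilon
    bin_centers: np.ndarray    # (n_bins, 2) cm
    grid_shape: tuple[int, int]
    bin_size: float
    epsilon: float = 0.01
    unit_ids: np.ndarray = field(default=None)  # original session unit indices

    def __post_init__(self) -> None:
        self.rates = np.maximum(np.asarray(self.rates, dtype=float),
                                self.epsilon)
        self.log_rates = np.log(self.rates)
        self.sum_rates = self.rates.sum(axis=0)
        if self.unit_ids is None:
            self.unit_ids = np.arange(self.rates.shape[0])

    @property
    def n_units(self) -> int:
        return self.rates.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]

    @classmethod
    def from_rate_maps(cls, rate_maps: list[RateMap],
                       unit_ids: np.ndarray | None = None,
                       epsilon: float = 0.01) -> "EncodingModel":
        """Stack place-cell rate maps; NaN (unvisited) bins become 0 before
        flooring."""
        if not rate_maps:
            raise ValueError("need at least one rate map")
        grid = rate_maps[0].shape
        rates = np.vstack([np.nan_to_num(m.rate, nan=0.0).ravel()
                           for m in rate_maps])
        return cls(rates=rates, bin_centers=rate_maps[0].bin_centers(),
                   grid_shape=grid, bin_size=rate_maps[0].bin_size,
                   epsilon=epsilon,
                   unit_ids=(np.arange(len(rate_maps))
                             if unit_ids is None else np.asarray(unit_ids)))


@dataclass
class PosteriorSeq:
    """Per-window posteriors over spatial bins.

    posteriors: (n_windows, n_bins); rows of NaN where undefined
    defined:    (n_windows,) bool — False for zero-spike (skipped) windows
    """

    windows: np.ndarray        # (n_windows, 2) start/end times (or phases)
    posteriors: np.ndarray
    spike_counts: np.ndarray   # (n_windows,) totals
    defined: np.ndarray

    def __len__(self) -> int:
        return len(self.windows)


def decode_window(counts: np.ndarray, tau: float, model: EncodingModel
                  ) -> np.ndarray:
    """Posterior over bins for one window of spike counts.

    Returns a vector of NaN (flagged undefined) if the likelihood
    underflows to zero everywhere.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    logp = counts @ model.log_rates - tau * model.sum_rates
    logp -= logp.max()
    p = np.exp(logp)
    z = p.sum()
    if not np.isfinite(z) or z <= 0:
        return np.full(model.n_bins, np.nan)
    return p / z


def decode_counts_matrix(counts: np.ndarray, tau: float,
                         model: EncodingModel) -> np.ndarray:
    """Vectorised :func:`decode_window` for a (n_windows, n_units) count
    matrix; rows normalised independently."""
    logp = counts @ model.log_rates - tau * model.sum_rates
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=1, keepdims=True)
    return p


def window_bounds(start: float, end: float, length: float, step: float
                  ) -> np.ndarray:
    """Sliding half-open windows [s, s+length) fully inside [start, end]."""
    n = int(np.floor((end - start - length) / step)) + 1
    if n < 1:
        return np.empty((0, 2))
    s = start + np.arange(n) * step
    return np.column_stack([s, s + length])


def count_spikes_in_windows(spikes: list[np.ndarray],
                            windows: np.ndarray) -> np.ndarray:
    """(n_windows, n_units) spike counts over half-open windows."""
    n_w = len(windows)
    out = np.zeros((n_w, len(spikes)))
    for u, st in enumerate(spikes):
        out[:, u] = (np.searchsorted(st, windows[:, 1])
                     - np.searchsorted(st, windows[:, 0]))
    return out


def decode_segment(spikes: list[np.ndarray], start: float, end: float,
                   model: EncodingModel, window: float = 0.02,
                   step: float = 0.005) -> PosteriorSeq:
    """Sliding-window decoding of a time segment (default 20 ms windows
    advanced in 5 ms steps).  Zero-spike windows are flagged undefined."""
    wins = window_bounds(start, end, window, step)
    counts = count_spikes_in_windows(spikes, wins)
    totals = counts.sum(axis=1)
    post = np.full((len(wins), model.n_bins), np.nan)
    defined = totals > 0
    if defined.any():
        post[defined] = decode_counts_matrix(counts[defined], window, model)
    return PosteriorSeq(windows=wins, posteriors=post,
                        spike_counts=totals, defined=defined)


def posterior_mean_xy(posterior: np.ndarray, model: EncodingModel
                      ) -> np.ndarray:
    """Posterior-weighted mean position [cm]."""
    return np.asarray(posterior) @ model.bin_centers


def decoding_error(posterior: np.ndarray, true_xy: np.ndarray,
                   model: EncodingModel) -> float:
    """Euclidean distance from the posterior-weighted mean to the true
    position [cm]; NaN for flagged posteriors."""
    if not np.all(np.isfinite(posterior)):
        return np.nan
    est = posterior_mean_xy(posterior, model)
    return float(np.hypot(*(est - np.asarray(true_xy))))


def max_posterior(posterior: np.ndarray) -> float:
    """Maximum posterior entry (precision of the spatial representation)."""
    return float(np.nanmax(posterior))
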