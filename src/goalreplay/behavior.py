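"""Behavioural quantification: velocity, path length, latency, well
partitions/crossings, Learning/Retrieval phase windows, and significance
matrices over window definitions."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import ranksums

from .core import ArenaSpec, SessionData


@dataclass(frozen=True)
class PhaseWindows:
    """Inclusive 1-based trial ranges bracketing memory acquisition
    (Learning) and stable use (Retrieval)."""

    learning: tuple[int, int] = (1, 4)
    retrieval: tuple[int, int] = (8, 11)

    def __post_init__(self) -> None:
        l0, l1 = self.learning
        r0, r1 = self.retrieval
        if l1 >= r0:
            raise ValueError("learning window must precede retrieval window")

    def learning_trials(self) -> np.ndarray:
        return np.arange(self.learning[0], self.learning[1] + 1)

    def retrieval_trials(self) -> np.ndarray:
        return np.arange(self.retrieval[0], self.retrieval[1] + 1)


class WellPartition:
    """Nearest-well partition of the arena: each location belongs to the
    well it is closest to, boundaries equidistant between adjacent wells.
    Exact ties break toward the lower well index."""

    def __init__(self, arena: ArenaSpec):
        self.arena = arena
        self.wells = arena.well_positions

    def assign(self, xy: np.ndarray) -> np.ndarray:
        """Well index for each (x, y) row; ties -> lower index (argmin)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        d2 = ((xy[:, None, :] - self.wells[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    def bin_labels(self, bin_centers: np.ndarray) -> np.ndarray:
        """Well assignment of decoding-grid bin centres (n_bins,)."""
        return self.assign(bin_centers)


def compute_velocity(position: pd.DataFrame, smoothing_sd: float = 0.1
                     ) -> np.ndarray:
    """Per-sample speed [cm/s] from Gaussian-smoothed position.

    ``smoothing_sd`` is in seconds (default 0.1 s, enough to suppress
    video-rate jitter without blunting movement onsets).
    """
    t = position["t"].to_numpy()
    if len(t) < 2:
        raise ValueError("need at least 2 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    dt = np.median(np.diff(t))
    sd_samples = max(smoothing_sd / dt, 1e-9)
    x = gaussian_filter1d(position["x"].to_numpy(), sd_samples)
    y = gaussian_filter1d(position["y"].to_numpy(), sd_samples)
    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    return np.hypot(vx, vy)


def path_length(position: pd.DataFrame,
                interval: tuple[float, float] | None = None) -> float:
    """Sum of Euclidean step lengths between consecutive samples [cm]."""
    t = position["t"].to_numpy()
    if interval is not None:
        m = (t >= interval[0]) & (t < interval[1])
        position = position.loc[m]
    if len(position) < 2:
        if len(position) == 0:
            warnings.warn("empty interval in path_length; returning 0")
        return 0.0
    dx = np.diff(position["x"].to_numpy())
    dy = np.diff(position["y"].to_numpy())
    return float(np.hypot(dx, dy).sum())


def latency(trial) -> float:
    """Trial duration [s]."""
    if trial.end_time < trial.start_time:
        raise ValueError("trial end before start")
    return float(trial.end_time - trial.start_time)


def well_crossings(position: pd.DataFrame, partition: WellPartition,
                   interval: tuple[float, float] | None = None
                   ) -> np.ndarray:
    """Per-well count of entries within the interval.

    An entry is a transition of the nearest-well assignment from a
    different well; the initial well is not counted.
    """
    t = position["t"].to_numpy()
    if interval is not None:
        m = (t >= interval[0]) & (t < interval[1])
        position = position.loc[m]
    counts = np.zeros(partition.arena.n_wells, dtype=int)
    if len(position) < 2:
        return counts
    lab = partition.assign(position[["x", "y"]].to_numpy())
    changed = np.nonzero(np.diff(lab) != 0)[0] + 1
    np.add.at(counts, lab[changed], 1)
    return counts


_METRICS = ("path_length", "latency", "mean_velocity")


def per_trial_metric_table(session: SessionData, metric: str,
                           active_speed: float = 10.0) -> pd.DataFrame:
    """Per-trial behavioural metric split by segment type.

    Columns: trial, segment, value.  ``mean_velocity`` is restricted to
    active-movement samples (speed > ``active_speed`` cm/s); a trial with
    no qualifying samples gets NaN (flagged, never silently 0).
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; one of {_METRICS}")
    speed = compute_velocity(session.position)
    t = session.position["t"].to_numpy()
    rows = []
    for tr in session.schedule:
        if metric == "path_length":
            val = path_length(session.position, (tr.start_time, tr.end_time))
        elif metric == "latency":
            val = latency(tr)
        else:
            m = (t >= tr.start_time) & (t < tr.end_time) & (speed > active_speed)
            val = float(speed[m].mean()) if m.any() else np.nan
        rows.append({"trial": tr.index, "segment": tr.segment, "value": val})
    return pd.DataFrame(rows)


def significance_matrix(per_trial: pd.DataFrame,
                        window_grid: list[tuple[tuple[int, int], tuple[int, int]]]
                        | None = None,
                        max_trial: int = 15) -> pd.DataFrame:
    """p-value matrix over (learning window, retrieval window) choices.

    ``per_trial`` must have columns (trial, value); trials are 0-based
    internally but windows are 1-based inclusive, matching the phase
    convention.  Each entry is the two-sided rank-sum p comparing the
    pooled per-trial values between the two windows.  Overlapping windows
    are marked invalid (NaN).

    The default grid slides 4-trial windows across starts (learning
    starting at trials 1-4, retrieval at 5 onward), the same window
    length as the default phase definitions.
    """
    if window_grid is None:
        window_grid = [((ls, ls + 3), (rs, rs + 3))
                       for ls in range(1, 5)
                       for rs in range(5, max_trial - 2)
                       if ls + 3 < rs]
    vals = per_trial.set_index("trial")["value"]
    rows = []
    for (lw, rw) in window_grid:
        if lw[1] >= rw[0]:
            p = np.nan
        else:
            a = vals.loc[[t for t in range(lw[0] - 1, lw[1])
                          if t in vals.index]].dropna().to_numpy()
            b = vals.loc[[t for t in range(rw[0] - 1, rw[1])
                          if t in vals.index]].dropna().to_numpy()
            p = ranksums(a, b).pvalue if len(a) and len(b) else np.nan
        rows.append({"learning": f"{lw[0]}-{lw[1]}",
                     "retrieval": f"{rw[0]}-{rw[1]}", "p": p})
    return pd.DataFrame(rows)
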