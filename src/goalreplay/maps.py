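"""Place-cell rate maps, field extraction, spatial correlation and
information, goal-relative cell classes, and population rate by well.

Maps are occupancy-normalised smoothed 2D firing histograms on a 2 cm
grid (Gaussian SD 4 cm), built from movement epochs (> 5 cm/s).  A place
field is a 4-connected component of bins above 20% of the unit's maximum
with at least 20 bins; a unit is a place cell iff it is excitatory and
its peak rate exceeds 1 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, label

from .behavior import WellPartition, compute_velocity
from .core import ArenaSpec, SessionData


@dataclass
class RateMap:
    rate: np.ndarray          # (ny, nx) smoothed rate [Hz]; NaN = unvisited
    occupancy: np.ndarray     # (ny, nx) smoothed time [s]
    raw_occupancy: np.ndarray
    bin_size: float = 2.0
    smoothing_sd: float = 4.0
    speed_threshold: float = 5.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.rate.shape

    @property
    def n_bins(self) -> int:
        return self.rate.size

    def bin_centers(self) -> np.ndarray:
        """(n_bins, 2) array of (x, y) bin-centre coordinates [cm],
        flattened row-major (y outer, x inner)."""
        ny, nx = self.rate.shape
        xs = (np.arange(nx) + 0.5) * self.bin_size
        ys = (np.arange(ny) + 0.5) * self.bin_size
        xx, yy = np.meshgrid(xs, ys)
        return np.column_stack([xx.ravel(), yy.ravel()])

    @property
    def peak_rate(self) -> float:
        r = self.rate[np.isfinite(self.rate)]
        return float(r.max()) if r.size else 0.0

    @property
    def peak_bin(self) -> tuple[int, int]:
        r = np.where(np.isfinite(self.rate), self.rate, -np.inf)
        return tuple(np.unravel_index(np.argmax(r), r.shape))

    def peak_xy(self) -> np.ndarray:
        iy, ix = self.peak_bin
        return np.array([(ix + 0.5) * self.bin_size, (iy + 0.5) * self.bin_size])


@dataclass
class PlaceField:
    mask: np.ndarray = field(repr=False)   # (ny, nx) boolean
    peak_rate: float = 0.0
    peak_bin: tuple[int, int] = (0, 0)
    area: int = 0


def build_rate_map(spikes: np.ndarray, position: pd.DataFrame,
                   arena: ArenaSpec, bin_size: float = 2.0,
                   smoothing_sd: float = 4.0, speed_threshold: float = 5.0,
                   interval_mask: np.ndarray | None = None,
                   speed: np.ndarray | None = None,
                   min_occupancy: float = 0.005) -> RateMap:
    """Occupancy-normalised smoothed rate map.

    Spike-count and occupancy histograms are smoothed separately with the
    same Gaussian kernel and then divided (the smoothing is therefore
    consistent between numerator and denominator).  ``interval_mask``
    optionally restricts position samples (e.g. to one segment type);
    spikes are restricted to the same samples' time support.

    Bins with less than ``min_occupancy`` seconds of smoothed occupancy
    are flagged NaN (unvisited) rather than given a rate: the count /
    occupancy ratio is numerically unstable where the denominator is a
    smoothing tail.
    """
    t = position["t"].to_numpy()
    x = position["x"].to_numpy()
    y = position["y"].to_numpy()
    if speed is None:
        speed = compute_velocity(position)
    sel = speed > speed_threshold
    if interval_mask is not None:
        sel = sel & interval_mask
    if not sel.any():
        raise ValueError("no qualifying movement samples for rate map")

    n = int(np.ceil(arena.side_length / bin_size))
    edges = np.arange(n + 1) * bin_size
    dt = np.median(np.diff(t))

    occ, _, _ = np.histogram2d(y[sel], x[sel], bins=[edges, edges])
    occ *= dt

    # spike positions by interpolation; keep spikes within selected samples
    spikes = np.asarray(spikes, dtype=float)
    idx = np.searchsorted(t, spikes)
    idx = np.clip(idx, 0, len(t) - 1)
    ok = sel[idx]
    sx = np.interp(spikes[ok], t, x)
    sy = np.interp(spikes[ok], t, y)
    cnt, _, _ = np.histogram2d(sy, sx, bins=[edges, edges])

    sd_bins = smoothing_sd / bin_size
    occ_s = gaussian_filter(occ, sd_bins)
    cnt_s = gaussian_filter(cnt, sd_bins)
    visited = occ_s > max(min_occupancy, 1e-9)
    rate = np.full_like(occ, np.nan)
    rate[visited] = cnt_s[visited] / occ_s[visited]
    return RateMap(rate=rate, occupancy=occ_s, raw_occupancy=occ,
                   bin_size=bin_size, smoothing_sd=smoothing_sd,
                   speed_threshold=speed_threshold)


def extract_fields(rmap: RateMap, threshold_frac: float = 0.2,
                   min_bins: int = 20, min_peak: float = 1.0
                   ) -> list[PlaceField]:
    """Connected components (4-connectivity) above ``threshold_frac`` of
    the map maximum, at least ``min_bins`` bins; empty when the peak rate
    does not exceed ``min_peak``.  Fields sorted by peak rate descending,
    ties toward the lower flattened peak-bin index."""
    peak = rmap.peak_rate
    if peak <= min_peak:
        return []
    above = np.where(np.isfinite(rmap.rate), rmap.rate, -np.inf) > threshold_frac * peak
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    lab, n = label(above, structure=structure)
    fields = []
    for k in range(1, n + 1):
        mask = lab == k
        if mask.sum() < min_bins:
            continue
        r = np.where(mask & np.isfinite(rmap.rate), rmap.rate, -np.inf)
        pb = np.unravel_index(np.argmax(r), r.shape)
        fields.append(PlaceField(mask=mask, peak_rate=float(r[pb]),
                                 peak_bin=(int(pb[0]), int(pb[1])),
                                 area=int(mask.sum())))
    fields.sort(key=lambda f: (-f.peak_rate,
                               f.peak_bin[0] * rmap.shape[1] + f.peak_bin[1]))
    return fields


def is_place_cell(rmap: RateMap, unit_class: str, min_peak: float = 1.0) -> bool:
    return unit_class == "excitatory" and rmap.peak_rate > min_peak


def spatial_correlation(map_a: RateMap, map_b: RateMap) -> float:
    """Pearson correlation of smoothed rates over the union of bins where
    either map is non-zero.  NaN when fewer than 2 qualifying bins."""
    a, b = map_a.rate, map_b.rate
    if a.shape != b.shape:
        raise ValueError("maps must share the grid")
    fin = np.isfinite(a) & np.isfinite(b)
    support = fin & ((a > 0) | (b > 0))
    if support.sum() < 2:
        return np.nan
    av, bv = a[support], b[support]
    if av.std() == 0 or bv.std() == 0:
        return np.nan
    return float(np.corrcoef(av, bv)[0, 1])


def spatial_information(rmap: RateMap) -> float:
    """Skaggs spatial information [bits/spike]:
    I = sum_b p_b (lam_b / lam_bar) log2(lam_b / lam_bar), with p_b the
    occupancy fraction and lam_bar the occupancy-weighted mean rate.
    Zero-occupancy bins are excluded.  NaN when the mean rate is zero."""
    occ = rmap.occupancy
    rate = rmap.rate
    ok = np.isfinite(rate) & (occ > 0)
    if not ok.any() or occ[ok].sum() <= 0:
        return np.nan
    p = occ[ok] / occ[ok].sum()
    lam = rate[ok]
    lam_bar = float((p * lam).sum())
    if lam_bar <= 0:
        return np.nan
    ratio = lam / lam_bar
    nz = ratio > 0
    return float((p[nz] * ratio[nz] * np.log2(ratio[nz])).sum())


def classify_goal_cells(peak_xy: np.ndarray, arena: ArenaSpec) -> str:
    """Label a place cell by which well its maximal-rate bin is nearest:
    'goal', 'goal_adjacent' (the up-to-8 grid neighbours of the goal), or
    'goal_distant'."""
    wells = arena.well_positions
    d = np.hypot(*(wells - np.asarray(peak_xy)).T)
    nearest = int(d.argmin())
    if nearest == arena.goal_well:
        return "goal"
    if nearest in arena.goal_adjacent_wells():
        return "goal_adjacent"
    return "goal_distant"


def population_rate_by_well(session: SessionData, partition: WellPartition,
                            speed_threshold: float = 5.0) -> pd.DataFrame:
    """Summed excitatory firing rate per well partition during movement.

    For each partition: total excitatory spikes emitted while the rat was
    in the partition moving > threshold, divided by that time.  Unvisited
    partitions get NaN.
    """
    pos = session.position
    t = pos["t"].to_numpy()
    dt = np.median(np.diff(t))
    speed = compute_velocity(pos)
    moving = speed > speed_threshold
    lab = partition.assign(pos[["x", "y"]].to_numpy())

    time_per = np.zeros(partition.arena.n_wells)
    np.add.at(time_per, lab[moving], dt)

    spikes_per = np.zeros(partition.arena.n_wells)
    for u, st in enumerate(session.spikes):
        if session.unit_class[u] != "excitatory":
            continue
        idx = np.clip(np.searchsorted(t, st), 0, len(t) - 1)
        ok = moving[idx]
        np.add.at(spikes_per, lab[idx[ok]], 1.0)

    rate = np.where(time_per > 0, spikes_per / np.maximum(time_per, 1e-12),
                    np.nan)
    return pd.DataFrame({"well": np.arange(partition.arena.n_wells),
                         "rate_hz": rate, "time_s": time_per,
                         "spikes": spikes_per})


def infield_rate_per_trial(spikes: np.ndarray, fields: list[PlaceField],
                           rmap: RateMap, session: SessionData,
                           speed_threshold: float = 5.0) -> pd.DataFrame:
    """Per-trial firing rate inside the unit's maximal field.

    Uses only the field with the maximal firing rate.  Trials with zero
    qualifying in-field time get NaN (flagged; excluded from means).
    """
    if not fields:
        raise ValueError("unit has no place fields")
    mask = fields[0].mask
    pos = session.position
    t = pos["t"].to_numpy()
    dt = np.median(np.diff(t))
    speed = compute_velocity(pos)
    bx = np.clip((pos["x"].to_numpy() / rmap.bin_size).astype(int), 0,
                 rmap.shape[1] - 1)
    by = np.clip((pos["y"].to_numpy() / rmap.bin_size).astype(int), 0,
                 rmap.shape[0] - 1)
    infield = mask[by, bx] & (speed > speed_threshold)

    sp = np.asarray(spikes, dtype=float)
    sp_idx = np.clip(np.searchsorted(t, sp), 0, len(t) - 1)
    sp_in = infield[sp_idx]

    rows = []
    for tr in session.schedule:
        m = (t >= tr.start_time) & (t < tr.end_time) & infield
        tin = m.sum() * dt
        ms = (sp >= tr.start_time) & (sp < tr.end_time) & sp_in
        rows.append({"trial": tr.index, "segment": tr.segment,
                     "value": (ms.sum() / tin) if tin > 0 else np.nan})
    return pd.DataFrame(rows)
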