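"""Ripple decoding, replay significance, and goal-representation statistics.

Each ripple is decoded in 20 ms windows advanced in 5 ms steps; the
sequence of posterior-weighted mean locations forms the decoded path.  A
ripple encodes a trajectory when some run of >= 15 consecutive defined
frames moves < 30 cm between frames yet covers > 40 cm start-to-end.
Trajectory-encoding events are tested against two Monte-Carlo nulls —
shuffled cell identity and independent 2D circular rotation of every
unit's place field — with p = (n + 1)/(r + 1); events with p < 0.05 for
both shuffles are replays.

For goal-representation analyses the posterior mass of the well partition
the rat currently occupies is zeroed in every frame (not renormalised),
so all statistics are about nonlocal content.  A ripple encodes the Goal
when the per-frame mean posterior mass inside a 30 cm x 30 cm box around
the Goal well exceeds 0.075.

The shuffle nulls are computed in float32 batches (one BLAS call per
shuffle block) — posteriors only enter binary trajectory criteria, which
are insensitive to single-precision error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import WellPartition
from .decoder import (EncodingModel, PosteriorSeq, count_spikes_in_windows,
                      decode_counts_matrix, window_bounds)
from .lfp import RippleEvent


@dataclass
class DecodedPath:
    positions: np.ndarray      # (n_frames, 2) weighted-mean xy [cm]
    defined: np.ndarray        # (n_frames,) bool
    windows: np.ndarray        # (n_frames, 2) frame boundaries [s]

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class ReplayResult:
    ripple: RippleEvent
    trial: int = -1
    criteria_pass: bool = False
    p_cell_shuffle: float = np.nan
    p_field_rotation: float = np.nan
    is_replay: bool = False
    degenerate: bool = False
    goal_encoding: bool = False
    heading_to_goal_deg: float = np.nan
    seq: PosteriorSeq | None = field(default=None, repr=False)
    path: DecodedPath | None = field(default=None, repr=False)
    well_representation: np.ndarray | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# decoding + trajectory criteria
# ---------------------------------------------------------------------------

def decode_ripple(ripple: RippleEvent, spikes: list[np.ndarray],
                  model: EncodingModel, window: float = 0.02,
                  step: float = 0.005) -> tuple[PosteriorSeq, DecodedPath]:
    """Sliding-window decode of one ripple and its weighted-mean path."""
    wins = window_bounds(ripple.start, ripple.end, window, step)
    counts = count_spikes_in_windows(spikes, wins)
    totals = counts.sum(axis=1)
    defined = totals > 0
    post = np.full((len(wins), model.n_bins), np.nan)
    if defined.any():
        post[defined] = decode_counts_matrix(counts[defined], window, model)
    xy = np.full((len(wins), 2), np.nan)
    xy[defined] = post[defined] @ model.bin_centers
    seq = PosteriorSeq(windows=wins, posteriors=post, spike_counts=totals,
                       defined=defined)
    return seq, DecodedPath(positions=xy, defined=defined, windows=wins)


def trajectory_criteria(path: DecodedPath | np.ndarray,
                        defined: np.ndarray | None = None,
                        min_frames: int = 15, max_step: float = 30.0,
                        min_net: float = 40.0) -> bool:
    """True iff some run of >= min_frames consecutive defined frames has
    every inter-frame step < max_step and start-to-end displacement >
    min_net."""
    if isinstance(path, DecodedPath):
        xy, ok = path.positions, path.defined
    else:
        xy = np.asarray(path, dtype=float)
        ok = np.ones(len(xy), bool) if defined is None else np.asarray(defined)
    n = len(xy)
    if n < min_frames:
        return False
    steps = np.hypot(*(np.diff(xy, axis=0)).T)
    # valid link between frame i and i+1
    link = ok[:-1] & ok[1:] & (steps < max_step)
    # maximal runs of linked frames
    i = 0
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < n - 1 and link[j]:
            j += 1
        run = np.arange(i, j + 1)
        if len(run) >= min_frames:
            sub = xy[run]
            L = len(run)
            for a in range(L - min_frames + 1):
                for b in range(a + min_frames - 1, L):
                    if np.hypot(*(sub[b] - sub[a])) > min_net:
                        return True
        i = j + 1
    return False


def monte_carlo_p(n_pass: int, r: int) -> float:
    """Monte-Carlo p-value (n + 1)/(r + 1)."""
    if r < 1 or not 0 <= n_pass <= r:
        raise ValueError("require 0 <= n_pass <= r and r >= 1")
    return (n_pass + 1) / (r + 1)


# ---------------------------------------------------------------------------
# shuffles
# ---------------------------------------------------------------------------

def shuffle_cell_identity(counts: np.ndarray, rng: np.random.Generator
                          ) -> np.ndarray:
    """Permute unit labels uniformly among units participating in the
    event; spike times (hence the count matrix rows) are unchanged."""
    part = np.nonzero(counts.sum(axis=0) > 0)[0]
    if len(part) < 2:
        raise ValueError("cell-identity shuffle needs >= 2 participating units")
    out = counts.copy()
    out[:, part[rng.permutation(len(part))]] = counts[:, part]
    return out


def shuffle_field_rotation(model: EncodingModel, rng: np.random.Generator
                           ) -> EncodingModel:
    """Independently rotate each unit's map by uniform circular shifts in
    x and y (toroidal wrap); total rate mass per map is conserved."""
    ny, nx = model.grid_shape
    rates = np.empty_like(model.rates)
    for u in range(model.n_units):
        dy, dx = int(rng.integers(ny)), int(rng.integers(nx))
        rates[u] = np.roll(model.rates[u].reshape(ny, nx),
                           (dy, dx), axis=(0, 1)).ravel()
    return EncodingModel(rates=rates, bin_centers=model.bin_centers,
                         grid_shape=model.grid_shape,
                         bin_size=model.bin_size, epsilon=model.epsilon,
                         unit_ids=model.unit_ids)


class RotationShuffleSet:
    """Pre-drawn field-rotation null shared across the events of a session.

    Holds r independent offset draws for every unit plus, per draw, the
    summed rotated rate over all units (the Poisson normaliser).  The
    per-event Monte-Carlo then only gathers the rotated log-rates of the
    event's participating units.
    """

    def __init__(self, model: EncodingModel, r: int, rng: np.random.Generator):
        ny, nx = model.grid_shape
        self.model = model
        self.r = r
        self.offsets = np.column_stack([rng.integers(0, ny, (r, model.n_units, 1)),
                                        rng.integers(0, nx, (r, model.n_units, 1))]
                                       ).reshape(r, model.n_units, 2)
        self.sum_rates = np.empty((r, model.n_bins), dtype=np.float32)
        for s in range(r):
            acc = np.zeros((ny, nx), dtype=np.float32)
            for u in range(model.n_units):
                dy, dx = self.offsets[s, u]
                acc += np.roll(model.rates[u].reshape(ny, nx).astype(np.float32),
                               (dy, dx), axis=(0, 1))
            self.sum_rates[s] = acc.ravel()

    def log_rates_block(self, units: np.ndarray, shuffles: np.ndarray
                        ) -> np.ndarray:
        """(len(shuffles), len(units), n_bins) float32 rotated log-rates."""
        ny, nx = self.model.grid_shape
        out = np.empty((len(shuffles), len(units), self.model.n_bins),
                       dtype=np.float32)
        logr = self.model.log_rates.astype(np.float32)
        for i, s in enumerate(shuffles):
            for j, u in enumerate(units):
                dy, dx = self.offsets[s, u]
                out[i, j] = np.roll(logr[u].reshape(ny, nx),
                                    (dy, dx), axis=(0, 1)).ravel()
        return out


def _paths_from_log_posteriors(logp: np.ndarray, bin_xy: np.ndarray
                               ) -> np.ndarray:
    """Softmax rows of (n, n_bins) log-posteriors -> weighted-mean xy."""
    logp = logp - logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=1, keepdims=True)
    return p @ bin_xy


def _shuffle_paths_cell_identity(counts: np.ndarray, model: EncodingModel,
                                 tau: float, r: int,
                                 rng: np.random.Generator,
                                 block: int = 100) -> np.ndarray:
    """(r, n_frames, 2) decoded paths under the cell-identity null."""
    part = np.nonzero(counts.sum(axis=0) > 0)[0]
    n_f = counts.shape[0]
    C = counts[:, part].astype(np.float32)
    logr = model.log_rates[part].astype(np.float32)
    base = (-tau * model.sum_rates).astype(np.float32)
    bin_xy = model.bin_centers.astype(np.float32)
    out = np.empty((r, n_f, 2), dtype=np.float32)
    for b0 in range(0, r, block):
        b1 = min(b0 + block, r)
        nb = b1 - b0
        # horizontally stacked permuted log-rate blocks: one BLAS call
        L = np.empty((len(part), nb * model.n_bins), dtype=np.float32)
        for i in range(nb):
            perm = rng.permutation(len(part))
            L[:, i * model.n_bins:(i + 1) * model.n_bins] = logr[perm]
        logp = C @ L                                  # (n_f, nb * n_bins)
        logp = logp.reshape(n_f, nb, model.n_bins).transpose(1, 0, 2)
        logp += base[None, None, :]
        flat = logp.reshape(nb * n_f, model.n_bins)
        out[b0:b1] = _paths_from_log_posteriors(flat, bin_xy).reshape(nb, n_f, 2)
    return out


def _shuffle_paths_rotation(counts: np.ndarray, model: EncodingModel,
                            tau: float, rot: RotationShuffleSet,
                            block: int = 100) -> np.ndarray:
    """(r, n_frames, 2) decoded paths under the field-rotation null."""
    part = np.nonzero(counts.sum(axis=0) > 0)[0]
    n_f = counts.shape[0]
    C = counts[:, part].astype(np.float32)
    bin_xy = model.bin_centers.astype(np.float32)
    out = np.empty((rot.r, n_f, 2), dtype=np.float32)
    for b0 in range(0, rot.r, block):
        shuffles = np.arange(b0, min(b0 + block, rot.r))
        L = rot.log_rates_block(part, shuffles)       # (nb, nP, B)
        nb = len(shuffles)
        Lflat = L.transpose(1, 0, 2).reshape(len(part), nb * model.n_bins)
        logp = C @ Lflat
        logp = logp.reshape(n_f, nb, model.n_bins).transpose(1, 0, 2)
        logp -= tau * rot.sum_rates[shuffles][:, None, :]
        flat = logp.reshape(nb * n_f, model.n_bins)
        out[b0:b0 + nb] = _paths_from_log_posteriors(flat, bin_xy
                                                     ).reshape(nb, n_f, 2)
    return out


def classify_replay(ripple: RippleEvent, spikes: list[np.ndarray],
                    model: EncodingModel, r_shuffles: int = 1000,
                    alpha: float = 0.05, seed: int = 0,
                    rotation_set: RotationShuffleSet | None = None,
                    window: float = 0.02, step: float = 0.005,
                    min_frames: int = 15, max_step: float = 30.0,
                    min_net: float = 40.0) -> ReplayResult:
    """Full significance pipeline for one ripple.

    Shuffled events are re-decoded with the same frame boundaries and the
    same zero-spike policy as the real event and scored by the same binary
    trajectory criteria; p = (n + 1)/(r + 1) per shuffle method; the event
    is a replay iff it passes the criteria and both p < alpha.
    """
    seq, path = decode_ripple(ripple, spikes, model, window, step)
    res = ReplayResult(ripple=ripple, seq=seq, path=path)
    res.criteria_pass = trajectory_criteria(path, min_frames=min_frames,
                                            max_step=max_step, min_net=min_net)
    if not res.criteria_pass:
        return res

    counts = count_spikes_in_windows(spikes, seq.windows)
    part = np.nonzero(counts.sum(axis=0) > 0)[0]
    if len(part) < 2:
        res.degenerate = True
        return res

    rng = np.random.default_rng(seed)
    defined = seq.defined

    def crit(paths: np.ndarray) -> int:
        return sum(trajectory_criteria(p, defined, min_frames, max_step,
                                       min_net) for p in paths)

    paths_id = _shuffle_paths_cell_identity(counts, model, window,
                                            r_shuffles, rng)
    res.p_cell_shuffle = monte_carlo_p(crit(paths_id), r_shuffles)

    if rotation_set is None or rotation_set.r != r_shuffles:
        rotation_set = RotationShuffleSet(model, r_shuffles, rng)
    paths_rot = _shuffle_paths_rotation(counts, model, window, rotation_set)
    res.p_field_rotation = monte_carlo_p(crit(paths_rot), r_shuffles)

    res.is_replay = (res.p_cell_shuffle < alpha
                     and res.p_field_rotation < alpha)
    return res


# ---------------------------------------------------------------------------
# nonlocal goal representation
# ---------------------------------------------------------------------------

def mask_local_well(seq: PosteriorSeq, bin_well_labels: np.ndarray,
                    local_well: int, renormalize: bool = False
                    ) -> np.ndarray:
    """Zero the posterior mass of the rat's current well partition in
    every frame.  By default frames are NOT renormalised — the masked
    mass is simply removed, so all downstream statistics are shares of
    the original posterior."""
    frames = np.array(seq.posteriors, copy=True)
    frames[:, bin_well_labels == local_well] = 0.0
    if renormalize:
        tot = np.nansum(frames, axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        frames = frames / tot
    return frames


def goal_box_mass(frames: np.ndarray, model: EncodingModel,
                  goal_xy: np.ndarray, box: float = 30.0) -> np.ndarray:
    """Per-frame posterior mass inside the goal-centred box."""
    c = model.bin_centers
    inbox = ((np.abs(c[:, 0] - goal_xy[0]) <= box / 2)
             & (np.abs(c[:, 1] - goal_xy[1]) <= box / 2))
    return np.nansum(frames[:, inbox], axis=1)


def goal_encoding(frames: np.ndarray, model: EncodingModel,
                  goal_xy: np.ndarray, defined: np.ndarray,
                  box: float = 30.0, threshold: float = 0.075,
                  mode: str = "mean") -> bool:
    """Does this event's nonlocal content represent the Goal well?

    mode="mean" (default): per-frame mean box mass over defined frames is
    compared with the threshold.  mode="sum": the raw sum over frames is
    used instead.
    """
    mass = goal_box_mass(frames, model, goal_xy, box)[defined]
    if len(mass) == 0:
        return False
    stat = mass.mean() if mode == "mean" else mass.sum()
    return bool(stat > threshold)


def well_representation(frames: np.ndarray, defined: np.ndarray,
                        bin_well_labels: np.ndarray, n_wells: int,
                        local_well: int | None = None) -> np.ndarray:
    """Per-well posterior mass averaged over defined frames; the local
    (masked) well is reported as NaN."""
    f = frames[defined]
    rep = np.zeros(n_wells)
    if len(f):
        mean_frame = np.nanmean(f, axis=0)
        np.add.at(rep, bin_well_labels, mean_frame)
    if local_well is not None:
        rep[local_well] = np.nan
    return rep


# ---------------------------------------------------------------------------
# Grubbs outlier statistics and trial-resolved representation
# ---------------------------------------------------------------------------

def grubbs_test(values: np.ndarray, alpha: float = 0.05,
                two_sided: bool = False) -> tuple[int | None, float]:
    """Single-outlier Grubbs test.

    Default is the one-sided maximum variant (G = (max - mean)/sd): the
    question asked of well-representation vectors is directional
    (elevated representation).  Returns (outlier index or None, G).
    Zero-variance input returns (None, 0).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 3:
        raise ValueError("Grubbs test needs >= 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        return None, 0.0
    mean = x.mean()
    if two_sided:
        idx = int(np.argmax(np.abs(x - mean)))
        G = float(np.abs(x[idx] - mean) / sd)
        t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    else:
        idx = int(np.argmax(x))
        G = float((x[idx] - mean) / sd)
        t = stats.t.ppf(1 - alpha / n, n - 2)
    g_crit = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
    if G > g_crit:
        # map back to the original (possibly NaN-containing) vector
        orig = np.nonzero(np.isfinite(values))[0]
        return int(orig[idx]), G
    return None, G


def running_goal_representation(event_reps: np.ndarray,
                                event_trials: np.ndarray, goal_well: int,
                                n_trials: int = 30, window: int = 4,
                                alpha: float = 0.05) -> pd.DataFrame:
    """Four-trial running mean of per-well representation with Grubbs
    outlier flags for the Goal well.

    event_reps: (n_events, n_wells) per-event well representation (local
    well NaN); event_trials: 0-based trial of each event.  Windows are
    [w, w+window) over 0-based trials.  A window with no events is a
    flagged gap (NaN row).
    """
    n_wells = event_reps.shape[1] if len(event_reps) else 0
    rows = []
    for w in range(0, n_trials - window + 1):
        m = (event_trials >= w) & (event_trials < w + window)
        if not m.any():
            rows.append({"window_start": w, "n_events": 0,
                         "goal_rep": np.nan, "other_mean": np.nan,
                         "goal_flag": False})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_rep = np.nanmean(event_reps[m], axis=0)
        flag = False
        if np.isfinite(mean_rep).sum() >= 3:
            idx, _ = grubbs_test(mean_rep, alpha=alpha)
            flag = idx == goal_well
        others = np.delete(mean_rep, goal_well)
        rows.append({"window_start": w, "n_events": int(m.sum()),
                     "goal_rep": mean_rep[goal_well] if n_wells else np.nan,
                     "other_mean": float(np.nanmean(others)) if len(others) else np.nan,
                     "goal_flag": bool(flag)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# heading and behavioural consequences of ripples
# ---------------------------------------------------------------------------

def heading_before_ripple(position: pd.DataFrame, speed: np.ndarray,
                          ripple_start: float, lookback: float = 0.5,
                          speed_min: float = 5.0) -> float:
    """Heading [deg] over the last ``lookback`` s of > speed_min movement
    preceding the ripple; NaN when no preceding movement exists."""
    t = position["t"].to_numpy()
    m = (t < ripple_start) & (speed > speed_min)
    if not m.any():
        return np.nan
    t_last = t[m][-1]
    sel = (t >= t_last - lookback) & (t <= t_last)
    if sel.sum() < 2:
        return np.nan
    x = position["x"].to_numpy()[sel]
    y = position["y"].to_numpy()[sel]
    return float(np.degrees(np.arctan2(y[-1] - y[0], x[-1] - x[0])))


def heading_split(headings_deg: np.ndarray, bearings_deg: np.ndarray,
                  half_angle: float = 45.0
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition events into toward-goal (|heading - bearing| <= half_angle),
    elsewhere, and unassigned (undefined heading) boolean masks."""
    h = np.asarray(headings_deg, dtype=float)
    b = np.asarray(bearings_deg, dtype=float)
    diff = np.abs((h - b + 180.0) % 360.0 - 180.0)
    unassigned = ~np.isfinite(h)
    toward = np.isfinite(h) & (diff <= half_angle)
    away = np.isfinite(h) & ~toward
    return toward, away, unassigned


def latency_after_ripple(ripples: list[RippleEvent],
                         goal_flags: np.ndarray, position: pd.DataFrame,
                         partition: WellPartition, goal_well: int
                         ) -> pd.DataFrame:
    """Per-ripple latency from ripple end to the next entry into the Goal
    well partition, for ripples occurring while the rat is outside the
    Goal partition.  Ripples with no subsequent goal entry are censored
    (latency NaN, censored=True).
    """
    t = position["t"].to_numpy()
    lab = partition.assign(position[["x", "y"]].to_numpy())
    at_goal = lab == goal_well
    rows = []
    for rip, flag in zip(ripples, goal_flags):
        i = np.searchsorted(t, rip.peak)
        i = min(i, len(t) - 1)
        if at_goal[i]:
            continue          # rat at the goal: excluded
        j = np.searchsorted(t, rip.end)
        nxt = np.nonzero(at_goal[j:])[0]
        if len(nxt):
            rows.append({"ripple_peak": rip.peak, "goal_encoding": bool(flag),
                         "latency": float(t[j + nxt[0]] - rip.end),
                         "censored": False})
        else:
            rows.append({"ripple_peak": rip.peak, "goal_encoding": bool(flag),
                         "latency": np.nan, "censored": True})
    return pd.DataFrame(rows)
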