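"""Theta-sequence analysis.

Each theta cycle (delimited at 60 deg, trough = 0 deg) is decoded either
in a single window spanning the whole cycle (accuracy/precision analyses)
or in 24 sliding phase windows of 60 deg advanced in 15 deg steps.  The
per-window posteriors are centred on the rat, rotated so a reference
direction (movement heading or rat-to-goal bearing) points along +x, and
collapsed over the perpendicular axis, giving a phase x relative-position
matrix.  The forward-encoding portion of the cycle (window centres in the
wrapped interval [240, 420) deg) carries the sequence's look-ahead sweep;
its weighted best-fit slope [cm/cycle] and the four-quadrant mass score
quantify sequence quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .decoder import EncodingModel, PosteriorSeq, decode_counts_matrix
from .lfp import ThetaCycle

N_PHASE_WINDOWS = 24
PHASE_STEP = 15.0
PHASE_WINDOW = 60.0
CYCLE_START_DEG = 60.0
FORWARD_START_DEG = 240.0


@dataclass
class RelativeMatrix:
    """Phase-window x relative-position posterior mass.

    matrix[k, j] is the posterior mass of phase window k at relative
    position rel_x[j] cm along the reference direction (+x = ahead).
    """

    matrix: np.ndarray
    rel_x: np.ndarray            # bin centres [cm]
    phase_centers: np.ndarray    # window-centre phase [deg], in [60, 420)
    reference: str = "movement_direction"
    crosses_boundary: np.ndarray | None = None   # windows wrapping the cycle edge

    @property
    def total_mass(self) -> float:
        return float(np.nansum(self.matrix))


@dataclass
class ThetaSeqScore:
    forward_slope: float     # cm/cycle
    quadrant_score: float
    path_extent: float       # cm


def phase_window_starts() -> np.ndarray:
    """Start phases [deg] of the 24 wrapped 60-deg windows of one cycle."""
    return CYCLE_START_DEG + PHASE_STEP * np.arange(N_PHASE_WINDOWS)


def cycle_spike_phases(cycle: ThetaCycle, spikes: list[np.ndarray],
                       phase_fn) -> tuple[np.ndarray, np.ndarray]:
    """(unit_labels, phases-within-cycle [deg, 0..360)) of all spikes in
    the cycle; phase 0 corresponds to the cycle start (60 deg absolute)."""
    labels, phases = [], []
    p0 = phase_fn(np.asarray([cycle.start]))[0]
    for u, st in enumerate(spikes):
        i0, i1 = np.searchsorted(st, [cycle.start, cycle.end])
        tt = st[i0:i1]
        if len(tt) == 0:
            continue
        ph = (phase_fn(tt) - p0) % 360.0
        labels.append(np.full(len(tt), u))
        phases.append(ph)
    if not labels:
        return np.empty(0, dtype=int), np.empty(0)
    return (np.concatenate(labels).astype(int), np.concatenate(phases))


def phase_window_counts(labels: np.ndarray, phases: np.ndarray,
                        n_units: int) -> np.ndarray:
    """(24, n_units) spike counts per wrapped phase window."""
    counts = np.zeros((N_PHASE_WINDOWS, n_units))
    for k in range(N_PHASE_WINDOWS):
        lo = (PHASE_STEP * k) % 360.0
        hi = (lo + PHASE_WINDOW) % 360.0
        if lo < hi:
            m = (phases >= lo) & (phases < hi)
        else:
            m = (phases >= lo) | (phases < hi)
        if m.any():
            np.add.at(counts[k], labels[m], 1)
    return counts


def decode_cycle_whole(cycle: ThetaCycle, spikes: list[np.ndarray],
                       model: EncodingModel) -> np.ndarray:
    """Single-window posterior over the whole cycle (60 deg to 60 deg).
    Returns NaN vector when the cycle contains no spikes (flagged)."""
    counts = np.array([np.searchsorted(s, cycle.end)
                       - np.searchsorted(s, cycle.start) for s in spikes],
                      dtype=float)
    if counts.sum() == 0:
        return np.full(model.n_bins, np.nan)
    return decode_counts_matrix(counts[None, :], cycle.duration, model)[0]


def decode_cycle_windows(cycle: ThetaCycle, spikes: list[np.ndarray],
                         phase_fn, model: EncodingModel) -> PosteriorSeq:
    """Decode one cycle in 24 wrapped phase windows of 60 deg at 15 deg
    steps.  tau for each window is the window's share of the cycle
    duration (60/360 of a cycle)."""
    labels, phases = cycle_spike_phases(cycle, spikes, phase_fn)
    counts = phase_window_counts(labels, phases, len(spikes))
    tau = cycle.duration * PHASE_WINDOW / 360.0
    totals = counts.sum(axis=1)
    post = np.full((N_PHASE_WINDOWS, model.n_bins), np.nan)
    defined = totals > 0
    if defined.any():
        post[defined] = decode_counts_matrix(counts[defined], tau, model)
    starts = phase_window_starts()
    wins = np.column_stack([starts, starts + PHASE_WINDOW])
    return PosteriorSeq(windows=wins, posteriors=post, spike_counts=totals,
                        defined=defined)


def build_relative_matrix(post_seq: PosteriorSeq, model: EncodingModel,
                          rat_xy: np.ndarray, ref_angle: float,
                          extent: float = 50.0,
                          reference: str = "movement_direction"
                          ) -> RelativeMatrix:
    """Centre each phase window's 2D posterior on the rat, rotate so the
    reference direction is +x, and collapse over the perpendicular axis.

    ref_angle: reference direction [rad].  Sampling uses bilinear
    interpolation on the native grid, which conserves total mass to
    within interpolation tolerance.
    """
    ny, nx = model.grid_shape
    h = model.bin_size
    n_rel = int(round(2 * extent / h))
    rel = (np.arange(n_rel) - n_rel / 2 + 0.5) * h
    u = np.array([np.cos(ref_angle), np.sin(ref_angle)])
    v = np.array([-u[1], u[0]])
    # world coordinates of every (rel_x, rel_y) sample
    rx, ry = np.meshgrid(rel, rel, indexing="ij")     # (n_rel, n_rel)
    wx = rat_xy[0] + rx * u[0] + ry * v[0]
    wy = rat_xy[1] + rx * u[1] + ry * v[1]
    col = wx / h - 0.5
    row = wy / h - 0.5
    coords = np.vstack([row.ravel(), col.ravel()])

    mat = np.zeros((len(post_seq), n_rel))
    for k in range(len(post_seq)):
        if not post_seq.defined[k]:
            continue
        grid = post_seq.posteriors[k].reshape(ny, nx)
        samp = map_coordinates(grid, coords, order=1, mode="constant",
                               cval=0.0).reshape(n_rel, n_rel)
        mat[k] = samp.sum(axis=1)     # collapse perpendicular axis
    centers = phase_window_starts() + PHASE_WINDOW / 2.0
    # wrap centres back into the cycle span [60, 420)
    centers = CYCLE_START_DEG + (centers - CYCLE_START_DEG) % 360.0
    rel_lo = PHASE_STEP * np.arange(N_PHASE_WINDOWS)
    crosses = rel_lo + PHASE_WINDOW > 360.0
    return RelativeMatrix(matrix=mat, rel_x=rel, phase_centers=centers,
                          reference=reference, crosses_boundary=crosses)


def _forward_mask(phase_centers: np.ndarray) -> np.ndarray:
    return (phase_centers >= FORWARD_START_DEG) & (phase_centers < 420.0)


def forward_slope(rm: RelativeMatrix) -> float:
    """Weighted least-squares slope of relative position vs phase over the
    forward-encoding portion, in cm per full cycle.

    Every (window, rel_x) cell contributes a point weighted by its
    posterior mass.  Windows whose span wraps across the cycle boundary
    are excluded: they mix the sawtooth discontinuity of phase precession
    (content jumps from farthest-ahead back to farthest-behind) and
    otherwise bias the fit toward zero.  NaN when fewer than 2 forward
    windows carry mass.
    """
    fwd = _forward_mask(rm.phase_centers)
    if rm.crosses_boundary is not None:
        fwd = fwd & ~rm.crosses_boundary
    sub = rm.matrix[fwd]
    if (sub.sum(axis=1) > 0).sum() < 2:
        return np.nan
    phases = (rm.phase_centers[fwd] - CYCLE_START_DEG) / 360.0   # cycles
    W = sub
    X = np.broadcast_to(phases[:, None], W.shape)
    Y = np.broadcast_to(rm.rel_x[None, :], W.shape)
    wsum = W.sum()
    if wsum <= 0:
        return np.nan
    xm = (W * X).sum() / wsum
    ym = (W * Y).sum() / wsum
    var = (W * (X - xm) ** 2).sum()
    if var <= 0:
        return np.nan
    cov = (W * (X - xm) * (Y - ym)).sum()
    return float(cov / var)


def quadrant_score(rm: RelativeMatrix) -> float:
    """Four-quadrant mass-difference score in [-1, 1].

    Phase axis split at the cycle midpoint, relative-position axis at 0:
    (early,behind) + (late,ahead) - (early,ahead) - (late,behind), over
    total mass.  NaN for zero total mass.
    """
    total = rm.matrix.sum()
    if total <= 0:
        return np.nan
    mid = CYCLE_START_DEG + 180.0
    early = rm.phase_centers < mid
    behind = rm.rel_x < 0
    eb = rm.matrix[np.ix_(early, behind)].sum()
    ea = rm.matrix[np.ix_(early, ~behind)].sum()
    lb = rm.matrix[np.ix_(~early, behind)].sum()
    la = rm.matrix[np.ix_(~early, ~behind)].sum()
    return float((eb + la - ea - lb) / total)


def path_extent(rm: RelativeMatrix) -> float:
    """Span [cm] of the per-window weighted-mean relative position over
    windows with defined mass."""
    w = rm.matrix.sum(axis=1)
    ok = w > 0
    if ok.sum() < 2:
        return np.nan
    means = (rm.matrix[ok] * rm.rel_x[None, :]).sum(axis=1) / w[ok]
    return float(means.max() - means.min())


def score_cycle(cycle: ThetaCycle, spikes: list[np.ndarray], phase_fn,
                model: EncodingModel, rat_xy: np.ndarray, ref_angle: float,
                reference: str = "movement_direction") -> ThetaSeqScore:
    """Decode one cycle and compute slope, quadrant score and extent."""
    seq = decode_cycle_windows(cycle, spikes, phase_fn, model)
    rm = build_relative_matrix(seq, model, rat_xy, ref_angle,
                               reference=reference)
    return ThetaSeqScore(forward_slope=forward_slope(rm),
                         quadrant_score=quadrant_score(rm),
                         path_extent=path_extent(rm))


def subsample_to_reference(cycle: ThetaCycle, spikes: list[np.ndarray],
                           phase_fn, model: EncodingModel,
                           rat_xy: np.ndarray, ref_angle: float,
                           reference_count: float, n_rep: int = 1000,
                           seed: int = 0) -> ThetaSeqScore:
    """Rate-matched control: randomly remove spikes from the cycle down to
    ``reference_count`` (the Learning-phase mean), recompute slope and
    quadrant score per repetition, and average over repetitions.

    If the cycle has fewer spikes than the reference the cycle is scored
    as-is (single repetition).
    """
    labels, phases = cycle_spike_phases(cycle, spikes, phase_fn)
    n = len(labels)
    target = int(round(reference_count))
    rng = np.random.default_rng(seed)
    tau = cycle.duration * PHASE_WINDOW / 360.0
    starts = phase_window_starts()
    wins = np.column_stack([starts, starts + PHASE_WINDOW])

    if n <= target or target < 1:
        reps = 1
    else:
        reps = n_rep
    slopes = np.empty(reps)
    qscores = np.empty(reps)
    extents = np.empty(reps)
    for r in range(reps):
        if n <= target or target < 1:
            keep = np.arange(n)
        else:
            keep = rng.choice(n, size=target, replace=False)
        counts = phase_window_counts(labels[keep], phases[keep], len(spikes))
        totals = counts.sum(axis=1)
        post = np.full((N_PHASE_WINDOWS, model.n_bins), np.nan)
        defined = totals > 0
        if defined.any():
            post[defined] = decode_counts_matrix(counts[defined], tau, model)
        seq = PosteriorSeq(windows=wins, posteriors=post,
                           spike_counts=totals, defined=defined)
        rm = build_relative_matrix(seq, model, rat_xy, ref_angle)
        slopes[r] = forward_slope(rm)
        qscores[r] = quadrant_score(rm)
        extents[r] = path_extent(rm)
    return ThetaSeqScore(forward_slope=float(np.nanmean(slopes)),
                         quadrant_score=float(np.nanmean(qscores)),
                         path_extent=float(np.nanmean(extents)))


def movement_heading(position, times: np.ndarray,
                     smoothing_sd: float = 0.1) -> np.ndarray:
    """Heading angle [rad] of the smoothed velocity at the given times;
    NaN where speed is ~0 (heading undefined)."""
    from scipy.ndimage import gaussian_filter1d

    t = position["t"].to_numpy()
    dt = np.median(np.diff(t))
    sd = smoothing_sd / dt
    vx = np.gradient(gaussian_filter1d(position["x"].to_numpy(), sd), t)
    vy = np.gradient(gaussian_filter1d(position["y"].to_numpy(), sd), t)
    hx = np.interp(times, t, vx)
    hy = np.interp(times, t, vy)
    ang = np.arctan2(hy, hx)
    ang = np.where(np.hypot(hx, hy) < 1e-3, np.nan, ang)
    return ang


def goal_alignment_analysis(cycles: list[ThetaCycle],
                            spikes: list[np.ndarray], phase_fn,
                            model: EncodingModel, position,
                            goal_xy: np.ndarray, radius: float = 25.0,
                            angle_window: tuple[float, float] = (30.0, 180.0)
                            ):
    """Paired movement- vs goal-referenced forward slopes near the goal.

    Restricts to cycles whose midpoint lies within ``radius`` cm of the
    goal and whose movement-to-goal angular difference is inside
    ``angle_window`` (degrees; excludes moving directly at or directly
    away from the goal).  Returns a DataFrame with one row per qualifying
    cycle: (slope_movement, slope_goal).
    """
    import pandas as pd
    import warnings

    rows = []
    mids = np.array([(c.start + c.end) / 2 for c in cycles])
    if len(mids) == 0:
        warnings.warn("no cycles supplied")
        return pd.DataFrame(columns=["slope_movement", "slope_goal"])
    t = position["t"].to_numpy()
    rx = np.interp(mids, t, position["x"].to_numpy())
    ry = np.interp(mids, t, position["y"].to_numpy())
    headings = movement_heading(position, mids)
    for i, c in enumerate(cycles):
        xy = np.array([rx[i], ry[i]])
        d = goal_xy - xy
        dist = np.hypot(*d)
        if dist > radius or not np.isfinite(headings[i]):
            continue
        bearing = np.arctan2(d[1], d[0])
        diff = np.degrees(np.abs(np.angle(np.exp(1j * (headings[i] - bearing)))))
        if not (angle_window[0] < diff < angle_window[1]):
            continue
        seq = decode_cycle_windows(c, spikes, phase_fn, model)
        rm_m = build_relative_matrix(seq, model, xy, headings[i],
                                     reference="movement_direction")
        rm_g = build_relative_matrix(seq, model, xy, bearing,
                                     reference="goal_direction")
        rows.append({"slope_movement": forward_slope(rm_m),
                     "slope_goal": forward_slope(rm_g)})
    if not rows:
        warnings.warn("no qualifying cycles for goal-alignment analysis")
        return pd.DataFrame(columns=["slope_movement", "slope_goal"])
    return pd.DataFrame(rows)
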