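"""Synthetic session generator with known ground truth.

Emulates the statistical structure of a goal-learning open-field session:
a rat alternates between goal-seeking and random-foraging trials in a
2 m x 2 m arena with a 6 x 6 well grid; CA1-like units carry 2D Gaussian
place fields and fire as theta-modulated inhomogeneous Poisson processes
with phase precession; an experience-dependent gain ramps firing and theta
power across the Learning phase and plateaus in Retrieval; immobility
pauses at wells contain ripple events whose spiking content is either a
spatially smooth virtual trajectory (replay-like), spatially incoherent
jumps, or stationary local representation.  Goal-well content begins
appearing in ripples at a configurable trial.

Everything is driven by a single integer seed; subsystems draw from fixed
sub-streams of that seed so each piece can be re-run reproducibly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import ArenaSpec, SessionData, TrialRecord, TrialSchedule, make_arena

RippleContent = Literal["smooth_trajectory", "jump", "stationary_local"]


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class TuningCurves:
    """Per-unit true tuning surfaces: single 2D Gaussian fields for
    excitatory units, spatially uniform rates for inhibitory units."""

    centers: np.ndarray        # (n_units, 2) cm; NaN for inhibitory
    peak_rates: np.ndarray     # (n_units,) Hz
    widths: np.ndarray         # (n_units,) Gaussian SD, cm
    baseline: np.ndarray       # (n_units,) Hz
    unit_class: list[str]

    @property
    def n_units(self) -> int:
        return len(self.peak_rates)

    def rate_at(self, xy: np.ndarray, units: Sequence[int] | None = None
                ) -> np.ndarray:
        """Evaluate true rates at positions ``xy`` (n, 2) -> (n, n_units)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        idx = np.arange(self.n_units) if units is None else np.asarray(units)
        out = np.empty((xy.shape[0], len(idx)))
        for j, u in enumerate(idx):
            if self.unit_class[u] == "inhibitory":
                out[:, j] = self.peak_rates[u]
            else:
                d2 = ((xy - self.centers[u]) ** 2).sum(axis=1)
                out[:, j] = self.baseline[u] + self.peak_rates[u] * np.exp(
                    -d2 / (2 * self.widths[u] ** 2))
        return out


@dataclass
class RippleSpec:
    time: float                    # centre of the event [s]
    duration: float                # [s]
    content: RippleContent
    waypoints: np.ndarray          # (k, 2) virtual locations [cm]
    trial: int
    encodes_goal: bool = False


@dataclass
class GroundTruth:
    tuning: TuningCurves
    theta_freq: float
    rate_gain: np.ndarray          # per-trial multiplicative gain
    theta_amp: np.ndarray          # per-trial theta amplitude [a.u.]
    sweep_speed: float             # phase-precession sweep [cm/cycle]
    ripples: list[RippleSpec]
    goal_emergence_trial: int


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryParams:
    """Behavioural generator knobs.

    Goal-trial tortuosity decays across the Learning phase so goal path
    length and latency improve and then plateau, mirroring acquisition of
    the goal memory.  Random-foraging tortuosity stays high throughout.
    Inter-trial reward-consumption dwells are free parameters (they are
    not constrained by the task design), defaulting to 2.5 s.
    """

    n_trials: int = 30
    sample_rate: float = 60.0          # Hz
    run_speed: float = 25.0            # cm/s
    dwell_duration: float = 2.5        # s of immobility at each reached well
    goal_tortuosity_start: float = 1.2
    goal_tortuosity_end: float = 0.15
    goal_learning_trials: int = 6      # goal trials over which tortuosity decays
    random_tortuosity: float = 0.9
    start_corner: int = 0              # which arena corner the rat starts in


@dataclass
class FieldParams:
    peak_rate_range: tuple[float, float] = (1.0, 30.0)   # Hz
    width_range: tuple[float, float] = (7.0, 12.0)       # Gaussian SD, cm
    baseline_rate: float = 0.1                           # Hz
    inhibitory_rate_range: tuple[float, float] = (10.0, 25.0)
    excitatory_fraction: float = 0.9
    # "stratified" scatters field centres on a jittered grid (statistically
    # uniform but without the large voids of a pure Poisson scatter, which
    # leave stretches of the arena undecodable); "uniform" is iid uniform.
    placement: str = "stratified"


@dataclass
class ThetaParams:
    frequency: float = 8.0             # Hz
    modulation_depth: float = 0.7      # 0..1 multiplicative depth
    sweep_speed: float = 16.0          # cm per theta cycle (phase precession)
    speed_threshold: float = 10.0      # cm/s; precession/theta active above


@dataclass
class GainSchedule:
    """Experience-dependent multiplicative rate gain: ramps across the
    Learning phase, then holds a plateau (non-decreasing then constant)."""

    start: float = 1.0
    plateau: float = 1.6
    ramp_trials: int = 6

    def per_trial(self, n_trials: int) -> np.ndarray:
        g = np.full(n_trials, self.plateau)
        ramp = np.linspace(self.start, self.plateau, self.ramp_trials)
        g[: min(self.ramp_trials, n_trials)] = ramp[:n_trials]
        return g


@dataclass
class RippleGenParams:
    rate_per_dwell: int = 3            # events scheduled per reward dwell
    duration_range: tuple[float, float] = (0.06, 0.12)   # s (jump/stationary)
    # trajectory-encoding events are the longer ripples: a smooth sweep
    # needs >= ~0.1 s to hold 15 consecutive 20 ms/5 ms decoding frames
    smooth_duration_range: tuple[float, float] = (0.10, 0.12)
    # total population firing rate of the replay ensemble along the
    # virtual path [Hz]; per-unit content intensity is the tuning-weighted
    # share of this rate, reflecting the winner-take-most competition of
    # the ripple burst (and guaranteeing decodable content in every frame)
    content_pop_rate: float = 800.0
    # per-unit rate [Hz] at which every excitatory cell fires during the
    # event regardless of its field location: sharp-wave ripples co-activate
    # a broad ensemble beyond the replayed path
    event_background_rate: float = 1.5
    smooth_path_length: float = 80.0   # cm virtual trajectory length
    jump_n_locations: int = 3
    p_goal_content: float = 0.75       # among post-emergence events
    p_smooth: float = 0.45             # content mix pre-emergence
    p_jump: float = 0.45               # remainder is stationary_local
    goal_emergence_trial: int = 7
    carrier_freq: float = 200.0        # Hz, LFP ripple band carrier
    amplitude: float = 8.0             # x band-noise SD, high SNR by default


@dataclass
class SessionConfig:
    arena: ArenaSpec = field(default_factory=make_arena)
    n_units: int | None = None         # None -> draw from [80, 263]
    trajectory: TrajectoryParams = field(default_factory=TrajectoryParams)
    fields: FieldParams = field(default_factory=FieldParams)
    theta: ThetaParams = field(default_factory=ThetaParams)
    gain: GainSchedule = field(default_factory=GainSchedule)
    ripples: RippleGenParams = field(default_factory=RippleGenParams)
    lfp_rate: float = 1250.0           # Hz
    lfp_noise_sd: float = 1.0
    immobility_rate: float = 0.3       # Hz spontaneous rate when immobile


N_UNITS_RANGE = (80, 263)   # observed simultaneous-unit yields per session


def replay_battery_config(n_trials: int = 60) -> "SessionConfig":
    """Session configuration for the high-SNR replay recovery battery.

    A large, well-covered session with strong compressed-timescale ripple
    content: 200 units, 60 trials (dense arena coverage for stable
    encoding maps), sharp fields (6-10 cm SD), hot replay bursts (2000 Hz
    ensemble content rate, ~40 spikes per 20 ms frame, over a broad
    co-active background) and smooth events at the long end of the ripple
    duration range so every event can hold a full 15-frame trajectory.  This is the regime in which the
    significance pipeline's sensitivity and specificity are
    characterised; typical sessions (the defaults) carry weaker, sparser
    content.
    """
    return SessionConfig(
        n_units=200,
        trajectory=TrajectoryParams(n_trials=n_trials),
        fields=FieldParams(width_range=(6.0, 10.0)),
        ripples=RippleGenParams(content_pop_rate=2000.0,
                                event_background_rate=2.5,
                                smooth_duration_range=(0.115, 0.125)),
    )


def _subrng(seed: int, stream: int) -> np.random.Generator:
    """Fixed per-subsystem stream of the session seed."""
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

def _wandering_polyline(start: np.ndarray, target: np.ndarray,
                        tortuosity: float, arena: ArenaSpec,
                        rng: np.random.Generator) -> np.ndarray:
    """Waypoint polyline from start to target; lateral excursions scale
    with tortuosity so path length decreases as tortuosity decreases."""
    d = target - start
    dist = np.hypot(*d)
    n_mid = max(0, int(round(tortuosity * max(2.0, dist / 40.0))))
    pts = [start]
    if n_mid:
        fr = np.sort(rng.uniform(0.1, 0.9, n_mid))
        perp = np.array([-d[1], d[0]]) / max(dist, 1e-9)
        for f in fr:
            lateral = rng.normal(0.0, tortuosity * 35.0)
            p = start + f * d + lateral * perp
            p = np.clip(p, 2.0, arena.side_length - 2.0)
            pts.append(p)
    pts.append(target)
    return np.asarray(pts)


def _sample_polyline(pts: np.ndarray, speed: float, rate: float,
                     t0: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample a polyline at constant speed on the video clock."""
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    duration = total / speed
    n = max(2, int(np.ceil(duration * rate)))
    tt = t0 + np.arange(n) / rate
    s = np.minimum((tt - t0) * speed, total)
    x = np.interp(s, cum, pts[:, 0])
    y = np.interp(s, cum, pts[:, 1])
    return tt, np.column_stack([x, y])


def simulate_trajectory(arena: ArenaSpec, params: TrajectoryParams,
                        seed: int) -> tuple["np.ndarray", TrialSchedule]:
    """Generate the position series and trial schedule for one session.

    Returns (position array with columns t, x, y; TrialSchedule).  Each
    trial is a run to the baited well followed by an immobile reward dwell
    at that well; trials alternate goal_seeking / random_foraging starting
    with goal_seeking.
    """
    rng = _subrng(seed, 0)
    rate = params.sample_rate
    side = arena.side_length
    corners = np.array([[5.0, 5.0], [side - 5, 5.0],
                        [5.0, side - 5], [side - 5, side - 5]])
    pos = corners[params.start_corner % 4].copy()

    wells = arena.well_positions
    goal = arena.goal_well
    recent_random: list[int] = []

    t_chunks: list[np.ndarray] = []
    xy_chunks: list[np.ndarray] = []
    trials: list[TrialRecord] = []
    t_cursor = 0.0
    goal_trial_counter = 0

    for i in range(params.n_trials):
        if i % 2 == 0:
            segment = "goal_seeking"
            target_well = goal
            frac = min(goal_trial_counter / max(params.goal_learning_trials - 1, 1), 1.0)
            tort = (params.goal_tortuosity_start
                    + frac * (params.goal_tortuosity_end - params.goal_tortuosity_start))
            goal_trial_counter += 1
        else:
            segment = "random_foraging"
            candidates = [w for w in range(arena.n_wells)
                          if w != goal and w not in recent_random[-8:]]
            target_well = int(rng.choice(candidates))
            recent_random.append(target_well)
            tort = params.random_tortuosity

        target = wells[target_well]
        pts = _wandering_polyline(pos, target, tort, arena, rng)
        tt, xy = _sample_polyline(pts, params.run_speed, rate, t_cursor)

        # immobile reward dwell: sub-1 cm/s jitter around the well
        n_dwell = int(round(params.dwell_duration * rate))
        td = tt[-1] + (np.arange(1, n_dwell + 1)) / rate
        jit = gaussian_filter1d(rng.normal(0, 0.05, (n_dwell, 2)), 5, axis=0)
        xyd = target + jit

        t_chunks += [tt, td]
        xy_chunks += [xy, xyd]
        t_end = td[-1] + 1.0 / rate
        trials.append(TrialRecord(i, segment, target_well, t_cursor, t_end))
        t_cursor = t_end
        pos = xyd[-1].copy()

    t = np.concatenate(t_chunks)
    xy = np.vstack(xy_chunks)
    xy = np.clip(xy, 0.0, side)
    position = np.column_stack([t, xy])
    return position, TrialSchedule(trials)


# ---------------------------------------------------------------------------
# tuning curves
# ---------------------------------------------------------------------------

def make_tuning_curves(arena: ArenaSpec, n_units: int,
                       params: FieldParams | None = None,
                       seed: int = 0) -> TuningCurves:
    """Draw per-unit ground-truth tuning: uniformly placed single Gaussian
    fields for excitatory units, spatially uniform rates for inhibitory."""
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    params = params or FieldParams()
    rng = _subrng(seed, 1)
    n_exc = int(round(params.excitatory_fraction * n_units))
    classes = ["excitatory"] * n_exc + ["inhibitory"] * (n_units - n_exc)
    centers = np.full((n_units, 2), np.nan)
    if params.placement == "stratified" and n_exc > 0:
        g = int(np.ceil(np.sqrt(n_exc)))
        cell = arena.side_length / g
        xx, yy = np.meshgrid(np.arange(g), np.arange(g))
        pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        pts = pts[rng.permutation(len(pts))[:n_exc]]
        centers[:n_exc] = (pts + rng.uniform(0, 1, (n_exc, 2))) * cell
    else:
        centers[:n_exc] = rng.uniform(0, arena.side_length, (n_exc, 2))
    peaks = np.empty(n_units)
    peaks[:n_exc] = rng.uniform(*params.peak_rate_range, n_exc)
    peaks[n_exc:] = rng.uniform(*params.inhibitory_rate_range, n_units - n_exc)
    widths = np.empty(n_units)
    widths[:n_exc] = rng.uniform(*params.width_range, n_exc)
    widths[n_exc:] = np.inf
    baseline = np.full(n_units, params.baseline_rate)
    baseline[n_exc:] = 0.0
    return TuningCurves(centers, peaks, widths, baseline, classes)


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def theta_phase_deg(times: np.ndarray, freq: float) -> np.ndarray:
    """Reference theta phase in degrees, trough = 0, shared by the spike
    and LFP generators so decoded phase aligns with the LFP convention."""
    return (np.asarray(times) * freq * 360.0) % 360.0


def simulate_spikes(position: np.ndarray, tuning: TuningCurves,
                    theta: ThetaParams, gain_per_trial: np.ndarray,
                    schedule: TrialSchedule, seed: int,
                    immobility_rate: float = 0.3,
                    quiet_windows: list[tuple[float, float]] | None = None,
                    dt: float = 0.001) -> list[np.ndarray]:
    """Inhomogeneous-Poisson spike trains.

    Intensity = tuning(x_eff(t)) * gain(trial(t)) * theta modulation during
    movement; a low spatially uniform rate during immobility.  Phase
    precession shifts each unit's effective sampling position along the
    instantaneous movement direction as a function of theta phase, from
    half a sweep behind (early cycle) to half a sweep ahead (late cycle).

    ``quiet_windows`` (e.g. scheduled ripple windows) suppress the
    spontaneous immobility rate: during a sharp-wave ripple the network
    is dominated by the participating ensemble, whose compressed content
    spiking is added separately.
    """
    if len(position) == 0:
        raise ValueError("empty position series")
    t_pos = position[:, 0]
    t0, t1 = t_pos[0], t_pos[-1]
    tg = np.arange(t0, t1, dt)
    x = np.interp(tg, t_pos, position[:, 1])
    y = np.interp(tg, t_pos, position[:, 2])

    # speed and heading from the video-rate series
    vx = np.gradient(gaussian_filter1d(position[:, 1], 6), t_pos)
    vy = np.gradient(gaussian_filter1d(position[:, 2], 6), t_pos)
    sp = np.hypot(vx, vy)
    speed = np.interp(tg, t_pos, sp)
    hx = np.interp(tg, t_pos, vx)
    hy = np.interp(tg, t_pos, vy)
    hnorm = np.hypot(hx, hy)
    hnorm[hnorm < 1e-9] = 1.0
    hx, hy = hx / hnorm, hy / hnorm

    phase = theta_phase_deg(tg, theta.frequency)
    cyc_frac = ((phase - 60.0) % 360.0) / 360.0      # cycle runs 60 -> 420 deg
    moving = speed > theta.speed_threshold
    # CA1 pyramidal firing is maximal near the theta trough (phase 0)
    mod = 1.0 + theta.modulation_depth * np.cos(np.radians(phase))

    offset = theta.sweep_speed * (cyc_frac - 0.5)
    x_eff = x + np.where(moving, hx * offset, 0.0)
    y_eff = y + np.where(moving, hy * offset, 0.0)

    trial_idx = schedule.trial_of_times(tg)
    gains = np.ones_like(tg)
    ok = trial_idx >= 0
    gains[ok] = gain_per_trial[np.clip(trial_idx[ok], 0, len(gain_per_trial) - 1)]

    immob = np.full_like(tg, immobility_rate)
    if quiet_windows:
        for a, b in quiet_windows:
            immob[(tg >= a) & (tg < b)] = 0.0

    rng = _subrng(seed, 2)
    xy_eff = np.column_stack([x_eff, y_eff])
    spikes: list[np.ndarray] = []
    chunk = 200_000
    for u in range(tuning.n_units):
        lam = np.empty_like(tg)
        for s in range(0, len(tg), chunk):
            sl = slice(s, min(s + chunk, len(tg)))
            lam[sl] = tuning.rate_at(xy_eff[sl], [u])[:, 0]
        lam = np.where(moving, lam * gains * mod, immob)
        counts = rng.poisson(lam * dt)
        nz = np.nonzero(counts)[0]
        reps = counts[nz]
        tt = np.repeat(tg[nz], reps) + rng.uniform(0, dt, int(reps.sum()))
        spikes.append(np.sort(tt))
    return spikes


# ---------------------------------------------------------------------------
# ripple schedule + replay content
# ---------------------------------------------------------------------------

def make_ripple_schedule(schedule: TrialSchedule, position: np.ndarray,
                         arena: ArenaSpec, params: RippleGenParams,
                         seed: int, dwell_duration: float = 2.5
                         ) -> list[RippleSpec]:
    """Place ripple events inside the immobile reward dwell that ends each
    trial and assign virtual content.

    Replay content reactivates the rat's own experience: smooth events
    follow segments of previously travelled paths (goal events follow a
    past approach to the goal well), and jump events teleport between
    previously visited locations.  Goal-well content appears only from
    ``goal_emergence_trial`` (0-based trial index) onward.
    """
    rng = _subrng(seed, 3)
    wells = arena.well_positions
    goal_xy = wells[arena.goal_well]
    # cumulative arc length of the behavioural trajectory
    steps = np.hypot(np.diff(position[:, 1]), np.diff(position[:, 2]))
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    t_samples = position[:, 0]
    goal_arrivals = [tr.end_time - dwell_duration for tr in schedule
                     if tr.segment == "goal_seeking"]
    out: list[RippleSpec] = []
    for tr in schedule:
        dwell_start = tr.end_time - dwell_duration
        n = params.rate_per_dwell
        # evenly spread centres with jitter, kept inside the dwell
        for k in range(n):
            base = dwell_start + (k + 0.5) * dwell_duration / n
            tc = base + rng.uniform(-0.1, 0.1)
            here = _pos_at(position, tc)
            emerged = tr.index >= params.goal_emergence_trial
            wants_goal = emerged and rng.random() < params.p_goal_content
            u = rng.random()
            i_now = int(np.searchsorted(t_samples, tc))
            past = position[:max(i_now, 1), 1:3]
            # a smooth event needs both enough travelled arc and enough
            # spatial extent of experienced territory to replay
            extent = np.hypot(past[:, 0].max() - past[:, 0].min(),
                              past[:, 1].max() - past[:, 1].min())
            enough_history = (arc[min(i_now, len(arc) - 1)]
                              >= 1.2 * params.smooth_path_length
                              and extent >= 60.0)
            if u < params.p_smooth and enough_history:
                content: RippleContent = "smooth_trajectory"
                dur = rng.uniform(*params.smooth_duration_range)
                wp = _past_path_segment(
                    t_samples, position, arc, tc, params.smooth_path_length,
                    rng, goal_xy,
                    end_at=(goal_arrivals if wants_goal else None))
            elif u < params.p_smooth + params.p_jump and enough_history:
                content = "jump"
                dur = rng.uniform(*params.duration_range)
                locs = [_visited_point(t_samples, position, tc, rng,
                                       goal_xy, avoid_goal=not wants_goal)
                        for _ in range(params.jump_n_locations - 1)]
                locs.append(goal_xy.copy() if wants_goal
                            else _visited_point(t_samples, position, tc, rng,
                                                goal_xy, avoid_goal=True))
                wp = np.asarray(locs)
            else:
                content = "stationary_local"
                dur = rng.uniform(*params.duration_range)
                wp = np.asarray([here])
                wants_goal = False
            tc = float(np.clip(tc, dwell_start + dur, tr.end_time - dur))
            out.append(RippleSpec(tc, dur, content, wp, tr.index, wants_goal))
    return out


def _past_path_segment(t_samples: np.ndarray, position: np.ndarray,
                       arc: np.ndarray, t_now: float, length: float,
                       rng: np.random.Generator, goal_xy: np.ndarray,
                       end_at: list[float] | None = None,
                       n_waypoints: int = 9, min_net: float = 50.0
                       ) -> np.ndarray:
    """A segment of the rat's own past trajectory with the requested arc
    length, decimated to waypoints.

    ``end_at`` (goal-encoding events): candidate end times, e.g. past
    arrivals at the goal well; a random one earlier than ``t_now`` is
    chosen so the virtual path terminates at the goal.  Otherwise a
    random past endpoint is drawn, retried a few times to keep non-goal
    content out of the goal neighbourhood.  Segments that double back on
    themselves (start-to-end displacement below ``min_net``) are retried:
    they would encode a loop rather than a trajectory.
    """
    i_now = int(np.searchsorted(t_samples, t_now))
    i_min = int(np.searchsorted(arc, length))
    if i_now <= i_min:          # too little history: straight fallback
        return np.linspace(position[0, 1:3], position[i_now - 1, 1:3]
                           if i_now > 1 else goal_xy, n_waypoints)
    wp = None
    for attempt in range(40):
        if end_at is not None:
            past = [t for t in end_at if t < t_now]
            t_end = past[rng.integers(len(past))] if past else t_now
            i1 = min(int(np.searchsorted(t_samples, t_end)), i_now - 1)
        else:
            i1 = int(rng.integers(i_min, i_now))
        # extend the segment backwards until its straight-line extent
        # reaches min_net (a tortuous stretch needs more arc)
        target = arc[i1] - length
        for _ in range(4):
            i0 = int(np.searchsorted(arc, target))
            if i0 >= i1 - n_waypoints:
                break
            # decimate at equal increments of ARC length, so waypoints
            # follow the experienced path (index-uniform decimation would
            # cluster waypoints inside reward dwells and shortcut across
            # unvisited territory between them)
            s_targets = np.linspace(arc[i0], arc[i1], n_waypoints)
            idx = np.clip(np.searchsorted(arc, s_targets), i0, i1)
            cand = position[idx, 1:3]
            if np.hypot(*(cand[-1] - cand[0])) >= min_net:
                break
            target -= 0.5 * length
        if i0 >= i1 - n_waypoints:
            continue
        wp = cand
        net_ok = np.hypot(*(wp[-1] - wp[0])) >= min_net
        if end_at is None:
            d = np.hypot(*(wp - goal_xy).T)
            if (d.min() < 30.0 or not net_ok) and attempt < 39:
                continue        # keep non-goal content away from the goal
        elif not net_ok and attempt < 39:
            continue
        return wp
    # fallback: straight segment between visited points (guaranteed extent)
    if end_at is not None:
        for _ in range(50):
            p0 = position[rng.integers(max(i_now, 2)), 1:3]
            if np.hypot(*(p0 - goal_xy)) >= min_net:
                return np.linspace(p0, goal_xy, n_waypoints)
        return np.linspace(position[0, 1:3], goal_xy, n_waypoints)
    for _ in range(50):
        p0 = position[rng.integers(max(i_now, 2)), 1:3]
        p1 = position[rng.integers(max(i_now, 2)), 1:3]
        if (np.hypot(*(p1 - p0)) >= min_net
                and np.hypot(*(p0 - goal_xy)) >= 30.0
                and np.hypot(*(p1 - goal_xy)) >= 30.0):
            return np.linspace(p0, p1, n_waypoints)
    return wp if wp is not None else np.linspace(position[0, 1:3],
                                                 position[i_now - 1, 1:3],
                                                 n_waypoints)


def _visited_point(t_samples: np.ndarray, position: np.ndarray,
                   t_now: float, rng: np.random.Generator,
                   goal_xy: np.ndarray, avoid_goal: bool,
                   min_goal_dist: float = 30.0) -> np.ndarray:
    """A previously visited location, optionally away from the goal box."""
    i_now = max(int(np.searchsorted(t_samples, t_now)), 2)
    for _ in range(50):
        p = position[rng.integers(i_now), 1:3].copy()
        if not avoid_goal or np.hypot(*(p - goal_xy)) >= min_goal_dist:
            return p
    return p


def _pos_at(position: np.ndarray, t: float) -> np.ndarray:
    x = np.interp(t, position[:, 0], position[:, 1])
    y = np.interp(t, position[:, 0], position[:, 2])
    return np.array([x, y])






def inject_replay(spikes: list[np.ndarray], ripple_schedule: list[RippleSpec],
                  tuning: TuningCurves, seed: int,
                  content_pop_rate: float = 800.0,
                  arena: ArenaSpec | None = None,
                  event_background_rate: float = 1.5) -> list[np.ndarray]:
    """Add compressed-timescale content spikes inside each ripple window.

    During a smooth_trajectory event, units whose fields cover the virtual
    path fire in path order; jump events place content at disjoint
    locations; stationary events hold one location.  Per-unit intensity is
    the unit's tuning-weighted share of ``content_pop_rate``, so the
    ensemble burst carries a constant population rate along the path.
    All injected spikes lie strictly inside their ripple window.
    """
    rng = _subrng(seed, 4)
    extra: list[list[float]] = [[] for _ in range(tuning.n_units)]
    exc = [u for u in range(tuning.n_units)
           if tuning.unit_class[u] == "excitatory"]
    for rip in ripple_schedule:
        if arena is not None:
            if np.any(rip.waypoints < 0) or np.any(rip.waypoints > arena.side_length):
                raise ValueError("replay path leaves the arena")
        t_start = rip.time - rip.duration / 2
        dt = 0.001
        n_steps = max(2, int(rip.duration / dt))
        tt = t_start + np.arange(n_steps) * dt
        wp = rip.waypoints
        if rip.content == "jump":
            # hold each location for an equal share of the window
            idx = np.minimum((np.arange(n_steps) * len(wp)) // n_steps,
                             len(wp) - 1)
            vpos = wp[idx]
        else:
            seg = np.diff(wp, axis=0)
            if len(seg) == 0:
                vpos = np.repeat(wp, n_steps, axis=0)
            else:
                seglen = np.hypot(seg[:, 0], seg[:, 1])
                cum = np.concatenate([[0.0], np.cumsum(seglen)])
                s = np.linspace(0, cum[-1], n_steps)
                vpos = np.column_stack([np.interp(s, cum, wp[:, 0]),
                                        np.interp(s, cum, wp[:, 1])])
        lam = tuning.rate_at(vpos, exc)
        # the burst ensemble is the cells with fields on the path, not the
        # distant Gaussian tails a 1/sum normalisation would recruit; in
        # sparsely covered spots the best-matching cells are kept even
        # below 1 Hz (the burst recruits whatever ensemble is available)
        thresh = np.minimum(1.0, 0.2 * lam.max(axis=1, keepdims=True))
        lam[lam < thresh] = 0.0
        lam = lam / np.maximum(lam.sum(axis=1, keepdims=True), 1e-9) \
            * content_pop_rate
        # ... plus the broad co-active ensemble every ripple recruits
        lam = lam + event_background_rate
        counts = rng.poisson(lam * dt)
        for j, u in enumerate(exc):
            nz = np.nonzero(counts[:, j])[0]
            if len(nz) == 0:
                continue
            reps = counts[nz, j]
            times = np.repeat(tt[nz], reps) + rng.uniform(0, dt, int(reps.sum()))
            extra[u].extend(times.tolist())
    out = []
    for u in range(tuning.n_units):
        if extra[u]:
            out.append(np.sort(np.concatenate([spikes[u], np.asarray(extra[u])])))
        else:
            out.append(spikes[u])
    return out


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def simulate_lfp(position: np.ndarray, theta_amp_per_trial: np.ndarray,
                 ripple_schedule: list[RippleSpec], schedule: TrialSchedule,
                 theta: ThetaParams, seed: int, fs: float = 1250.0,
                 noise_sd: float = 1.0, carrier_freq: float = 200.0,
                 ripple_amplitude: float = 8.0
                 ) -> tuple[np.ndarray, np.ndarray]:
    """One LFP channel: movement theta + broadband noise + ripple packets.

    Theta amplitude follows the per-trial schedule and is gated by
    movement; ripple packets are Gaussian-windowed carrier bursts at the
    scheduled times.  Scheduled ripples that fall in movement epochs are
    rejected with a warning.  Returns (t, signal[:, None]).
    """
    if fs < 1000:
        raise ValueError("fs must be >= 1000 Hz for ripple-band content")
    t_pos = position[:, 0]
    tg = np.arange(t_pos[0], t_pos[-1], 1.0 / fs)
    rng = _subrng(seed, 5)

    vx = np.gradient(gaussian_filter1d(position[:, 1], 6), t_pos)
    vy = np.gradient(gaussian_filter1d(position[:, 2], 6), t_pos)
    speed = np.interp(tg, t_pos, np.hypot(vx, vy))
    move_gate = gaussian_filter1d((speed > theta.speed_threshold).astype(float),
                                  int(0.2 * fs))

    trial_idx = schedule.trial_of_times(tg)
    amp = np.ones_like(tg)
    ok = trial_idx >= 0
    amp[ok] = theta_amp_per_trial[
        np.clip(trial_idx[ok], 0, len(theta_amp_per_trial) - 1)]

    phase = np.radians(theta_phase_deg(tg, theta.frequency))
    sig = -amp * move_gate * np.cos(phase)
    sig = sig + rng.normal(0, noise_sd, len(tg))

    # ripple-band noise floor: white noise power in a 100 Hz band
    band_sd = noise_sd * np.sqrt(100.0 / (fs / 2))
    for rip in ripple_schedule:
        i0 = np.searchsorted(tg, rip.time)
        if i0 >= len(tg) or speed[min(i0, len(tg) - 1)] >= 5.0:
            warnings.warn(
                f"scheduled ripple at t={rip.time:.2f}s falls in movement; skipped")
            continue
        half = rip.duration / 2
        sel = (tg >= rip.time - half) & (tg <= rip.time + half)
        tt = tg[sel]
        env = np.exp(-0.5 * ((tt - rip.time) / (rip.duration / 4)) ** 2)
        sig[sel] += (ripple_amplitude * band_sd * env
                     * np.sin(2 * np.pi * carrier_freq * (tt - rip.time)))
    return tg, sig[:, None]


# ---------------------------------------------------------------------------
# the whole session
# ---------------------------------------------------------------------------

def generate_session(config: SessionConfig | None = None, seed: int = 0
                     ) -> SessionData:
    """Generate a full synthetic session from a single seed."""
    config = config or SessionConfig()
    rng = _subrng(seed, 6)
    n_units = config.n_units
    if n_units is None:
        n_units = int(rng.integers(N_UNITS_RANGE[0], N_UNITS_RANGE[1] + 1))

    position, schedule = simulate_trajectory(config.arena, config.trajectory, seed)
    tuning = make_tuning_curves(config.arena, n_units, config.fields, seed)
    gain = config.gain.per_trial(config.trajectory.n_trials)
    theta_amp = 1.0 + 0.8 * (gain - gain[0]) / max(gain.max() - gain[0], 1e-9)

    ripple_schedule = make_ripple_schedule(
        schedule, position, config.arena, config.ripples, seed,
        config.trajectory.dwell_duration)
    quiet = [(r.time - r.duration / 2, r.time + r.duration / 2)
             for r in ripple_schedule]
    spikes = simulate_spikes(position, tuning, config.theta, gain, schedule,
                             seed, config.immobility_rate, quiet)
    spikes = inject_replay(spikes, ripple_schedule, tuning, seed,
                           config.ripples.content_pop_rate, config.arena,
                           config.ripples.event_background_rate)
    lfp_t, lfp = simulate_lfp(position, theta_amp, ripple_schedule, schedule,
                              config.theta, seed, config.lfp_rate,
                              config.lfp_noise_sd,
                              config.ripples.carrier_freq,
                              config.ripples.amplitude)
    truth = GroundTruth(
        tuning=tuning,
        theta_freq=config.theta.frequency,
        rate_gain=gain,
        theta_amp=theta_amp,
        sweep_speed=config.theta.sweep_speed,
        ripples=ripple_schedule,
        goal_emergence_trial=config.ripples.goal_emergence_trial,
    )
    pos_df = _position_frame(position)
    return SessionData(
        position=pos_df,
        spikes=spikes,
        unit_class=list(tuning.unit_class),
        lfp=lfp,
        lfp_t=lfp_t,
        lfp_rate=config.lfp_rate,
        arena=config.arena,
        schedule=schedule,
        seed=seed,
        ground_truth=truth,
    )


def _position_frame(position: np.ndarray):
    import pandas as pd

    return pd.DataFrame({"t": position[:, 0], "x": position[:, 1],
                         "y": position[:, 2]})
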