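"""Theta-sequence scoring: geometry, closed-form slope, quadrant score,
subsampling control."""

import numpy as np
import pytest

from goalreplay.decoder import EncodingModel, PosteriorSeq
from goalreplay.lfp import ThetaCycle
from goalreplay.theta import (CYCLE_START_DEG, N_PHASE_WINDOWS,
                              RelativeMatrix, build_relative_matrix,
                              forward_slope, movement_heading, path_extent,
                              phase_window_starts, quadrant_score,
                              subsample_to_reference)


def _grid_model(n=50, h=2.0):
    xs = (np.arange(n) + 0.5) * h
    xx, yy = np.meshgrid(xs, xs)
    centers = np.column_stack([xx.ravel(), yy.ravel()])
    return EncodingModel(rates=np.ones((1, n * n)), bin_centers=centers,
                         grid_shape=(n, n), bin_size=h)


def _seq_with_mass_at(model, xy, n_windows=N_PHASE_WINDOWS, sd=3.0):
    """PosteriorSeq with a small Gaussian blob at xy in every window."""
    d2 = ((model.bin_centers - np.asarray(xy)) ** 2).sum(axis=1)
    blob = np.exp(-d2 / (2 * sd**2))
    blob /= blob.sum()
    posts = np.tile(blob, (n_windows, 1))
    starts = phase_window_starts()
    wins = np.column_stack([starts, starts + 60.0])
    return PosteriorSeq(windows=wins, posteriors=posts,
                        spike_counts=np.ones(n_windows),
                        defined=np.ones(n_windows, bool))


class TestRelativeMatrix:
    def test_mass_ahead_maps_to_positive_x(self):
        model = _grid_model()
        rat = np.array([50.0, 50.0])
        seq = _seq_with_mass_at(model, rat + [10.0, 0.0])
        rm = build_relative_matrix(seq, model, rat, ref_angle=0.0)
        com = (rm.matrix.sum(axis=0) * rm.rel_x).sum() / rm.matrix.sum()
        assert abs(com - 10.0) < 1.0

    def test_reference_flip_mirrors_mass(self):
        model = _grid_model()
        rat = np.array([50.0, 50.0])
        seq = _seq_with_mass_at(model, rat + [10.0, 0.0])
        rm = build_relative_matrix(seq, model, rat, ref_angle=np.pi)
        com = (rm.matrix.sum(axis=0) * rm.rel_x).sum() / rm.matrix.sum()
        assert abs(com + 10.0) < 1.0

    def test_oblique_reference_projects_correctly(self):
        model = _grid_model()
        rat = np.array([50.0, 50.0])
        ang = np.radians(35.0)
        offset = 12.0 * np.array([np.cos(ang), np.sin(ang)])
        seq = _seq_with_mass_at(model, rat + offset)
        rm = build_relative_matrix(seq, model, rat, ref_angle=ang)
        com = (rm.matrix.sum(axis=0) * rm.rel_x).sum() / rm.matrix.sum()
        assert abs(com - 12.0) < 1.0

    def test_mass_conserved_within_interpolation_tolerance(self):
        model = _grid_model()
        rng = np.random.default_rng(0)
        rat = np.array([47.0, 55.0])
        posts = rng.random((N_PHASE_WINDOWS, model.n_bins))
        # concentrate the mass near the rat so the +-50 cm window holds it
        d2 = ((model.bin_centers - rat) ** 2).sum(axis=1)
        posts *= np.exp(-d2 / (2 * 15.0**2))
        posts /= posts.sum(axis=1, keepdims=True)
        starts = phase_window_starts()
        seq = PosteriorSeq(windows=np.column_stack([starts, starts + 60]),
                           posteriors=posts,
                           spike_counts=np.ones(N_PHASE_WINDOWS),
                           defined=np.ones(N_PHASE_WINDOWS, bool))
        rm = build_relative_matrix(seq, model, rat, 0.7)
        per_window = rm.matrix.sum(axis=1)
        assert np.all(np.abs(per_window - 1.0) < 0.02)


class TestForwardSlope:
    @staticmethod
    def _matrix(masses_positions):
        """RelativeMatrix with specified (window_index, rel_x, mass) cells."""
        rel = (np.arange(50) - 25 + 0.5) * 2.0
        centers = phase_window_starts() + 30.0
        centers = CYCLE_START_DEG + (centers - CYCLE_START_DEG) % 360.0
        k = np.arange(N_PHASE_WINDOWS)
        crosses = 15.0 * k + 60.0 > 360.0
        mat = np.zeros((N_PHASE_WINDOWS, 50))
        for w, x, m in masses_positions:
            j = np.argmin(np.abs(rel - x))
            mat[w, j] += m
        return RelativeMatrix(matrix=mat, rel_x=rel, phase_centers=centers,
                              crosses_boundary=crosses)

    def test_hand_built_weighted_regression(self):
        # forward windows are indices 10..20 (crossing windows excluded)
        pts = [(12, -5.0, 1.0), (15, 1.0, 2.0), (18, 9.0, 1.0)]
        rm = self._matrix(pts)
        rel = rm.rel_x
        centers = rm.phase_centers
        # pen-and-paper weighted least squares on the same three points
        xs = np.array([(centers[w] - 60.0) / 360.0 for w, _, _ in pts])
        ys = np.array([rel[np.argmin(np.abs(rel - x))] for _, x, _ in pts])
        ws = np.array([m for _, _, m in pts])
        xm = (ws * xs).sum() / ws.sum()
        ym = (ws * ys).sum() / ws.sum()
        expect = ((ws * (xs - xm) * (ys - ym)).sum()
                  / (ws * (xs - xm) ** 2).sum())
        assert np.isclose(forward_slope(rm), expect, atol=1e-12)

    def test_single_window_undefined(self):
        rm = self._matrix([(12, 3.0, 1.0)])
        assert np.isnan(forward_slope(rm))

    def test_slope_sign_flips_with_reflected_positions(self):
        pts = [(11, -6.0, 1.0), (14, 0.0, 1.0), (19, 8.0, 1.0)]
        rm_pos = self._matrix(pts)
        rm_neg = self._matrix([(w, -x, m) for w, x, m in pts])
        assert np.isclose(forward_slope(rm_neg), -forward_slope(rm_pos),
                          atol=1e-9)


class TestQuadrantScore:
    def test_all_mass_late_ahead_scores_one(self):
        rel = (np.arange(50) - 25 + 0.5) * 2.0
        centers = phase_window_starts() + 30.0
        centers = CYCLE_START_DEG + (centers - CYCLE_START_DEG) % 360.0
        mat = np.zeros((N_PHASE_WINDOWS, 50))
        late = centers >= 240.0
        mat[np.ix_(late, rel > 0)] = 1.0
        rm = RelativeMatrix(matrix=mat, rel_x=rel, phase_centers=centers)
        assert np.isclose(quadrant_score(rm), 1.0)

    def test_uniform_mass_scores_zero(self):
        rel = (np.arange(50) - 25 + 0.5) * 2.0
        centers = phase_window_starts() + 30.0
        centers = CYCLE_START_DEG + (centers - CYCLE_START_DEG) % 360.0
        rm = RelativeMatrix(matrix=np.ones((N_PHASE_WINDOWS, 50)),
                            rel_x=rel, phase_centers=centers)
        assert abs(quadrant_score(rm)) < 1e-12

    def test_matches_four_sum_oracle_and_scale_invariance(self):
        rng = np.random.default_rng(3)
        rel = (np.arange(50) - 25 + 0.5) * 2.0
        centers = phase_window_starts() + 30.0
        centers = CYCLE_START_DEG + (centers - CYCLE_START_DEG) % 360.0
        for _ in range(10):
            mat = rng.random((N_PHASE_WINDOWS, 50))
            rm = RelativeMatrix(matrix=mat, rel_x=rel, phase_centers=centers)
            early = centers < 240.0
            behind = rel < 0
            eb = mat[np.ix_(early, behind)].sum()
            ea = mat[np.ix_(early, ~behind)].sum()
            lb = mat[np.ix_(~early, behind)].sum()
            la = mat[np.ix_(~early, ~behind)].sum()
            expect = (eb + la - ea - lb) / mat.sum()
            got = quadrant_score(rm)
            assert np.isclose(got, expect, atol=1e-12)
            scaled = RelativeMatrix(matrix=5.5 * mat, rel_x=rel,
                                    phase_centers=centers)
            assert np.isclose(quadrant_score(scaled), got, atol=1e-12)
            assert -1.0 <= got <= 1.0


class TestSubsample:
    def test_full_count_reference_is_identity(self, small_session, small_model):
        from goalreplay.lfp import bandpass, phase_interpolator, segment_theta_cycles
        from goalreplay.behavior import compute_velocity
        from goalreplay.theta import score_cycle

        model, spikes, _ = small_model
        s = small_session
        speed = compute_velocity(s.position)
        filt = bandpass(s.lfp[:, 0], s.lfp_rate, 6, 12)
        cycles = segment_theta_cycles(filt, s.lfp_t, speed,
                                      s.position["t"].to_numpy())
        pf = phase_interpolator(filt, s.lfp_t)
        # a cycle with a decent number of spikes
        cyc = max(cycles[:50], key=lambda c: sum(
            np.searchsorted(st, c.end) - np.searchsorted(st, c.start)
            for st in spikes))
        mid = (cyc.start + cyc.end) / 2
        xy = s.position_at(np.array([mid]))[0]
        ang = movement_heading(s.position, np.array([mid]))[0]
        n_spk = sum(np.searchsorted(st, cyc.end) - np.searchsorted(st, cyc.start)
                    for st in spikes)
        direct = score_cycle(cyc, spikes, pf, model, xy, ang)
        sub = subsample_to_reference(cyc, spikes, pf, model, xy, ang,
                                     reference_count=n_spk, n_rep=5, seed=1)
        assert np.isclose(sub.forward_slope, direct.forward_slope, atol=1e-9)
        assert np.isclose(sub.quadrant_score, direct.quadrant_score,
                          atol=1e-9)
        # determinism under a fixed seed
        again = subsample_to_reference(cyc, spikes, pf, model, xy, ang,
                                       reference_count=max(n_spk // 2, 1),
                                       n_rep=8, seed=7)
        again2 = subsample_to_reference(cyc, spikes, pf, model, xy, ang,
                                        reference_count=max(n_spk // 2, 1),
                                        n_rep=8, seed=7)
        assert again.forward_slope == again2.forward_slope


class TestGoalAlignment:
    """Movement- vs goal-referenced slopes near the goal, on controlled
    sequences whose sweep direction is known by construction."""

    @staticmethod
    def _run(sweep_along, n_cycles=40, seed=0):
        import pandas as pd

        from goalreplay.core import make_arena
        from goalreplay.synthetic import FieldParams, make_tuning_curves
        from goalreplay.theta import goal_alignment_analysis

        rng = np.random.default_rng(seed)
        arena = make_arena(goal_well=14)
        goal_xy = arena.well_positions[14]          # (83.3, 83.3)
        tun = make_tuning_curves(arena, 300,
                                 FieldParams(peak_rate_range=(10, 30),
                                             excitatory_fraction=1.0),
                                 seed=1)
        n, h = 100, 2.0
        xs = (np.arange(n) + 0.5) * h
        xx, yy = np.meshgrid(xs, xs)
        centers = np.column_stack([xx.ravel(), yy.ravel()])
        model = EncodingModel(rates=tun.rate_at(centers).T,
                              bin_centers=centers, grid_shape=(n, n),
                              bin_size=h)
        f = 8.0
        # rat ~20 cm below the goal, creeping slowly along +x: the
        # rat-to-goal bearing is ~+y, so the movement/goal angular
        # difference is ~90 deg (inside the 30-180 deg gate) and the rat
        # stays within the 25 cm radius throughout
        rat0 = goal_xy - [0.0, 20.0]
        dt = 0.001
        T = n_cycles / f + 0.5
        tt = np.arange(0, T, dt)
        x = rat0[0] + np.linspace(-3, 3, len(tt))
        y = np.full_like(tt, rat0[1])
        phase = (tt * f * 360) % 360
        frac = ((phase - 60) % 360) / 360
        mod = 1 + 0.7 * np.cos(np.radians(phase))
        u = sweep_along
        xeff = np.column_stack([x, y]) \
            + u[None, :] * (16.0 * (frac - 0.5))[:, None]
        lam = tun.rate_at(xeff) * 3.0
        cnt = rng.poisson(lam * mod[:, None] * dt)
        spikes = [np.sort(np.repeat(tt[np.nonzero(cnt[:, j])[0]],
                                    cnt[np.nonzero(cnt[:, j])[0], j]))
                  for j in range(tun.n_units)]
        phase_fn = lambda times: np.asarray(times) * f * 360.0  # noqa: E731
        cycles = [ThetaCycle(start=(k + 60 / 360) / f,
                             end=(k + 1 + 60 / 360) / f, mean_speed=15.0)
                  for k in range(n_cycles)]
        t60 = np.arange(0, T, 1 / 60)
        pos = pd.DataFrame({"t": t60,
                            "x": rat0[0] + np.linspace(-3, 3, len(t60)),
                            "y": np.full_like(t60, rat0[1])})
        return goal_alignment_analysis(cycles, spikes, phase_fn, model, pos,
                                       goal_xy)

    def test_movement_aligned_sequences_favor_movement_reference(self):
        tab = self._run(np.array([1.0, 0.0]))
        assert len(tab) > 20
        assert np.nanmean(tab["slope_movement"]) > \
            np.nanmean(tab["slope_goal"]) + 3.0

    def test_goal_aligned_sequences_flip_the_comparison(self):
        tab = self._run(np.array([0.0, 1.0]))   # sweep toward the goal
        assert len(tab) > 20
        assert np.nanmean(tab["slope_goal"]) > \
            np.nanmean(tab["slope_movement"]) + 3.0

    def test_direct_approach_cycles_excluded(self):
        import pandas as pd

        from goalreplay.core import make_arena
        from goalreplay.theta import goal_alignment_analysis

        arena = make_arena(goal_well=14)
        goal_xy = arena.well_positions[14]
        model = _grid_model()
        t60 = np.arange(0, 3, 1 / 60)
        # moving straight at the goal: angle difference < 30 deg
        pos = pd.DataFrame({"t": t60, "x": goal_xy[0] - 20 + 10 * t60,
                            "y": np.full_like(t60, goal_xy[1])})
        cycles = [ThetaCycle(start=1.0, end=1.125, mean_speed=12.0)]
        tab = goal_alignment_analysis(cycles, [np.array([1.05])],
                                      lambda t: np.asarray(t) * 8 * 360.0,
                                      model, pos, goal_xy)
        assert len(tab) == 0


def test_path_extent_of_linear_sweep():
    rel = (np.arange(50) - 25 + 0.5) * 2.0
    centers = phase_window_starts() + 30.0
    centers = CYCLE_START_DEG + (centers - CYCLE_START_DEG) % 360.0
    mat = np.zeros((N_PHASE_WINDOWS, 50))
    for k in range(N_PHASE_WINDOWS):
        x = -6.0 + 12.0 * k / (N_PHASE_WINDOWS - 1)
        mat[k, np.argmin(np.abs(rel - x))] = 1.0
    rm = RelativeMatrix(matrix=mat, rel_x=rel, phase_centers=centers)
    assert 10.0 <= path_extent(rm) <= 14.0


def test_heading_undefined_when_still():
    import pandas as pd

    t = np.arange(0, 5, 1 / 60)
    pos = pd.DataFrame({"t": t, "x": np.full_like(t, 30.0),
                        "y": np.full_like(t, 30.0)})
    ang = movement_heading(pos, np.array([2.5]))
    assert np.isnan(ang[0])
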