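"""Replay criteria, shuffles, Monte-Carlo significance, goal statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from goalreplay.behavior import WellPartition
from goalreplay.core import make_arena
from goalreplay.decoder import EncodingModel, PosteriorSeq
from goalreplay.lfp import RippleEvent
from goalreplay.replay import (DecodedPath, grubbs_test, goal_box_mass,
                               goal_encoding, heading_before_ripple,
                               heading_split, latency_after_ripple,
                               mask_local_well, monte_carlo_p,
                               running_goal_representation,
                               shuffle_cell_identity, shuffle_field_rotation,
                               trajectory_criteria, well_representation)


def _path(xy, defined=None):
    xy = np.asarray(xy, float)
    if defined is None:
        defined = np.ones(len(xy), bool)
    wins = np.column_stack([np.arange(len(xy)) * 0.005,
                            np.arange(len(xy)) * 0.005 + 0.02])
    return DecodedPath(positions=xy, defined=np.asarray(defined), windows=wins)


class TestTrajectoryCriteria:
    def test_straight_path_passes(self):
        xy = np.column_stack([np.arange(20) * 3.0, np.zeros(20)])
        assert trajectory_criteria(_path(xy))           # 57 cm net

    def test_corner_alternation_fails_step_rule(self):
        xy = np.array([[0, 0], [200, 200]] * 10, float)
        assert not trajectory_criteria(_path(xy))

    def test_stationary_path_fails_net_rule(self):
        xy = np.tile([50.0, 50.0], (20, 1))
        assert not trajectory_criteria(_path(xy))

    def test_undefined_frames_break_runs(self):
        xy = np.column_stack([np.arange(20) * 3.0, np.zeros(20)])
        defined = np.ones(20, bool)
        defined[9] = False                             # splits 20 into 9+10
        assert not trajectory_criteria(_path(xy, defined))

    def test_matches_exhaustive_run_scan_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = rng.integers(5, 30)
            xy = rng.uniform(0, 200, (n, 2))
            if rng.random() < 0.5:   # make smooth-ish paths sometimes
                xy = np.cumsum(rng.normal(0, 8, (n, 2)), axis=0) + 100
            defined = rng.random(n) > 0.1
            got = trajectory_criteria(_path(xy, defined))
            # oracle: test every contiguous frame range independently
            expect = False
            for i in range(n):
                for j in range(i + 14, n):
                    if not defined[i:j + 1].all():
                        continue
                    steps = np.hypot(*np.diff(xy[i:j + 1], axis=0).T)
                    if np.all(steps < 30.0) and np.hypot(*(xy[j] - xy[i])) > 40.0:
                        expect = True
            assert got == expect


class TestMonteCarloP:
    def test_published_formula_values(self):
        assert monte_carlo_p(0, 1000) == 1 / 1001
        assert monte_carlo_p(49, 999) == 0.05
        assert monte_carlo_p(5, 5) == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_p(-1, 100)
        with pytest.raises(ValueError):
            monte_carlo_p(5, 4)
        with pytest.raises(ValueError):
            monte_carlo_p(0, 0)


class TestShuffles:
    def test_cell_identity_preserves_row_sums_and_multiset(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 3, (10, 6)).astype(float)
        out = shuffle_cell_identity(counts, rng)
        assert np.array_equal(out.sum(axis=1), counts.sum(axis=1))
        assert sorted(map(tuple, out.T.tolist())) == \
            sorted(map(tuple, counts.T.tolist()))

    def test_cell_identity_needs_two_participants(self):
        counts = np.zeros((5, 4))
        counts[:, 2] = 1.0
        with pytest.raises(ValueError):
            shuffle_cell_identity(counts, np.random.default_rng(0))

    def test_cell_identity_label_frequencies_uniform(self):
        rng = np.random.default_rng(1)
        counts = np.zeros((1, 3))
        counts[0] = [1, 2, 3]          # distinguishable columns
        landed = np.zeros((3, 3))
        for _ in range(3000):
            out = shuffle_cell_identity(counts, rng)
            for col in range(3):
                landed[col, int(out[0, col]) - 1] += 1
        p = min(chisquare(landed[c]).pvalue for c in range(3))
        assert p > 1e-4

    def test_rotation_conserves_mass_and_composes(self):
        rng = np.random.default_rng(2)
        n = 10
        xs = (np.arange(n) + 0.5) * 2.0
        xx, yy = np.meshgrid(xs, xs)
        model = EncodingModel(rates=rng.uniform(0.1, 5, (4, n * n)),
                              bin_centers=np.column_stack([xx.ravel(),
                                                           yy.ravel()]),
                              grid_shape=(n, n), bin_size=2.0)
        rot = shuffle_field_rotation(model, np.random.default_rng(3))
        assert np.allclose(rot.rates.sum(axis=1), model.rates.sum(axis=1))
        # rolling forward then backward restores the map (group property)
        m = model.rates[0].reshape(n, n)
        rolled = np.roll(np.roll(m, (3, 4), axis=(0, 1)), (-3, -4),
                         axis=(0, 1))
        assert np.array_equal(rolled, m)


class TestLocalWellMasking:
    @staticmethod
    def _setup():
        arena = make_arena()
        part = WellPartition(arena)
        n = 100
        xs = (np.arange(n) + 0.5) * 2.0
        xx, yy = np.meshgrid(xs, xs)
        centers = np.column_stack([xx.ravel(), yy.ravel()])
        model = EncodingModel(rates=np.ones((1, n * n)), bin_centers=centers,
                              grid_shape=(n, n), bin_size=2.0)
        labels = part.bin_labels(centers)
        return arena, part, model, labels

    def test_all_local_mass_removed(self):
        arena, part, model, labels = self._setup()
        local = 7
        post = np.where(labels == local, 1.0, 0.0)
        post = post / post.sum()
        seq = PosteriorSeq(windows=np.zeros((1, 2)),
                           posteriors=post[None, :],
                           spike_counts=np.ones(1), defined=np.ones(1, bool))
        masked = mask_local_well(seq, labels, local)
        assert np.nansum(masked) == 0.0

    def test_no_local_mass_unchanged(self):
        arena, part, model, labels = self._setup()
        post = np.where(labels == 3, 1.0, 0.0)
        post = post / post.sum()
        seq = PosteriorSeq(windows=np.zeros((1, 2)),
                           posteriors=post[None, :],
                           spike_counts=np.ones(1), defined=np.ones(1, bool))
        masked = mask_local_well(seq, labels, local_well=20)
        assert np.array_equal(masked[0], post)

    def test_masked_mass_equals_partition_sum_oracle(self):
        arena, part, model, labels = self._setup()
        rng = np.random.default_rng(4)
        posts = rng.random((5, model.n_bins))
        posts /= posts.sum(axis=1, keepdims=True)
        seq = PosteriorSeq(windows=np.zeros((5, 2)), posteriors=posts,
                           spike_counts=np.ones(5),
                           defined=np.ones(5, bool))
        local = 14
        masked = mask_local_well(seq, labels, local)
        for k in range(5):
            removed = posts[k].sum() - masked[k].sum()
            oracle = posts[k][labels == local].sum()
            assert np.isclose(removed, oracle, atol=1e-12)


class TestGoalEncoding:
    @staticmethod
    def _model():
        n = 100
        xs = (np.arange(n) + 0.5) * 2.0
        xx, yy = np.meshgrid(xs, xs)
        return EncodingModel(rates=np.ones((1, n * n)),
                             bin_centers=np.column_stack([xx.ravel(),
                                                          yy.ravel()]),
                             grid_shape=(n, n), bin_size=2.0)

    def test_ten_percent_in_box_encodes(self):
        model = self._model()
        goal = np.array([100.0, 100.0])
        inbox = (np.abs(model.bin_centers[:, 0] - 100) <= 15) \
            & (np.abs(model.bin_centers[:, 1] - 100) <= 15)
        frames = np.zeros((10, model.n_bins))
        frames[:, inbox] = 0.10 / inbox.sum()
        frames[:, ~inbox] = 0.90 / (~inbox).sum()
        defined = np.ones(10, bool)
        assert goal_encoding(frames, model, goal, defined)

    def test_zero_mass_does_not_encode(self):
        model = self._model()
        goal = np.array([100.0, 100.0])
        frames = np.zeros((5, model.n_bins))
        assert not goal_encoding(frames, model, goal, np.ones(5, bool))

    def test_both_modes_match_box_sum_oracle(self):
        model = self._model()
        rng = np.random.default_rng(5)
        goal = np.array([61.0, 143.0])
        frames = rng.random((7, model.n_bins))
        frames /= frames.sum(axis=1, keepdims=True)
        defined = rng.random(7) > 0.3
        inbox = (np.abs(model.bin_centers[:, 0] - goal[0]) <= 15) \
            & (np.abs(model.bin_centers[:, 1] - goal[1]) <= 15)
        sums = frames[defined][:, inbox].sum(axis=1)
        got_mean = goal_encoding(frames, model, goal, defined, mode="mean")
        got_sum = goal_encoding(frames, model, goal, defined, mode="sum")
        assert got_mean == (sums.mean() > 0.075)
        assert got_sum == (sums.sum() > 0.075)
        assert np.allclose(goal_box_mass(frames, model, goal)[defined], sums)


class TestWellRepresentation:
    def test_matches_partition_sum_oracle(self):
        arena = make_arena()
        part = WellPartition(arena)
        n = 100
        xs = (np.arange(n) + 0.5) * 2.0
        xx, yy = np.meshgrid(xs, xs)
        centers = np.column_stack([xx.ravel(), yy.ravel()])
        labels = part.bin_labels(centers)
        rng = np.random.default_rng(6)
        frames = rng.random((4, n * n))
        frames /= frames.sum(axis=1, keepdims=True)
        defined = np.array([True, True, False, True])
        rep = well_representation(frames, defined, labels, arena.n_wells,
                                 local_well=5)
        mean_frame = frames[defined].mean(axis=0)
        for w in range(arena.n_wells):
            if w == 5:
                assert np.isnan(rep[w])
            else:
                assert np.isclose(rep[w], mean_frame[labels == w].sum(),
                                  atol=1e-12)


class TestGrubbs:
    def test_extreme_value_flagged(self):
        idx, G = grubbs_test(np.array([1.0, 1.0, 1.0, 10.0]))
        assert idx == 3 and G > 1.0

    def test_constant_vector_returns_none(self):
        idx, G = grubbs_test(np.full(10, 2.5))
        assert idx is None and G == 0.0

    def test_max_but_not_outlying_unflagged(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 36)
        x = (x - x.mean()) / x.std()          # no extreme point
        idx, _ = grubbs_test(np.clip(x, -1.5, 1.5))
        assert idx is None

    def test_needs_three_values(self):
        with pytest.raises(ValueError):
            grubbs_test(np.array([1.0, 2.0]))

    def test_nan_handling_maps_back_to_original_index(self):
        x = np.array([1.0, np.nan, 1.0, 1.0, 25.0])
        idx, _ = grubbs_test(x)
        assert idx == 4


class TestRunningGoal:
    def test_goal_zeroed_never_flags(self):
        rng = np.random.default_rng(8)
        n_ev, n_wells = 120, 36
        reps = rng.random((n_ev, n_wells)) * 0.02
        reps[:, 9] = 0.0                       # goal channel empty
        trials = rng.integers(0, 30, n_ev)
        tab = running_goal_representation(reps, trials, goal_well=9)
        assert not tab["goal_flag"].any()

    def test_injected_goal_elevation_flags_from_onset(self):
        rng = np.random.default_rng(9)
        n_ev = 200
        reps = rng.random((n_ev, 36)) * 0.01
        trials = rng.integers(0, 30, n_ev)
        late = trials >= 7
        reps[late, 9] = 0.3                    # strong goal content
        tab = running_goal_representation(reps, trials, goal_well=9)
        flagged = tab.loc[tab["goal_flag"], "window_start"]
        # windows wholly before trial 7 (0-based): starts 0..3 cover 0-6
        assert not tab.loc[tab["window_start"] <= 2, "goal_flag"].any()
        assert (tab.loc[tab["window_start"] >= 7, "goal_flag"]).all()

    def test_empty_window_is_flagged_gap(self):
        reps = np.ones((3, 36)) * 0.01
        trials = np.array([0, 1, 2])
        tab = running_goal_representation(reps, trials, goal_well=0,
                                          n_trials=12)
        gap = tab[tab["window_start"] >= 3]
        assert (gap["n_events"] == 0).all()
        assert gap["goal_rep"].isna().all()


class TestHeading:
    def test_split_trivial_angles(self):
        toward, away, un = heading_split([10.0, 190.0, np.nan], [10.0, 10.0, 10.0])
        assert toward.tolist() == [True, False, False]
        assert away.tolist() == [False, True, False]
        assert un.tolist() == [False, False, True]

    def test_uniform_headings_give_quarter_fraction(self):
        rng = np.random.default_rng(10)
        h = rng.uniform(0, 360, 20000)
        toward, _, _ = heading_split(h, np.zeros_like(h))
        assert abs(toward.mean() - 0.25) < 0.01

    def test_heading_before_ripple_uses_last_movement(self):
        t = np.arange(0, 10, 1 / 60)
        x = np.where(t < 5, 20 * t, 100.0)     # runs +x then sits still
        pos = pd.DataFrame({"t": t, "x": x, "y": np.zeros_like(t)})
        speed = np.where(t < 5, 20.0, 0.0)
        hd = heading_before_ripple(pos, speed, ripple_start=8.0)
        assert abs(hd) < 15.0


class TestLatencyAfterRipple:
    def test_latency_and_censoring(self):
        arena = make_arena(goal_well=0)
        part = WellPartition(arena)
        goal = arena.well_positions[0]
        far = arena.well_positions[35]
        # sit far away, then run to the goal, then sit far again
        t = np.arange(0, 30, 1 / 60)
        x = np.interp(t, [0, 10, 12, 20, 22, 30],
                      [far[0], far[0], goal[0], goal[0], far[0], far[0]])
        y = np.interp(t, [0, 10, 12, 20, 22, 30],
                      [far[1], far[1], goal[1], goal[1], far[1], far[1]])
        pos = pd.DataFrame({"t": t, "x": x, "y": y})
        rips = [RippleEvent(5.0, 5.05, 5.1, 4.0, 0.1),    # before goal visit
                RippleEvent(15.0, 15.05, 15.1, 4.0, 0.1),  # rat AT the goal
                RippleEvent(25.0, 25.05, 25.1, 4.0, 0.1)]  # no later visit
        tab = latency_after_ripple(rips, [True, True, False], pos, part, 0)
        assert len(tab) == 2                   # at-goal ripple excluded
        first = tab.iloc[0]
        assert not first["censored"]
        assert 5.0 < first["latency"] < 7.0    # goal reached ~t=11-12
        assert tab.iloc[1]["censored"] and np.isnan(tab.iloc[1]["latency"])
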