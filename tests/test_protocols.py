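"""Trial generators for the three tasks and the feedback scoring rule."""

import dataclasses
import math
from collections import Counter

import numpy as np
import pytest

from quantnav import (
    DomainError,
    Position,
    euclidean_distance,
    generate_estimation_trials,
    generate_forced_choice_trials,
    generate_navigation_trials,
    score_response,
    slider_to_distance,
)
from quantnav.protocols import EstimationProtocol, distance_to_slider


class TestNavigationTrials:
    @pytest.mark.parametrize("seed, group", [(0, "GG"), (1, "MG"), (42, "GG")])
    def test_training_phases_then_tests(self, cfg, seed, group):
        trials = generate_navigation_trials(seed, group, cfg)
        phases = [t.phase for t in trials]
        assert phases[:8] == ["train_notify"] * 5 + ["train_press"] * 3
        assert all(p == "test" for p in phases[8:])

    def test_gamepad_group_runs_28_test_trials(self, cfg):
        trials = generate_navigation_trials(3, "GG", cfg)
        assert sum(t.phase == "test" for t in trials) == 28

    def test_movement_group_pool_covers_the_time_budget(self, cfg):
        trials = generate_navigation_trials(3, "MG", cfg)
        assert sum(t.phase == "test" for t in trials) >= 28

    @pytest.mark.parametrize("seed", [0, 5, 99])
    def test_chaining_and_minimum_separation(self, cfg, seed):
        trials = generate_navigation_trials(seed, "GG", cfg)
        for prev, nxt in zip(trials, trials[1:]):
            assert nxt.start == prev.goal  # continuous navigation
        for t in trials:
            assert euclidean_distance(t.start, t.goal) >= 30.0
            assert 0 <= t.goal.q1 <= cfg.axis_length
            assert 0 <= t.goal.q2 <= cfg.axis_length

    def test_determinism(self, cfg):
        a = generate_navigation_trials(11, "GG", cfg)
        b = generate_navigation_trials(11, "GG", cfg)
        assert a == b

    def test_unknown_group(self, cfg):
        with pytest.raises(DomainError):
            generate_navigation_trials(0, "XX", cfg)


class TestFeedbackScore:
    def test_perfect_response(self, cfg):
        s = score_response(Position(50, 50), Position(50, 50), cfg)
        assert (s.error_pct, s.points) == (0.0, 20)

    def test_maximum_error(self, cfg):
        s = score_response(Position(0, 0), Position(200, 200), cfg)
        assert s.error_pct == pytest.approx(100.0)
        assert s.points == 0

    def test_five_percent_bin_boundary(self, cfg):
        d = 0.05 * cfg.max_distance  # exactly 5% of the diagonal
        s = score_response(Position(100 + d, 100), Position(100, 100), cfg)
        assert s.error_pct == pytest.approx(5.0)
        assert s.points == 19

    def test_points_weakly_decrease_with_error(self, cfg):
        goal = Position(100, 100)
        pts = [score_response(Position(min(100 + d, 200), 100), goal, cfg).points
               for d in np.linspace(0, 150, 40)]
        assert all(a >= b for a, b in zip(pts, pts[1:]))
        assert max(pts) == 20


@pytest.fixture(scope="module")
def est_trials(cfg):
    return generate_estimation_trials(13, cfg)


class TestEstimationTrials:
    def test_counts_and_blocks(self, est_trials):
        test = [t for t in est_trials if not t.practice]
        assert len(test) == 36
        assert sum(t.practice for t in est_trials) == 3
        blocks = Counter(t.block for t in test)
        assert blocks == {1: 9, 2: 9, 3: 9, 4: 9}

    def test_factorial_bin_coverage(self, est_trials):
        test = [t for t in est_trials if not t.practice]
        cells = Counter((t.distance_bin, t.direction_bin) for t in test)
        assert len(cells) == 36 and set(cells.values()) == {1}
        dirs = Counter(t.direction_bin for t in test)
        assert all(v == 4 for v in dirs.values())

    @pytest.mark.parametrize("seed", [0, 13, 77])
    def test_distances_and_bins(self, cfg, seed):
        proto = EstimationProtocol()
        edges = proto.distance_bin_edges()
        for t in generate_estimation_trials(seed, cfg):
            if t.practice:
                continue
            assert 20.0 <= t.distance <= 180.0
            assert edges[t.distance_bin - 1] <= t.distance <= edges[t.distance_bin]
            lo = (t.direction_bin - 1) * 40.0
            assert lo <= t.direction <= lo + 40.0

    def test_separation_constraints(self, cfg, est_trials):
        pos = []
        for t in est_trials:
            if not t.practice:
                pos += [t.start, t.goal]
        for p in pos:
            assert 10.0 <= p.q1 <= 190.0 and 10.0 <= p.q2 <= 190.0
        for i, a in enumerate(pos):
            for b in pos[i + 1:]:
                assert euclidean_distance(a, b) >= 10.0 - 1e-9

    def test_determinism(self, cfg):
        assert generate_estimation_trials(5, cfg) == generate_estimation_trials(5, cfg)


class TestSlider:
    @pytest.mark.parametrize("pos, d", [(0, 0.0), (28, 200 * math.sqrt(2)),
                                        (14, 100 * math.sqrt(2))])
    def test_linear_map(self, cfg, pos, d):
        assert slider_to_distance(pos, cfg) == pytest.approx(d)

    def test_round_trip(self, cfg):
        for pos in range(29):
            assert distance_to_slider(slider_to_distance(pos, cfg), cfg) == pos

    def test_out_of_range(self, cfg):
        with pytest.raises(DomainError):
            slider_to_distance(29, cfg)


@pytest.fixture(scope="module")
def fc_trials(cfg):
    return generate_forced_choice_trials(21, cfg)


class TestForcedChoiceTrials:
    def test_battery_counts(self, fc_trials):
        test = [t for t in fc_trials if not t.practice]
        assert len(test) == 216
        sub = Counter(t.subtask for t in test)
        assert sub == {"similarity": 96, "dimensional": 120}
        assert sum(t.practice for t in fc_trials) == 5
        assert Counter(t.block for t in test) == {1: 54, 2: 54, 3: 54, 4: 54}

    def test_similarity_condition_counts(self, fc_trials):
        sim = [t for t in fc_trials if not t.practice and t.subtask == "similarity"]
        per_cond = Counter((t.near_condition, t.far_distortion) for t in sim)
        assert all(v == 16 for v in per_cond.values()) and len(per_cond) == 6
        aligned = Counter(t.colour_aligned for t in sim
                          if t.near_condition == "dissimilar")
        assert aligned == {True: 24, False: 24}

    def test_similarity_geometry(self, cfg, fc_trials):
        for t in fc_trials:
            if t.practice or t.subtask != "similarity":
                continue
            near, far = sorted(
                [euclidean_distance(t.A, t.B), euclidean_distance(t.A, t.C)])
            assert near == pytest.approx(10.0)
            assert far in (pytest.approx(60.0), pytest.approx(90.0),
                           pytest.approx(120.0))
            for dim in (t.A.q1, t.A.q2):
                assert 90.0 <= min(dim, cfg.axis_length - dim) <= 100.0
            assert t.colour_theta in (45.0, 225.0)

    def test_dimensional_condition_counts(self, fc_trials):
        dim = [t for t in fc_trials if not t.practice and t.subtask == "dimensional"]
        corners = Counter(t.corner for t in dim)
        assert corners == {"lower_left": 60, "upper_right": 60}
        scen = Counter((t.corner, t.far_distortion, t.near_dim) for t in dim)
        assert all(v == 10 for v in scen.values()) and len(scen) == 12

    def test_dimensional_margins_and_corners(self, cfg, fc_trials):
        for t in fc_trials:
            if t.practice or t.subtask != "dimensional":
                continue
            assert t.distance_margin in (10.0, 25.0, 50.0)
            for dim in (t.A.q1, t.A.q2):
                assert 4.0 <= min(dim, cfg.axis_length - dim) <= 10.0
            base = (t.colour_theta - 135.0) % 180.0
            assert base <= 10.0 or base >= 170.0  # 135/315 with 10 deg jitter

    def test_correct_label_matches_smaller_distance(self, fc_trials):
        for t in fc_trials:
            d_b = euclidean_distance(t.A, t.B)
            d_c = euclidean_distance(t.A, t.C)
            assert d_b != d_c
            assert t.correct == ("B" if d_b < d_c else "C")

    def test_all_positions_in_bounds_sharing_one_colour(self, cfg, fc_trials):
        for t in fc_trials:
            for p in (t.A, t.B, t.C):
                assert 0 <= p.q1 <= cfg.axis_length
                assert 0 <= p.q2 <= cfg.axis_length
            assert 0.0 <= t.colour_theta < 360.0

    def test_determinism(self, cfg):
        assert (generate_forced_choice_trials(9, cfg)
                == generate_forced_choice_trials(9, cfg))
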