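import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from runvalue.features import (
    FEATURE_NAMES,
    FeatureConfig,
    angle_to_goal,
    build_feature_matrix,
    distance_to_goal,
    pitch_control_areas,
    team_motion_features,
    team_shape_features,
)
from runvalue.pitch import Pitch
from runvalue.trackdata import PlayerMeta, Possession, downsample
from conftest import make_frame_table

GOAL = (52.5, 0.0)


class TestDistanceAndAngle:
    def test_distance_examples(self):
        assert distance_to_goal((0, 0), GOAL) == pytest.approx(52.5)
        assert distance_to_goal(GOAL, GOAL) == 0.0
        # 9-40-41 Pythagorean triple
        assert distance_to_goal((12.5, 9), GOAL) == pytest.approx(41.0)

    def test_angle_printed_anchors(self):
        assert angle_to_goal((0, 0), GOAL) == pytest.approx(math.pi / 2)
        assert angle_to_goal((52.5, 34), GOAL) == pytest.approx(math.pi)

    def test_both_corners_agree(self):
        assert angle_to_goal((52.5, 34), GOAL) == \
            pytest.approx(angle_to_goal((52.5, -34), GOAL))

    def test_goal_centre_degenerate(self):
        assert angle_to_goal(GOAL, GOAL) == pytest.approx(math.pi / 2)

    @given(x=st.floats(-52.5, 52.4), y=st.floats(-34, 34))
    @settings(max_examples=200, deadline=None)
    def test_angle_range(self, x, y):
        a = angle_to_goal((x, y), GOAL)
        assert math.pi / 2 - 1e-9 <= a <= math.pi + 1e-9


class TestTeamShape:
    def test_triangle_centroid_and_hull(self):
        xy = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        gk = np.zeros(3, dtype=bool)
        cx, cy, dist, xdist, nb, hull = team_shape_features(xy, gk, (0, 0), 52.5)
        assert (cx, cy) == (pytest.approx(10 / 3), pytest.approx(10 / 3))
        assert hull == pytest.approx(50.0)

    def test_square_hull(self):
        xy = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], dtype=float)
        gk = np.zeros(4, dtype=bool)
        *_, hull = team_shape_features(xy, gk, (0, 0), 52.5)
        assert hull == pytest.approx(100.0)

    def test_beyond_ball_count(self):
        xy = np.array([[5, 0], [-5, 0], [10, 0]], dtype=float)
        gk = np.zeros(3, dtype=bool)
        *_, nb, _ = team_shape_features(xy, gk, (0, 0), 52.5)
        assert nb == 2

    def test_degenerate_hull_flagged(self):
        xy = np.array([[0, 0], [1, 1]], dtype=float)
        gk = np.zeros(2, dtype=bool)
        *_, hull = team_shape_features(xy, gk, (0, 0), 52.5)
        assert math.isnan(hull)

    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-30, 30)),
                    min_size=3, max_size=10))
    @settings(max_examples=300, deadline=None)
    def test_hull_area_matches_gift_wrapping_oracle(self, pts):
        xy = np.array(pts, dtype=float)
        gk = np.zeros(len(xy), dtype=bool)
        *_, hull = team_shape_features(xy, gk, (0, 0), 52.5)
        expected = _jarvis_hull_area(xy)
        if math.isnan(expected):
            assert math.isnan(hull)
        else:
            assert hull == pytest.approx(expected, abs=1e-6)


def _jarvis_hull_area(pts: np.ndarray) -> float:
    """Independent oracle: gift-wrapping hull + shoelace area."""
    pts = np.unique(pts, axis=0)
    if len(pts) < 3:
        return float("nan")
    start = min(range(len(pts)), key=lambda i: (pts[i][0], pts[i][1]))
    hull = [start]
    while True:
        cur = hull[-1]
        cand = (cur + 1) % len(pts)
        for j in range(len(pts)):
            if j == cur:
                continue
            u = pts[cand] - pts[cur]
            v = pts[j] - pts[cur]
            cross = u[0] * v[1] - u[1] * v[0]
            if cross < 0 or (cross == 0 and
                             np.linalg.norm(pts[j] - pts[cur]) >
                             np.linalg.norm(pts[cand] - pts[cur])):
                cand = j
        if cand == start:
            break
        hull.append(cand)
        if len(hull) > len(pts):
            break
    if len(hull) < 3:
        return float("nan")
    v = pts[hull]
    x, y = v[:, 0], v[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return float("nan") if area < 1e-12 else area


class TestTeamMotion:
    def test_stationary_players(self):
        hist = np.zeros((26, 4, 2))
        d1, d5, ang = team_motion_features(hist)
        assert (d1, d5, ang) == (0.0, 0.0, 0.0)

    def test_straight_line_motion(self):
        t = np.arange(26)[:, None, None]
        hist = np.concatenate([t * 0.4, np.zeros((26, 1, 1))], axis=2)  # 2 m/s at 5 Hz
        d1, d5, ang = team_motion_features(hist)
        assert d1 == pytest.approx(2.0)
        assert d5 == pytest.approx(10.0)
        assert ang == pytest.approx(0.0)

    def test_right_angle_turn_averages_over_team(self):
        n = 4
        hist = np.zeros((11, n, 2))
        # player 0 walks +x for 1 s then +y for 1 s; others stationary
        hist[:6, 0, 0] = np.arange(6)
        hist[6:, 0, 0] = 5
        hist[6:, 0, 1] = np.arange(1, 6)
        d1, d5, ang = team_motion_features(hist, steps_1s=5, steps_5s=25)
        assert ang == pytest.approx((math.pi / 2) / n)


class TestPitchControl:
    def _pitch(self):
        return Pitch()

    def test_mirror_symmetric_split(self):
        pitch = self._pitch()
        a = np.array([[-10.0, 0.0], [-20.0, 5.0]])
        b = -a
        va = np.zeros_like(a)
        area_a, area_b = pitch_control_areas(a, b, va, va, pitch,
                                             FeatureConfig(pc_grid_cell=1.0))
        assert area_a == pytest.approx(area_b)
        assert area_a + area_b == pytest.approx(pitch.area)

    def test_single_players_split_at_midline(self):
        pitch = self._pitch()
        a = np.array([[-10.0, 0.0]])
        b = np.array([[10.0, 0.0]])
        z = np.zeros_like(a)
        cfg = FeatureConfig(pc_grid_cell=1.0)
        area_a, area_b = pitch_control_areas(a, b, z, z, pitch, cfg)
        assert abs(area_a - pitch.area / 2) <= pitch.width * cfg.pc_grid_cell

    def test_area_conservation_random(self):
        pitch = self._pitch()
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = rng.uniform((-50, -30), (50, 30), size=(11, 2))
            b = rng.uniform((-50, -30), (50, 30), size=(11, 2))
            va = rng.normal(size=a.shape)
            vb = rng.normal(size=b.shape)
            area_a, area_b = pitch_control_areas(a, b, va, vb, pitch,
                                                 FeatureConfig(pc_grid_cell=2.0))
            assert area_a + area_b == pytest.approx(pitch.area)

    def test_retreating_team_loses_area(self):
        pitch = self._pitch()
        b = np.array([[10.0, 0.0], [15.0, 5.0]])
        z = np.zeros_like(b)
        cfg = FeatureConfig(pc_grid_cell=2.0)
        spread = np.array([[-10.0, 0.0], [-15.0, -5.0]])
        edge = np.array([[-52.0, -33.0], [-52.0, -30.0]])
        a1, _ = pitch_control_areas(spread, b, z, z, pitch, cfg)
        a2, _ = pitch_control_areas(edge, b, z, z, pitch, cfg)
        assert a2 < a1

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            pitch_control_areas(np.zeros((1, 2)), np.zeros((1, 2)),
                                np.zeros((1, 2)), np.zeros((1, 2)),
                                self._pitch(), FeatureConfig(pc_grid_cell=0))


def _static_toy_match():
    """Two point-symmetric static teams, centred ball, possession flip."""
    ys = [0, 7, -7, 14, -14, 3, -3, 10, -10, 1, -1]
    players_a = {f"A{i:02d}": (-5.0 - 3 * i, float(ys[i])) for i in range(11)}
    players_b = {f"B{i:02d}": (5.0 + 3 * i, -float(ys[i])) for i in range(11)}
    ft = make_frame_table(range(0, 300), players_a, players_b, (0.0, 0.0))
    meta = ([PlayerMeta("A00", "A", "GK")] +
            [PlayerMeta(f"A{i:02d}", "A", "CM") for i in range(1, 11)] +
            [PlayerMeta("B00", "B", "GK")] +
            [PlayerMeta(f"B{i:02d}", "B", "CM") for i in range(1, 11)])
    poss = [Possession("p0", "t0", "A", 0, 149, 0),
            Possession("p1", "t0", "B", 155, 299, 0)]
    pitch = Pitch(attack_directions={("A", 1): 1, ("B", 1): -1})
    return ft, meta, poss, pitch


class TestBuildFeatureMatrix:
    def test_shape_and_exclusions(self, fast_feature_config):
        ft, meta, poss, pitch = _static_toy_match()
        fm = build_feature_matrix(downsample(ft, 5), meta, poss, pitch,
                                  fast_feature_config)
        assert list(fm.X.columns) == FEATURE_NAMES
        # grid frames 0..295; in possession: 0..145 (30) + 155..295 (29)
        assert len(fm) == 59
        assert 150 not in fm.X.index.get_level_values("frame")

    def test_orientation_flips_with_possession(self, fast_feature_config):
        ft, meta, poss, pitch = _static_toy_match()
        fm = build_feature_matrix(downsample(ft, 5), meta, poss, pitch,
                                  fast_feature_config)
        a_frame = fm.X.loc[("t0", 0)]
        b_frame = fm.X.loc[("t0", 200)]
        # with the static point-symmetric layout, team A in possession sees
        # the same in-side geometry as team B does when possession flips
        assert a_frame["in_centroid_x"] == pytest.approx(
            b_frame["in_centroid_x"], abs=1e-9)
        assert a_frame["dist_ball_goal"] == pytest.approx(
            b_frame["dist_ball_goal"], abs=1e-9)

    def test_history_masking_first_five_seconds(self, fast_feature_config):
        ft, meta, poss, pitch = _static_toy_match()
        fm = build_feature_matrix(downsample(ft, 5), meta, poss, pitch,
                                  fast_feature_config)
        frames = fm.X.index.get_level_values("frame")
        assert not fm.mask[frames < 130].any()
        assert fm.mask[frames >= 135].all()

    def test_reflection_invariance_on_simulated_match(self, small_match,
                                                      fast_feature_config):
        f5 = downsample(small_match.frames, 5)
        fm = build_feature_matrix(f5, small_match.players,
                                  small_match.possessions, small_match.pitch,
                                  fast_feature_config)
        refl = f5.copy()
        refl.df["x"] = -refl.df["x"]
        refl.df["y"] = -refl.df["y"]
        swapped = Pitch(attack_directions={
            k: -v for k, v in small_match.pitch.attack_directions.items()})
        fm2 = build_feature_matrix(refl, small_match.players,
                                   small_match.possessions, swapped,
                                   fast_feature_config)
        pd.testing.assert_frame_equal(fm.X, fm2.X)

    def test_displacement_bounded_by_speed_cap(self, small_match,
                                               fast_feature_config):
        f5 = downsample(small_match.frames, 5)
        fm = build_feature_matrix(f5, small_match.players,
                                  small_match.possessions, small_match.pitch,
                                  fast_feature_config).valid()
        cap = small_match.config.max_speed
        assert (fm.X["in_displacement_1s"] <= cap + 0.02).all()
        assert (fm.X["out_displacement_1s"] <= cap + 0.02).all()

    def test_pitch_control_conserves_area(self, small_match, fast_feature_config):
        f5 = downsample(small_match.frames, 5)
        fm = build_feature_matrix(f5, small_match.players,
                                  small_match.possessions, small_match.pitch,
                                  fast_feature_config)
        total = fm.X["in_pitch_control_area"] + fm.X["out_pitch_control_area"]
        assert np.allclose(total, small_match.pitch.area)
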