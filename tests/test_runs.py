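import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from runvalue.runs import (
    RunPhase,
    RunSegment,
    SpeedSeries,
    bucket_run,
    compute_acceleration,
    compute_speed,
    compute_tortuosity,
    count_concurrent_runs,
    derive_high_value_threshold,
    detect_runs,
    run_movement_metrics,
    run_value,
    split_run_by_possession,
)
from runvalue.trackdata import Possession
from runvalue.valuemodel import ValueSeries


def _series(values, match_id="m0", start=0):
    """ValueSeries with identical raw/smoothed values at 5 Hz grid frames."""
    frames = [start + 5 * i for i in range(len(values))]
    idx = pd.MultiIndex.from_arrays([[match_id] * len(values), frames],
                                    names=["match_id", "frame"])
    df = pd.DataFrame({"raw": values, "smoothed": values,
                       "possession_id": "p0"}, index=idx)
    return ValueSeries(df)


def _speed(values, start=0, fps=25.0):
    v = np.asarray(values, dtype=float)
    return SpeedSeries(np.arange(start, start + len(v)), v,
                       np.isfinite(v))


class TestComputeSpeed:
    def test_straight_line_exact(self):
        t = np.arange(50) / 25.0
        pos = np.column_stack([5.0 * t, np.zeros_like(t)])
        ss = compute_speed(pos, np.arange(50))
        assert np.allclose(ss.speed[2:-2], 5.0)
        assert not ss.valid[:2].any() and not ss.valid[-2:].any()

    def test_stationary_zero(self):
        pos = np.zeros((30, 2))
        ss = compute_speed(pos, np.arange(30))
        assert np.allclose(ss.speed[ss.valid], 0.0)

    def test_uniform_circular_motion(self):
        # radius 10 m, omega 0.5 rad/s -> speed 5 m/s; 0.16 s window error < 0.01
        t = np.arange(200) / 25.0
        pos = np.column_stack([10 * np.cos(0.5 * t), 10 * np.sin(0.5 * t)])
        ss = compute_speed(pos, np.arange(200))
        assert np.allclose(ss.speed[ss.valid], 5.0, atol=0.01)

    def test_gap_masks_window(self):
        frames = np.concatenate([np.arange(10), np.arange(20, 30)])
        pos = np.zeros((20, 2))
        ss = compute_speed(pos, frames)
        # each 10-frame segment masks its own two edge frames
        assert not ss.valid[8:12].any()
        assert ss.valid[2:8].all() and ss.valid[12:18].all()


class TestComputeAcceleration:
    def test_constant_speed_zero(self):
        ss = _speed([6.0] * 60)
        gf, a = compute_acceleration(ss)
        assert np.allclose(a[np.isfinite(a)], 0.0)

    def test_linear_ramp(self):
        # 0 -> 4 m/s over 2 s at 25 Hz
        ss = _speed(np.linspace(0, 4, 51))
        gf, a = compute_acceleration(ss)
        assert np.allclose(a[np.isfinite(a)], 2.0)

    def test_single_grid_step_of_one_unit(self):
        v = np.array([2.0] * 10 + [3.0] * 10)
        ss = _speed(v)
        gf, a = compute_acceleration(ss)
        finite = a[np.isfinite(a)]
        assert finite.max() == pytest.approx(5.0)   # 1 m/s over 0.2 s

    def test_first_grid_frame_masked(self):
        ss = _speed([6.0] * 30)
        gf, a = compute_acceleration(ss)
        assert math.isnan(a[0])


class TestComputeTortuosity:
    def test_straight_path_zero(self):
        t = np.arange(125) / 25.0
        pos = np.column_stack([6 * t, np.zeros_like(t)])
        gf, tort = compute_tortuosity(pos, np.arange(125))
        vals = tort[np.isfinite(tort)]
        assert len(vals) and np.allclose(vals, 0.0, atol=1e-9)

    def test_semicircle(self):
        # semicircular arc covered in exactly 3 s: T = 1 - 2/pi
        n = 76  # frames 0..75 = 3 s at 25 Hz
        theta = np.linspace(0, math.pi, n)
        r = 10.0
        pos = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        frames = np.arange(n)
        gf, tort = compute_tortuosity(pos, frames)
        # the window ending at exactly 3 s covers the whole arc
        val = tort[gf == 75][0]
        assert val == pytest.approx(1 - 2 / math.pi, abs=0.01)

    def test_stationary_degenerate_guard(self):
        pos = np.zeros((125, 2))
        gf, tort = compute_tortuosity(pos, np.arange(125))
        assert np.allclose(tort[np.isfinite(tort)], 0.0)

    def test_masked_without_history(self):
        pos = np.zeros((30, 2))
        gf, tort = compute_tortuosity(pos, np.arange(30))
        assert np.isnan(tort).all()

    def test_bounded_below_one(self):
        rng = np.random.default_rng(5)
        pos = np.cumsum(rng.normal(size=(300, 2)), axis=0)
        gf, tort = compute_tortuosity(pos, np.arange(300))
        vals = tort[np.isfinite(tort)]
        assert ((vals >= 0) & (vals < 1)).all()


class TestDetectRuns:
    def test_thirty_frames_is_one_run(self):
        ss = _speed([6.0] * 30)
        runs = detect_runs(ss)
        assert len(runs) == 1
        assert runs[0].n_frames == 30

    def test_twenty_frames_too_short(self):
        ss = _speed([6.0] * 20)
        assert detect_runs(ss) == []

    def test_single_frame_dip_splits(self):
        ss = _speed([6.0] * 30 + [5.0] + [6.0] * 30)
        runs = detect_runs(ss)
        assert len(runs) == 2
        assert [r.n_frames for r in runs] == [30, 30]

    def test_exact_threshold_terminates(self):
        ss = _speed([6.0] * 30 + [5.5] + [6.0] * 10)
        runs = detect_runs(ss)
        assert len(runs) == 1 and runs[0].end_frame == 29

    @given(st.lists(st.floats(0, 10), min_size=30, max_size=120))
    @settings(max_examples=200, deadline=None)
    def test_rescan_oracle(self, values):
        ss = _speed(values)
        runs = detect_runs(ss)
        v = np.asarray(values)
        for r in runs:
            assert r.n_frames >= 25
            assert (v[r.start_frame:r.end_frame + 1] > 5.5).all()
            # maximality
            if r.start_frame > 0:
                assert not v[r.start_frame - 1] > 5.5
            if r.end_frame < len(v) - 1:
                assert not v[r.end_frame + 1] > 5.5
        # every long-enough supra-threshold stretch is found
        above = v > 5.5
        i = 0
        expected = 0
        while i < len(above):
            if above[i]:
                j = i
                while j + 1 < len(above) and above[j + 1]:
                    j += 1
                if j - i + 1 >= 25:
                    expected += 1
                i = j + 1
            else:
                i += 1
        assert len(runs) == expected


class TestRunValue:
    def test_worked_example(self):
        # printed start value 0.0132 and 24-frame mean 0.0462 -> 0.033
        rest = (0.0462 * 24 - 0.0132) / 23
        series = _series([0.0132] + [rest] * 23, start=5)
        phase = RunPhase("r", "in_possession", 1, 122)
        v = run_value(phase, series, "m0")
        assert round(v, 3) == 0.033

    def test_constant_series_zero(self):
        series = _series([0.3] * 10)
        assert run_value(RunPhase("r", "in_possession", 0, 45), series, "m0") \
            == pytest.approx(0.0)

    def test_linear_ramp_half_range(self):
        vals = np.linspace(0, 0.1, 11)
        series = _series(list(vals))
        v = run_value(RunPhase("r", "in_possession", 0, 50), series, "m0")
        assert v == pytest.approx(0.05)

    def test_no_grid_frames_errors(self):
        series = _series([0.1] * 3)
        with pytest.raises(ValueError):
            run_value(RunPhase("r", "in_possession", 1, 3), series, "m0")

    @given(st.integers(0, 1000), st.integers(1, 40), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=300, deadline=None)
    def test_brute_force_oracle(self, start, n_grid, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random(n_grid)
        first_grid = math.ceil(start / 5) * 5
        series = _series(list(vals), start=first_grid)
        end = first_grid + 5 * (n_grid - 1)
        phase = RunPhase("r", "in_possession", start, end)
        got = run_value(phase, series, "m0")
        expected = sum(vals) / len(vals) - vals[0]
        assert got == pytest.approx(expected, abs=1e-12)


class TestThresholdAndBuckets:
    def test_percentile_of_1_to_100(self):
        assert derive_high_value_threshold(range(1, 101)) == pytest.approx(95.05)

    def test_all_equal(self):
        assert derive_high_value_threshold([0.3] * 25) == pytest.approx(0.3)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            derive_high_value_threshold([0.1] * 5)

    def test_bucket_rules(self):
        assert bucket_run(0.033) == "high"
        assert bucket_run(-0.01) == "negative"
        assert bucket_run(0.0) == "positive_negligible"
        assert bucket_run(0.014) == "high"          # boundary is inclusive
        assert bucket_run(0.0139) == "positive_negligible"


def _run(start, end, pid="p1", team="A", match="m0"):
    return RunSegment(f"{match}:{pid}:{start}", match, pid, team, start, end)


class TestPhaseSplitting:
    QS = [Possession("q0", "m0", "A", 0, 100, 0),
          Possession("q1", "m0", "B", 101, 200, 0),
          Possession("q2", "m0", "A", 226, 300, 1)]

    def test_run_inside_own_possession(self):
        phases = split_run_by_possession(_run(10, 60), self.QS)
        assert [(p.phase, p.start_frame, p.end_frame) for p in phases] == \
            [("in_possession", 10, 60)]

    def test_turnover_splits_into_two_phases(self):
        phases = split_run_by_possession(_run(80, 130), self.QS)
        assert [(p.phase, p.start_frame, p.end_frame) for p in phases] == \
            [("in_possession", 80, 100), ("out_of_possession", 101, 130)]

    def test_dead_ball_gap_is_neither(self):
        phases = split_run_by_possession(_run(205, 220), self.QS)
        assert [p.phase for p in phases] == ["neither"]

    @given(st.integers(0, 290), st.integers(25, 100))
    @settings(max_examples=200, deadline=None)
    def test_phases_partition_run(self, start, length):
        run = _run(start, min(start + length, 300))
        phases = split_run_by_possession(run, self.QS)
        total = sum(p.end_frame - p.start_frame + 1 for p in phases)
        assert total == run.n_frames
        cursor = run.start_frame
        for p in phases:
            assert p.start_frame == cursor
            cursor = p.end_frame + 1


class TestMetricsAndConcurrency:
    def test_max_speed_of_run(self):
        ss = _speed([6.0] * 10 + [7.0] * 10 + [6.5] * 10)
        run = _run(0, 29)
        accel = compute_acceleration(ss)
        tort = (np.array([]), np.array([]))
        m = run_movement_metrics(run, ss, accel, tort)
        assert m.max_speed == pytest.approx(7.0)
        assert math.isnan(m.max_tortuosity)

    def test_constant_run_zero_acceleration(self):
        ss = _speed([6.0] * 60)
        run = _run(10, 50)
        m = run_movement_metrics(run, ss, compute_acceleration(ss),
                                 (np.array([]), np.array([])))
        assert m.max_abs_accel == pytest.approx(0.0)

    def test_isolated_run_has_no_concurrency(self):
        runs = [_run(0, 30, "p1"), _run(100, 130, "p2")]
        assert count_concurrent_runs(runs[0], runs) == 0

    def test_simultaneous_runs_count_each_other(self):
        runs = [_run(0, 30, "p1"), _run(0, 30, "p2")]
        assert count_concurrent_runs(runs[0], runs) == 1
        assert count_concurrent_runs(runs[1], runs) == 1

    def test_same_teammate_two_instances_count_twice(self):
        long_run = _run(0, 200, "p1")
        others = [_run(10, 40, "p2"), _run(150, 180, "p2")]
        assert count_concurrent_runs(long_run, [long_run] + others) == 2
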