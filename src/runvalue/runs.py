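"""High-intensity run detection, movement metrics and run valuation.

A high-intensity run is a maximal interval where a player's speed stays
strictly above 5.5 m/s on every 25 Hz frame for at least one second; the
run terminates at the last frame before speed drops to or below the
threshold, and single-frame dips split runs.  Speed is the magnitude of the
per-axis least-squares slope through the five frames centred on the current
frame; acceleration is the backward difference of speed on the 5 Hz grid
with no further smoothing; tortuosity is 1 - (straight-line displacement /
path length) over the trailing 3 s window on the 5 Hz grid.  Run-level
movement metrics are the maxima over the run (absolute value for
acceleration).

The value accrued by a run (or by each constant-possession phase of a run
that spans a turnover) is the mean smoothed goal probability over its
retained 5 Hz grid frames minus the value at its first grid frame; phases
where neither team possesses carry no value.  Values bucket into negative
(V < 0), positive-negligible (0 <= V < threshold) and high (V >= threshold),
with the default threshold 0.014 — the 95th percentile of in-possession run
values in the reference season.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .trackdata import FrameTable, PlayerMeta, Possession
from .valuemodel import ValueSeries

__all__ = [
    "SPEED_THRESHOLD",
    "MIN_RUN_DURATION_S",
    "HIGH_VALUE_THRESHOLD",
    "SpeedSeries",
    "RunSegment",
    "RunPhase",
    "RunMetrics",
    "compute_speed",
    "compute_acceleration",
    "compute_tortuosity",
    "detect_runs",
    "run_movement_metrics",
    "split_run_by_possession",
    "run_value",
    "derive_high_value_threshold",
    "bucket_run",
    "count_concurrent_runs",
    "apply_values",
    "analyse_runs",
]

SPEED_THRESHOLD = 5.5        # m/s, strict ">"
MIN_RUN_DURATION_S = 1.0
HIGH_VALUE_THRESHOLD = 0.014
BUCKETS = ("negative", "positive_negligible", "high")


@dataclass
class SpeedSeries:
    """Per-player speed at 25 Hz with an edge-validity mask."""

    frames: np.ndarray       # global frame indices, strictly increasing
    speed: np.ndarray        # m/s, NaN where invalid
    valid: np.ndarray        # False on window edges / gaps


@dataclass
class RunSegment:
    run_id: str
    match_id: str
    player_id: str
    team_id: str
    start_frame: int
    end_frame: int           # inclusive

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def duration_s(self, fps: float = 25.0) -> float:
        return self.n_frames / fps

    def grid_frames(self, factor: int = 5) -> np.ndarray:
        first = math.ceil(self.start_frame / factor) * factor
        return np.arange(first, self.end_frame + 1, factor)

    def overlaps(self, other: "RunSegment") -> bool:
        return (self.start_frame <= other.end_frame
                and other.start_frame <= self.end_frame)


@dataclass
class RunPhase:
    run_id: str
    phase: str               # "in_possession" | "out_of_possession" | "neither"
    start_frame: int
    end_frame: int

    def grid_frames(self, factor: int = 5) -> np.ndarray:
        first = math.ceil(self.start_frame / factor) * factor
        return np.arange(first, self.end_frame + 1, factor)


@dataclass
class RunMetrics:
    max_speed: float
    max_abs_accel: float
    max_tortuosity: float    # NaN when undefined throughout the run


# ---------------------------------------------------------------------------
# Movement series
# ---------------------------------------------------------------------------

def compute_speed(positions: np.ndarray, frames: np.ndarray,
                  fps: float = 25.0) -> SpeedSeries:
    """Speed from a centred 5-frame regression line, per axis.

    ``positions`` is (n, 2) at 25 Hz, ``frames`` the matching global frame
    indices.  The slope of each coordinate against time over the window
    (2 frames either side) gives the velocity components; speed is their
    magnitude.  The first/last two frames of each contiguous segment are
    masked, as is any window spanning a gap in the frame indices.
    """
    positions = np.asarray(positions, dtype=float)
    frames = np.asarray(frames)
    n = len(frames)
    speed = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    if n == 0:
        return SpeedSeries(frames, speed, valid)
    dt = 1.0 / fps
    gaps = np.flatnonzero(np.diff(frames) != 1)
    starts = np.concatenate([[0], gaps + 1])
    ends = np.concatenate([gaps, [n - 1]])
    for s, e in zip(starts, ends):
        m = e - s + 1
        if m < 5:
            continue
        x = positions[s:e + 1, 0]
        y = positions[s:e + 1, 1]
        # least-squares slope over 5 evenly spaced samples:
        # sum(k * z_{i+k}) / (10 dt), k in {-2..2}
        vx = (2 * (x[4:] - x[:-4]) + (x[3:-1] - x[1:-3])) / (10 * dt)
        vy = (2 * (y[4:] - y[:-4]) + (y[3:-1] - y[1:-3])) / (10 * dt)
        speed[s + 2:e - 1] = np.hypot(vx, vy)
        valid[s + 2:e - 1] = True
    return SpeedSeries(frames, speed, valid)


def compute_acceleration(speed: SpeedSeries, factor: int = 5,
                         fps: float = 25.0) -> Tuple[np.ndarray, np.ndarray]:
    """Backward-difference acceleration on the downsampled grid.

    Returns ``(grid_frames, accel)`` where accel[k] = (s(g_k) - s(g_{k-1}))
    / (factor/fps); the first grid frame of each contiguous stretch is NaN.
    The speeds themselves come from the full-rate series, so the 25 Hz data
    enter implicitly.
    """
    on_grid = (speed.frames % factor == 0) & speed.valid
    gf = speed.frames[on_grid]
    sv = speed.speed[on_grid]
    accel = np.full(len(gf), np.nan)
    if len(gf) > 1:
        step = factor / fps
        contiguous = np.diff(gf) == factor
        accel[1:][contiguous] = np.diff(sv)[contiguous] / step
    return gf, accel


def compute_tortuosity(positions: np.ndarray, frames: np.ndarray,
                       window_s: float = 3.0, factor: int = 5,
                       fps: float = 25.0,
                       min_path: float = 0.5) -> Tuple[np.ndarray, np.ndarray]:
    """Trailing-window tortuosity 1 - L/C on the downsampled grid.

    L is the straight-line distance over the trailing ``window_s`` seconds,
    C the path length summed over grid steps.  Values lie in [0, 1);
    0 when the path is shorter than ``min_path`` (degenerate guard), NaN
    while history is incomplete.  Returns ``(grid_frames, tortuosity)``.
    """
    positions = np.asarray(positions, dtype=float)
    frames = np.asarray(frames)
    on_grid = frames % factor == 0
    gf = frames[on_grid]
    gp = positions[on_grid]
    n = len(gf)
    tort = np.full(n, np.nan)
    steps = int(round(window_s * fps / factor))
    if n == 0 or steps < 1:
        return gf, tort
    seg = np.linalg.norm(np.diff(gp, axis=0), axis=1)
    contiguous = np.diff(gf) == factor
    for i in range(steps, n):
        if not contiguous[i - steps:i].all():
            continue
        path = float(seg[i - steps:i].sum())
        if path < min_path:
            tort[i] = 0.0
        else:
            straight = float(np.linalg.norm(gp[i] - gp[i - steps]))
            tort[i] = 1.0 - straight / path
    return gf, tort


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_runs(speed: SpeedSeries, threshold: float = SPEED_THRESHOLD,
                min_duration_s: float = MIN_RUN_DURATION_S, fps: float = 25.0,
                match_id: str = "", player_id: str = "", team_id: str = "",
                ) -> List[RunSegment]:
    """Maximal intervals with speed strictly above threshold on every frame.

    Intervals shorter than ``min_duration_s`` are dropped; a single frame at
    or below the threshold terminates a run (no dip bridging).
    """
    min_frames = int(round(min_duration_s * fps))
    above = speed.valid & (speed.speed > threshold)
    runs: List[RunSegment] = []
    i, n = 0, len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while (j + 1 < n and above[j + 1]
               and speed.frames[j + 1] == speed.frames[j] + 1):
            j += 1
        length = j - i + 1
        if length >= min_frames:
            rid = f"{match_id}:{player_id}:{int(speed.frames[i])}"
            runs.append(RunSegment(rid, match_id, player_id, team_id,
                                   int(speed.frames[i]), int(speed.frames[j])))
        i = j + 1
    return runs


def run_movement_metrics(run: RunSegment, speed: SpeedSeries,
                         accel: Tuple[np.ndarray, np.ndarray],
                         tort: Tuple[np.ndarray, np.ndarray]) -> RunMetrics:
    """Component-wise maxima over the run (|a| for acceleration)."""
    in_run = (speed.frames >= run.start_frame) & (speed.frames <= run.end_frame)
    max_speed = float(np.nanmax(speed.speed[in_run]))
    gf_a, av = accel
    sel_a = (gf_a >= run.start_frame) & (gf_a <= run.end_frame)
    vals_a = av[sel_a]
    max_acc = float(np.nanmax(np.abs(vals_a))) if np.isfinite(vals_a).any() else float("nan")
    gf_t, tv = tort
    sel_t = (gf_t >= run.start_frame) & (gf_t <= run.end_frame)
    vals_t = tv[sel_t]
    max_tort = float(np.nanmax(vals_t)) if np.isfinite(vals_t).any() else float("nan")
    return RunMetrics(max_speed, max_acc, max_tort)


# ---------------------------------------------------------------------------
# Possession phases and valuation
# ---------------------------------------------------------------------------

def split_run_by_possession(run: RunSegment,
                            possessions: Sequence[Possession]) -> List[RunPhase]:
    """Split a run into maximal constant-possession-phase sub-intervals.

    Phase is "in_possession" where the runner's team controls the ball,
    "out_of_possession" where the opponent does, "neither" in dead-ball
    gaps.  Phases partition the run exactly.
    """
    qs = sorted((q for q in possessions
                 if q.match_id == run.match_id
                 and q.start_frame <= run.end_frame
                 and q.end_frame >= run.start_frame),
                key=lambda q: q.start_frame)
    phases: List[RunPhase] = []

    def add(phase: str, a: int, b: int) -> None:
        if b < a:
            return
        if phases and phases[-1].phase == phase and phases[-1].end_frame == a - 1:
            phases[-1] = RunPhase(run.run_id, phase, phases[-1].start_frame, b)
        else:
            phases.append(RunPhase(run.run_id, phase, a, b))

    cursor = run.start_frame
    for q in qs:
        a = max(q.start_frame, run.start_frame)
        if a > cursor:
            add("neither", cursor, a - 1)
        b = min(q.end_frame, run.end_frame)
        phase = ("in_possession" if q.team_id == run.team_id
                 else "out_of_possession")
        add(phase, a, b)
        cursor = b + 1
    if cursor <= run.end_frame:
        add("neither", cursor, run.end_frame)
    return phases


def run_value(phase: Union[RunPhase, RunSegment], values: ValueSeries,
              match_id: Optional[str] = None, factor: int = 5) -> float:
    """Value accrued over a phase: mean smoothed V over its grid frames
    minus V at its first grid frame.

    For out-of-possession phases the identical number is the opponent value
    accrued — the model output is always the possessing team's probability.
    """
    mid = match_id or getattr(phase, "match_id", None)
    if mid is None:
        raise ValueError("match_id required to look up values")
    gf = phase.grid_frames(factor)
    if len(gf) == 0:
        raise ValueError("phase contains no downsampled grid frames")
    v = values.at_frames(mid, list(gf))
    if len(v) == 0:
        raise ValueError("no frame values available inside the phase")
    arr = v.to_numpy(dtype=float)
    return float(arr.mean() - arr[0])


def derive_high_value_threshold(values: Sequence[float],
                                percentile: float = 95.0) -> float:
    """Empirical percentile (linear interpolation) of in-possession run values."""
    vals = np.asarray(list(values), dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("no values to take a percentile of")
    if len(vals) < 20:
        raise ValueError("need at least 20 values for a stable 95th percentile")
    return float(np.percentile(vals, percentile, method="linear"))


def bucket_run(value: float, threshold: float = HIGH_VALUE_THRESHOLD) -> str:
    """negative (V < 0) | positive_negligible (0 <= V < thr) | high (V >= thr)."""
    if not np.isfinite(value):
        raise ValueError("run value must be finite")
    if value < 0:
        return "negative"
    if value >= threshold:
        return "high"
    return "positive_negligible"


def count_concurrent_runs(run: RunSegment,
                          team_runs: Sequence[RunSegment]) -> int:
    """Teammate run *instances* overlapping this run by >= 1 frame at 25 Hz.

    Counts instances, not distinct teammates: two separate overlapping runs
    by the same teammate count twice.  The player's own runs are excluded.
    """
    return sum(1 for other in team_runs
               if other.player_id != run.player_id
               and other.match_id == run.match_id
               and run.overlaps(other))


# ---------------------------------------------------------------------------
# End-to-end analysis of one or more matches
# ---------------------------------------------------------------------------

RECORD_COLUMNS = [
    "run_id", "phase_id", "match_id", "player_id", "team_id", "position",
    "starter", "start_frame", "end_frame", "phase_start", "phase_end",
    "duration_s", "phase", "value", "bucket", "max_speed", "max_abs_accel",
    "max_tortuosity", "n_concurrent",
]


def apply_values(records: pd.DataFrame, values: ValueSeries,
                 threshold: float = HIGH_VALUE_THRESHOLD,
                 factor: int = 5) -> pd.DataFrame:
    """Fill the value/bucket columns of phase records from a value series.

    Lets the physical analysis (detection, metrics, phases) run before the
    value model exists; valuation is a pure lookup over each phase's grid
    frames.  Neither-phases stay unvalued.
    """
    out = records.copy()
    vals, buckets = [], []
    for r in out.itertuples():
        if r.phase == "neither":
            vals.append(np.nan)
            buckets.append(None)
            continue
        ph = RunPhase(r.run_id, r.phase, int(r.phase_start), int(r.phase_end))
        try:
            v = run_value(ph, values, r.match_id, factor)
            vals.append(v)
            buckets.append(bucket_run(v, threshold))
        except ValueError:
            vals.append(np.nan)
            buckets.append(None)
    out["value"] = vals
    out["bucket"] = buckets
    return out


def analyse_runs(frames25: FrameTable, meta: Sequence[PlayerMeta],
                 possessions: Sequence[Possession],
                 values: Optional[ValueSeries] = None,
                 threshold: float = HIGH_VALUE_THRESHOLD,
                 speed_threshold: float = SPEED_THRESHOLD,
                 min_duration_s: float = MIN_RUN_DURATION_S,
                 factor: int = 5) -> pd.DataFrame:
    """Detect, split, measure and value every run in a 25 Hz frame table.

    Returns one row per run phase (see :data:`RECORD_COLUMNS`).  Neither-
    phases are kept but carry no value or bucket.  If ``values`` is None the
    value/bucket columns stay empty (useful for purely physical summaries).
    """
    fps = frames25.fps
    meta_by_id = {m.player_id: m for m in meta}
    rows = []
    runs_by_team: Dict[Tuple[str, str], List[RunSegment]] = {}
    per_run: List[Tuple[RunSegment, RunMetrics, List[RunPhase]]] = []

    for match_id in frames25.match_ids:
        mdf = frames25.df[(frames25.df["match_id"] == match_id)
                          & (frames25.df["kind"] == "player")]
        for player_id, pdf in mdf.groupby("player_id", sort=True):
            pdf = pdf.sort_values("frame")
            m = meta_by_id.get(str(player_id))
            team_id = m.team_id if m else str(pdf["team_id"].iloc[0])
            frames = pdf["frame"].to_numpy()
            positions = pdf[["x", "y"]].to_numpy(dtype=float)
            speed = compute_speed(positions, frames, fps)
            segs = detect_runs(speed, speed_threshold, min_duration_s, fps,
                               match_id=match_id, player_id=str(player_id),
                               team_id=team_id)
            if not segs:
                continue
            accel = compute_acceleration(speed, factor, fps)
            tort = compute_tortuosity(positions, frames, factor=factor, fps=fps)
            for run in segs:
                metrics = run_movement_metrics(run, speed, accel, tort)
                phases = split_run_by_possession(run, possessions)
                per_run.append((run, metrics, phases))
                runs_by_team.setdefault((match_id, team_id), []).append(run)

    for run, metrics, phases in per_run:
        m = meta_by_id.get(run.player_id)
        conc = count_concurrent_runs(
            run, runs_by_team.get((run.match_id, run.team_id), []))
        for k, ph in enumerate(phases):
            value = np.nan
            bucket = None
            if ph.phase != "neither" and values is not None:
                try:
                    value = run_value(ph, values, run.match_id, factor)
                    bucket = bucket_run(value, threshold)
                except ValueError:
                    value = np.nan
            rows.append((run.run_id, f"{run.run_id}#{k}", run.match_id,
                         run.player_id, run.team_id,
                         m.position if m else None,
                         m.starter if m else None,
                         run.start_frame, run.end_frame,
                         ph.start_frame, ph.end_frame,
                         run.duration_s(frames25.fps), ph.phase, value, bucket,
                         metrics.max_speed, metrics.max_abs_accel,
                         metrics.max_tortuosity, conc))
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)
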