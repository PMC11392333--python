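"""Frame-level features for the goal-probability model.

Each in-possession frame on the 5 Hz grid yields a 22-dimensional vector:
two overall features (ball distance and angle to the attacked goal) plus ten
features per side — team centroid x/y, ball-centroid distance (total and
along the goal-to-goal axis), players beyond the ball line, convex-hull
area, 1 s and 5 s mean displacements, mean angular displacement, and
pitch-control area.  Centroids, hulls and displacement features use the
non-goalkeeper players only; the beyond-ball count includes goalkeepers.

Every frame is oriented so the in-possession team attacks +x (coordinates
are point-reflected through the pitch centre when it attacks -x), which
makes features invariant to reflecting the pitch together with swapping
attack directions.

Frames without the full 5 s of history for the displacement features are
masked rather than zero-filled; training drops masked rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .pitch import Pitch
from .trackdata import FrameTable, PlayerMeta, Possession, annotate_possession

__all__ = [
    "FEATURE_NAMES",
    "FeatureConfig",
    "FeatureMatrix",
    "distance_to_goal",
    "angle_to_goal",
    "team_shape_features",
    "team_motion_features",
    "pitch_control_areas",
    "build_feature_matrix",
]

_SIDE_FEATURES = [
    "centroid_x",
    "centroid_y",
    "dist_ball_centroid",
    "xdist_ball_centroid",
    "n_players_beyond_ball",
    "hull_area",
    "displacement_1s",
    "displacement_5s",
    "angular_displacement_1s",
    "pitch_control_area",
]

#: Canonical, frozen feature order: 2 overall + 10 per side = 22 columns.
FEATURE_NAMES: List[str] = (
    ["dist_ball_goal", "angle_ball_goal"]
    + [f"in_{name}" for name in _SIDE_FEATURES]
    + [f"out_{name}" for name in _SIDE_FEATURES]
)


@dataclass(frozen=True)
class FeatureConfig:
    """Tunables of the feature computation.

    Pitch control uses a velocity-displaced isotropic Gaussian influence per
    player on a square grid: influence is centred at position + velocity*tau
    with spread sigma; a cell belongs to the team with the larger summed
    influence and ties are split half-half.
    """

    pc_grid_cell: float = 1.0    # m
    pc_tau: float = 0.5          # s of velocity projection
    pc_sigma: float = 6.0        # m


@dataclass
class FeatureMatrix:
    """Feature rows for the in-possession 5 Hz frames of one or more matches.

    ``X`` is indexed by (match_id, frame); ``mask`` is True where the full
    history was available (rows to keep for training/prediction).
    """

    X: pd.DataFrame
    mask: pd.Series
    possession_id: pd.Series
    feature_names: List[str] = field(default_factory=lambda: list(FEATURE_NAMES))

    def valid(self) -> "FeatureMatrix":
        keep = self.mask.to_numpy(dtype=bool)
        return FeatureMatrix(self.X.loc[keep], self.mask.loc[keep],
                             self.possession_id.loc[keep], list(self.feature_names))

    def __len__(self) -> int:
        return len(self.X)

    @staticmethod
    def concat(parts: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        return FeatureMatrix(
            pd.concat([p.X for p in parts]),
            pd.concat([p.mask for p in parts]),
            pd.concat([p.possession_id for p in parts]),
            list(parts[0].feature_names),
        )


# ---------------------------------------------------------------------------
# Elementary geometry
# ---------------------------------------------------------------------------

def distance_to_goal(ball_xy: Sequence[float], goal_xy: Sequence[float]) -> float:
    """Planar Euclidean distance from the ball to the goal centre, metres."""
    return float(math.hypot(ball_xy[0] - goal_xy[0], ball_xy[1] - goal_xy[1]))


def angle_to_goal(ball_xy: Sequence[float], goal_xy: Sequence[float],
                  pitch: Optional[Pitch] = None) -> float:
    """Angle (radians) between the ball→goal vector and the goal line.

    The reference direction is the goal-line unit vector pointing from the
    goal centre toward the ball's side of the pitch, so the angle is pi/2
    for a ball level with the goal centre (e.g. the pitch centre) and pi at
    either corner flag.  Range [pi/2, pi]; a ball exactly at the goal centre
    degenerates to pi/2.
    """
    vx = goal_xy[0] - ball_xy[0]
    vy = goal_xy[1] - ball_xy[1]
    dy = ball_xy[1] - goal_xy[1]
    if dy == 0.0:
        return math.pi / 2.0
    norm = math.hypot(vx, vy)
    if norm == 0.0:
        return math.pi / 2.0
    s = 1.0 if dy > 0 else -1.0
    cosang = (vy * s) / norm
    return float(math.acos(np.clip(cosang, -1.0, 1.0)))


# ---------------------------------------------------------------------------
# Per-frame team features
# ---------------------------------------------------------------------------

def _hull_area(points: np.ndarray) -> float:
    """Convex-hull area of a 2-D point set; NaN if degenerate (< 3 points
    or collinear)."""
    pts = points[np.isfinite(points).all(axis=1)]
    if len(pts) < 3:
        return float("nan")
    try:
        return float(ConvexHull(pts).volume)   # .volume is the 2-D area
    except QhullError:
        return float("nan")


def team_shape_features(team_xy: np.ndarray, gk_mask: np.ndarray,
                        ball_xy: Sequence[float],
                        goal_x: float) -> Tuple[float, float, float, float, int, float]:
    """Shape features of one team on one frame.

    ``team_xy`` is (n, 2); ``gk_mask`` flags the goalkeeper(s).  The centroid
    and hull use non-goalkeeper players only; the beyond-ball count includes
    every player strictly between the ball's x-line and the goal line at
    ``goal_x``.  Returns (centroid_x, centroid_y, dist_ball_centroid,
    xdist_ball_centroid, n_players_beyond_ball, hull_area).
    """
    field_xy = team_xy[~gk_mask]
    cx, cy = field_xy[:, 0].mean(), field_xy[:, 1].mean()
    dist = math.hypot(ball_xy[0] - cx, ball_xy[1] - cy)
    xdist = abs(ball_xy[0] - cx)
    lo, hi = sorted((ball_xy[0], goal_x))
    beyond = int(np.sum((team_xy[:, 0] > lo) & (team_xy[:, 0] < hi)))
    return float(cx), float(cy), float(dist), float(xdist), beyond, _hull_area(field_xy)


def team_motion_features(history: np.ndarray, steps_1s: int = 5,
                         steps_5s: int = 25) -> Tuple[float, float, float]:
    """Displacement and angular-displacement features from a position history.

    ``history`` is (t, n_players, 2) on the 5 Hz grid ending at the current
    frame.  Returns the mean 1 s displacement, mean 5 s displacement and
    mean unsigned angle between each player's consecutive 1 s movement
    vectors; players with a zero-length movement vector contribute 0.
    NaN where the history is too short.
    """
    t = history.shape[0]
    if t <= steps_1s:
        return float("nan"), float("nan"), float("nan")
    cur = history[-1]
    d1 = np.linalg.norm(cur - history[-1 - steps_1s], axis=1)
    disp1 = float(np.nanmean(d1))
    if t > steps_5s:
        disp5 = float(np.nanmean(np.linalg.norm(cur - history[-1 - steps_5s], axis=1)))
    else:
        disp5 = float("nan")
    if t > 2 * steps_1s:
        v2 = cur - history[-1 - steps_1s]
        v1 = history[-1 - steps_1s] - history[-1 - 2 * steps_1s]
        ang = _mean_unsigned_angle(v1, v2)
    else:
        ang = float("nan")
    return disp1, disp5, ang


def _mean_unsigned_angle(v1: np.ndarray, v2: np.ndarray) -> float:
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    ok = (n1 > 1e-12) & (n2 > 1e-12)
    angles = np.zeros(len(v1))
    if ok.any():
        cosang = np.einsum("ij,ij->i", v1[ok], v2[ok]) / (n1[ok] * n2[ok])
        angles[ok] = np.arccos(np.clip(cosang, -1.0, 1.0))
    return float(np.mean(angles))


def pitch_control_areas(team_a_xy: np.ndarray, team_b_xy: np.ndarray,
                        vel_a: np.ndarray, vel_b: np.ndarray,
                        pitch: Pitch,
                        config: FeatureConfig = FeatureConfig(),
                        ) -> Tuple[float, float]:
    """Surface area (m²) controlled by each team.

    Each player projects an isotropic Gaussian influence centred at
    position + velocity*tau; every grid cell goes to the team with the
    larger summed influence, ties split half-half, so the two areas always
    sum to the pitch area.
    """
    if config.pc_grid_cell <= 0:
        raise ValueError("grid cell size must be positive")
    xs, ys = _grid_centres(pitch, config.pc_grid_cell)
    inf_a = _influence(team_a_xy + config.pc_tau * vel_a, xs, ys, config.pc_sigma)
    inf_b = _influence(team_b_xy + config.pc_tau * vel_b, xs, ys, config.pc_sigma)
    # actual cell dimensions (the nominal size may not divide the pitch),
    # so the two areas always sum to exactly the pitch area
    cell_area = (pitch.length / len(xs)) * (pitch.width / len(ys))
    a_cells = float(np.sum(inf_a > inf_b))
    b_cells = float(np.sum(inf_b > inf_a))
    ties = inf_a.size - a_cells - b_cells
    return ((a_cells + ties / 2.0) * cell_area,
            (b_cells + ties / 2.0) * cell_area)


def _grid_centres(pitch: Pitch, cell: float) -> Tuple[np.ndarray, np.ndarray]:
    nx = max(1, int(round(pitch.length / cell)))
    ny = max(1, int(round(pitch.width / cell)))
    xs = -pitch.length / 2 + (np.arange(nx) + 0.5) * (pitch.length / nx)
    ys = -pitch.width / 2 + (np.arange(ny) + 0.5) * (pitch.width / ny)
    return xs, ys


def _influence(centres: np.ndarray, xs: np.ndarray, ys: np.ndarray,
               sigma: float) -> np.ndarray:
    centres = centres[np.isfinite(centres).all(axis=1)]
    dx = xs[None, :, None] - centres[:, 0][:, None, None]
    dy = ys[None, None, :] - centres[:, 1][:, None, None]
    return np.exp(-(dx * dx + dy * dy) / (2.0 * sigma * sigma)).sum(axis=0)


# ---------------------------------------------------------------------------
# Feature-matrix builder
# ---------------------------------------------------------------------------

def build_feature_matrix(frames5: FrameTable, meta: Sequence[PlayerMeta],
                         possessions: Sequence[Possession], pitch: Pitch,
                         config: FeatureConfig = FeatureConfig()) -> FeatureMatrix:
    """Compute the 22-column feature matrix on the 5 Hz grid.

    One row per in-possession frame (frames with no team in possession are
    excluded); columns follow :data:`FEATURE_NAMES`.  Rows whose 5 s history
    window is incomplete, or whose hull is degenerate, are masked.
    """
    parts = []
    for match_id in frames5.match_ids:
        parts.append(_build_single_match(frames5.for_match(match_id), meta,
                                         possessions, pitch, config))
    return FeatureMatrix.concat(parts)


def _build_single_match(frames5: FrameTable, meta: Sequence[PlayerMeta],
                        possessions: Sequence[Possession], pitch: Pitch,
                        config: FeatureConfig) -> FeatureMatrix:
    """Vectorised builder: per-team arrays over the whole grid, then per-frame
    in/out assembly by possession.  Only hulls and the pitch-control grid
    evaluation run in (chunked) loops."""
    match_id = frames5.match_ids[0]
    df = frames5.df
    if "possession_team" not in df.columns:
        frames5 = annotate_possession(frames5, [q for q in possessions
                                                if q.match_id == match_id])
        df = frames5.df

    grid = np.sort(pd.unique(df["frame"]))
    frame_pos = {f: i for i, f in enumerate(grid)}
    n_t = len(grid)
    steps_1s = int(round(frames5.fps))          # 1 s on this grid
    steps_5s = 5 * steps_1s

    teams = sorted(pd.unique(df.loc[df["kind"] == "player", "team_id"].dropna()))
    if len(teams) != 2:
        raise ValueError(f"match {match_id}: expected 2 teams, found {teams}")
    gk_ids = {m.player_id for m in meta if m.position == "GK"}

    # (t, n_players, 2) per team, NaN where a player is absent
    pos: Dict[str, np.ndarray] = {}
    gk_masks: Dict[str, np.ndarray] = {}
    for team in teams:
        tdf = df[(df["kind"] == "player") & (df["team_id"] == team)]
        pids = sorted(pd.unique(tdf["player_id"]))
        arr = np.full((n_t, len(pids), 2), np.nan)
        rows = tdf["frame"].map(frame_pos).to_numpy()
        cols = tdf["player_id"].map({p: i for i, p in enumerate(pids)}).to_numpy()
        arr[rows, cols, 0] = tdf["x"].to_numpy(dtype=float)
        arr[rows, cols, 1] = tdf["y"].to_numpy(dtype=float)
        pos[team] = arr
        gk_masks[team] = np.array([p in gk_ids for p in pids])

    bdf = df[df["kind"] == "ball"]
    ball = np.full((n_t, 2), np.nan)
    rows = bdf["frame"].map(frame_pos).to_numpy()
    ball[rows, 0] = bdf["x"].to_numpy(dtype=float)
    ball[rows, 1] = bdf["y"].to_numpy(dtype=float)

    one = df.drop_duplicates("frame").set_index("frame")
    poss_team = one["possession_team"].reindex(grid)
    poss_id = one["possession_id"].reindex(grid)
    period = one["period"].reindex(grid).to_numpy()

    in_poss = poss_team.notna().to_numpy()
    keep = np.flatnonzero(in_poss)
    if len(keep) == 0:
        idx = pd.MultiIndex.from_arrays([[], []], names=["match_id", "frame"])
        return FeatureMatrix(pd.DataFrame(columns=FEATURE_NAMES, index=idx),
                             pd.Series([], index=idx, name="mask", dtype=bool),
                             pd.Series([], index=idx, name="possession_id",
                                       dtype="string"))

    # orientation sign per kept frame: in-possession team attacks +x
    signs = np.empty(len(keep))
    is_a = np.empty(len(keep), dtype=bool)
    pt = poss_team.to_numpy()
    for k, ti in enumerate(keep):
        team_in = str(pt[ti])
        is_a[k] = team_in == teams[0]
        try:
            signs[k] = pitch.attack_direction(team_in, int(period[ti]))
        except KeyError:
            raise ValueError(
                f"match {match_id}: no attack direction for possessing team "
                f"{team_in!r} in period {int(period[ti])}") from None

    half_l = pitch.length / 2.0
    b_or = ball[keep] * signs[:, None]
    d_goal = np.hypot(half_l - b_or[:, 0], b_or[:, 1])
    a_goal = np.array([angle_to_goal(b, (half_l, 0.0), pitch) for b in b_or])

    # per-team blocks, then pick in/out per frame
    blocks: Dict[str, np.ndarray] = {}
    pc_vals = _pitch_control_all(pos[teams[0]][keep], pos[teams[1]][keep],
                                 _grid_velocity(pos[teams[0]])[keep],
                                 _grid_velocity(pos[teams[1]])[keep],
                                 signs, pitch, config)
    for t_i, team in enumerate(teams):
        p = pos[team]
        fld = ~gk_masks[team]
        p_or = p[keep] * signs[:, None, None]
        cx = np.nanmean(p_or[:, fld, 0], axis=1)
        cy = np.nanmean(p_or[:, fld, 1], axis=1)
        dist_bc = np.hypot(b_or[:, 0] - cx, b_or[:, 1] - cy)
        xdist_bc = np.abs(b_or[:, 0] - cx)
        between = (p_or[:, :, 0] > b_or[:, 0][:, None]) & (p_or[:, :, 0] < half_l)
        n_beyond = np.nansum(between, axis=1).astype(float)
        hull = np.array([_hull_area(p[ti][fld]) for ti in keep])
        disp1 = _mean_displacement(p, fld, keep, steps_1s)
        disp5 = _mean_displacement(p, fld, keep, steps_5s)
        ang = _mean_angular(p, fld, keep, steps_1s)
        blocks[team] = np.column_stack([cx, cy, dist_bc, xdist_bc, n_beyond,
                                        hull, disp1, disp5, ang, pc_vals[t_i]])

    in_block = np.where(is_a[:, None], blocks[teams[0]], blocks[teams[1]])
    out_block = np.where(is_a[:, None], blocks[teams[1]], blocks[teams[0]])
    X_arr = np.column_stack([d_goal, a_goal, in_block, out_block])

    ok = np.isfinite(X_arr).all(axis=1)
    ok &= keep >= steps_5s + 1          # full 5 s history from the match start

    index = pd.MultiIndex.from_arrays(
        [[match_id] * len(keep), grid[keep]], names=["match_id", "frame"])
    X = pd.DataFrame(X_arr, columns=FEATURE_NAMES, index=index)
    return FeatureMatrix(X, pd.Series(ok, index=index, name="mask"),
                         pd.Series(poss_id.to_numpy()[keep], index=index,
                                   name="possession_id", dtype="string"))


def _grid_velocity(p: np.ndarray) -> np.ndarray:
    """Finite-difference velocity on the grid; zero at the first frame."""
    v = np.zeros_like(p)
    v[1:] = np.nan_to_num(p[1:] - p[:-1]) * 5.0
    return v


def _mean_displacement(p: np.ndarray, fld: np.ndarray, keep: np.ndarray,
                       steps: int) -> np.ndarray:
    out = np.full(len(keep), np.nan)
    okk = keep >= steps
    ti = keep[okk]
    d = np.linalg.norm(p[ti][:, fld] - p[ti - steps][:, fld], axis=2)
    out[okk] = np.nanmean(d, axis=1)
    return out


def _mean_angular(p: np.ndarray, fld: np.ndarray, keep: np.ndarray,
                  steps: int) -> np.ndarray:
    out = np.full(len(keep), np.nan)
    okk = keep >= 2 * steps
    ti = keep[okk]
    v2 = p[ti][:, fld] - p[ti - steps][:, fld]
    v1 = p[ti - steps][:, fld] - p[ti - 2 * steps][:, fld]
    n1 = np.linalg.norm(v1, axis=2)
    n2 = np.linalg.norm(v2, axis=2)
    dot = np.einsum("fpi,fpi->fp", v1, v2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = dot / (n1 * n2)
    ang = np.arccos(np.clip(cosang, -1.0, 1.0))
    ang[(n1 <= 1e-12) | (n2 <= 1e-12)] = 0.0   # zero-length vectors contribute 0
    out[okk] = np.nanmean(ang, axis=1)
    return out


def _pitch_control_all(pa: np.ndarray, pb: np.ndarray, va: np.ndarray,
                       vb: np.ndarray, signs: np.ndarray, pitch: Pitch,
                       config: FeatureConfig,
                       chunk: int = 64) -> Tuple[np.ndarray, np.ndarray]:
    """Pitch-control areas for many frames at once (chunked).

    Areas are reflection-invariant, so the orientation signs only matter in
    that they don't: positions are used as-is.
    """
    xs, ys = _grid_centres(pitch, config.pc_grid_cell)
    cell_area = (pitch.length / len(xs)) * (pitch.width / len(ys))
    n = pa.shape[0]
    area_a = np.empty(n)
    area_b = np.empty(n)
    two_s2 = 2.0 * config.pc_sigma ** 2
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        inf = []
        for p, v in ((pa, va), (pb, vb)):
            c = p[lo:hi] + config.pc_tau * v[lo:hi]          # (f, np, 2)
            # separable Gaussian: exp(-(dx²+dy²)) = exp(-dx²)·exp(-dy²)
            dx = xs[None, None, :] - c[..., 0][:, :, None]
            dy = ys[None, None, :] - c[..., 1][:, :, None]
            gx = np.exp(-dx * dx / two_s2)
            gy = np.exp(-dy * dy / two_s2)
            gx = np.where(np.isfinite(gx), gx, 0.0)
            gy = np.where(np.isfinite(gy), gy, 0.0)
            inf.append(np.einsum("fpx,fpy->fxy", gx, gy))    # (f, nx, ny)
        gt = (inf[0] > inf[1]).sum(axis=(1, 2)).astype(float)
        lt = (inf[1] > inf[0]).sum(axis=(1, 2)).astype(float)
        ties = inf[0].shape[1] * inf[0].shape[2] - gt - lt
        area_a[lo:hi] = (gt + ties / 2.0) * cell_area
        area_b[lo:hi] = (lt + ties / 2.0) * cell_area
    return area_a, area_b
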