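"""Synthetic match generator with ground truth for every downstream stage.

Real tracking feeds (22 players + ball at 25 Hz, possession annotations,
rare goal outcomes, heavy-tailed sprint durations) are proprietary, so this
module generates matches with the same statistical structure plus the
generative truth needed to test the pipeline:

* players follow mean-reverting (Ornstein-Uhlenbeck-style) noise around
  formation anchors that shift with the ball, with non-sprint speed hard
  capped at three times the movement-noise scale;
* sprint events override the noise with a constant-heading (optionally
  arced) speed profile — ramp, plateau at the logged target speed, decay;
* the ball tracks a pass target on the possessing team, preferring players
  advanced toward the attacked goal;
* each second of possession a goal may *fire* with a logistic hazard in
  ball distance-to-goal; fires are latent draws that set the possession's
  outcome without altering its course, so possession lengths stay
  independent of the outcome.  Possessions end per tick in a turnover or a
  dead ball followed by a possession-free gap; they are always split on
  dead balls and carry a binary goal outcome.

The logged ground truth holds the injected sprint intervals, the per-tick
goal hazard, the per-tick generative goal probability (the probability any
remaining tick of the possession fires — exactly calibrated against the
recorded outcomes by construction), and the possession outcomes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterator, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .pitch import Pitch
from .trackdata import (
    FrameTable,
    PlayerMeta,
    Possession,
    annotate_possession,
    write_metadata,
    write_tracking,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SyntheticMatch",
    "simulate_match",
    "simulate_batch",
    "truth_summary",
    "write_match",
    "DEFAULT_FORMATION",
]

# Formation anchors for a team attacking +x (mirrored for the other team).
# One GK, 2 CB, 2 FB, 3 CM, 2 W, 1 F — a 4-3-3.
DEFAULT_FORMATION: Tuple[Tuple[str, float, float], ...] = (
    ("GK", -48.0, 0.0),
    ("CB", -35.0, -8.0),
    ("CB", -35.0, 8.0),
    ("FB", -32.0, -24.0),
    ("FB", -32.0, 24.0),
    ("CM", -15.0, -12.0),
    ("CM", -15.0, 12.0),
    ("CM", -10.0, 0.0),
    ("W", 5.0, -22.0),
    ("W", 5.0, 22.0),
    ("F", 12.0, 0.0),
)


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of a synthetic match.

    Rates and scales are chosen to mirror elite-football tracking data:
    roughly 0.6 sprint events per player per minute, sprint durations with a
    heavy right tail and a 1-2 s mode, short possessions split by dead balls, and goal hazards small enough that goals stay rare events.
    """

    n_players_per_team: int = 11
    formation: Tuple[Tuple[str, float, float], ...] = DEFAULT_FORMATION
    duration_s: float = 600.0
    fps: float = 25.0
    noise_scale: float = 1.5            # typical non-sprint speed, m/s
    max_speed: float = 9.5              # hard cap on any player speed, m/s
    sprint_rate: float = 0.6            # events per player per minute
    sprint_speed_range: Tuple[float, float] = (5.0, 9.4)   # m/s
    sprint_duration_lognorm: Tuple[float, float] = (0.4, 0.6)  # mu, sigma of log s
    sprint_duration_bounds: Tuple[float, float] = (0.7, 10.0)  # s
    sprint_curved_fraction: float = 0.25
    sprint_ramp_s: float = 0.5
    possession_mean_length_s: float = 12.0
    deadball_fraction: float = 0.4      # share of non-goal endings that are dead balls
    deadball_gap_mean_s: float = 4.0
    hazard_intercept: float = -1.6
    hazard_slope: float = -0.30         # per metre of ball distance-to-goal
    ball_max_speed: float = 14.0
    attack_push_m: float = 8.0          # forward anchor shift of the possessing team
    defence_retreat_m: float = 4.0      # backward shift of the defending team
    penetration_prob: float = 0.10      # chance a pass targets the box instead of a player
    penetration_follow: float = 0.5     # chance the NEXT pass stays in the box (sustained attack)
    possession_age_scale_s: float = 15.0  # end hazard grows with possession age on this scale
    line_height_sd_m: float = 8.0       # stationary spread of each team's slow line drift
    line_height_tau_s: float = 30.0     # timescale of the line drift
    pitch_length: float = 105.0
    pitch_width: float = 68.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("frame rate must be positive")
        for name in ("sprint_rate", "noise_scale", "possession_mean_length_s",
                     "deadball_gap_mean_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if len(self.formation) != self.n_players_per_team:
            raise ValueError("formation must list one anchor per player")
        # the hazard must be a probability for any on-pitch distance
        worst = _sigmoid(self.hazard_intercept)
        if not (0.0 < worst < 1.0):
            raise ValueError("goal hazard must lie in (0, 1)")


@dataclass
class GroundTruth:
    """What the generator injected, for scoring the pipeline against."""

    sprints: pd.DataFrame      # match_id, player_id, team_id, start/end_frame, target_speed, curved
    ticks: pd.DataFrame        # match_id, frame, possession_id, hazard, p_goal
    possessions: List[Possession]


@dataclass
class SyntheticMatch:
    match_id: str
    frames: FrameTable         # 25 Hz, possession-annotated
    players: List[PlayerMeta]
    possessions: List[Possession]
    truth: GroundTruth
    pitch: Pitch
    config: SimConfig


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


def _sample_sprints(cfg: SimConfig, rng: np.random.Generator,
                    n_players: int) -> List[List[Tuple[float, float, float, bool]]]:
    """Per player: list of (plateau_start_s, plateau_dur_s, target_speed, curved)."""
    ramp = cfg.sprint_ramp_s
    lo_d, hi_d = cfg.sprint_duration_bounds
    out: List[List[Tuple[float, float, float, bool]]] = []
    for _ in range(n_players):
        lam = cfg.sprint_rate * cfg.duration_s / 60.0
        n = rng.poisson(lam) if lam > 0 else 0
        events = []
        for _ in range(n):
            start = rng.uniform(2.0, max(2.5, cfg.duration_s - hi_d - 2 * ramp))
            dur = float(np.clip(rng.lognormal(*cfg.sprint_duration_lognorm), lo_d, hi_d))
            speed = rng.uniform(*cfg.sprint_speed_range)
            curved = bool(rng.random() < cfg.sprint_curved_fraction)
            events.append((start, dur, speed, curved))
        events.sort()
        kept: List[Tuple[float, float, float, bool]] = []
        last_end = -math.inf
        for ev in events:
            if ev[0] - ramp > last_end + 0.2:   # no overlap incl. ramps
                kept.append(ev)
                last_end = ev[0] + ev[1] + ramp
        out.append(kept)
    return out


def simulate_match(config: SimConfig, seed: int, match_id: str = "m000") -> SyntheticMatch:
    """Generate one synthetic match.  Same ``(config, seed)`` ⇒ identical output."""
    cfg = config
    if cfg.duration_s < 10.0:
        raise ValueError("match duration must be at least 10 s (5-s history features)")
    rng = np.random.default_rng(seed)
    fps = cfg.fps
    dt = 1.0 / fps
    n_frames = int(round(cfg.duration_s * fps))
    tick_every = int(round(fps))            # one possession tick per second
    n_side = cfg.n_players_per_team
    n_play = 2 * n_side

    team_ids = ("home", "away")
    pitch = Pitch(cfg.pitch_length, cfg.pitch_width,
                  {("home", 1): 1, ("away", 1): -1})
    half_l, half_w = cfg.pitch_length / 2.0, cfg.pitch_width / 2.0
    dirs = np.repeat([1.0, -1.0], n_side)          # attack direction per player
    team_of = np.repeat([0, 1], n_side)
    gk_damp = np.tile([0.2 if lab == "GK" else 1.0
                       for lab, _, _ in config.formation], 2)

    labels = [lab for lab, _, _ in cfg.formation]
    base = np.array([[x, y] for _, x, y in cfg.formation])
    anchors0 = np.vstack([base, base * -1.0])      # away mirrored through centre

    players = [
        PlayerMeta(f"{team_ids[t]}_{i:02d}", team_ids[t], labels[i], True)
        for t in (0, 1) for i in range(n_side)
    ]
    player_ids = [p.player_id for p in players]

    # --- sprint speed profiles -------------------------------------------
    sprints = _sample_sprints(cfg, rng, n_play)
    profile = np.zeros((n_frames, n_play))
    curved_omega = np.zeros(n_play)                # filled at activation
    sprint_log: List[Tuple[str, str, int, int, float, bool]] = []
    ramp_f = int(round(cfg.sprint_ramp_s * fps))
    event_curved: Dict[Tuple[int, int], bool] = {}
    for j, events in enumerate(sprints):
        for (start_s, dur_s, speed, curved) in events:
            s0 = int(round(start_s * fps))
            s1 = min(int(round((start_s + dur_s) * fps)), n_frames - 1)
            if s1 - s0 < 2:
                continue
            r0 = max(s0 - ramp_f, 0)
            r1 = min(s1 + ramp_f, n_frames - 1)
            if ramp_f > 0:
                profile[r0:s0, j] = speed * np.linspace(0, 1, s0 - r0, endpoint=False)
                profile[s1 + 1:r1 + 1, j] = speed * np.linspace(1, 0, r1 - s1,
                                                                endpoint=False)
            profile[s0:s1 + 1, j] = speed
            event_curved[(j, r0)] = curved
            sprint_log.append((match_id, player_ids[j], s0, s1, speed, curved))

    # --- state -----------------------------------------------------------
    pos = anchors0 + rng.normal(scale=2.0, size=(n_play, 2))
    vel = rng.normal(scale=cfg.noise_scale / math.sqrt(2.0), size=(n_play, 2))
    heading = np.zeros((n_play, 2))
    sprinting_prev = np.zeros(n_play, dtype=bool)
    ball = np.array([0.0, 0.0])
    ball_target = 10                                 # player index; -1 = virtual point
    target_point = np.array([0.0, 0.0])
    line_off = rng.normal(scale=cfg.line_height_sd_m, size=2)
    line_sigma = cfg.line_height_sd_m * math.sqrt(2.0 / cfg.line_height_tau_s)

    ar = 0.95                                        # AR(1) velocity memory
    eta = cfg.noise_scale / math.sqrt(2.0) * math.sqrt(1 - ar * ar)
    nonsprint_cap = min(3.0 * cfg.noise_scale, cfg.max_speed)
    k_anchor = 2.5                                   # pull toward anchor, 1/s
    gamma_shift = 0.25                               # formation shift with ball
    noise = rng.normal(size=(n_frames, n_play, 2)) * eta

    e_tick = min(0.999, 1.0 / max(cfg.possession_mean_length_s, 1.0))
    poss_team = 0                                    # home starts
    poss_start = 0
    gap_left = 0
    retarget_left = 0

    pos_hist = np.empty((n_frames, n_play, 2))
    ball_hist = np.empty((n_frames, 2))
    possessions: List[Possession] = []
    tick_rows: List[Tuple[int, int, float]] = []     # frame, possession idx, hazard
    pending_goal = False

    def close_possession(end_frame: int, goal: int) -> None:
        nonlocal poss_start
        idx = len(possessions)
        possessions.append(Possession(
            f"{match_id}_p{idx:03d}", match_id, team_ids[poss_team],
            poss_start, end_frame, goal))

    for f in range(n_frames):
        in_gap = gap_left > 0

        # ---- possession tick --------------------------------------------
        # The goal draw is latent: a fire marks the possession as scoring
        # but play runs on to the possession's natural end, so possession
        # lengths are independent of the outcome and the per-tick goal
        # probability 1 - prod(1 - h_k) over the remaining ticks is exactly
        # calibrated against the recorded outcomes.
        if not in_gap and f % tick_every == 0 and f > poss_start:
            goal_x = dirs[poss_team * n_side] * half_l
            dist = float(np.hypot(goal_x - ball[0], ball[1]))
            h = _sigmoid(cfg.hazard_intercept + cfg.hazard_slope * dist)
            tick_rows.append((f, len(possessions), h))
            if rng.random() < h:
                pending_goal = True
            age_s = (f - poss_start) / fps
            e_now = min(0.5, e_tick * (1.0 + age_s / cfg.possession_age_scale_s))
            if rng.random() < e_now:                 # possession ends now
                goal = int(pending_goal)
                pending_goal = False
                close_possession(f, goal)
                if goal or rng.random() < cfg.deadball_fraction:
                    gap_left = max(tick_every,
                                   int(rng.exponential(cfg.deadball_gap_mean_s) * fps))
                    poss_team = (1 - poss_team if goal
                                 else int(rng.random() < 0.5))
                    poss_start = f + gap_left + 1
                    if goal:
                        ball = np.array([0.0, 0.0])  # restart from centre
                else:                                # live turnover
                    poss_team = 1 - poss_team
                    poss_start = f + 1
                retarget_left = 0
                ball_target = max(ball_target, 0)    # leave deep-attack mode

        # ---- ball --------------------------------------------------------
        if gap_left > 0:
            gap_left -= 1
        else:
            if retarget_left <= 0:
                p_pen = (cfg.penetration_follow if ball_target == -1
                         else cfg.penetration_prob)
                if rng.random() < p_pen:
                    # through-ball toward the attacked goal mouth; attacks
                    # dwell there (longer hold, likely deep follow-up pass)
                    gx = dirs[poss_team * n_side] * half_l
                    depth = abs(rng.normal(8.0, 4.0))
                    target_point = np.array([
                        gx - dirs[poss_team * n_side] * depth,
                        float(np.clip(rng.normal(0.0, 12.0), -half_w + 1, half_w - 1)),
                    ])
                    ball_target = -1
                    retarget_left = max(1, int((1.0 + rng.exponential(3.0)) * fps))
                else:
                    side = slice(poss_team * n_side, (poss_team + 1) * n_side)
                    adv = dirs[side] * pos[side, 0]
                    w = np.exp(0.08 * adv)
                    w /= w.sum()
                    ball_target = poss_team * n_side + int(rng.choice(n_side, p=w))
                    retarget_left = max(1, int(rng.exponential(2.5) * fps))
            retarget_left -= 1
            tgt = target_point if ball_target < 0 else pos[ball_target]
            to_target = tgt - ball
            d = float(np.hypot(*to_target))
            if d > 1e-9:
                step = min(cfg.ball_max_speed * dt, 0.3 * d)
                ball = ball + to_target / d * step
        ball = np.clip(ball, (-half_l, -half_w), (half_l, half_w))
        ball_hist[f] = ball

        # ---- players ----------------------------------------------------
        # slow per-team line-height drift (teams choose high/low blocks
        # independently of the instant ball position)
        line_off += (-line_off / cfg.line_height_tau_s * dt
                     + line_sigma * math.sqrt(dt) * rng.normal(size=2))
        anchors = anchors0 + gamma_shift * ball
        anchors[:, 0] += line_off[team_of] * dirs * gk_damp
        if gap_left <= 0:
            # possessing team pushes toward the attacked goal, defenders drop
            attacking = team_of == poss_team
            shift = np.where(attacking, cfg.attack_push_m, -cfg.defence_retreat_m)
            shift = shift * dirs * gk_damp
            anchors[:, 0] += shift
        anchors[:, 0] = np.clip(anchors[:, 0], -half_l + 1, half_l - 1)
        anchors[:, 1] = np.clip(anchors[:, 1], -half_w + 1, half_w - 1)

        vel = ar * vel + k_anchor * (anchors - pos) * dt * (1 - ar) * 10 + noise[f]
        speed_now = np.hypot(vel[:, 0], vel[:, 1])
        over = speed_now > nonsprint_cap
        if over.any():
            vel[over] *= (nonsprint_cap / speed_now[over])[:, None]

        spr = profile[f] > 0
        newly = spr & ~sprinting_prev
        for j in np.flatnonzero(newly):
            target_pt = rng.uniform((-0.7 * half_l, -0.7 * half_w),
                                    (0.7 * half_l, 0.7 * half_w))
            v = target_pt - pos[j]
            nv = float(np.hypot(*v))
            heading[j] = v / nv if nv > 1e-9 else np.array([dirs[j], 0.0])
            if event_curved.get((j, f), False):
                curved_omega[j] = rng.uniform(0.25, 0.7) * (1 if rng.random() < 0.5 else -1)
            else:
                curved_omega[j] = 0.0
        sprinting_prev = spr

        if spr.any():
            idx = np.flatnonzero(spr)
            om = curved_omega[idx] * dt
            c, s = np.cos(om), np.sin(om)
            hx = c * heading[idx, 0] - s * heading[idx, 1]
            hy = s * heading[idx, 0] + c * heading[idx, 1]
            heading[idx, 0], heading[idx, 1] = hx, hy
            # reflect heading off the pitch boundary (0.5 m margin)
            nxt = pos[idx] + heading[idx] * (profile[f, idx, None] * dt)
            flip_x = np.abs(nxt[:, 0]) > half_l - 0.5
            flip_y = np.abs(nxt[:, 1]) > half_w - 0.5
            heading[idx[flip_x], 0] *= -1
            heading[idx[flip_y], 1] *= -1
            vel[idx] = heading[idx] * profile[f, idx, None]

        pos = pos + vel * dt
        np.clip(pos[:, 0], -half_l, half_l, out=pos[:, 0])
        np.clip(pos[:, 1], -half_w, half_w, out=pos[:, 1])
        pos_hist[f] = pos

    if poss_start < n_frames and gap_left <= 0:
        close_possession(n_frames - 1, int(pending_goal))

    # --- generative goal probability per tick ----------------------------
    tick_df = _tick_probabilities(tick_rows, possessions, e_tick, match_id)

    frames = _to_frame_table(match_id, pos_hist, ball_hist, player_ids,
                             [p.team_id for p in players], fps)
    frames = annotate_possession(frames, possessions)

    sprints_df = pd.DataFrame(
        [(m, pid, pid.split("_")[0], s0, s1, sp, cu)
         for (m, pid, s0, s1, sp, cu) in sprint_log],
        columns=["match_id", "player_id", "team_id", "start_frame", "end_frame",
                 "target_speed", "curved"],
    ).sort_values(["player_id", "start_frame"]).reset_index(drop=True)

    truth = GroundTruth(sprints=sprints_df, ticks=tick_df, possessions=possessions)
    return SyntheticMatch(match_id, frames, players, possessions, truth, pitch, cfg)


def _tick_probabilities(tick_rows: Sequence[Tuple[int, int, float]],
                        possessions: Sequence[Possession],
                        e_tick: float, match_id: str) -> pd.DataFrame:
    """Per-tick generative goal probability along each possession's realised
    hazard sequence: P_j = 1 - prod_{k>=j} (1 - h_k) over the possession's
    remaining ticks.  Because goal fires never alter the possession's course
    (they only set its outcome), this is the exact conditional probability
    the outcome ends up 1 given the state at tick j."""
    rows = []
    by_poss: Dict[int, List[Tuple[int, float]]] = {}
    for frame, pidx, h in tick_rows:
        by_poss.setdefault(pidx, []).append((frame, h))
    for pidx, seq in by_poss.items():
        seq.sort()
        hs = [h for _, h in seq]
        p_next = 0.0
        ps = [0.0] * len(hs)
        for j in range(len(hs) - 1, -1, -1):
            ps[j] = 1.0 - (1.0 - hs[j]) * (1.0 - p_next)
            p_next = ps[j]
        pid = (possessions[pidx].possession_id
               if pidx < len(possessions) else f"{match_id}_p{pidx:03d}")
        for (frame, h), p in zip(seq, ps):
            rows.append((match_id, frame, pid, h, p))
    return pd.DataFrame(rows, columns=["match_id", "frame", "possession_id",
                                       "hazard", "p_goal"]).sort_values("frame")


def _to_frame_table(match_id: str, pos_hist: np.ndarray, ball_hist: np.ndarray,
                    player_ids: List[str], team_ids: List[str],
                    fps: float) -> FrameTable:
    n_frames, n_play, _ = pos_hist.shape
    per_frame = n_play + 1
    frames = np.repeat(np.arange(n_frames), per_frame)
    kinds = np.tile(["ball"] + ["player"] * n_play, n_frames)
    pids = np.tile([None] + player_ids, n_frames)
    tids = np.tile([None] + team_ids, n_frames)
    xy = np.concatenate([ball_hist[:, None, :], pos_hist], axis=1).reshape(-1, 2)
    df = pd.DataFrame({
        "match_id": pd.array([match_id] * len(frames), dtype="string"),
        "period": 1,
        "frame": frames,
        "time_s": np.round(frames / fps, 6),
        "kind": pd.array(kinds, dtype="string"),
        "team_id": pd.array(tids, dtype="string"),
        "player_id": pd.array(pids, dtype="string"),
        "x": np.round(xy[:, 0], 4),
        "y": np.round(xy[:, 1], 4),
    })
    return FrameTable(df, fps=fps)


def simulate_batch(config: SimConfig, n_matches: int,
                   seed: int) -> Iterator[SyntheticMatch]:
    """Yield ``n_matches`` independent matches with derived per-match seeds."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_matches)
    for i, child in enumerate(children):
        sub = int(child.generate_state(1)[0] % (2 ** 31 - 1))
        yield simulate_match(config, sub, match_id=f"m{i:03d}")


# ---------------------------------------------------------------------------
# Calibration against ground truth
# ---------------------------------------------------------------------------

def truth_summary(truth: GroundTruth, predictions: pd.Series,
                  n_bins: int = 10) -> pd.DataFrame:
    """Reliability table of predictions against realised possession outcomes.

    ``predictions`` is a probability series indexed like ``truth.ticks``
    (by ``(match_id, frame)`` or by ``frame`` for a single match).  Bins are
    equal-width on [0, 1]; each row reports (bin_lo, bin_hi, mean predicted
    probability, empirical goal fraction, n).  Row counts sum to the number
    of overlapping ticks.
    """
    ticks = truth.ticks
    outcome_by_pid = {q.possession_id: q.goal for q in truth.possessions}
    if isinstance(predictions.index, pd.MultiIndex):
        key = list(zip(ticks["match_id"], ticks["frame"]))
    else:
        key = ticks["frame"].tolist()
    pred = predictions.reindex(key).to_numpy(dtype=float)
    mask = np.isfinite(pred)
    if not mask.any():
        raise ValueError("predictions do not overlap the ground-truth ticks")
    pred = pred[mask]
    outcomes = ticks["possession_id"].map(outcome_by_pid).to_numpy(dtype=float)[mask]

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(pred, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        n = int(sel.sum())
        if n == 0:
            continue
        rows.append((edges[b], edges[b + 1], float(pred[sel].mean()),
                     float(outcomes[sel].mean()), n))
    return pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "mean_pred",
                                       "empirical", "n"])


# ---------------------------------------------------------------------------
# Disk output
# ---------------------------------------------------------------------------

def write_match(match: SyntheticMatch, outdir: Union[str, Path]) -> None:
    """Write the three interchange CSVs plus the ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tracking(match.frames, outdir / "tracking.csv")
    write_metadata(match.players, match.possessions,
                   outdir / "players.csv", outdir / "possessions.csv")
    truth = {
        "match_id": match.match_id,
        "sprints": match.truth.sprints.to_dict(orient="records"),
        "ticks": match.truth.ticks.to_dict(orient="records"),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
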