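"""Tracking-data model: frame tables, metadata, validation and downsampling.

The interchange format is a long CSV with one row per tracked object per
frame (22 players + the ball at 25 Hz).  Possessions are closed frame
intervals carrying a binary goal outcome; they never overlap within a match
because dead balls always terminate a possession.

Frame indices are 0-based and global within a match (periods partition the
index range); intervals are closed on both ends.  Downsampling keeps the
frames whose *global* index is a multiple of the factor, so the number of
retained frames inside a run depends on how the run aligns with the grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .pitch import Pitch

__all__ = [
    "TRACKING_COLUMNS",
    "POSITION_LABELS",
    "FrameTable",
    "PlayerMeta",
    "Possession",
    "ValidationIssue",
    "ValidationReport",
    "SchemaError",
    "IntegrityError",
    "read_tracking",
    "write_tracking",
    "read_metadata",
    "write_metadata",
    "downsample",
    "validate",
    "annotate_possession",
    "retained_frame_count",
]

TRACKING_COLUMNS = [
    "match_id",
    "period",
    "frame",
    "time_s",
    "kind",
    "team_id",
    "player_id",
    "x",
    "y",
]

POSITION_LABELS = ("GK", "CB", "FB", "CM", "W", "F")


class SchemaError(ValueError):
    """A file does not conform to the interchange schema."""


class IntegrityError(ValueError):
    """Parsed data violates a structural invariant (e.g. overlapping possessions)."""


@dataclass
class FrameTable:
    """Long-format per-frame positions of all players and the ball.

    ``df`` holds one row per object per frame with the canonical columns
    :data:`TRACKING_COLUMNS`; ball rows have null ``team_id``/``player_id``.
    ``fps`` is the sampling rate in Hz.  After :func:`annotate_possession`
    the frame also carries ``possession_team`` / ``possession_id`` columns
    (null outside any possession).
    """

    df: pd.DataFrame
    fps: float = 25.0

    def __post_init__(self) -> None:
        missing = [c for c in TRACKING_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"FrameTable missing columns: {missing}")

    @property
    def match_ids(self) -> List[str]:
        return list(pd.unique(self.df["match_id"]))

    def frames(self, match_id: Optional[str] = None) -> np.ndarray:
        df = self.df if match_id is None else self.df[self.df["match_id"] == match_id]
        return np.sort(pd.unique(df["frame"]))

    @property
    def n_frames(self) -> int:
        return self.df.groupby("match_id")["frame"].nunique().sum()

    def for_match(self, match_id: str) -> "FrameTable":
        return FrameTable(self.df[self.df["match_id"] == match_id].copy(), fps=self.fps)

    def copy(self) -> "FrameTable":
        return FrameTable(self.df.copy(), fps=self.fps)


@dataclass(frozen=True)
class PlayerMeta:
    player_id: str
    team_id: str
    position: str
    starter: bool = True

    def __post_init__(self) -> None:
        if self.position not in POSITION_LABELS:
            raise SchemaError(
                f"unknown position label {self.position!r}; expected one of {POSITION_LABELS}"
            )


@dataclass(frozen=True)
class Possession:
    """A team's control interval [start_frame, end_frame] with goal outcome."""

    possession_id: str
    match_id: str
    team_id: str
    start_frame: int
    end_frame: int
    goal: int

    def __post_init__(self) -> None:
        if self.goal not in (0, 1):
            raise SchemaError(f"possession outcome must be 0 or 1, got {self.goal!r}")
        if self.end_frame < self.start_frame:
            raise IntegrityError(
                f"possession {self.possession_id}: end before start "
                f"({self.start_frame}..{self.end_frame})"
            )

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass(frozen=True)
class ValidationIssue:
    rule_id: str
    severity: str  # "error" | "warning"
    frame_span: Tuple[int, int]
    message: str


@dataclass
class ValidationReport:
    issues: List[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    @property
    def empty(self) -> bool:
        return not self.issues

    def add(self, rule_id: str, severity: str, span: Tuple[int, int], message: str) -> None:
        self.issues.append(ValidationIssue(rule_id, severity, span, message))

    def __len__(self) -> int:
        return len(self.issues)

    def __repr__(self) -> str:
        if self.empty:
            return "ValidationReport(clean)"
        lines = [f"{i.severity.upper()} {i.rule_id} frames {i.frame_span}: {i.message}"
                 for i in self.issues]
        return "ValidationReport(\n  " + "\n  ".join(lines) + "\n)"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_STR_COLS = ["match_id", "kind", "team_id", "player_id"]


def read_tracking(path: Union[str, Path], pitch: Optional[Pitch] = None,
                  fps: float = 25.0) -> FrameTable:
    """Read an interchange tracking CSV into a :class:`FrameTable`.

    The coordinates are taken verbatim; no re-projection happens here.
    """
    df = pd.read_csv(
        path,
        dtype={c: "string" for c in _STR_COLS},
        keep_default_na=False,
        na_values=[""],
    )
    missing = [c for c in TRACKING_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    for col in ("period", "frame", "time_s", "x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at data row {row}"
            )
        df[col] = coerced
    if df[["x", "y", "frame"]].isna().any().any():
        raise SchemaError(f"{path}: missing coordinate or frame values")
    df["period"] = df["period"].astype(int)
    df["frame"] = df["frame"].astype(int)
    return FrameTable(df[TRACKING_COLUMNS].copy(), fps=fps)


def write_tracking(frames: FrameTable, path: Union[str, Path]) -> None:
    """Write the canonical tracking CSV (column order fixed, empty = null)."""
    frames.df[TRACKING_COLUMNS].to_csv(path, index=False)


def read_metadata(players_path: Union[str, Path],
                  possessions_path: Union[str, Path],
                  ) -> Tuple[List[PlayerMeta], List[Possession]]:
    """Read player and possession metadata CSVs and enforce their invariants."""
    pdf = pd.read_csv(players_path, dtype={"player_id": str, "team_id": str,
                                           "position": str})
    for col in ("player_id", "team_id", "position", "starter"):
        if col not in pdf.columns:
            raise SchemaError(f"{players_path}: missing column {col!r}")
    players = [
        PlayerMeta(r.player_id, r.team_id, r.position, bool(r.starter))
        for r in pdf.itertuples()
    ]

    qdf = pd.read_csv(possessions_path, dtype={"possession_id": str,
                                               "match_id": str, "team_id": str})
    for col in ("possession_id", "match_id", "team_id", "start_frame",
                "end_frame", "goal"):
        if col not in qdf.columns:
            raise SchemaError(f"{possessions_path}: missing column {col!r}")
    possessions = [
        Possession(r.possession_id, r.match_id, r.team_id,
                   int(r.start_frame), int(r.end_frame), int(r.goal))
        for r in qdf.itertuples()
    ]
    _check_non_overlapping(possessions)
    return players, possessions


def write_metadata(players: Sequence[PlayerMeta], possessions: Sequence[Possession],
                   players_path: Union[str, Path],
                   possessions_path: Union[str, Path]) -> None:
    pd.DataFrame(
        [(p.player_id, p.team_id, p.position, p.starter) for p in players],
        columns=["player_id", "team_id", "position", "starter"],
    ).to_csv(players_path, index=False)
    pd.DataFrame(
        [(q.possession_id, q.match_id, q.team_id, q.start_frame, q.end_frame, q.goal)
         for q in possessions],
        columns=["possession_id", "match_id", "team_id", "start_frame",
                 "end_frame", "goal"],
    ).to_csv(possessions_path, index=False)


def _check_non_overlapping(possessions: Sequence[Possession]) -> None:
    by_match: dict = {}
    for q in possessions:
        by_match.setdefault(q.match_id, []).append(q)
    for match_id, qs in by_match.items():
        qs = sorted(qs, key=lambda q: q.start_frame)
        for a, b in zip(qs, qs[1:]):
            if b.start_frame <= a.end_frame:
                raise IntegrityError(
                    f"match {match_id}: possessions {a.possession_id} "
                    f"[{a.start_frame},{a.end_frame}] and {b.possession_id} "
                    f"[{b.start_frame},{b.end_frame}] overlap"
                )


# ---------------------------------------------------------------------------
# Downsampling
# ---------------------------------------------------------------------------

def downsample(frames: FrameTable, factor: int = 5) -> FrameTable:
    """Keep only frames whose global index is a multiple of ``factor``.

    The grid is anchored at frame 0 for the whole match, so an interval's
    retained count depends on its alignment: a run over indices 1..122
    keeps the 24 multiples of 5 it contains, not 122/5.
    """
    if not isinstance(factor, (int, np.integer)) or factor <= 0:
        raise ValueError(f"downsample factor must be a positive integer, got {factor!r}")
    if factor == 1:
        return frames.copy()
    df = frames.df[frames.df["frame"] % factor == 0].copy()
    return FrameTable(df, fps=frames.fps / factor)


def retained_frame_count(start: int, end: int, factor: int = 5) -> int:
    """Number of grid frames (index ≡ 0 mod factor) inside [start, end]."""
    if end < start:
        return 0
    return end // factor - math.ceil(start / factor) + 1


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate(frames: FrameTable,
             meta: Optional[Sequence[PlayerMeta]] = None) -> ValidationReport:
    """Check every structural invariant of a :class:`FrameTable`.

    Breaches are reported, never raised, so a season of imperfect data can be
    triaged.  Fewer than 11 players on a team is a warning down to 7 (red
    cards happen); fewer than 7 is an error.
    """
    report = ValidationReport()
    df = frames.df

    bad = ~np.isfinite(df[["x", "y"]].to_numpy(dtype=float)).all(axis=1)
    if bad.any():
        rows = df.loc[bad, "frame"]
        report.add("finite-coords", "error", (int(rows.min()), int(rows.max())),
                   f"{int(bad.sum())} rows with non-finite coordinates")

    meta_team = {m.player_id: m.team_id for m in meta} if meta else {}
    meta_gk = {m.player_id for m in meta if m.position == "GK"} if meta else set()

    for match_id, mdf in df.groupby("match_id", sort=False):
        # frame ordering per period
        for period, pdf in mdf.groupby("period", sort=False):
            fr = pdf["frame"].to_numpy()
            uniq = pd.unique(fr)
            if not np.all(np.diff(uniq) > 0):
                report.add("frame-order", "error",
                           (int(uniq.min()), int(uniq.max())),
                           f"match {match_id} period {period}: frame indices "
                           "not strictly increasing")

        # duplicated object rows within a frame
        dup = mdf.duplicated(subset=["frame", "kind", "team_id", "player_id"])
        if dup.any():
            fs = mdf.loc[dup, "frame"]
            report.add("dup-rows", "error", (int(fs.min()), int(fs.max())),
                       f"match {match_id}: {int(dup.sum())} duplicated object rows")

        # exactly one ball row per frame
        ball_counts = (mdf[mdf["kind"] == "ball"].groupby("frame").size()
                       .reindex(np.sort(pd.unique(mdf["frame"])), fill_value=0))
        off = ball_counts[ball_counts != 1]
        if len(off):
            report.add("one-ball", "error", (int(off.index.min()), int(off.index.max())),
                       f"match {match_id}: {len(off)} frames without exactly one "
                       f"ball row (first at frame {int(off.index[0])})")

        players = mdf[mdf["kind"] == "player"]
        counts = players.groupby(["frame", "team_id"]).size()
        over = counts[counts > 11]
        if len(over):
            f0 = int(over.index[0][0])
            report.add("max-11", "error", (f0, int(over.index[-1][0])),
                       f"match {match_id}: team {over.index[0][1]} has "
                       f"{int(over.iloc[0])} players at frame {f0}")
        short = counts[counts < 11]
        too_short = short[short < 7]
        if len(too_short):
            f0 = int(too_short.index[0][0])
            report.add("min-7", "error", (f0, f0),
                       f"match {match_id}: fewer than 7 players "
                       f"(team {too_short.index[0][1]}, frame {f0})")
        elif len(short):
            f0 = int(short.index[0][0])
            report.add("short-team", "warning", (f0, int(short.index[-1][0])),
                       f"match {match_id}: a team fields fewer than 11 players "
                       f"on {len(short)} frame-team combinations")

        if meta:
            wrong_team = players["player_id"].map(meta_team) != players["team_id"]
            wrong_team &= players["player_id"].isin(meta_team)
            if wrong_team.any():
                f0 = int(players.loc[wrong_team, "frame"].iloc[0])
                report.add("team-mismatch", "error", (f0, f0),
                           f"match {match_id}: player listed under a different "
                           "team than metadata")
            gk_counts = (players[players["player_id"].isin(meta_gk)]
                         .groupby(["frame", "team_id"]).size())
            n_frames = players["frame"].nunique()
            n_teams = players["team_id"].nunique()
            if len(gk_counts) != n_frames * n_teams or (gk_counts != 1).any():
                report.add("one-gk", "error",
                           (int(mdf["frame"].min()), int(mdf["frame"].max())),
                           f"match {match_id}: not exactly one goalkeeper per "
                           "team on every frame")
    return report


# ---------------------------------------------------------------------------
# Possession annotation
# ---------------------------------------------------------------------------

def annotate_possession(frames: FrameTable,
                        possessions: Sequence[Possession]) -> FrameTable:
    """Attach per-frame possession columns to a frame table.

    Adds ``possession_team`` and ``possession_id`` (null where no team is in
    possession, e.g. dead-ball gaps).  Possessions must be non-overlapping.
    """
    _check_non_overlapping(possessions)
    df = frames.df.copy()
    df["possession_team"] = pd.Series(pd.NA, index=df.index, dtype="string")
    df["possession_id"] = pd.Series(pd.NA, index=df.index, dtype="string")
    for match_id, qs in _group_by_match(possessions).items():
        sel = df["match_id"] == match_id
        fr = df.loc[sel, "frame"].to_numpy()
        starts = np.array([q.start_frame for q in qs])
        ends = np.array([q.end_frame for q in qs])
        idx = np.searchsorted(starts, fr, side="right") - 1
        inside = (idx >= 0) & (fr <= ends[np.clip(idx, 0, None)])
        teams = np.array([q.team_id for q in qs], dtype=object)
        pids = np.array([q.possession_id for q in qs], dtype=object)
        team_col = np.where(inside, teams[np.clip(idx, 0, None)], None)
        pid_col = np.where(inside, pids[np.clip(idx, 0, None)], None)
        df.loc[sel, "possession_team"] = pd.array(team_col, dtype="string")
        df.loc[sel, "possession_id"] = pd.array(pid_col, dtype="string")
    out = FrameTable(df, fps=frames.fps)
    return out


def _group_by_match(possessions: Sequence[Possession]) -> dict:
    out: dict = {}
    for q in possessions:
        out.setdefault(q.match_id, []).append(q)
    for match_id in out:
        out[match_id] = sorted(out[match_id], key=lambda q: q.start_frame)
    return out
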