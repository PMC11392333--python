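"""Season- and player-level aggregation of valued runs.

Produces the standard summaries practitioners read: total runs with
per-match and per-player-match rates (overall and by possession phase),
duration-bucket percentages, correlations between movement metrics and
value accrued, positional breakdowns (goalkeepers and substitutes removed),
and single player-match reports with a phase-by-bucket grid plus a run
timeline.  Every aggregate is a deterministic group-by over the phase-level
records produced by :func:`runvalue.runs.analyse_runs`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .runs import BUCKETS
from .trackdata import PlayerMeta

__all__ = [
    "RunSummary",
    "CorrelationTable",
    "PlayerMatchReport",
    "per_match_rate",
    "per_player_match_rate",
    "duration_bucket_percentages",
    "run_summary",
    "metric_value_correlations",
    "positional_breakdown",
    "player_match_report",
]

DURATION_BUCKETS = [(1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7), (7, np.inf)]
METRICS = ["max_speed", "max_abs_accel", "max_tortuosity"]
PHASES = ["in_possession", "out_of_possession"]


def per_match_rate(total: int, n_matches: int, dp: int = 2) -> float:
    """Runs per match, rounded to ``dp`` decimals (Table-style formatting)."""
    if n_matches <= 0:
        raise ValueError("n_matches must be positive")
    return round(total / n_matches, dp)


def per_player_match_rate(per_match: float, players_per_match: int = 22,
                          dp: int = 2) -> float:
    """Per-player-match rate; the divisor 22 is both teams' starters."""
    if players_per_match <= 0:
        raise ValueError("players_per_match must be positive")
    return round(per_match / players_per_match, dp)


def duration_bucket_percentages(durations: Sequence[float],
                                dp: int = 1) -> Dict[str, float]:
    """Percent of runs in each duration bucket (1-2 s, ..., 7+ s)."""
    d = np.asarray(list(durations), dtype=float)
    if len(d) == 0:
        raise ValueError("no durations")
    out = {}
    for lo, hi in DURATION_BUCKETS:
        key = f"{lo}+ s" if np.isinf(hi) else f"{lo}-{hi} s"
        out[key] = round(100.0 * float(np.mean((d >= lo) & (d < hi))), dp)
    return out


@dataclass
class RunSummary:
    n_matches: int
    total_runs: int
    per_match: float
    per_player_match: float
    by_phase: pd.DataFrame          # index phase; columns total, per_match, per_player_match
    duration_pct: Dict[str, float]
    pct_overlap: float              # runs with both in and out phases
    pct_neither: float              # runs that are entirely possession-free

    def to_frame(self) -> pd.DataFrame:
        rows = [("Overall", self.total_runs, self.per_match, self.per_player_match)]
        for phase, r in self.by_phase.iterrows():
            rows.append((phase, int(r["total"]), r["per_match"],
                         r["per_player_match"]))
        return pd.DataFrame(rows, columns=["phase", "total", "per_match",
                                           "per_player_match"])


def run_summary(records: pd.DataFrame, n_matches: int,
                players_per_match: int = 22) -> RunSummary:
    """Totals, rates and duration buckets from phase-level records.

    ``records`` has one row per run phase; run-level quantities come from
    the unique run ids.  A run counts toward a phase if it has at least one
    segment in it, so in + out totals exceed the overall total by the
    overlap runs.
    """
    if records.empty:
        raise ValueError("no run records")
    if n_matches <= 0:
        raise ValueError("n_matches must be positive")
    runs = records.drop_duplicates("run_id")
    total = len(runs)
    pm = per_match_rate(total, n_matches)
    ppm = per_player_match_rate(pm, players_per_match)

    phase_rows = {}
    for phase in PHASES:
        ids = records.loc[records["phase"] == phase, "run_id"].unique()
        t = len(ids)
        p = per_match_rate(t, n_matches)
        phase_rows[phase] = {"total": t, "per_match": p,
                             "per_player_match": per_player_match_rate(p, players_per_match)}
    by_phase = pd.DataFrame(phase_rows).T

    phases_per_run = records.groupby("run_id")["phase"].agg(set)
    overlap = phases_per_run.apply(
        lambda s: "in_possession" in s and "out_of_possession" in s)
    neither_only = phases_per_run.apply(lambda s: s == {"neither"})
    return RunSummary(
        n_matches=n_matches,
        total_runs=total,
        per_match=pm,
        per_player_match=ppm,
        by_phase=by_phase,
        duration_pct=duration_bucket_percentages(runs["duration_s"]),
        pct_overlap=round(100.0 * float(overlap.mean()), 1),
        pct_neither=round(100.0 * float(neither_only.mean()), 1),
    )


@dataclass
class CorrelationTable:
    table: pd.DataFrame      # index metric, columns phase; Pearson r (NaN = undefined)
    n: pd.DataFrame          # matching sample sizes

    def __repr__(self) -> str:
        return f"CorrelationTable(\n{self.table.round(3)}\n)"


def metric_value_correlations(records: pd.DataFrame,
                              min_n: int = 3) -> CorrelationTable:
    """Pearson r between each run movement metric and value accrued,
    separately for in- and out-of-possession phases.

    Out-of-possession values are opponent value accrued, as recorded.
    Cells with fewer than ``min_n`` complete pairs or zero variance are NaN.
    """
    r = pd.DataFrame(index=METRICS, columns=PHASES, dtype=float)
    n = pd.DataFrame(index=METRICS, columns=PHASES, dtype=int)
    for phase in PHASES:
        sub = records[(records["phase"] == phase) & records["value"].notna()]
        for metric in METRICS:
            pair = sub[[metric, "value"]].dropna()
            n.loc[metric, phase] = len(pair)
            if (len(pair) < min_n or pair[metric].nunique() < 2
                    or pair["value"].nunique() < 2):
                r.loc[metric, phase] = np.nan
                continue
            r.loc[metric, phase] = pearsonr(pair[metric], pair["value"])[0]
    return CorrelationTable(r, n)


def positional_breakdown(records: pd.DataFrame,
                         meta: Optional[Sequence[PlayerMeta]] = None,
                         ) -> pd.DataFrame:
    """Phase x bucket run counts per outfield position.

    Goalkeeper and substitute runs are removed; unknown positions are
    excluded with a warning column left to the caller (they simply drop).
    Rows: position in (CB, FB, CM, W, F); columns: (phase, bucket).
    """
    df = records.copy()
    if meta is not None:
        pos = {m.player_id: m.position for m in meta}
        starter = {m.player_id: m.starter for m in meta}
        df["position"] = df["player_id"].map(pos)
        df["starter"] = df["player_id"].map(starter)
    df = df[df["value"].notna() & df["bucket"].notna()]
    df = df[df["position"].isin(["CB", "FB", "CM", "W", "F"])]
    df = df[df["starter"].fillna(False).astype(bool)]
    out = (df.groupby(["position", "phase", "bucket"], observed=True)
           .size().unstack(["phase", "bucket"], fill_value=0))
    order = [p for p in ["CB", "FB", "CM", "W", "F"] if p in out.index]
    return out.loc[order]


@dataclass
class PlayerMatchReport:
    player_id: str
    match_id: str
    grid: pd.DataFrame       # 2x3 phase-by-bucket counts
    timeline: pd.DataFrame   # minute, value, max_speed, phase

    def total_runs(self) -> int:
        return int(self.grid.to_numpy().sum())


def player_match_report(records: pd.DataFrame, player_id: str,
                        match_id: str, fps: float = 25.0,
                        roster: Optional[Sequence[PlayerMeta]] = None,
                        ) -> PlayerMatchReport:
    """Phase-by-bucket grid and minute-ordered timeline for one player-match.

    A player with no runs yields an all-zero grid and empty timeline provided
    they appear on the ``roster``; otherwise absence from the records is an
    error.
    """
    sub = records[(records["player_id"] == player_id)
                  & (records["match_id"] == match_id)]
    present = player_id in set(
        records.loc[records["match_id"] == match_id, "player_id"])
    if roster is not None:
        present = present or any(m.player_id == player_id for m in roster)
    if not present:
        raise ValueError(f"player {player_id!r} not present in match {match_id!r}")
    grid = pd.DataFrame(0, index=PHASES, columns=list(BUCKETS))
    valued = sub[sub["bucket"].notna()]
    counts = valued.groupby(["phase", "bucket"], observed=True).size()
    for (phase, bucket), c in counts.items():
        if phase in grid.index:
            grid.loc[phase, bucket] = int(c)
    timeline = (valued.assign(minute=valued["start_frame"] / fps / 60.0)
                [["minute", "value", "max_speed", "phase"]]
                .sort_values("minute").reset_index(drop=True))
    return PlayerMatchReport(player_id, match_id, grid, timeline)
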