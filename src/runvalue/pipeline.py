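"""End-to-end orchestration over batches of matches.

Matches are processed one at a time so a whole study never holds more than
one 25 Hz frame table in memory: each match is simulated (or loaded),
reduced to its feature matrix, frame labels, physical run records and
ground truth, and the frame table is discarded.  The value model is then
fitted on the training matches and every match's run records are valued
from its smoothed prediction series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .features import FeatureConfig, FeatureMatrix, build_feature_matrix
from .pitch import Pitch
from .runs import HIGH_VALUE_THRESHOLD, analyse_runs, apply_values
from .simulate import SimConfig, SyntheticMatch, simulate_batch
from .trackdata import PlayerMeta, Possession, downsample
from .valuemodel import (
    FrameLabels,
    FrameValueModel,
    FrameValueResults,
    RandomSearchConfig,
    calibration_slope,
    label_frames,
    reliability_table,
)

__all__ = [
    "MatchData",
    "StudyData",
    "extract_match",
    "build_study",
    "fit_study_model",
    "value_study_records",
    "sprint_recall",
    "study_calibration",
]


@dataclass
class MatchData:
    """The compact per-match artefacts the study keeps."""

    match_id: str
    features: FeatureMatrix
    labels: FrameLabels
    physical_records: pd.DataFrame     # analyse_runs output, unvalued
    possessions: List[Possession]
    players: List[PlayerMeta]
    sprints: pd.DataFrame              # injected ground truth (empty for real data)
    ticks: pd.DataFrame


@dataclass
class StudyData:
    matches: List[MatchData]
    pitch: Pitch

    @property
    def match_ids(self) -> List[str]:
        return [m.match_id for m in self.matches]

    def features(self, ids: Optional[Sequence[str]] = None) -> FeatureMatrix:
        sel = self._select(ids)
        return FeatureMatrix.concat([m.features for m in sel])

    def labels(self, ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
        sel = self._select(ids)
        return pd.concat([m.labels.frame for m in sel])

    def _select(self, ids: Optional[Sequence[str]]) -> List[MatchData]:
        if ids is None:
            return self.matches
        keep = set(ids)
        return [m for m in self.matches if m.match_id in keep]


def extract_match(match: SyntheticMatch,
                  feature_config: FeatureConfig = FeatureConfig(),
                  factor: int = 5) -> MatchData:
    """Reduce one simulated match to its study artefacts."""
    frames5 = downsample(match.frames, factor)
    fm = build_feature_matrix(frames5, match.players, match.possessions,
                              match.pitch, feature_config)
    labels = label_frames(fm, match.possessions)
    physical = analyse_runs(match.frames, match.players, match.possessions,
                            values=None, factor=factor)
    return MatchData(match.match_id, fm, labels, physical, match.possessions,
                     match.players, match.truth.sprints, match.truth.ticks)


def build_study(config: SimConfig, n_matches: int, seed: int,
                feature_config: FeatureConfig = FeatureConfig(),
                factor: int = 5) -> StudyData:
    """Simulate and extract ``n_matches`` matches (memory-bounded)."""
    matches = []
    pitch = None
    for match in simulate_batch(config, n_matches, seed):
        pitch = match.pitch
        matches.append(extract_match(match, feature_config, factor))
    return StudyData(matches, pitch)


def fit_study_model(study: StudyData, train_ids: Sequence[str],
                    search: Optional[RandomSearchConfig] = None,
                    seed: int = 0) -> FrameValueResults:
    fm = study.features(train_ids).valid()
    lab = study.labels(train_ids)
    common = fm.X.index.intersection(lab.index)
    model = FrameValueModel(fm.X.loc[common], lab.loc[common, "label"].to_numpy(),
                            lab.loc[common, "match_id"].to_numpy())
    return model.fit(search=search, seed=seed)


def value_study_records(study: StudyData, results: FrameValueResults,
                        threshold: float = HIGH_VALUE_THRESHOLD,
                        factor: int = 5) -> pd.DataFrame:
    """Predict each match's value series and value its run records."""
    out = []
    for m in study.matches:
        if len(m.features.valid()) == 0 or m.physical_records.empty:
            continue
        series = results.predict_series(m.features)
        out.append(apply_values(m.physical_records, series, threshold, factor))
    if not out:
        return pd.DataFrame()
    return pd.concat(out, ignore_index=True)


def sprint_recall(study: StudyData, min_speed: float = 6.0,
                  min_duration_s: float = 1.2, fps: float = 25.0) -> Tuple[float, int]:
    """Fraction of injected sprints recovered by the run detector.

    Only clearly supra-threshold sprints count (target speed >= 6 m/s,
    plateau >= 1.2 s); a sprint is recovered when a detected run by the
    same player overlaps its plateau interval.  Returns (recall, n_truth).
    """
    hits = 0
    total = 0
    for m in study.matches:
        runs = m.physical_records.drop_duplicates("run_id")
        by_player: Dict[str, List[Tuple[int, int]]] = {}
        for r in runs.itertuples():
            by_player.setdefault(str(r.player_id), []).append(
                (int(r.start_frame), int(r.end_frame)))
        truth = m.sprints
        sel = (truth["target_speed"] >= min_speed) & \
              ((truth["end_frame"] - truth["start_frame"]) / fps >= min_duration_s)
        for t in truth[sel].itertuples():
            total += 1
            spans = by_player.get(str(t.player_id), [])
            if any(a <= t.end_frame and t.start_frame <= b for a, b in spans):
                hits += 1
    return (hits / total if total else float("nan")), total


def study_calibration(study: StudyData, results: FrameValueResults,
                      ids: Optional[Sequence[str]] = None,
                      n_bins: int = 10,
                      oof_params: Optional[dict] = None,
                      seed: int = 0) -> Tuple[pd.DataFrame, float]:
    """Reliability table and calibration slope on held-out predictions.

    With ``oof_params`` given, predictions are grouped out-of-fold at those
    hyperparameters over the selected matches (every frame predicted by a
    model that never saw its match); otherwise the fitted model predicts
    the selected matches directly (use ids disjoint from training).
    """
    fm = study.features(ids).valid()
    lab = study.labels(ids)
    common = fm.X.index.intersection(lab.index)
    X = fm.X.loc[common]
    y = lab.loc[common, "label"].to_numpy(dtype=int)
    if oof_params is not None:
        model = FrameValueModel(X, y, lab.loc[common, "match_id"].to_numpy())
        pred = model.cross_val_predict(oof_params, seed=seed)
    else:
        pred = results.predict(X)
    table = reliability_table(pred, y, n_bins=n_bins, strategy="quantile")
    return table, calibration_slope(table)
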