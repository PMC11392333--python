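"""Frame-level goal-probability model.

A gradient-boosted binary classifier maps each in-possession frame's feature
vector to the probability that the possessing team scores before the
possession ends.  Every frame of a possession inherits the possession's
binary outcome as its label; hyperparameters are tuned by random search
scored with grouped cross-validated log-loss (matches as groups, so no match
contributes to both training and validation folds); the best setting is
refit on all training matches.  Predictions are smoothed within possessions
with a 3-frame moving average to remove single-frame blips.

Organised like a statsmodels model: :class:`FrameValueModel` holds the data,
``fit`` returns a :class:`FrameValueResults` carrying the fitted booster,
the search diagnostics, importances and prediction methods.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import loguniform, randint, uniform
from sklearn.metrics import log_loss
from sklearn.model_selection import GroupKFold, ParameterSampler
import xgboost as xgb
from xgboost import XGBClassifier

from .features import FEATURE_NAMES, FeatureMatrix
from .trackdata import FrameTable, IntegrityError, Possession

__all__ = [
    "FrameLabels",
    "ValueSeries",
    "RandomSearchConfig",
    "FrameValueModel",
    "FrameValueResults",
    "label_frames",
    "train_value_model",
    "predict_frame_values",
    "smooth_series",
    "feature_importance",
    "reliability_table",
    "calibration_slope",
]


@dataclass
class FrameLabels:
    """Per-frame binary outcome labels, indexed by (match_id, frame)."""

    frame: pd.DataFrame   # columns: possession_id, label, match_id

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=int)

    @property
    def groups(self) -> np.ndarray:
        return self.frame["match_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class ValueSeries:
    """Raw and smoothed per-frame goal probabilities for the possessing team."""

    frame: pd.DataFrame   # index (match_id, frame); columns raw, smoothed, possession_id

    @property
    def raw(self) -> pd.Series:
        return self.frame["raw"]

    @property
    def smoothed(self) -> pd.Series:
        return self.frame["smoothed"]

    def at_frames(self, match_id: str, frames: Sequence[int]) -> pd.Series:
        """Smoothed values at the given global frame indices (NaN-dropped)."""
        idx = pd.MultiIndex.from_product([[match_id], frames])
        return self.frame["smoothed"].reindex(idx).dropna().droplevel(0)


def label_frames(frames5: Union[FrameTable, FeatureMatrix],
                 possessions: Sequence[Possession]) -> FrameLabels:
    """Assign each in-possession 5 Hz frame its possession's goal outcome.

    Frames outside every possession (dead-ball gaps) are excluded.  Raises
    if any frame would map to two possessions (overlap upstream).
    """
    outcome = {q.possession_id: q.goal for q in possessions}
    _check_overlap(possessions)
    if isinstance(frames5, FeatureMatrix):
        pid = frames5.possession_id
        idx = frames5.X.index
    else:
        df = frames5.df
        if "possession_team" not in df.columns:
            raise ValueError("frame table lacks possession annotation")
        one = df.drop_duplicates(["match_id", "frame"])
        idx = pd.MultiIndex.from_arrays([one["match_id"], one["frame"]],
                                        names=["match_id", "frame"])
        pid = pd.Series(one["possession_id"].to_numpy(), index=idx)
    keep = pid.notna()
    pid = pid[keep]
    out = pd.DataFrame({
        "possession_id": pid.astype(str),
        "label": pid.map(lambda p: outcome.get(str(p))).astype(int),
        "match_id": pid.index.get_level_values("match_id"),
    }, index=pid.index)
    return FrameLabels(out)


def _check_overlap(possessions: Sequence[Possession]) -> None:
    by_match: Dict[str, list] = {}
    for q in possessions:
        by_match.setdefault(q.match_id, []).append(q)
    for match_id, qs in by_match.items():
        qs = sorted(qs, key=lambda q: q.start_frame)
        for a, b in zip(qs, qs[1:]):
            if b.start_frame <= a.end_frame:
                raise IntegrityError(
                    f"match {match_id}: frame would map to two possessions "
                    f"({a.possession_id}, {b.possession_id})")


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def smooth_series(raw: Union[pd.Series, np.ndarray],
                  possession_ids: Union[pd.Series, np.ndarray, Sequence],
                  weights: Optional[Tuple[float, float, float]] = None,
                  ) -> np.ndarray:
    """3-frame moving average of predictions, confined within possessions.

    The default is the uniform mean of the frame and its two neighbours;
    boundary frames average the available neighbours only.  ``weights``
    switches to a weighted window, e.g. ``(1, 2, 1)`` for a triangular
    kernel, renormalised over the neighbours present at the edges.
    Smoothing never crosses a possession boundary.
    """
    vals = np.asarray(raw, dtype=float)
    pids = np.asarray(possession_ids)
    w = np.asarray(weights if weights is not None else (1.0, 1.0, 1.0), dtype=float)
    out = np.empty_like(vals)
    n = len(vals)
    for i in range(n):
        acc = vals[i] * w[1]
        tot = w[1]
        if i > 0 and pids[i - 1] == pids[i]:
            acc += vals[i - 1] * w[0]
            tot += w[0]
        if i + 1 < n and pids[i + 1] == pids[i]:
            acc += vals[i + 1] * w[2]
            tot += w[2]
        out[i] = acc / tot
    return out


# ---------------------------------------------------------------------------
# Random-search configuration
# ---------------------------------------------------------------------------

@dataclass
class RandomSearchConfig:
    """Search space and budget for hyperparameter tuning.

    Bounds cover the usual effective ranges for boosted trees on tabular
    frame features while keeping a desk-scale fit fast.
    """

    n_iter: int = 50
    cv_folds: int = 3
    param_space: Dict[str, object] = field(default_factory=lambda: {
        "max_depth": randint(2, 9),
        "learning_rate": loguniform(0.03, 0.3),
        "n_estimators": randint(50, 301),
        "subsample": uniform(0.6, 0.4),
        "colsample_bytree": uniform(0.6, 0.4),
        "min_child_weight": loguniform(1.0, 64.0),
    })


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class FrameValueModel:
    """Goal-probability model over frame features.

    Parameters
    ----------
    X : array-like or DataFrame, shape (n_frames, 22)
        Feature rows in the canonical order.
    y : array-like of {0, 1}
        Possession outcome per frame.
    groups : array-like
        Match id per frame, for grouped cross-validation.
    """

    def __init__(self, X, y, groups, feature_names: Optional[List[str]] = None):
        if isinstance(X, pd.DataFrame):
            self.feature_names = list(X.columns)
            self.X = X.to_numpy(dtype=float)
        else:
            self.feature_names = list(feature_names or FEATURE_NAMES)
            self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        self.groups = np.asarray(groups)
        if self.X.shape[0] != len(self.y):
            raise ValueError("X and y lengths differ")
        classes = np.unique(self.y)
        if len(classes) < 2:
            raise ValueError("training labels contain a single class; "
                             "a goal-probability model needs both outcomes")
        if len(np.unique(self.groups)) < 2:
            raise ValueError("need at least 2 matches for grouped validation")

    @classmethod
    def from_feature_matrix(cls, fm: FeatureMatrix,
                            labels: FrameLabels) -> "FrameValueModel":
        """Align a feature matrix with labels, dropping masked rows."""
        fm = fm.valid()
        common = fm.X.index.intersection(labels.frame.index)
        X = fm.X.loc[common]
        lab = labels.frame.loc[common]
        return cls(X, lab["label"].to_numpy(), lab["match_id"].to_numpy())

    # -- fitting -----------------------------------------------------------

    def fit(self, search: Optional[RandomSearchConfig] = None,
            seed: int = 0) -> "FrameValueResults":
        """Random-search + grouped-CV tune, refit best on all data."""
        search = search or RandomSearchConfig()
        n_groups = len(np.unique(self.groups))
        folds = search.cv_folds
        if n_groups < folds:
            warnings.warn(
                f"only {n_groups} matches; reducing CV folds from {folds}",
                stacklevel=2)
            folds = n_groups
        sampler = ParameterSampler(search.param_space, n_iter=search.n_iter,
                                   random_state=seed)
        cv = GroupKFold(n_splits=folds)
        records = []
        best_loss, best_params = np.inf, None
        for params in sampler:
            losses = []
            for tr, va in cv.split(self.X, self.y, self.groups):
                if len(np.unique(self.y[tr])) < 2:
                    continue
                clf = self._make_clf(params, seed)
                clf.fit(self.X[tr], self.y[tr])
                p = clf.predict_proba(self.X[va])[:, 1]
                losses.append(log_loss(self.y[va], p, labels=[0, 1]))
            mean_loss = float(np.mean(losses)) if losses else np.inf
            records.append({**params, "cv_logloss": mean_loss})
            if mean_loss < best_loss:
                best_loss, best_params = mean_loss, params
        clf = self._make_clf(best_params, seed)
        clf.fit(self.X, self.y)
        return FrameValueResults(
            booster=clf, params=dict(best_params),
            feature_names=list(self.feature_names),
            cv_logloss=best_loss, cv_results=pd.DataFrame(records),
            seed=seed, n_folds=folds, n_obs=len(self.y),
            n_groups=len(np.unique(self.groups)),
            goal_frame_rate=float(self.y.mean()), model=self,
        )

    def cross_val_predict(self, params: dict, seed: int = 0,
                          n_folds: int = 3) -> np.ndarray:
        """Out-of-fold predictions at fixed hyperparameters (grouped folds).

        Every frame is predicted by a model whose training folds exclude its
        match, so the output behaves like held-out predictions for
        calibration checks.
        """
        folds = min(n_folds, len(np.unique(self.groups)))
        cv = GroupKFold(n_splits=folds)
        out = np.full(len(self.y), np.nan)
        for tr, va in cv.split(self.X, self.y, self.groups):
            clf = self._make_clf(params, seed)
            clf.fit(self.X[tr], self.y[tr])
            out[va] = clf.predict_proba(self.X[va])[:, 1]
        return out

    def _make_clf(self, params: dict, seed: int) -> XGBClassifier:
        return XGBClassifier(
            objective="binary:logistic", tree_method="hist", n_jobs=1,
            random_state=seed, eval_metric="logloss", verbosity=0,
            **{k: (int(v) if k in ("max_depth", "n_estimators") else v)
               for k, v in params.items()},
        )


@dataclass
class FrameValueResults:
    """Fitted value model with diagnostics.

    Exposes prediction (raw and possession-smoothed), gain-based feature
    importances normalised to sum 1, a text summary, and round-trip
    serialisation (xgboost JSON plus a sidecar with the canonical feature
    order and chosen hyperparameters).
    """

    booster: XGBClassifier
    params: dict
    feature_names: List[str]
    cv_logloss: float
    cv_results: pd.DataFrame
    seed: int
    n_folds: int
    n_obs: int = 0
    n_groups: int = 0
    goal_frame_rate: float = float("nan")
    model: Optional[FrameValueModel] = None

    def predict(self, X: Union[np.ndarray, pd.DataFrame, FeatureMatrix]) -> np.ndarray:
        """Raw per-frame goal probabilities, in [0, 1]."""
        if isinstance(X, FeatureMatrix):
            X = X.X
        if isinstance(X, pd.DataFrame):
            if list(X.columns) != self.feature_names:
                raise ValueError(
                    "feature columns do not match the model's canonical order")
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}")
        if isinstance(self.booster, xgb.Booster):     # deserialised model
            return self.booster.inplace_predict(X)
        return self.booster.predict_proba(X)[:, 1]

    def predict_series(self, fm: FeatureMatrix,
                       weights: Optional[Tuple[float, float, float]] = None,
                       ) -> ValueSeries:
        """Predict on a feature matrix and smooth within possessions."""
        fm = fm.valid()
        raw = self.predict(fm.X)
        pid = fm.possession_id.to_numpy()
        # smoothing requires frame order within each match
        order = np.lexsort((fm.X.index.get_level_values("frame"),
                            fm.X.index.get_level_values("match_id")))
        inv = np.argsort(order)
        smoothed = smooth_series(raw[order], pid[order], weights)[inv]
        out = pd.DataFrame({"raw": raw, "smoothed": smoothed,
                            "possession_id": fm.possession_id},
                           index=fm.X.index)
        return ValueSeries(out)

    def feature_importance(self) -> pd.DataFrame:
        """Gain importances normalised to sum 1, descending."""
        booster = (self.booster if isinstance(self.booster, xgb.Booster)
                   else self.booster.get_booster())
        raw = booster.get_score(importance_type="gain")
        gains = np.array([raw.get(f"f{i}", 0.0)
                          for i in range(len(self.feature_names))])
        total = gains.sum()
        if total > 0:
            gains = gains / total
        out = pd.DataFrame({"feature": self.feature_names, "importance": gains})
        return out.sort_values("importance", ascending=False).reset_index(drop=True)

    def summary(self) -> str:
        imp = self.feature_importance().head(5)
        lines = [
            "Frame value model (gradient-boosted trees)",
            "=" * 46,
            f"n frames:            {self.n_obs}",
            f"n matches (groups):  {self.n_groups}",
            f"goal-frame rate:     {self.goal_frame_rate:.4f}",
            f"CV folds (grouped):  {self.n_folds}",
            f"CV log-loss (best):  {self.cv_logloss:.5f}",
            f"search draws:        {len(self.cv_results)}",
            f"seed:                {self.seed}",
            "best hyperparameters:",
        ]
        for k, v in sorted(self.params.items()):
            lines.append(f"  {k:>18}: {v:.4g}" if isinstance(v, float)
                         else f"  {k:>18}: {v}")
        lines.append("top features (gain share):")
        for r in imp.itertuples():
            lines.append(f"  {r.feature:>28}: {r.importance:.3f}")
        return "\n".join(lines)


    def save(self, stem: Union[str, "Path"]) -> None:
        """Write ``<stem>.model.json`` (booster) and ``<stem>.meta.json``."""
        stem = Path(stem)
        stem.parent.mkdir(parents=True, exist_ok=True)
        booster = (self.booster if isinstance(self.booster, xgb.Booster)
                   else self.booster.get_booster())
        booster.save_model(f"{stem}.model.json")
        meta = {
            "feature_names": self.feature_names,
            "params": {k: (float(v) if isinstance(v, (int, float, np.floating))
                           else v) for k, v in self.params.items()},
            "cv_logloss": self.cv_logloss,
            "seed": self.seed,
            "n_folds": self.n_folds,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "goal_frame_rate": self.goal_frame_rate,
        }
        Path(f"{stem}.meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, stem: Union[str, "Path"]) -> "FrameValueResults":
        stem = Path(stem)
        booster = xgb.Booster()
        booster.load_model(f"{stem}.model.json")
        meta = json.loads(Path(f"{stem}.meta.json").read_text())
        return cls(booster=booster, params=meta["params"],
                   feature_names=meta["feature_names"],
                   cv_logloss=meta["cv_logloss"], cv_results=pd.DataFrame(),
                   seed=meta["seed"], n_folds=meta["n_folds"],
                   n_obs=meta.get("n_obs", 0), n_groups=meta.get("n_groups", 0),
                   goal_frame_rate=meta.get("goal_frame_rate", float("nan")))


# ---------------------------------------------------------------------------
# Calibration diagnostics
# ---------------------------------------------------------------------------

def reliability_table(pred: np.ndarray, y: np.ndarray, n_bins: int = 10,
                      strategy: str = "quantile") -> pd.DataFrame:
    """Binned reliability of predictions against binary outcomes.

    ``strategy`` "quantile" bins by predicted-probability deciles (equal
    counts), "uniform" by equal-width bins on [0, 1].  Returns per-bin
    (mean_pred, empirical, n).
    """
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(pred)
    pred, y = pred[ok], y[ok]
    if strategy == "quantile":
        edges = np.unique(np.quantile(pred, np.linspace(0, 1, n_bins + 1)))
    else:
        edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(pred, edges[1:-1]), 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        if not sel.any():
            continue
        rows.append((float(pred[sel].mean()), float(y[sel].mean()),
                     int(sel.sum())))
    return pd.DataFrame(rows, columns=["mean_pred", "empirical", "n"])


def calibration_slope(table: pd.DataFrame) -> float:
    """Weighted least-squares slope of empirical frequency on mean predicted
    probability across reliability bins (1.0 = perfectly calibrated)."""
    x = table["mean_pred"].to_numpy(dtype=float)
    z = table["empirical"].to_numpy(dtype=float)
    w = table["n"].to_numpy(dtype=float)
    xbar = np.average(x, weights=w)
    zbar = np.average(z, weights=w)
    den = np.average((x - xbar) ** 2, weights=w)
    if den <= 0:
        return float("nan")
    return float(np.average((x - xbar) * (z - zbar), weights=w) / den)


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def train_value_model(X, y, groups, search: Optional[RandomSearchConfig] = None,
                      seed: int = 0) -> FrameValueResults:
    return FrameValueModel(X, y, groups).fit(search=search, seed=seed)


def predict_frame_values(results: FrameValueResults, X) -> np.ndarray:
    return results.predict(X)


def feature_importance(results: FrameValueResults) -> pd.DataFrame:
    return results.feature_importance()
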