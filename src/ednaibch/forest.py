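"""Taxonomy-free prediction of the biotic index from OTU presence/absence.

A random-forest regressor is trained on binary site x OTU detection
features (all OTUs of the surveyed macroinvertebrate phyla, not only the
taxonomically matched ones) with the kick-net-derived index score as the
response.  Hyperparameters come from a seeded grid search; per-site
predictions are strictly out-of-sample (leave-one-out refits by default,
out-of-bag as a cheaper alternative).  Agreement between observed and
predicted scores is summarised by the adjusted R^2 of a linear model,
Cohen's kappa on the five-category classification, and the signed
category-deviation histogram.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from ._seeds import derive_seed
from .diversity import RegressionSummary, richness_regression
from .errors import ConfigError, ValidationError
from .ibch import IbchConfig, category_index, classify_score

log = logging.getLogger(__name__)

KAPPA_BANDS = (
    (0.05, "no agreement"),
    (0.20, "very poor"),
    (0.40, "poor"),
    (0.55, "fair"),
    (0.70, "good"),
    (0.85, "very good"),
    (0.99, "excellent"),
)


@dataclass
class RfConfig:
    """Forest hyperparameters; mtry defaults to the n/3 rule."""

    ntrees: int = 500
    mtry: Optional[int] = None  # None -> floor(n_features / 3)
    min_node_size: int = 3
    prediction_scheme: str = "leave_one_out"
    seed: Optional[int] = None
    cv_rmse: Optional[float] = None  # filled in by the grid search

    def __post_init__(self) -> None:
        if self.ntrees < 1:
            raise ConfigError("ntrees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ConfigError("mtry must be >= 1")
        if self.min_node_size < 1:
            raise ConfigError("min_node_size must be >= 1")
        if self.prediction_scheme not in ("leave_one_out", "out_of_bag"):
            raise ConfigError(
                f"unknown prediction scheme {self.prediction_scheme!r}"
            )
        if self.seed is None:
            raise ConfigError("a seed is mandatory for forest fitting")

    def resolved_mtry(self, n_features: int) -> int:
        mtry = self.mtry if self.mtry is not None else max(1, n_features // 3)
        if mtry > n_features:
            raise ConfigError(
                f"mtry={mtry} exceeds the {n_features} available features"
            )
        return mtry


def default_grid(n_features: int) -> dict[str, list[int]]:
    """Grid around the n/3 rule: the reported optimum is always inside."""
    mtrys = sorted({max(1, n_features // 5), max(1, n_features // 3),
                    max(1, n_features // 2)})
    return {"mtry": mtrys, "min_node_size": [3, 5, 10], "ntrees": [500]}


def build_presence_features(table) -> pd.DataFrame:
    """Binary site x OTU matrix; constant columns are uninformative."""
    presence = table.presence.astype(np.int8)
    if presence.shape[0] < 2:
        raise ValidationError("need at least 2 sites to build features")
    keep = presence.columns[presence.nunique() > 1]
    dropped = presence.shape[1] - len(keep)
    if dropped:
        log.info("dropped %d zero-variance feature columns", dropped)
    if len(keep) == 0:
        raise ValidationError("no informative features")
    return presence[keep]


def _forest(ntrees: int, mtry: int, node: int, seed: int,
            oob: bool = False) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=ntrees, max_features=mtry, min_samples_leaf=node,
        random_state=seed, n_jobs=1, oob_score=oob, bootstrap=True,
    )


def tune_hyperparameters(features: pd.DataFrame, response: Sequence[float],
                         grid: Optional[dict] = None,
                         seed: int = 0, n_folds: int = 5,
                         prediction_scheme: str = "leave_one_out"
                         ) -> RfConfig:
    """Pick the grid cell with minimal seeded cross-validated RMSE.

    Ties break toward smaller mtry, then smaller ntrees, then smaller node
    size, so the cheaper model wins.
    """
    X = features.to_numpy()
    y = np.asarray(response, dtype=float)
    if grid is None:
        grid = default_grid(X.shape[1])
    cells = [
        (mtry, node, ntrees)
        for mtry in grid["mtry"]
        for node in grid["min_node_size"]
        for ntrees in grid["ntrees"]
    ]
    if not cells:
        raise ConfigError("empty hyperparameter grid")
    kf = KFold(n_splits=min(n_folds, len(y)), shuffle=True,
               random_state=derive_seed(seed, "cv_split"))
    splits = list(kf.split(X))
    results = []
    for mtry, node, ntrees in cells:
        if mtry > X.shape[1]:
            log.warning("grid cell mtry=%d skipped (> %d features)",
                        mtry, X.shape[1])
            continue
        sq_errs = []
        for f, (tr, te) in enumerate(splits):
            rf = _forest(ntrees, mtry, node,
                         derive_seed(seed, "cv", mtry, node, ntrees, f))
            rf.fit(X[tr], y[tr])
            sq_errs.append(np.mean((rf.predict(X[te]) - y[te]) ** 2))
        rmse = float(np.sqrt(np.mean(sq_errs)))
        results.append((rmse, mtry, ntrees, node))
    if not results:
        raise ConfigError("no valid cell in the hyperparameter grid")
    rmse, mtry, ntrees, node = min(results)
    log.info("grid search: best RMSE %.3f at mtry=%d node=%d ntrees=%d",
             rmse, mtry, node, ntrees)
    return RfConfig(ntrees=ntrees, mtry=mtry, min_node_size=node,
                    prediction_scheme=prediction_scheme, seed=seed,
                    cv_rmse=rmse)


def predict_scores(features: pd.DataFrame, response: Sequence[float],
                   config: RfConfig) -> pd.Series:
    """Strictly out-of-sample per-site predictions of the index score.

    ``leave_one_out`` refits the forest without each site in turn;
    ``out_of_bag`` fits once and uses each site's out-of-bag tree average.
    """
    X = features.to_numpy()
    y = np.asarray(response, dtype=float)
    if len(y) != X.shape[0]:
        raise ValidationError("response length must match feature rows")
    mtry = config.resolved_mtry(X.shape[1])
    if config.prediction_scheme == "leave_one_out":
        preds = np.empty(len(y))
        for i in range(len(y)):
            mask = np.ones(len(y), dtype=bool)
            mask[i] = False
            rf = _forest(config.ntrees, mtry, config.min_node_size,
                         derive_seed(config.seed, "loo", i))
            rf.fit(X[mask], y[mask])
            preds[i] = rf.predict(X[i:i + 1])[0]
    else:
        rf = _forest(config.ntrees, mtry, config.min_node_size,
                     derive_seed(config.seed, "oob"), oob=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # few-tree OOB coverage warning
            rf.fit(X, y)
        preds = np.asarray(rf.oob_prediction_)
    return pd.Series(preds, index=features.index, name="predicted_score")


def cohen_kappa(a: Sequence, b: Sequence) -> float:
    """Unweighted Cohen's kappa: (p_o - p_e) / (1 - p_e)."""
    a = np.asarray(a, dtype=object)
    b = np.asarray(b, dtype=object)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("label vectors must be equal-length 1-D")
    n = len(a)
    if n == 0:
        raise ValidationError("empty label vectors")
    labels = sorted(set(a) | set(b), key=str)
    p_o = float(np.mean(a == b))
    p_e = sum(
        float(np.mean(a == lab)) * float(np.mean(b == lab)) for lab in labels
    )
    if p_e >= 1.0 - 1e-15:
        warnings.warn("degenerate marginals (p_e = 1); kappa by convention")
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def kappa_band(kappa: float) -> str:
    """Verbal agreement band; boundary values fall to the lower band."""
    if not -1.0 <= kappa <= 1.0:
        raise ValidationError(f"kappa {kappa} outside [-1, 1]")
    if kappa == 1.0:
        return "perfect"
    for upper, label in KAPPA_BANDS:
        if kappa <= upper:
            return label
    return "excellent"  # kappa in (0.99, 1)


@dataclass
class PredictionEvaluation:
    """Observed-versus-predicted agreement on scores and categories."""

    per_site: pd.DataFrame
    regression: RegressionSummary
    kappa: float
    kappa_band: str
    pct_exact: float
    pct_within_one: float
    deviation_histogram: dict[int, float] = field(default_factory=dict)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def evaluate_predictions(observed: Sequence[float],
                         predicted: Sequence[float],
                         ibch_config: Optional[IbchConfig] = None,
                         site_ids: Optional[Sequence[str]] = None
                         ) -> PredictionEvaluation:
    """Full agreement summary between observed and predicted index scores.

    Scores are rounded half-up to integers before categorisation; the
    linear model regresses observed on predicted.
    """
    cfg = ibch_config or IbchConfig()
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValidationError("observed/predicted must have equal length")
    if len(obs) < 3:
        raise ValidationError("need at least 3 sites to evaluate")
    if np.ptp(pred) == 0:
        warnings.warn("constant predictions; regression summary degenerate")
        reg = RegressionSummary(slope=0.0, intercept=float(obs.mean()),
                                r_squared=0.0, adj_r_squared=0.0,
                                p_value=1.0, n=len(obs))
    else:
        reg = richness_regression(pred, obs)
    obs_cat = [classify_score(int(s), cfg) for s in _round_half_up(obs)]
    pred_cat = [classify_score(int(s), cfg) for s in _round_half_up(pred)]
    dev = np.array([
        category_index(p, cfg) - category_index(o, cfg)
        for o, p in zip(obs_cat, pred_cat)
    ])
    kappa = cohen_kappa(obs_cat, pred_cat)
    hist = {
        int(d): float(np.mean(dev == d) * 100.0)
        for d in sorted(set(dev.tolist()))
    }
    index = list(site_ids) if site_ids is not None else list(range(len(obs)))
    per_site = pd.DataFrame({
        "observed_score": obs,
        "predicted_score": pred,
        "observed_category": obs_cat,
        "predicted_category": pred_cat,
        "category_deviation": dev,
    }, index=index)
    return PredictionEvaluation(
        per_site=per_site,
        regression=reg,
        kappa=float(kappa),
        kappa_band=kappa_band(float(kappa)),
        pct_exact=float(np.mean(dev == 0) * 100.0),
        pct_within_one=float(np.mean(np.abs(dev) <= 1) * 100.0),
        deviation_histogram=hist,
    )
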