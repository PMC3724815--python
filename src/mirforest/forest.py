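"""Random-forest classifier over duplex features.

Bagged decision trees with per-node random feature subsets (mtry), grown on
bootstrap samples (~2/3 unique rows each); class probability of a new
instance is the fraction of trees voting TARGET, and the hard class is
TARGET only when that fraction strictly exceeds the decision threshold.

Nominal position features are one-hot encoded for the tree learner; Gini
importance is reported per original feature by summing over its dummies, so
the ranking keeps its per-feature semantics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import (
    FEATURE_NAMES,
    LABEL_NON_TARGET,
    LABEL_TARGET,
    NUMERIC_FEATURES,
    POSITION_LEVELS,
    FeatureTable,
)

logger = logging.getLogger(__name__)

#: Misclassification penalties emphasising the negative class.
WEIGHTED_PRESET = {LABEL_TARGET: 0.3, LABEL_NON_TARGET: 0.7}


@dataclass(frozen=True)
class RFConfig:
    """Forest hyperparameters.

    ``mtry`` counts encoded (post one-hot) columns sampled per split; None
    selects floor(sqrt(p)).  ``class_weights`` maps labels to per-class
    sample weights.  A tie at exactly ``decision_threshold`` is classified
    NON_TARGET (strictly-greater rule).
    """

    n_trees: int = 500
    mtry: Optional[int] = None
    class_weights: Optional[dict] = None
    rng_seed: int = 0
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.class_weights is not None and any(
            w <= 0 for w in self.class_weights.values()
        ):
            raise ValueError("class weights must be positive")


def encode_features(
    frame: pd.DataFrame, feature_names: Sequence[str]
) -> pd.DataFrame:
    """One-hot encode nominal position features with a fixed level set."""
    cols = {}
    for name in feature_names:
        if name in NUMERIC_FEATURES:
            cols[name] = frame[name].astype(float)
        else:
            values = frame[name].astype(str)
            for level in POSITION_LEVELS:
                cols[f"{name}={level}"] = (values == level).astype(float)
    return pd.DataFrame(cols, index=frame.index)


def _original_feature(encoded_name: str) -> str:
    return encoded_name.split("=", 1)[0]


@dataclass
class TrainedForest:
    """A fitted ensemble plus its OOB estimates and feature importances."""

    estimator: RandomForestClassifier
    feature_names: list[str]
    encoded_columns: list[str]
    config: RFConfig
    oob_error: float
    oob_error_per_class: dict
    oob_proba: np.ndarray  # P(TARGET) per training row, OOB trees only
    gini_importance: pd.Series  # per original feature, >= 0


def _check_schema(table: FeatureTable, feature_names: Sequence[str]) -> None:
    missing = [n for n in feature_names if n not in table.frame.columns]
    if missing:
        raise ValueError(f"feature table is missing features: {missing}")


def train_forest(
    table: FeatureTable,
    cfg: RFConfig | None = None,
    feature_names: Optional[Sequence[str]] = None,
) -> TrainedForest:
    """Grow a forest on a labeled feature table."""
    cfg = cfg or RFConfig()
    feature_names = list(feature_names or FEATURE_NAMES)
    if not table.has_labels:
        raise ValueError("training requires a labeled feature table")
    if len(table) < 10:
        raise ValueError("need at least 10 training rows")
    y = table.labels.to_numpy()
    if len(set(y)) < 2:
        raise ValueError("training labels contain a single class")
    _check_schema(table, feature_names)
    X = encode_features(table.frame, feature_names)
    p = X.shape[1]
    if cfg.mtry is not None and not 1 <= cfg.mtry <= p:
        raise ValueError(f"mtry must be in 1..{p}, got {cfg.mtry}")
    est = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=cfg.mtry if cfg.mtry is not None else "sqrt",
        oob_score=True,
        bootstrap=True,
        class_weight=cfg.class_weights,
        random_state=cfg.rng_seed,
        n_jobs=1,
    )
    est.fit(X.to_numpy(), y)

    target_idx = list(est.classes_).index(LABEL_TARGET)
    oob_proba = est.oob_decision_function_[:, target_idx]
    valid = ~np.isnan(oob_proba)
    oob_pred = np.where(
        oob_proba > cfg.decision_threshold, LABEL_TARGET, LABEL_NON_TARGET
    )
    oob_error = float(np.mean(oob_pred[valid] != y[valid]))
    per_class = {}
    for label in (LABEL_TARGET, LABEL_NON_TARGET):
        mask = valid & (y == label)
        per_class[label] = (
            float(np.mean(oob_pred[mask] != label)) if mask.any() else math.nan
        )

    raw = pd.Series(est.feature_importances_, index=X.columns)
    gini = raw.groupby(_original_feature).sum().reindex(feature_names).fillna(0.0)

    return TrainedForest(
        estimator=est,
        feature_names=feature_names,
        encoded_columns=list(X.columns),
        config=cfg,
        oob_error=oob_error,
        oob_error_per_class=per_class,
        oob_proba=oob_proba,
        gini_importance=gini,
    )


def predict(forest: TrainedForest, table: FeatureTable) -> pd.DataFrame:
    """Per-row P(TARGET) (fraction of trees voting TARGET) and hard class."""
    _check_schema(table, forest.feature_names)
    X = encode_features(table.frame, forest.feature_names)
    X = X[forest.encoded_columns].to_numpy()
    target_code = list(forest.estimator.classes_).index(LABEL_TARGET)
    votes = np.zeros(len(X))
    for tree in forest.estimator.estimators_:
        votes += tree.predict(X) == target_code
    proba = votes / len(forest.estimator.estimators_)
    hard = np.where(
        proba > forest.config.decision_threshold, LABEL_TARGET, LABEL_NON_TARGET
    )
    return pd.DataFrame(
        {"pair_id": table.ids, "probability": proba, "predicted": hard}
    )


def rank_features_by_gini(forest: TrainedForest) -> list[tuple[str, float]]:
    """Features in non-increasing Gini-importance order (schema order breaks ties)."""
    order = sorted(
        range(len(forest.feature_names)),
        key=lambda i: (-forest.gini_importance.iloc[i], i),
    )
    return [
        (forest.feature_names[i], float(forest.gini_importance.iloc[i]))
        for i in order
    ]


def tune_mtry(
    table: FeatureTable,
    cfg: RFConfig | None = None,
    grid: Optional[Sequence[int]] = None,
    k: int = 10,
    repeats: int = 5,
    feature_names: Optional[Sequence[str]] = None,
) -> tuple[int, pd.DataFrame]:
    """Pick mtry by resampled AUC and the one-standard-error rule.

    Each grid value is profiled with repeated stratified cross-validation;
    the chosen value is the smallest mtry whose mean AUC lies within one
    standard error of the best mean (simplest model near the optimum).
    """
    from .evaluation import repeated_cv  # local import: avoid cycle

    cfg = cfg or RFConfig()
    feature_names = list(feature_names or FEATURE_NAMES)
    p = encode_features(table.frame.iloc[:2], feature_names).shape[1]
    if grid is None:
        grid = sorted({2, int(math.isqrt(p)), p // 3, p // 2})
    usable = []
    for m in grid:
        if 1 <= m <= p:
            usable.append(int(m))
        else:
            logger.warning("dropping mtry=%s (outside 1..%d)", m, p)
    if not usable:
        raise ValueError("empty mtry grid after validation")

    rows = []
    for m in usable:
        result = repeated_cv(
            table,
            replace(cfg, mtry=m),
            k=k,
            repeats=repeats,
            seed=cfg.rng_seed,
            feature_names=feature_names,
        )
        aucs = result.fold_metrics["auc"].to_numpy()
        rows.append(
            {
                "mtry": m,
                "mean_auc": float(np.mean(aucs)),
                "se_auc": float(np.std(aucs, ddof=1) / math.sqrt(len(aucs))),
            }
        )
    profile = pd.DataFrame(rows)
    best = profile.loc[profile["mean_auc"].idxmax()]
    cutoff = best["mean_auc"] - best["se_auc"]
    chosen = int(profile.loc[profile["mean_auc"] >= cutoff, "mtry"].min())
    return chosen, profile


def forward_feature_selection(
    table: FeatureTable,
    cfg: RFConfig | None = None,
    ranking: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, int]:
    """Restricted forward selection along a fixed relevance ranking.

    Trains one forest per prefix of the ranking (most to least relevant) and
    scores it on OOB data; the recommended prefix size maximizes OOB MCC
    (ties favour the smaller model).
    """
    from .evaluation import ConfusionMatrix, metrics_from_confusion

    cfg = cfg or RFConfig()
    if ranking is None:
        ranking = [n for n, _ in rank_features_by_gini(train_forest(table, cfg))]
    ranking = list(ranking)
    y = table.labels.to_numpy()
    rows = []
    for size in range(1, len(ranking) + 1):
        sub = train_forest(table, cfg, feature_names=ranking[:size])
        valid = ~np.isnan(sub.oob_proba)
        pred = np.where(
            sub.oob_proba > cfg.decision_threshold, LABEL_TARGET, LABEL_NON_TARGET
        )
        cm = ConfusionMatrix(
            tp=float(np.sum((pred == LABEL_TARGET) & (y == LABEL_TARGET) & valid)),
            tn=float(np.sum((pred == LABEL_NON_TARGET) & (y == LABEL_NON_TARGET) & valid)),
            fp=float(np.sum((pred == LABEL_TARGET) & (y == LABEL_NON_TARGET) & valid)),
            fn=float(np.sum((pred == LABEL_NON_TARGET) & (y == LABEL_TARGET) & valid)),
        )
        met = metrics_from_confusion(cm)
        rows.append(
            {
                "k": size,
                "feature_added": ranking[size - 1],
                "acc": met.acc,
                "sen": met.sen,
                "spe": met.spe,
                "mcc": met.mcc,
            }
        )
    profile = pd.DataFrame(rows)
    recommended = int(profile.loc[profile["mcc"].idxmax(), "k"])
    return profile, recommended


def partial_dependence(
    forest: TrainedForest,
    feature: str,
    table: FeatureTable,
    grid: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Marginal effect of one feature on P(TARGET).

    For every level (nominal features) or quantile-grid value (numeric
    features) the feature is forced to that value in every row and the mean
    predicted probability is recorded.
    """
    if feature not in forest.feature_names:
        raise KeyError(f"unknown feature: {feature}")
    if grid is None:
        if feature in NUMERIC_FEATURES:
            qs = np.linspace(0.0, 1.0, 11)
            grid = sorted(set(np.quantile(table.frame[feature].astype(float), qs)))
        else:
            grid = POSITION_LEVELS
    rows = []
    for value in grid:
        forced = FeatureTable(table.frame.copy())
        forced.frame[feature] = value
        proba = predict(forest, forced)["probability"].to_numpy()
        rows.append({"value": value, "mean_probability": float(np.mean(proba))})
    return pd.DataFrame(rows)
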