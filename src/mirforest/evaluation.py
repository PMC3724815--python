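"""Performance assessment: confusion-matrix metrics, ROC/AUC, repeated
cross-validation, label-permutation significance and probability-vector
comparisons.

Conventions
-----------
* ACC, SEN and SPE are percentages; MCC is in [-1, 1]; AUC in [0, 1].
* Confusion-matrix cells may be fractional: fold-averaged matrices from
  repeated cross-validation are reported as means over repetitions.
* Printed-precision reporting TRUNCATES toward zero instead of rounding
  (:func:`truncate`); internal computation always uses full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import LABEL_NON_TARGET, LABEL_TARGET, FeatureTable

METRIC_NAMES = ("acc", "sen", "spe", "mcc", "auc")


def truncate(value: float, decimals: int) -> float:
    """Truncate toward zero at ``decimals`` places (87.208 -> 87.20).

    Float noise is first rounded away far below the reporting precision so
    that values sitting exactly on a digit boundary are not nudged down.
    """
    scale = 10 ** decimals
    return math.trunc(round(value * scale, 6)) / scale


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/TN/FP/FN counts; fractional cells allowed for fold averages."""

    tp: float
    tn: float
    fp: float
    fn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion matrix cells must be non-negative")

    @property
    def total(self) -> float:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(
        cls, labels: Sequence[str], predicted: Sequence[str]
    ) -> "ConfusionMatrix":
        y = np.asarray(labels)
        p = np.asarray(predicted)
        return cls(
            tp=float(np.sum((p == LABEL_TARGET) & (y == LABEL_TARGET))),
            tn=float(np.sum((p == LABEL_NON_TARGET) & (y == LABEL_NON_TARGET))),
            fp=float(np.sum((p == LABEL_TARGET) & (y == LABEL_NON_TARGET))),
            fn=float(np.sum((p == LABEL_NON_TARGET) & (y == LABEL_TARGET))),
        )


@dataclass(frozen=True)
class MetricSet:
    """ACC/SEN/SPE in percent, MCC in [-1, 1], optional AUC in [0, 1]."""

    acc: float
    sen: float
    spe: float
    mcc: float
    auc: float = math.nan

    def truncated(self, acc_dec=2, mcc_dec=3) -> "MetricSet":
        return MetricSet(
            acc=truncate(self.acc, acc_dec),
            sen=truncate(self.sen, acc_dec),
            spe=truncate(self.spe, acc_dec),
            mcc=truncate(self.mcc, mcc_dec),
            auc=self.auc if math.isnan(self.auc) else truncate(self.auc, 3),
        )


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricSet:
    """ACC/SEN/SPE (percent) and MCC from a confusion matrix.

    A metric whose denominator vanishes is reported as NaN (undefined);
    an all-zero matrix is an error.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    acc = 100.0 * (cm.tp + cm.tn) / cm.total
    sen = 100.0 * cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else math.nan
    spe = 100.0 * cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp > 0 else math.nan
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    mcc = (
        (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)
        if denom > 0
        else math.nan
    )
    return MetricSet(acc=acc, sen=sen, spe=spe, mcc=mcc)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(
    scores: Sequence[float], labels: Sequence[str]
) -> tuple[float, list[tuple[float, float]]]:
    """AUC via a threshold sweep plus the (FPR, TPR) curve points.

    Equals the probability that a random positive outscores a random
    negative, with ties counted 1/2.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == LABEL_TARGET
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    # keep only the last index of each tied score block
    distinct = np.r_[np.diff(s) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def pairwise_auc(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Brute-force pairwise-ranking AUC (reference implementation)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == LABEL_TARGET
    pos, neg = s[y], s[~y]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC requires both classes present")
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return float(wins / (len(pos) * len(neg)))


# ---------------------------------------------------------------------------
# Repeated cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-fold metrics, per-repeat aggregates and the fold-averaged matrix."""

    fold_metrics: pd.DataFrame          # repeat, fold, acc..auc
    repeat_metrics: pd.DataFrame        # one row per repeat (summed matrices)
    mean_confusion: ConfusionMatrix     # cells averaged over repeats
    summary: dict                       # metric -> (mean, sd) across repeats

    def metric_mean(self, name: str) -> float:
        return self.summary[name][0]


def _stratified_folds(
    y: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Index partition into k stratified folds, sizes differing by <= 1."""
    folds: list[list[int]] = [[] for _ in range(k)]
    start = 0
    for label in np.unique(y):
        idx = np.flatnonzero(y == label)
        rng.shuffle(idx)
        for offset, i in enumerate(idx):
            folds[(start + offset) % k].append(int(i))
        start += len(idx)
    return [np.array(sorted(f)) for f in folds]


def repeated_cv(
    table: FeatureTable,
    cfg=None,
    k: int = 10,
    repeats: int = 5,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
) -> CVResult:
    """Repeated stratified k-fold cross-validation of the forest.

    Per fold: train on k-1 folds, predict the held-out fold, score.  Per
    repeat the fold confusion matrices are summed (the folds partition the
    data, so the sum covers every row once); the reported matrix and the
    metric mean/sd are taken across repeats.
    """
    from .forest import RFConfig, predict, train_forest

    cfg = cfg or RFConfig()
    if not table.has_labels:
        raise ValueError("cross-validation requires labels")
    y = table.labels.to_numpy()
    n = len(y)
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} rows for {k}-fold CV")

    fold_rows, repeat_rows = [], []
    repeat_cms = []
    for r in range(repeats):
        rng = np.random.default_rng((seed * 1_000_003 + r) % (2**31))
        folds = _stratified_folds(y, k, rng)
        cm_sum = np.zeros(4)  # tp, tn, fp, fn
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            train_tab = FeatureTable(table.frame.iloc[train_idx].reset_index(drop=True))
            test_tab = FeatureTable(table.frame.iloc[test_idx].reset_index(drop=True))
            fit_cfg = replace(cfg, rng_seed=(cfg.rng_seed + 7919 * r + f) % (2**31))
            model = train_forest(train_tab, fit_cfg, feature_names=feature_names)
            preds = predict(model, test_tab)
            cm = ConfusionMatrix.from_predictions(
                y[test_idx], preds["predicted"].to_numpy()
            )
            auc, _ = roc_auc(preds["probability"].to_numpy(), y[test_idx])
            met = metrics_from_confusion(cm)
            fold_rows.append(
                {
                    "repeat": r,
                    "fold": f,
                    "acc": met.acc,
                    "sen": met.sen,
                    "spe": met.spe,
                    "mcc": met.mcc,
                    "auc": auc,
                }
            )
            cm_sum += (cm.tp, cm.tn, cm.fp, cm.fn)
        rep_cm = ConfusionMatrix(*cm_sum)
        rep_met = metrics_from_confusion(rep_cm)
        rep_auc = float(
            np.mean([row["auc"] for row in fold_rows if row["repeat"] == r])
        )
        repeat_cms.append(cm_sum)
        repeat_rows.append(
            {
                "repeat": r,
                "tp": rep_cm.tp,
                "tn": rep_cm.tn,
                "fp": rep_cm.fp,
                "fn": rep_cm.fn,
                "acc": rep_met.acc,
                "sen": rep_met.sen,
                "spe": rep_met.spe,
                "mcc": rep_met.mcc,
                "auc": rep_auc,
            }
        )

    fold_metrics = pd.DataFrame(fold_rows)
    repeat_metrics = pd.DataFrame(repeat_rows)
    mean_cells = np.mean(repeat_cms, axis=0)
    summary = {
        m: (
            float(repeat_metrics[m].mean()),
            float(repeat_metrics[m].std(ddof=1)) if repeats > 1 else 0.0,
        )
        for m in METRIC_NAMES
    }
    return CVResult(
        fold_metrics=fold_metrics,
        repeat_metrics=repeat_metrics,
        mean_confusion=ConfusionMatrix(*mean_cells),
        summary=summary,
    )


# ---------------------------------------------------------------------------
# Significance tests
# ---------------------------------------------------------------------------

def permutation_test_auc(
    scores: Sequence[float],
    labels: Sequence[str],
    n_perm: int = 2000,
    seed: int = 0,
    corrected: bool = False,
) -> float:
    """Label-permutation p-value for the observed AUC.

    p is the fraction of label permutations whose AUC is at least the
    observed one; ``corrected`` applies the (r+1)/(n+1) adjustment.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    observed, _ = roc_auc(scores, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    perm = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        auc, _ = roc_auc(scores, perm)
        if auc >= observed:
            hits += 1
    if corrected:
        return (hits + 1) / (n_perm + 1)
    return hits / n_perm


def compare_probability_vectors(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two probability vectors."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("probability vectors must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def paired_resample_test(
    aucs_a: Sequence[float], aucs_b: Sequence[float]
) -> tuple[float, float]:
    """Paired t-test on per-resample AUC differences.

    Zero-variance differences make the statistic undefined: NaNs are
    returned rather than a number.
    """
    a, b = np.asarray(aucs_a, float), np.asarray(aucs_b, float)
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("paired test needs equal-length non-empty vectors")
    diff = a - b
    if np.all(diff == diff[0]):
        return math.nan, math.nan
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
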