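"""Random-Forest feature selection and cultivar classification.

Feature importance is Mean Decrease in Impurity (Gini) from a 100-tree
forest; the accuracy-vs-top-k curve refits the forest on the leading k
descriptors of the ranking under a fixed 80/20 train/test split.  The
classification report mirrors the standard multiclass panel: confusion
matrix (rows = true, columns = predicted), per-class precision/recall/F1
with the return-0 convention on empty denominators, weighted averages and
overall accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

__all__ = [
    "FeatureRanking", "ClassificationReport", "rank_features_mdi",
    "accuracy_vs_topk", "common_top_features", "train_rf",
    "classification_metrics", "f1_from_precision_recall",
    "DEFAULT_RF_PARAMS", "COMMON_SIX_DESCRIPTORS",
]

#: Forest hyperparameters used throughout (exposed for config overrides).
DEFAULT_RF_PARAMS = dict(
    n_estimators=100, criterion="gini", max_depth=None, min_samples_split=2,
    min_samples_leaf=1, max_features="sqrt", bootstrap=True,
)

#: The six descriptors shared by the pooled classification / clustering / PCA
#: stages.  The per-class top-10 rankings intersect in only four descriptors
#: (BAC, I2y, I2_TP, PL_L1); the six-descriptor list used downstream adds
#: WxH and PL, and is kept as an explicit config default with the discrepancy
#: flagged by :func:`common_top_features` callers.
COMMON_SIX_DESCRIPTORS = ["WxH", "PL", "I2_TP", "I2y", "PL_L1", "BAC"]


@dataclass(frozen=True)
class FeatureRanking:
    """Descriptors ordered by MDI importance (non-increasing)."""
    features: List[str]
    importances: List[float]
    importance_sds: List[float]

    def top(self, k: int) -> List[str]:
        if k > len(self.features):
            raise ValueError(f"k={k} exceeds ranking length {len(self.features)}")
        return self.features[:k]


@dataclass
class ClassificationReport:
    labels: List[str]
    confusion: np.ndarray
    precision: Dict[str, float]
    recall: Dict[str, float]
    f1: Dict[str, float]
    accuracy: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    warnings: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "confusion": self.confusion.tolist(),
            "per_class": {c: {"precision": self.precision[c],
                              "recall": self.recall[c],
                              "f1": self.f1[c]} for c in self.labels},
            "accuracy": self.accuracy,
            "weighted": {"precision": self.weighted_precision,
                         "recall": self.weighted_recall,
                         "f1": self.weighted_f1},
            "warnings": self.warnings,
        }


def _check_X(X: pd.DataFrame) -> None:
    if X.isna().any().any():
        raise ValueError("descriptor matrix contains missing values")


def rank_features_mdi(X: pd.DataFrame, y: Sequence[str], seed: int,
                      rf_params: dict | None = None) -> FeatureRanking:
    """MDI (Gini) importance ranking over all columns of X.

    Importances sum to 1; ties break on importance descending then name
    ascending, so the ranking is reproducible for a fixed seed.
    """
    _check_X(X)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes")
    params = {**DEFAULT_RF_PARAMS, **(rf_params or {})}
    rf = RandomForestClassifier(random_state=seed, **params)
    rf.fit(X.to_numpy(), y)
    imp = rf.feature_importances_
    per_tree = np.array([t.feature_importances_ for t in rf.estimators_])
    sds = per_tree.std(axis=0)
    order = sorted(range(X.shape[1]), key=lambda j: (-imp[j], X.columns[j]))
    return FeatureRanking(
        features=[str(X.columns[j]) for j in order],
        importances=[float(imp[j]) for j in order],
        importance_sds=[float(sds[j]) for j in order])


def _split(X: np.ndarray, y: np.ndarray, split: float, seed: int,
           stratify: bool) -> Tuple[np.ndarray, ...]:
    strat = y if stratify else None
    return train_test_split(X, y, train_size=split, random_state=seed,
                            stratify=strat)


def accuracy_vs_topk(X: pd.DataFrame, y: Sequence[str],
                     ranking: FeatureRanking, split: float = 0.8,
                     seed: int = 10, stratify: bool = True,
                     rf_params: dict | None = None) -> List[Tuple[int, float]]:
    """Held-out accuracy as a function of the number of top-ranked descriptors.

    One point per k = 1..p, each from refitting the forest on the top-k
    columns under the same fixed split.
    """
    _check_X(X)
    if set(ranking.features) != set(map(str, X.columns)):
        raise ValueError("ranking does not cover the columns of X")
    y = np.asarray(y)
    params = {**DEFAULT_RF_PARAMS, **(rf_params or {})}
    curve = []
    for k in range(1, len(ranking.features) + 1):
        cols = ranking.top(k)
        Xtr, Xte, ytr, yte = _split(X[cols].to_numpy(), y, split, seed,
                                    stratify)
        rf = RandomForestClassifier(random_state=seed, **params)
        rf.fit(Xtr, ytr)
        curve.append((k, float((rf.predict(Xte) == yte).mean())))
    return curve


def common_top_features(rankingA: FeatureRanking, rankingB: FeatureRanking,
                        k: int = 10) -> Set[str]:
    """Descriptors present in the top k of both rankings."""
    return set(rankingA.top(k)) & set(rankingB.top(k))


def train_rf(X: pd.DataFrame, y: Sequence[str], split: float = 0.8,
             seed: int = 10, stratify: bool = True,
             rf_params: dict | None = None):
    """Fit the forest on an 80/20 split and report held-out performance.

    The split is stratified by cultivar when every class has >= 2 members;
    otherwise it falls back to an unstratified split with a warning recorded
    on the report.
    """
    _check_X(X)
    y = np.asarray(y)
    warnings: List[str] = []
    labels, counts = np.unique(y, return_counts=True)
    if stratify and counts.min() < 2:
        warnings.append("class with a single member; unstratified split used")
        stratify = False
    Xtr, Xte, ytr, yte = _split(X.to_numpy(), y, split, seed, stratify)
    params = {**DEFAULT_RF_PARAMS, **(rf_params or {})}
    rf = RandomForestClassifier(random_state=seed, **params)
    rf.fit(Xtr, ytr)
    pred = rf.predict(Xte)
    label_list = [str(c) for c in labels]
    index = {c: i for i, c in enumerate(label_list)}
    conf = np.zeros((len(label_list), len(label_list)), dtype=int)
    for t, p in zip(yte, pred):
        conf[index[str(t)], index[str(p)]] += 1
    report = classification_metrics(conf, labels=label_list)
    report.warnings.extend(warnings)
    return rf, report


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic-mean F1 = 2PR / (P + R); 0 when both are 0."""
    if precision == 0 and recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def classification_metrics(confusion: np.ndarray,
                           labels: Sequence[str] | None = None) -> ClassificationReport:
    """Per-class precision/recall/F1, accuracy and weighted averages.

    ``confusion`` is square with rows = true labels, columns = predicted.
    Empty denominators (a class never predicted, or absent from the test
    fold) yield 0 by convention.  Weighted averages weight by true-class
    counts, so weighted recall equals accuracy identically.
    """
    conf = np.asarray(confusion)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(conf < 0) or not np.issubdtype(conf.dtype, np.integer):
        raise ValueError("confusion matrix must hold non-negative integers")
    total = conf.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zero")
    n = conf.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    labels = list(labels)
    tp = np.diag(conf).astype(float)
    pred_tot = conf.sum(axis=0).astype(float)
    true_tot = conf.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(pred_tot > 0, tp / pred_tot, 0.0)
        rec = np.where(true_tot > 0, tp / true_tot, 0.0)
    f1 = np.array([f1_from_precision_recall(p, r) for p, r in zip(prec, rec)])
    w = true_tot / total
    return ClassificationReport(
        labels=labels,
        confusion=conf,
        precision={c: float(p) for c, p in zip(labels, prec)},
        recall={c: float(r) for c, r in zip(labels, rec)},
        f1={c: float(v) for c, v in zip(labels, f1)},
        accuracy=float(tp.sum() / total),
        weighted_precision=float((w * prec).sum()),
        weighted_recall=float((w * rec).sum()),
        weighted_f1=float((w * f1).sum()),
    )
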