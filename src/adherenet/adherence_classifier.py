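"""High/low adherence classification from nodal connectome features.

Participants are split into high adherence (homework strictly above the
cutoff, default 10 of 20) and low adherence. Features are nodal clustering
coefficient and degree centrality at the robust nodes, taken at a reference
threshold (default T = 0.35). A quarter of participants is held out with
stratification; on the training partition only, backward elimination with a
100-tree random forest prunes features, then four classifiers (random forest,
AdaBoost, decision tree, Gaussian naive Bayes) are scored by leave-one-out
cross-validation repeated over five seeds and finally evaluated on the
held-out set via ROC/AUC.

All data-dependent choices -- feature selection included -- happen inside the
training partition; the held-out set is touched exactly once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import LeaveOneOut, cross_val_score, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier

from .io_formats import AdherenceRecord, RunConfig
from .stat_inference import RobustNodeSet

CLASSIFIER_NAMES = ("random_forest", "adaboost", "decision_tree", "naive_bayes")


@dataclass(frozen=True)
class AdherenceLabel:
    participant_id: str
    label: str  # "high" or "low"


@dataclass(frozen=True)
class FeatureTable:
    """Participants x (node, metric) feature matrix with provenance."""

    values: pd.DataFrame  # index participant_id, columns "node|metric"
    threshold: float
    provenance: tuple[tuple[str, str], ...]  # (node, metric) per column

    @property
    def participant_ids(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    def subset(self, columns: Sequence[str]) -> "FeatureTable":
        keep = [c for c in self.values.columns if c in set(columns)]
        prov = tuple(p for c, p in zip(self.values.columns, self.provenance)
                     if c in set(columns))
        return FeatureTable(self.values[keep], self.threshold, prov)


@dataclass(frozen=True)
class ClassifierScores:
    cv_scores: tuple[float, ...]  # one LOOCV accuracy per seed
    heldout_score: float
    roc_fpr: tuple[float, ...]
    roc_tpr: tuple[float, ...]
    auc: float | None

    @property
    def cv_mean(self) -> float:
        return float(np.mean(self.cv_scores))

    @property
    def cv_ci95(self) -> float:
        s = np.asarray(self.cv_scores)
        if len(s) < 2 or s.std(ddof=1) == 0:
            return 0.0
        return float(1.96 * s.std(ddof=1) / np.sqrt(len(s)))


@dataclass(frozen=True)
class ClassifierReport:
    per_classifier: Mapping[str, ClassifierScores]
    pooled_cv_mean: float = field(default=float("nan"))
    pooled_cv_ci95: float = field(default=float("nan"))


def label_binarize(records: Sequence[AdherenceRecord],
                   cutoff: int = 10) -> list[AdherenceLabel]:
    """'high' iff homework > cutoff (strict); everyone else 'low'."""
    return [
        AdherenceLabel(r.participant_id, "high" if r.homework > cutoff else "low")
        for r in records
    ]


def build_feature_table(metric_table: pd.DataFrame,
                        robust_sets: Sequence[RobustNodeSet],
                        threshold: float = 0.35) -> FeatureTable:
    """Assemble (node, metric) features at the reference threshold.

    Each robust set contributes its nodes under its own metric; columns are
    named ``node|metric`` and provenance keeps the pairing explicit.
    """
    pieces = []
    provenance: list[tuple[str, str]] = []
    for rs in robust_sets:
        for node in rs.nodes:
            sub = metric_table[
                (metric_table["metric"] == rs.metric)
                & (metric_table["scope"] == node)
                & (np.isclose(metric_table["threshold"], threshold))
            ]
            col = sub.set_index("participant_id")["value"].rename(f"{node}|{rs.metric}")
            pieces.append(col)
            provenance.append((node, rs.metric))
    if not pieces:
        raise ValueError("no robust nodes: feature table would be empty")
    values = pd.concat(pieces, axis=1)
    if values.isna().any().any():
        raise ValueError("feature table has missing values")
    return FeatureTable(values, threshold, tuple(provenance))


def holdout_split(table: FeatureTable, labels: Sequence[AdherenceLabel],
                  fraction: float = 0.25, seed: int = 0
                  ) -> tuple[FeatureTable, list[AdherenceLabel],
                             FeatureTable, list[AdherenceLabel]]:
    """Stratified split into (train, heldout); heldout size = round(fraction*n)."""
    by_id = {l.participant_id: l for l in labels}
    ids = list(table.participant_ids)
    y = [by_id[i].label for i in ids]
    for cls in ("high", "low"):
        if y.count(cls) < 2:
            raise ValueError(f"class {cls!r} has < 2 members: cannot stratify")
    n_test = int(round(fraction * len(ids)))
    train_ids, test_ids = train_test_split(
        ids, test_size=n_test, stratify=y, random_state=seed
    )
    train = FeatureTable(table.values.loc[train_ids], table.threshold, table.provenance)
    test = FeatureTable(table.values.loc[test_ids], table.threshold, table.provenance)
    return (train, [by_id[i] for i in train_ids], test, [by_id[i] for i in test_ids])


def _y_array(labels: Sequence[AdherenceLabel]) -> np.ndarray:
    return np.array([1 if l.label == "high" else 0 for l in labels])


def loocv_accuracy(clf, X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out cross-validated accuracy."""
    return float(cross_val_score(clf, X, y, cv=LeaveOneOut()).mean())


def backward_elimination(table: FeatureTable, labels: Sequence[AdherenceLabel],
                         seed: int = 0, min_features: int = 2,
                         n_estimators: int = 100
                         ) -> tuple[FeatureTable, list[str]]:
    """Greedy backward elimination scored by a random-forest LOOCV accuracy.

    At each step the feature whose removal yields the best (or least harmed)
    accuracy is dropped; the loop stops when every removal would lower the
    accuracy or ``min_features`` is reached. Returns the reduced table and the
    elimination order (dropped first to last).
    """
    X = table.values.to_numpy()
    y = _y_array(labels)
    columns = list(table.values.columns)
    if len(columns) < 2:
        warnings.warn("single-feature table: nothing to eliminate", UserWarning,
                      stacklevel=2)
        return table, []

    def score(cols: list[str]) -> float:
        idx = [columns.index(c) for c in cols]
        clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
        return loocv_accuracy(clf, X[:, idx], y)

    current = list(columns)
    current_score = score(current)
    eliminated: list[str] = []
    while len(current) > min_features:
        candidates = [(score([c for c in current if c != drop]), drop)
                      for drop in current]
        best_score, best_drop = max(candidates, key=lambda t: t[0])
        if best_score < current_score:
            break
        current = [c for c in current if c != best_drop]
        current_score = best_score
        eliminated.append(best_drop)
    return table.subset(current), eliminated


def roc_curve(scores: Sequence[float], labels: Sequence[int]
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points by threshold sweep and trapezoidal AUC.

    AUC equals the Mann-Whitney concordance count normalized by
    n_pos * n_neg (ties counted half).
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def _make_classifier(name: str, seed: int):
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "naive_bayes":
        return GaussianNB()
    raise ValueError(f"unknown classifier {name!r}")


def train_and_evaluate(train: FeatureTable, train_labels: Sequence[AdherenceLabel],
                       heldout: FeatureTable, heldout_labels: Sequence[AdherenceLabel],
                       cfg: RunConfig,
                       classifiers: Sequence[str] = CLASSIFIER_NAMES
                       ) -> ClassifierReport:
    """Score the four classifiers by per-seed LOOCV, then on the held-out set.

    Seeds drive classifier-internal randomness only; the LOOCV split itself is
    deterministic. The held-out ROC uses the mean predicted high-class
    probability across seeds; a single-class held-out set leaves the AUC
    undefined (None).
    """
    X_tr = train.values.to_numpy()
    y_tr = _y_array(train_labels)
    X_te = heldout.values.to_numpy()
    y_te = _y_array(heldout_labels)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training set must contain both classes")

    per: dict[str, ClassifierScores] = {}
    all_cv: list[float] = []
    for name in classifiers:
        cv_scores = []
        probas = []
        heldout_accs = []
        for seed in cfg.seeds:
            clf = _make_classifier(name, seed)
            cv_scores.append(loocv_accuracy(clf, X_tr, y_tr))
            clf.fit(X_tr, y_tr)
            heldout_accs.append(float(clf.score(X_te, y_te)))
            probas.append(clf.predict_proba(X_te)[:, list(clf.classes_).index(1)])
        mean_proba = np.mean(probas, axis=0)
        if len(np.unique(y_te)) < 2:
            fpr, tpr, auc = (np.array([]), np.array([]), None)
        else:
            fpr, tpr, auc = roc_curve(mean_proba, y_te)
        per[name] = ClassifierScores(
            cv_scores=tuple(cv_scores),
            heldout_score=float(np.mean(heldout_accs)),
            roc_fpr=tuple(fpr), roc_tpr=tuple(tpr), auc=auc,
        )
        all_cv.extend(cv_scores)
    pooled = np.asarray(all_cv)
    pooled_ci = 0.0
    if len(pooled) > 1 and pooled.std(ddof=1) > 0:
        pooled_ci = float(1.96 * pooled.std(ddof=1) / np.sqrt(len(pooled)))
    return ClassifierReport(per, float(pooled.mean()), pooled_ci)
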