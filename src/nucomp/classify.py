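"""Feature-based taxonomic classification harness.

Given a per-genome feature table with a label column (a taxonomic rank or
the genome type), the harness prunes classes with too few members, runs a
repeated stratified train/test holdout (default 80/20, 50 repetitions) over
one of five classifier families — linear discriminant analysis (LDA),
Gaussian naive Bayes (GNB), k-nearest neighbors (KNN), support vector
machine (SVM), gradient-boosted trees (XGB) — and reports mean accuracy (in
percent) and mean weighted F1 across repetitions, next to the analytic
random-classifier baseline

    p_hit = sum_i p(c_i) * (1/N) = 1/N,

which depends only on the number of classes N, never on class imbalance.
Classifier hyperparameters are library defaults (recorded in the result for
audit); repetition r uses seed ``task.seed + r``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import LabelEncoder, StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from nucomp.measures import DEFAULT_FEATURES

logger = logging.getLogger(__name__)

CLASSIFIERS = ("LDA", "GNB", "KNN", "SVM", "XGB")


@dataclass(frozen=True)
class ClassificationTask:
    """Protocol parameters for one classification target."""

    target: str = "label"
    features: tuple[str, ...] = DEFAULT_FEATURES
    min_class_size: int = 4
    test_fraction: float = 0.2
    repetitions: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.min_class_size < 1:
            raise ValueError("min_class_size must be >= 1")


@dataclass
class TaskResult:
    """Mean metrics over repetitions for one (task, classifier) pair."""

    classifier: str
    accuracy: float  # percent
    weighted_f1: float  # in [0, 1]
    n_classes: int
    n_samples: int
    p_hit_random: float  # percent
    hyperparameters: Mapping = field(default_factory=dict)


def drop_rare_classes(
    table: pd.DataFrame, min_n: int = 4, label_col: str = "label"
) -> tuple[pd.DataFrame, list[str]]:
    """Remove every class with fewer than ``min_n`` members.

    Returns the pruned table and the removed class names. Pruning happens
    once, before any splitting. Fewer than two surviving classes is an error
    (the task is undefined).
    """
    counts = table[label_col].value_counts()
    removed = sorted(counts.index[counts < min_n].tolist())
    kept = table[~table[label_col].isin(removed)]
    if kept[label_col].nunique() < 2:
        raise ValueError(
            f"fewer than 2 classes remain after dropping classes with < {min_n} samples"
        )
    return kept, removed


def weighted_f1(y_true: Sequence, y_pred: Sequence) -> float:
    """Support-weighted mean of per-class F1 scores.

    Per class: precision P = TP/(TP+FP), recall R = TP/(TP+FN), F1 = 2PR/(P+R)
    (0 when P+R = 0). Weights are class supports in ``y_true`` divided by the
    total; classes never seen in ``y_true`` contribute nothing.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if not y_true:
        raise ValueError("need at least one label")
    support = Counter(y_true)
    pred_counts = Counter(y_pred)
    tp = Counter(t for t, p in zip(y_true, y_pred) if t == p)
    total = len(y_true)
    score = 0.0
    for cls, sup in support.items():
        tpc = tp.get(cls, 0)
        fpc = pred_counts.get(cls, 0) - tpc
        precision = tpc / (tpc + fpc) if tpc + fpc else 0.0
        recall = tpc / sup
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        score += (sup / total) * f1
    return score


def p_hit_random(class_counts: Mapping[str, int]) -> float:
    """Expected accuracy (percent) of a uniformly random classifier.

    p_hit = sum_i p(c_i) * p_correct(c_i) with p(c_i) the empirical class
    probability and p_correct = 1/N for a random guesser; the sum collapses
    to 1/N whatever the counts. Returned unrounded, in percent (report
    rounded to 2 decimals).
    """
    if not class_counts:
        raise ValueError("need at least one class")
    counts = np.array(list(class_counts.values()), dtype=float)
    if np.any(counts <= 0):
        raise ValueError("class counts must be positive")
    n_classes = len(counts)
    p = counts / counts.sum()
    return 100.0 * float(np.sum(p * (1.0 / n_classes)))


def make_classifier(name: str, seed: int):
    """Instantiate one of the five classifier families with library defaults."""
    if name == "LDA":
        return LinearDiscriminantAnalysis()
    if name == "GNB":
        return GaussianNB()
    if name == "KNN":
        return KNeighborsClassifier()
    if name == "SVM":
        return SVC(random_state=seed)
    if name == "XGB":
        return XGBClassifier(random_state=seed, verbosity=0)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


def repeated_stratified_holdout(
    table: pd.DataFrame, task: ClassificationTask, classifier: str
) -> TaskResult:
    """Repeated stratified holdout evaluation of one classifier family.

    For repetition r (seed ``task.seed + r``): stratified split holding out
    ``task.test_fraction`` of each class (proportions preserved to within one
    sample), fit on the training part, predict the held-out part, record
    accuracy and weighted F1. Features are standardized on the training fold
    only. A degenerate split (a class ending up with a single training
    member making stratification impossible) is re-drawn with the next seed
    and logged. Returns means over repetitions; bit-reproducible for a fixed
    task seed.
    """
    label_col = task.target if task.target in table.columns else "label"
    missing = [f for f in task.features if f not in table.columns]
    if missing:
        raise KeyError(f"features missing from table: {missing}")
    x = table[list(task.features)].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be numeric and finite")
    y = LabelEncoder().fit_transform(table[label_col].to_numpy())
    counts = Counter(table[label_col])
    n_classes = len(counts)
    if n_classes < 2:
        raise ValueError("need at least 2 classes (run drop_rare_classes first)")

    accs, f1s = [], []
    extra = 0
    for r in range(task.repetitions):
        while True:
            seed_r = task.seed + r + extra
            try:
                x_tr, x_te, y_tr, y_te = train_test_split(
                    x,
                    y,
                    test_size=task.test_fraction,
                    stratify=y,
                    random_state=seed_r,
                )
                break
            except ValueError:
                extra += 1
                logger.warning("degenerate split at seed %d; redrawing", seed_r)
                if extra > task.repetitions + 10:
                    raise
        scaler = StandardScaler().fit(x_tr)
        model = make_classifier(classifier, seed_r)
        model.fit(scaler.transform(x_tr), y_tr)
        pred = model.predict(scaler.transform(x_te))
        accs.append(100.0 * float(np.mean(pred == y_te)))
        f1s.append(weighted_f1(y_te.tolist(), pred.tolist()))

    params = make_classifier(classifier, task.seed).get_params()
    return TaskResult(
        classifier=classifier,
        accuracy=float(np.mean(accs)),
        weighted_f1=float(np.mean(f1s)),
        n_classes=n_classes,
        n_samples=len(y),
        p_hit_random=p_hit_random(counts),
        hyperparameters={k: v for k, v in params.items() if v is not None},
    )


def run_task(
    table: pd.DataFrame,
    task: ClassificationTask,
    classifiers: Sequence[str] = CLASSIFIERS,
) -> pd.DataFrame:
    """Prune rare classes once, then evaluate each classifier family.

    Returns a tidy DataFrame (one row per classifier) mirroring the usual
    results layout: task target, class/sample counts, p_hit baseline,
    accuracy and weighted F1.
    """
    label_col = task.target if task.target in table.columns else "label"
    pruned, removed = drop_rare_classes(table, task.min_class_size, label_col)
    if removed:
        logger.info("dropped %d rare classes: %s", len(removed), removed)
    rows = []
    for name in classifiers:
        res = repeated_stratified_holdout(pruned, task, name)
        rows.append(
            {
                "target": task.target,
                "classifier": name,
                "n_classes": res.n_classes,
                "n_samples": res.n_samples,
                "p_hit": round(res.p_hit_random, 2),
                "accuracy": round(res.accuracy, 2),
                "weighted_f1": round(res.weighted_f1, 4),
            }
        )
    return pd.DataFrame(rows)
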