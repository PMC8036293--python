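"""Evaluation statistics for staged keratoconus detection.

Two metric conventions coexist deliberately:

* the *literal* forms used by the source tables this package reproduces —
  ``accuracy = (TP + TN) / (TP + FP + FN + TN)``,
  ``sensitivity = TP / (TP + FP)``, ``specificity = TN / (TN + FN)`` — note
  the nonstandard denominators (sensitivity over FP, specificity over FN);
* the textbook forms, exposed under distinct names
  (``recall = TP / (TP + FN)``, ``specificity_tn_fp = TN / (TN + FP)``).

Confusion-matrix bookkeeping likewise reports both a strict-diagonal TP per
class and a "row total minus misses into the normal column" reading, because
published 4-class tables mix the two; reports say which is used.

Also here: stratified k-fold cross-validation, the sample Pearson
correlation (n-1 normalization, sample SDs), and Bland-Altman limits of
agreement (mean difference +/- 1.96 SD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .errors import Kerato3dError, UndefinedMetricError
from .phantom import STAGES

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "AgreementStats",
    "confusion",
    "metrics",
    "kfold_split",
    "kfold_evaluate",
    "pearson_r",
    "bland_altman",
]

#: Display order used by the 4-class detection tables (normal last).
TABLE_ORDER = ("mild", "moderate", "severe", "normal")


@dataclass
class ConfusionMatrix:
    """4-class actual x predicted counts with keratoconus-vs-normal summary.

    ``counts`` rows/cols follow ``classes``.  ``tp_diagonal`` is the strict
    per-class TP; ``tp_row_minus_normal`` counts everything in a keratoconus
    row except misses into the normal column as that class's TP.  The binary
    summary reads the normal row: TN = normal predicted normal, FP = normal
    predicted as any keratoconus stage; FN = keratoconus predicted normal.
    """

    counts: np.ndarray
    classes: tuple[str, ...] = TABLE_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.classes), len(self.classes)):
            raise Kerato3dError("confusion matrix shape does not match classes")
        if (self.counts < 0).any():
            raise Kerato3dError("confusion counts must be non-negative")

    def _i(self, name: str) -> int:
        return self.classes.index(name)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def tp_diagonal(self) -> np.ndarray:
        return np.diag(self.counts).copy()

    @property
    def tp_row_minus_normal(self) -> np.ndarray:
        """Row total minus misses into the normal column (normal: diagonal)."""
        i_norm = self._i("normal")
        tp = self.row_totals - self.counts[:, i_norm]
        tp[i_norm] = self.counts[i_norm, i_norm]
        return tp

    @property
    def tn(self) -> int:
        i = self._i("normal")
        return int(self.counts[i, i])

    @property
    def fp(self) -> int:
        """Normal cases called keratoconus (normal row, off-normal columns)."""
        i = self._i("normal")
        return int(self.row_totals[i] - self.counts[i, i])

    @property
    def fn(self) -> int:
        """Keratoconus cases called normal (normal column, off-normal rows)."""
        i = self._i("normal")
        return int(self.counts[:, i].sum() - self.counts[i, i])

    @property
    def accuracy_multiclass(self) -> float:
        """Strict-diagonal 4-class accuracy, as a percentage."""
        total = int(self.counts.sum())
        if total == 0:
            raise UndefinedMetricError("empty confusion matrix")
        return 100.0 * float(np.trace(self.counts)) / total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


def confusion(
    actual: list[str], predicted: list[str], classes: tuple[str, ...] = TABLE_ORDER
) -> ConfusionMatrix:
    """Tabulate actual x predicted labels (order-invariant)."""
    if len(actual) != len(predicted):
        raise Kerato3dError("label lists differ in length")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for a, p in zip(actual, predicted):
        if a not in index or p not in index:
            raise Kerato3dError(f"unknown label in ({a!r}, {p!r})")
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


@dataclass(frozen=True)
class ClassMetrics:
    """Binary detection counts and the literal + textbook statistics (%)."""

    TP: int
    TN: int
    FP: int
    FN: int
    accuracy: float
    sensitivity: float  # literal: TP / (TP + FP)
    specificity: float  # literal: TN / (TN + FN)
    recall: float  # textbook sensitivity: TP / (TP + FN)
    specificity_tn_fp: float  # textbook specificity: TN / (TN + FP)


def metrics(TP: int, TN: int, FP: int, FN: int) -> ClassMetrics:
    """Accuracy / sensitivity / specificity from raw counts, as percentages.

    Uses the literal definitions (sensitivity over TP+FP, specificity over
    TN+FN); the textbook variants are included under separate names.
    """

    def pct(num: int, den: int, what: str) -> float:
        if den == 0:
            raise UndefinedMetricError(f"{what} undefined: zero denominator")
        return 100.0 * num / den

    return ClassMetrics(
        TP=TP, TN=TN, FP=FP, FN=FN,
        accuracy=pct(TP + TN, TP + FP + FN + TN, "accuracy"),
        sensitivity=pct(TP, TP + FP, "sensitivity"),
        specificity=pct(TN, TN + FN, "specificity"),
        recall=pct(TP, TP + FN, "recall"),
        specificity_tn_fp=pct(TN, TN + FP, "specificity (TN/FP)"),
    )


def kfold_split(
    labels: list[str], k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partition: (train_idx, test_idx) per fold.

    Every case appears in exactly one test fold; per-class fold sizes differ
    by at most one.  Classes smaller than k are rejected.
    """
    labels = list(labels)
    if k < 2:
        raise Kerato3dError("k must be >= 2")
    values, counts = np.unique(labels, return_counts=True)
    too_small = values[counts < k]
    if len(too_small):
        raise Kerato3dError(
            f"classes smaller than k={k}: {', '.join(map(str, too_small))}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (train.copy(), test.copy())
        for train, test in skf.split(np.zeros(len(labels)), labels)
    ]


def kfold_evaluate(
    cases: list,
    labels: list[str],
    k: int,
    seed: int,
    fit_predict,
) -> pd.DataFrame:
    """Cross-validated metrics averaged over folds.

    ``fit_predict(train_cases, train_labels, test_cases) -> predicted labels``
    embodies the classifier.  Returns one row per fold plus a ``mean`` row
    with accuracy, macro precision/recall/F1 (percent).
    """
    from sklearn.metrics import precision_recall_fscore_support

    rows = []
    for fold, (train_idx, test_idx) in enumerate(kfold_split(labels, k, seed)):
        train_cases = [cases[i] for i in train_idx]
        train_labels = [labels[i] for i in train_idx]
        test_cases = [cases[i] for i in test_idx]
        test_labels = [labels[i] for i in test_idx]
        pred = list(fit_predict(train_cases, train_labels, test_cases))
        acc = 100.0 * float(np.mean(np.asarray(pred) == np.asarray(test_labels)))
        prec, rec, f1, _ = precision_recall_fscore_support(
            test_labels, pred, labels=list(STAGES), average="macro", zero_division=0
        )
        rows.append(
            {"fold": fold, "n_test": len(test_idx), "accuracy": acc,
             "precision": 100 * prec, "recall": 100 * rec, "f1": 100 * f1}
        )
    df = pd.DataFrame(rows)
    mean = df.drop(columns="fold").mean()
    mean["fold"] = "mean"
    return pd.concat([df, mean.to_frame().T], ignore_index=True)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation: mean product of z-scores with n-1
    normalization and sample standard deviations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise Kerato3dError("x and y must be 1D of equal length")
    n = len(x)
    if n < 3:
        raise Kerato3dError("need at least 3 pairs")
    sdx = x.std(ddof=1)
    sdy = y.std(ddof=1)
    if sdx == 0 or sdy == 0:
        raise UndefinedMetricError("correlation undefined: zero variance")
    return float(np.sum((x - x.mean()) / sdx * (y - y.mean()) / sdy) / (n - 1))


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman agreement between two measurements of the same quantity."""

    n: int
    mean_diff: float
    sd_diff: float
    lower_limit: float
    upper_limit: float
    table: pd.DataFrame = field(repr=False, compare=False, default=None)


def bland_altman(measured_a: np.ndarray, measured_b: np.ndarray) -> AgreementStats:
    """Differences (a - b) vs means, with 95% limits of agreement
    (mean +/- 1.96 SD).  ``table`` holds per-pair (mean, difference) rows for
    plotting."""
    a = np.asarray(measured_a, dtype=float)
    b = np.asarray(measured_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise Kerato3dError("inputs must be 1D of equal length")
    if len(a) < 3:
        raise Kerato3dError("need at least 3 pairs")
    diff = a - b
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    table = pd.DataFrame({"mean": (a + b) / 2.0, "difference": diff})
    return AgreementStats(
        n=len(a),
        mean_diff=mean_diff,
        sd_diff=sd,
        lower_limit=mean_diff - 1.96 * sd,
        upper_limit=mean_diff + 1.96 * sd,
        table=table,
    )
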