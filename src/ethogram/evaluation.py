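"""Classifier performance metrics and inter-position agreement.

Confusion matrices follow the convention: each row is an *observed*
behaviour, each column the behaviour *predicted* by the classifier.
Per-class precision, recall, F-score and specificity come from the
one-vs-rest collapse of that matrix; overall accuracy is trace/total,
the standard multiclass generalization of (TP+TN)/(TP+TN+FP+FN).

Agreement between the ear-based and collar-based classifiers is
measured with Cohen's weighted κ using linear weights
w_ij = |i−j|/(k−1) over the fixed class order lying < standing <
walking (the "equal weights" convention of the R ``irr`` package);
an unweighted (0/1) variant is provided since the classes are nominal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .signals import CLASSES

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "KappaResult",
    "confusion_matrix",
    "class_metrics",
    "overall_accuracy",
    "compute_metrics",
    "weighted_kappa",
]


@dataclass
class ConfusionMatrix:
    """Observed × predicted counts over the three behaviours."""

    counts: np.ndarray  # shape (k, k); rows observed, columns predicted
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise DataError(f"confusion matrix must be {k}x{k}")
        if np.any(self.counts < 0):
            raise DataError("confusion matrix counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, cls: str) -> dict[str, int]:
        """TP/FP/FN/TN counts for one behaviour against the rest."""
        i = self.classes.index(cls)
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum()) - tp
        fn = int(self.counts[i, :].sum()) - tp
        tn = self.total - tp - fp - fn
        return {"tp": tp, "fp": fp, "fn": fn, "tn": tn}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.classes, name="observed"),
            columns=pd.Index(self.classes, name="predicted"),
        )


@dataclass
class MetricSet:
    """Per-class metrics plus overall accuracy, all as fractions.

    An undefined metric (empty denominator, e.g. precision of a class
    that is never predicted) is NaN, and its name is listed in
    ``undefined`` rather than being silently reported as 0.
    """

    per_class: dict[str, dict[str, float]]
    overall_accuracy: float
    undefined: list[str]

    def to_frame(self, as_percent: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(self.per_class).T
        df.index.name = "behaviour"
        return 100.0 * df if as_percent else df


@dataclass
class KappaResult:
    kappa: float
    weighting: str  # "linear" or "unweighted"
    classes: tuple[str, ...]
    n: int
    degenerate: bool = False  # both sequences constant and equal


def _as_codes(labels) -> np.ndarray:
    code = {c: i for i, c in enumerate(CLASSES)}
    out = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        try:
            out[i] = code[lab]
        except KeyError:
            raise DataError(f"label {lab!r} not in ethogram {CLASSES}") from None
    return out


def confusion_matrix(observed, predicted) -> ConfusionMatrix:
    """Count observed (rows) × predicted (columns) label pairs."""
    if len(observed) != len(predicted):
        raise DataError("observed and predicted must have equal length")
    obs, pred = _as_codes(observed), _as_codes(predicted)
    k = len(CLASSES)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (obs, pred), 1)
    return ConfusionMatrix(counts)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def class_metrics(cm: ConfusionMatrix, cls: str) -> dict[str, float]:
    """Precision, recall, F-score and specificity for one behaviour."""
    if cm.total == 0:
        raise DataError("empty confusion matrix")
    c = cm.one_vs_rest(cls)
    precision = _safe_div(c["tp"], c["tp"] + c["fp"])
    recall = _safe_div(c["tp"], c["tp"] + c["fn"])
    if math.isnan(precision) or math.isnan(recall):
        f_score = math.nan
    elif precision + recall == 0:
        f_score = 0.0
    else:
        f_score = 2 * precision * recall / (precision + recall)
    specificity = _safe_div(c["tn"], c["tn"] + c["fp"])
    return {
        "precision": precision,
        "recall": recall,
        "f_score": f_score,
        "specificity": specificity,
    }


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified windows: trace / total."""
    if cm.total == 0:
        raise DataError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def compute_metrics(cm: ConfusionMatrix) -> MetricSet:
    per_class = {c: class_metrics(cm, c) for c in cm.classes}
    undefined = [
        f"{metric}({c})"
        for c, metrics in per_class.items()
        for metric, v in metrics.items()
        if math.isnan(v)
    ]
    return MetricSet(
        per_class=per_class,
        overall_accuracy=overall_accuracy(cm),
        undefined=undefined,
    )


def weighted_kappa(labels_a, labels_b, weighting: str = "linear") -> KappaResult:
    """Cohen's κ between two label sequences.

    κ = 1 − Σ w_ij O_ij / Σ w_ij E_ij, with O the observed joint
    proportions, E the outer product of the marginals, and weights
    w_ij = |i−j|/(k−1) (``linear``) or 1[i≠j] (``unweighted``).  Two
    identical constant sequences have zero expected disagreement; κ is
    then 1 by convention and flagged ``degenerate``.
    """
    if weighting not in ("linear", "unweighted"):
        raise DataError(f"unknown weighting {weighting!r}")
    if len(labels_a) != len(labels_b):
        raise DataError("label sequences must have equal length")
    if len(labels_a) == 0:
        raise DataError("label sequences must be non-empty")
    a, b = _as_codes(labels_a), _as_codes(labels_b)
    k = len(CLASSES)
    O = np.zeros((k, k))
    np.add.at(O, (a, b), 1.0)
    O /= len(a)
    E = np.outer(O.sum(axis=1), O.sum(axis=0))
    i, j = np.indices((k, k))
    if weighting == "linear":
        W = np.abs(i - j) / (k - 1)
    else:
        W = (i != j).astype(float)
    expected = float((W * E).sum())
    if expected == 0.0:
        return KappaResult(
            kappa=1.0, weighting=weighting, classes=CLASSES, n=len(a), degenerate=True
        )
    kappa = 1.0 - float((W * O).sum()) / expected
    return KappaResult(kappa=kappa, weighting=weighting, classes=CLASSES, n=len(a))
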