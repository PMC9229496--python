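"""One-vs-rest evaluation: confusion counts, metrics, ROC and importance.

Multiclass performance is assessed one class at a time against all others
pooled.  From the binarized counts (TP, TN, FP, FN) six metrics follow:

    accuracy     = (TP + TN) / (TP + FN + TN + FP)
    sensitivity  = TP / (TP + FN)
    specificity  = TN / (TN + FP)
    PPV          = TP / (TP + FP)          (precision)
    NPV          = TN / (TN + FN)
    F1           = 2 * PPV * sensitivity / (PPV + sensitivity)

Zero-denominator cases are surfaced as NaN with the metric named in
``undefined`` — never as a silent 0.  The cumulative summary is the
unweighted (macro) mean of the per-class metric rows.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.metrics import auc as _sk_auc, roc_curve as _sk_roc_curve

from .errors import ConfigError
from .features import FEATURE_NAMES, feature_matrix

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "f1", "ppv", "npv")


@dataclass
class ConfusionCounts:
    """One-vs-rest counts for one positive class."""

    class_label: str
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsRow:
    """The six metrics; NaN entries are listed in ``undefined``."""

    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    ppv: float
    npv: float
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in METRIC_NAMES}
        d["undefined"] = list(self.undefined)
        return d


@dataclass
class ROCResult:
    """Per-class one-vs-rest ROC curves and AUCs."""

    classes: list[str]
    fpr: dict[str, np.ndarray]
    tpr: dict[str, np.ndarray]
    auc: dict[str, float]


def confusion_counts(
    y_true: Sequence, y_pred: Sequence, positive_class
) -> ConfusionCounts:
    """Binarize labels as positive_class-vs-rest and count outcomes."""
    yt = np.asarray([str(v) for v in y_true])
    yp = np.asarray([str(v) for v in y_pred])
    if len(yt) != len(yp) or len(yt) == 0:
        raise ConfigError("y_true and y_pred must have equal nonzero length")
    pos = str(positive_class)
    t = yt == pos
    p = yp == pos
    return ConfusionCounts(
        class_label=pos,
        TP=int(np.sum(t & p)),
        TN=int(np.sum(~t & ~p)),
        FP=int(np.sum(~t & p)),
        FN=int(np.sum(t & ~p)),
    )


def _ratio(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return float("nan")
    return num / den


def metrics_from_counts(cc: ConfusionCounts) -> MetricsRow:
    """The six one-vs-rest metrics from one class's counts."""
    if cc.total == 0:
        raise ConfigError("all-zero confusion counts")
    undefined: list[str] = []
    accuracy = (cc.TP + cc.TN) / cc.total
    sensitivity = _ratio(cc.TP, cc.TP + cc.FN, "sensitivity", undefined)
    specificity = _ratio(cc.TN, cc.TN + cc.FP, "specificity", undefined)
    ppv = _ratio(cc.TP, cc.TP + cc.FP, "ppv", undefined)
    npv = _ratio(cc.TN, cc.TN + cc.FN, "npv", undefined)
    if np.isnan(ppv) or np.isnan(sensitivity) or (ppv + sensitivity) == 0:
        undefined.append("f1")
        f1 = float("nan")
    else:
        f1 = 2 * ppv * sensitivity / (ppv + sensitivity)
    return MetricsRow(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        f1=f1,
        ppv=ppv,
        npv=npv,
        undefined=undefined,
    )


def macro_summary(rows: Sequence[MetricsRow]) -> MetricsRow:
    """Unweighted mean of each metric across the per-class rows."""
    if len(rows) == 0:
        raise ConfigError("macro_summary needs at least one row")
    values = {}
    undefined: list[str] = []
    for name in METRIC_NAMES:
        col = np.array([getattr(r, name) for r in rows], dtype=float)
        if np.isnan(col).any():
            undefined.append(name)
        values[name] = float(np.mean(col))
    return MetricsRow(**values, undefined=undefined)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, for comparison with printed tables."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def roc_ovr(scores: np.ndarray, y_true: Sequence, classes: Sequence[str]) -> ROCResult:
    """One-vs-rest ROC per class from a per-row per-class score matrix."""
    scores = np.asarray(scores, dtype=float)
    yt = np.asarray([str(v) for v in y_true])
    if scores.shape[0] != len(yt):
        raise ConfigError("score matrix rows must match labels")
    if scores.shape[1] != len(classes):
        raise ConfigError("score matrix columns must match classes")
    fpr, tpr, aucs = {}, {}, {}
    for j, cls in enumerate(classes):
        f, t, _ = _sk_roc_curve(yt == str(cls), scores[:, j])
        fpr[str(cls)] = f
        tpr[str(cls)] = t
        aucs[str(cls)] = float(_sk_auc(f, t))
    return ROCResult(classes=[str(c) for c in classes], fpr=fpr, tpr=tpr, auc=aucs)


def permutation_importance(
    model, table: pd.DataFrame, n_repeats: int = 20, seed: int = 22
) -> pd.Series:
    """Mean accuracy drop per feature column under repeated shuffling.

    Model-agnostic, so the same definition applies to KNN, SVM and GB alike.
    """
    if "stage" not in table.columns:
        raise ConfigError("permutation importance needs a labeled table")
    X = feature_matrix(table)
    y = table["stage"].astype(str).to_numpy()
    result = _sk_permutation_importance(
        model.estimator, X, y, scoring="accuracy", n_repeats=n_repeats,
        random_state=seed, n_jobs=1,
    )
    return pd.Series(result.importances_mean, index=list(FEATURE_NAMES))


def confusion_matrix_table(
    y_true: Sequence, y_pred: Sequence, classes: Sequence[str], normalize: bool = False
) -> pd.DataFrame:
    """Square confusion matrix (rows true, columns predicted)."""
    yt = np.asarray([str(v) for v in y_true])
    yp = np.asarray([str(v) for v in y_pred])
    classes = [str(c) for c in classes]
    mat = np.zeros((len(classes), len(classes)))
    for i, ct in enumerate(classes):
        for j, cp in enumerate(classes):
            mat[i, j] = np.sum((yt == ct) & (yp == cp))
    if normalize:
        row_sums = mat.sum(axis=1, keepdims=True)
        mat = np.divide(mat, row_sums, out=np.zeros_like(mat), where=row_sums > 0)
    return pd.DataFrame(mat, index=classes, columns=classes)


def evaluation_report(y_true: Sequence, y_pred: Sequence,
                      scores: np.ndarray | None, classes: Sequence[str]) -> dict:
    """Per-class counts + metrics, macro row, and (optionally) per-class AUC."""
    per_class = {}
    rows = []
    for cls in classes:
        cc = confusion_counts(y_true, y_pred, cls)
        row = metrics_from_counts(cc)
        rows.append(row)
        per_class[str(cls)] = {
            "counts": {"TP": cc.TP, "TN": cc.TN, "FP": cc.FP, "FN": cc.FN},
            "metrics": row.as_dict(),
        }
    report = {
        "per_class": per_class,
        "macro": macro_summary(rows).as_dict(),
        "n_rows": int(len(np.asarray(y_true))),
    }
    if scores is not None:
        roc = roc_ovr(scores, y_true, classes)
        report["auc"] = roc.auc
    return report
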