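"""ROC/AUC and classification-table evaluation of risk scores against the
three-way survival grouping.

Discrimination is always judged on the patients with a clear prognosis: the
positives are the short-survival group (<= 12 months), the negatives the
long-survival group (>= 60 months), and intermediate-survival patients are
excluded before ROC or pooled-accuracy computation (they have no unambiguous
label to be right or wrong about). A higher score predicts the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import UndefinedStatisticError, ValidationError
from .survival import GROUP_LONG, GROUP_MID, GROUP_SHORT

_GROUPS = (GROUP_SHORT, GROUP_MID, GROUP_LONG)
_RISK_ORDER = ("low", "intermediate", "high", "good", "bad", "unclassifiable")


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    n_positive: int
    n_negative: int


@dataclass
class ClassificationTable:
    """Risk-class x survival-group contingency counts.

    ``counts`` carries one row per predicted class and one column per survival
    group, plus the marginals. For binary (good/bad) predictions the table
    also reports sensitivity — the fraction of short-survival (<= 12 months)
    patients predicted ``bad`` — and specificity — the fraction of
    long-survival (>= 60 months) patients predicted ``good`` — each as a
    (numerator, denominator) pair the way clinical tables print them.
    """

    counts: pd.DataFrame
    sensitivity: tuple[int, int] | None = None
    specificity: tuple[int, int] | None = None

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    def cell(self, risk_class: str, group: str) -> int:
        return int(self.counts.loc[risk_class, group])

    def row_total(self, risk_class: str) -> int:
        return int(self.counts.loc[risk_class].sum())

    def column_total(self, group: str) -> int:
        return int(self.counts[group].sum())

    def with_margins(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["total"] = out.sum(axis=1)
        out.loc["total"] = out.sum(axis=0)
        return out


def roc_auc(scores, groups) -> RocResult:
    """ROC of a risk score for separating <=12-month from >=60-month
    survivors. AUC is the Mann-Whitney pairwise probability that a positive
    outscores a negative, with half credit for ties; thresholds sweep every
    distinct observed score plus the open endpoints."""
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    keep = groups != GROUP_MID
    scores, groups = scores[keep], groups[keep]
    unknown = set(np.unique(groups)) - {GROUP_SHORT, GROUP_LONG}
    if unknown:
        raise ValidationError(f"unknown survival group label(s): {sorted(unknown)}")
    y = (groups == GROUP_SHORT).astype(int)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedStatisticError(
            "roc_auc: need at least one le12 and one ge60 patient"
        )
    fpr, tpr, thresholds = roc_curve(y, scores, drop_intermediate=False)
    return RocResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=float(roc_auc_score(y, scores)),
        n_positive=n_pos,
        n_negative=n_neg,
    )


def classification_table(predictions, groups) -> ClassificationTable:
    """Cross-tabulate predicted risk classes against survival groups."""
    predictions = list(predictions)
    groups = list(groups)
    if not predictions or len(predictions) != len(groups):
        raise ValidationError(
            "classification_table: predictions and groups must be equal-length "
            "and non-empty"
        )
    bad_groups = set(groups) - set(_GROUPS)
    if bad_groups:
        raise ValidationError(f"unknown survival group label(s): {sorted(bad_groups)}")
    bad_preds = set(predictions) - set(_RISK_ORDER)
    if bad_preds:
        raise ValidationError(f"unknown risk-class label(s): {sorted(bad_preds)}")
    pred_order = [c for c in _RISK_ORDER if c in set(predictions)]
    counts = pd.DataFrame(0, index=pred_order, columns=list(_GROUPS), dtype=int)
    for p, g in zip(predictions, groups):
        counts.loc[p, g] += 1
    table = ClassificationTable(counts)
    if set(predictions) <= {"good", "bad", "unclassifiable"}:
        n_short = table.column_total(GROUP_SHORT)
        n_long = table.column_total(GROUP_LONG)
        bad_short = table.cell("bad", GROUP_SHORT) if "bad" in counts.index else 0
        good_long = table.cell("good", GROUP_LONG) if "good" in counts.index else 0
        table.sensitivity = (bad_short, n_short)
        table.specificity = (good_long, n_long)
    return table


def pooled_accuracy(table: ClassificationTable) -> float:
    """Fraction of clear-prognosis patients classified correctly: bad-predicted
    short survivors plus good-predicted long survivors, over all patients in
    the two clear groups. Only defined for binary (good/bad) tables."""
    if table.sensitivity is None or table.specificity is None:
        raise ValidationError(
            "pooled_accuracy needs a binary (good/bad) classification table"
        )
    c_short, n_short = table.sensitivity
    c_long, n_long = table.specificity
    if n_short + n_long == 0:
        raise UndefinedStatisticError("pooled_accuracy: no clear-prognosis patients")
    return (c_short + c_long) / (n_short + n_long)


def pooled_accuracy_percent(table: ClassificationTable) -> int:
    """Pooled accuracy as the rounded percentage clinical abstracts print."""
    return round(100 * pooled_accuracy(table))
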