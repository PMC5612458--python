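"""Classification and rater-agreement metrics.

The positive class is always "exclude" (an image flagged for rejection);
confusion counts, per-class precision/recall/F1, accuracy, the
rank-based ROC AUC and Cohen's kappa are all implemented directly from
their definitions so they can be cross-checked against library
implementations in the test suite.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import UndefinedMetricError, ValidationError

POSITIVE_LABEL = "exclude"
NEGATIVE_LABEL = "accept"


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with "exclude" as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        t = np.asarray(y_true)
        p = np.asarray(y_pred)
        if t.shape != p.shape:
            raise ValidationError("label vectors differ in length")
        pos_t = t == POSITIVE_LABEL if t.dtype.kind in "UO" else t.astype(bool)
        pos_p = p == POSITIVE_LABEL if p.dtype.kind in "UO" else p.astype(bool)
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
        )


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator for {what}; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def classification_metrics(c: ConfusionCounts) -> dict:
    """Per-class precision/recall/F1, supports, accuracy and
    support-weighted averages for a binary quality-rating task."""
    if c.total == 0:
        raise UndefinedMetricError("no samples")
    support_pos = c.tp + c.fn
    support_neg = c.tn + c.fp
    prec_pos = _safe_div(c.tp, c.tp + c.fp, "exclude precision")
    rec_pos = _safe_div(c.tp, support_pos, "exclude recall")
    f1_pos = _safe_div(2 * prec_pos * rec_pos, prec_pos + rec_pos, "exclude F1")
    prec_neg = _safe_div(c.tn, c.tn + c.fn, "accept precision")
    rec_neg = _safe_div(c.tn, support_neg, "accept recall")
    f1_neg = _safe_div(2 * prec_neg * rec_neg, prec_neg + rec_neg, "accept F1")
    accuracy = (c.tp + c.tn) / c.total
    w_pos, w_neg = support_pos / c.total, support_neg / c.total
    return {
        "accept": {
            "precision": prec_neg, "recall": rec_neg, "f1": f1_neg,
            "predicted_accept": c.tn, "predicted_exclude": c.fp,
            "support": support_neg,
        },
        "exclude": {
            "precision": prec_pos, "recall": rec_pos, "f1": f1_pos,
            "predicted_accept": c.fn, "predicted_exclude": c.tp,
            "support": support_pos,
        },
        "accuracy": accuracy,
        "weighted_avg": {
            "precision": w_pos * prec_pos + w_neg * prec_neg,
            "recall": accuracy,
            "f1": w_pos * f1_pos + w_neg * f1_neg,
        },
        "naive_all_accept_accuracy": _safe_div(support_neg, c.total, "baseline"),
    }


def metrics_table(c: ConfusionCounts) -> pd.DataFrame:
    """Report table: one row per true class plus the weighted average,
    with per-class predicted counts and supports."""
    m = classification_metrics(c)
    rows = []
    for cls in (NEGATIVE_LABEL, POSITIVE_LABEL):
        d = m[cls]
        rows.append(
            {
                "true": cls,
                "precision": round(d["precision"], 2),
                "recall": round(d["recall"], 2),
                "f1": round(d["f1"], 2),
                "pred_accept": d["predicted_accept"],
                "pred_exclude": d["predicted_exclude"],
                "support": d["support"],
            }
        )
    w = m["weighted_avg"]
    rows.append(
        {
            "true": "avg / total",
            "precision": round(w["precision"], 2),
            "recall": round(w["recall"], 2),
            "f1": round(w["f1"], 2),
            "pred_accept": c.tn + c.fn,
            "pred_exclude": c.fp + c.tp,
            "support": c.total,
        }
    )
    return pd.DataFrame(rows)


def format_percent(fraction: float) -> str:
    """Render a fraction as a whole-number percentage string."""
    return f"{round(fraction * 100):.0f}%"


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve by the Mann-Whitney rank formulation;
    tied scores contribute 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = y == POSITIVE_LABEL if y.dtype.kind in "UO" else y.astype(bool)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("roc_auc undefined with a single class")
    ranks = rankdata(s)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def cohens_kappa(ratings_a, ratings_b, categories=None) -> float:
    """Cohen's kappa between two raters: (p_o - p_e)/(1 - p_e) with the
    chance agreement p_e from the marginal products.

    Supports any shared category vocabulary (3-class ratings or the
    binarized accept/exclude form).  Returns NaN when both raters use a
    single category (p_e = 1, agreement is vacuous).
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.size < 2:
        raise ValidationError("need two equal-length rating vectors (n >= 2)")
    if categories is None:
        categories = np.unique(np.concatenate([a, b]))
    categories = list(categories)
    n = a.size
    p_o = float(np.mean(a == b))
    p_e = sum(
        (np.sum(a == c) / n) * (np.sum(b == c) / n) for c in categories
    )
    if p_e >= 1.0:
        return float("nan")
    return (p_o - p_e) / (1.0 - p_e)
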