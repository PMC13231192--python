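"""Patient-level performance metrics.

AUROC follows the Mann-Whitney formulation (ties credited 1/2), AUPRC the
non-interpolated step summation over descending-score thresholds — both as
computed by scikit-learn, and both cross-checked against brute-force oracles
in the test suite.  Operating-point metrics are reported at an explicit,
recorded threshold; ratios with a zero denominator come back as NaN with a
flag rather than a silent 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve

__all__ = [
    "MetricsReport",
    "auroc",
    "auprc",
    "operating_point_metrics",
    "youden_threshold",
    "compute_report",
    "summarize_folds",
]

DEFAULT_THRESHOLD = 0.5


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    return scores, labels


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability that a random positive outscores a random negative
    (ties counted 1/2); equals the trapezoidal area under the ROC curve."""
    scores, labels = _validate(scores, labels)
    if labels.min() == labels.max():
        raise ValueError("AUROC undefined: both classes must be present")
    return float(roc_auc_score(labels, scores))


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve by non-interpolated step
    summation, sum_k (R_k - R_{k-1}) P_k over descending-score thresholds."""
    scores, labels = _validate(scores, labels)
    if labels.sum() == 0:
        raise ValueError("AUPRC undefined: no positive labels")
    return float(average_precision_score(labels, scores))


def operating_point_metrics(scores: Sequence[float], labels: Sequence[int],
                            threshold: float = DEFAULT_THRESHOLD
                            ) -> dict[str, float]:
    """Sensitivity/specificity/PPV/NPV with prediction positive iff
    score >= threshold.  Undefined ratios are NaN, listed in ``undefined``."""
    scores, labels = _validate(scores, labels)
    if labels.min() == labels.max():
        raise ValueError("operating point undefined: both classes must be present")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    out = {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }
    out["undefined"] = [k for k, v in out.items() if isinstance(v, float) and np.isnan(v)]
    return out


def youden_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Threshold maximising Youden's J = sensitivity + specificity - 1."""
    scores, labels = _validate(scores, labels)
    fpr, tpr, thr = roc_curve(labels, scores)
    return float(thr[np.argmax(tpr - fpr)])


@dataclass
class MetricsReport:
    auroc: float
    auprc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    threshold: float
    n_pos: int
    n_neg: int
    fold_index: int | None = None
    undefined: list[str] = field(default_factory=list)


def compute_report(scores: Sequence[float], labels: Sequence[int],
                   threshold: float = DEFAULT_THRESHOLD,
                   fold_index: int | None = None) -> MetricsReport:
    """Full per-fold report at one operating point."""
    scores, labels = _validate(scores, labels)
    op = operating_point_metrics(scores, labels, threshold)
    return MetricsReport(
        auroc=auroc(scores, labels),
        auprc=auprc(scores, labels),
        sensitivity=op["sensitivity"],
        specificity=op["specificity"],
        ppv=op["ppv"],
        npv=op["npv"],
        threshold=threshold,
        n_pos=int(labels.sum()),
        n_neg=int((1 - labels).sum()),
        fold_index=fold_index,
        undefined=op["undefined"],
    )


_SUMMARY_METRICS = ("auroc", "auprc", "sensitivity", "specificity", "ppv", "npv")


def summarize_folds(reports: Sequence[MetricsReport]) -> dict[str, dict[str, float | None]]:
    """Per-metric mean and sample standard deviation (n-1 denominator)
    across folds; with a single fold the sd is reported as None.  NaN fold
    values (undefined ratios) are excluded from that metric's summary."""
    if not reports:
        raise ValueError("no reports to summarise")
    out: dict[str, dict[str, float | None]] = {}
    for m in _SUMMARY_METRICS:
        vals = np.array([getattr(r, m) for r in reports], dtype=np.float64)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            out[m] = {"mean": float("nan"), "sd": None, "n": 0}
        else:
            sd = float(np.std(vals, ddof=1)) if vals.size >= 2 else None
            out[m] = {"mean": float(np.mean(vals)), "sd": sd, "n": int(vals.size)}
    return out
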