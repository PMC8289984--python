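"""ROC analysis of per-image anomaly scores, with Monte-Carlo aggregation.

Normal records are the negative class; positives are either all abnormal
records or one abnormal class with the other excluded entirely.  AUROC uses
the trapezoidal rule over the full threshold sweep, which equals the
Mann-Whitney pairwise probability with ties counted half.  Repeated-split
results are summarized by the mean AUROC with a t-based 95% confidence
interval over the repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn import metrics as _skm

from .data_io import LABEL_NORMAL, LABEL_NOT_NORMAL, LABEL_OPACITY
from .exceptions import InsufficientRepeatsError, UndefinedAurocError

POS_ALL = "all_abnormal"
POS_OPACITY = "opacity_only"
POS_NOT_NORMAL = "not_normal_only"
POSITIVES_DEFINITIONS = (POS_ALL, POS_OPACITY, POS_NOT_NORMAL)


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auroc: float
    positives_definition: str

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


@dataclass
class CvSummary:
    aurocs: list[float]
    mean: float
    ci95: tuple[float, float]


def _restrict(scores: dict[str, float], labels: dict[str, str],
              positives_definition: str):
    if positives_definition not in POSITIVES_DEFINITIONS:
        raise ValueError(f"unknown positives definition {positives_definition!r}")
    keep_abnormal = {POS_ALL: (LABEL_OPACITY, LABEL_NOT_NORMAL),
                     POS_OPACITY: (LABEL_OPACITY,),
                     POS_NOT_NORMAL: (LABEL_NOT_NORMAL,)}[positives_definition]
    y_true, y_score = [], []
    for image_id, value in scores.items():
        if image_id not in labels:
            raise KeyError(f"no label for scored id {image_id!r}")
        label = labels[image_id]
        if label == LABEL_NORMAL:
            y_true.append(0)
        elif label in keep_abnormal:
            y_true.append(1)
        else:
            continue  # the other abnormal class is excluded, not relabeled
        y_score.append(float(value))
    return np.asarray(y_true), np.asarray(y_score)


def roc_curve(scores: dict[str, float], labels: dict[str, str],
              positives_definition: str = POS_ALL) -> RocResult:
    """Threshold sweep ROC; higher score = more anomalous."""
    y_true, y_score = _restrict(scores, labels, positives_definition)
    if len(np.unique(y_true)) < 2:
        raise UndefinedAurocError(
            "ROC requires at least one positive and one negative")
    fpr, tpr, thresholds = _skm.roc_curve(y_true, y_score,
                                          drop_intermediate=False)
    auroc = float(_skm.auc(fpr, tpr))
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auroc=auroc,
                     positives_definition=positives_definition)


def sensitivity_at_fpr(roc: RocResult, target_fpr: float) -> float:
    """TPR of the ROC curve at a target false-positive rate.

    Linear interpolation along the curve (tied scores yield diagonal
    segments); at a vertical jump the upper TPR is taken.
    """
    if not 0.0 <= target_fpr <= 1.0:
        raise ValueError("target_fpr must be in [0, 1]")
    # collapse repeated FPR values to their maximal TPR, then interpolate
    uniq_fpr, inverse = np.unique(roc.fpr, return_inverse=True)
    max_tpr = np.zeros_like(uniq_fpr)
    np.maximum.at(max_tpr, inverse, roc.tpr)
    return float(np.interp(target_fpr, uniq_fpr, max_tpr))


def cross_validate(repeat_aurocs: list[float]) -> CvSummary:
    """Mean AUROC over repeats with a t-based 95% confidence interval."""
    values = np.asarray(repeat_aurocs, dtype=np.float64)
    n = len(values)
    if n < 2:
        raise InsufficientRepeatsError("need at least two repeats")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    half = float(stats.t.ppf(0.975, n - 1)) * sd / np.sqrt(n)
    return CvSummary(aurocs=values.tolist(), mean=mean,
                     ci95=(mean - half, mean + half))
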