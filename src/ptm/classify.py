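"""Leave-one-subject-out (LOSO) PD-vs-HC classification of profiles.

Each subject's 50-point KDE profile ``x_f`` is one example.  For every fold
an RBF SVM (C = 1) is fitted on all remaining subjects with class weights
inversely proportional to class frequency, and its decision value on the
left-out subject is recorded (PD is the positive class).  The pooled scores
yield a threshold-sweep ROC, a trapezoid AUC, and two operating points: the
best-specificity point subject to sensitivity >= 0.85 and the
best-sensitivity point subject to specificity >= 0.85.  Profiles enter the
SVM as-is — their values are already on a common density scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .config import ClassifierConfig
from .profiling import SubjectProfile

POSITIVE = "PD"
NEGATIVE = "HC"


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "precision": self.precision, "f1": self.f1,
        }


@dataclass
class LosoResult:
    subject_ids: list[str]
    scores: np.ndarray
    labels: np.ndarray  # 1 = PD, 0 = HC
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    operating_points: dict[str, OperatingPoint] = field(default_factory=dict)


def loso_classify(
    profiles: Sequence[SubjectProfile],
    cfg: ClassifierConfig | None = None,
) -> LosoResult:
    """Run all LOSO folds and assemble the pooled ROC."""
    cfg = cfg or ClassifierConfig()
    labels = np.array([1 if p.label == POSITIVE else 0 for p in profiles])
    bad = [p.subject_id for p in profiles if p.label not in (POSITIVE, NEGATIVE)]
    if bad:
        raise ValueError(f"profiles with unknown label: {bad}")
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise ValueError("need >= 2 subjects per class for LOSO")
    X = np.vstack([p.x_f for p in profiles])
    scores = np.empty(len(profiles))
    for i in range(len(profiles)):
        mask = np.ones(len(profiles), dtype=bool)
        mask[i] = False
        if len(np.unique(labels[mask])) < 2:
            raise ValueError("training fold contains a single class")
        clf = SVC(kernel="rbf", C=cfg.C, gamma=cfg.gamma, class_weight="balanced")
        clf.fit(X[mask], labels[mask])
        scores[i] = clf.decision_function(X[i:i + 1])[0]
    fpr, tpr, thr = roc_curve(scores, labels)
    auc = trapezoid_auc(fpr, tpr)
    ops = operating_points(scores, labels, cfg)
    return LosoResult(
        subject_ids=[p.subject_id for p in profiles], scores=scores, labels=labels,
        fpr=fpr, tpr=tpr, thresholds=thr, auc=auc, operating_points=ops,
    )


# ---------------------------------------------------------------------------
# ROC machinery (threshold sweep; verified against the pairwise-concordance
# estimator in the tests)
# ---------------------------------------------------------------------------

def roc_curve(scores: Sequence[float], labels: Sequence[int]):
    """(fpr, tpr, thresholds) from a descending sweep over unique scores.

    A subject is called positive when ``score >= threshold``; the sweep
    starts at +inf (nothing positive) and visits every unique score.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    thr = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    tpr = np.empty(len(thr))
    fpr = np.empty(len(thr))
    for k, t in enumerate(thr):
        pred = scores >= t
        tpr[k] = (pred & (labels == 1)).sum() / n_pos
        fpr[k] = (pred & (labels == 0)).sum() / n_neg
    return fpr, tpr, thr


def trapezoid_auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def operating_points(
    scores: Sequence[float],
    labels: Sequence[int],
    cfg: ClassifierConfig | None = None,
) -> dict[str, OperatingPoint]:
    """The two reporting points: high-sensitivity and high-specificity.

    ``high_sensitivity``: among thresholds with sensitivity >= the floor,
    the one maximizing specificity (ties -> higher sensitivity).
    ``high_specificity``: symmetric.  If a floor is unattainable the closest
    point is used.
    """
    cfg = cfg or ClassifierConfig()
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    fpr, tpr, thr = roc_curve(scores, labels)
    spec = 1.0 - fpr

    def metrics_at(t: float) -> OperatingPoint:
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        fn = int((~pred & (labels == 1)).sum())
        tn = int((~pred & (labels == 0)).sum())
        sens = tp / (tp + fn) if tp + fn else 0.0
        specificity = tn / (tn + fp) if tn + fp else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
        return OperatingPoint(float(t), sens, specificity, prec, f1)

    def pick(primary: np.ndarray, secondary: np.ndarray, floor: float) -> float:
        ok = np.flatnonzero(primary >= floor)
        if len(ok) == 0:
            ok = np.flatnonzero(primary == primary.max())
        best = ok[np.lexsort((primary[ok], secondary[ok]))[-1]]
        return float(thr[best])

    return {
        "high_sensitivity": metrics_at(pick(tpr, spec, cfg.sensitivity_floor)),
        "high_specificity": metrics_at(pick(spec, tpr, cfg.specificity_floor)),
    }
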