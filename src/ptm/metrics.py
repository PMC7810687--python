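"""Evaluation machinery: strict bite matching, P/R/F1, and PtM agreement.

Strict matching scheme: within each ground-truth intake interval the
earliest detected bite is a true positive and any further detections are
false positives; detections outside every interval are false positives;
intervals with no detection are false negatives.  True negatives are
undefined by construction.  Interval boundaries follow the package's
half-open convention: a bite exactly at the start is inside, at the end is
outside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .intake import BiteSet


@dataclass
class MatchResult:
    TP: int
    FP: int
    FN: int
    assignments: list[dict] = field(default_factory=list)


def match_bites(
    detected: BiteSet | Sequence[float],
    gt_intervals: Sequence[tuple[float, float]],
) -> MatchResult:
    """Apply the strict scheme; ``TP + FN`` always equals the interval count."""
    bites = sorted(detected.bites if isinstance(detected, BiteSet) else map(float, detected))
    ivs = [(float(s), float(e)) for s, e in gt_intervals]
    for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
        if s1 < e0:
            raise ValueError(f"overlapping GT intervals [{s0},{e0}) and [{s1},{e1})")
    tp = fp = fn = 0
    log: list[dict] = []
    taken = [False] * len(ivs)
    for b in bites:
        hit = next((k for k, (s, e) in enumerate(ivs) if s <= b < e), None)
        if hit is None:
            fp += 1
            log.append({"bite": b, "interval": None, "kind": "FP"})
        elif not taken[hit]:
            taken[hit] = True
            tp += 1
            log.append({"bite": b, "interval": hit, "kind": "TP"})
        else:
            fp += 1
            log.append({"bite": b, "interval": hit, "kind": "FP"})
    for k, got in enumerate(taken):
        if not got:
            fn += 1
            log.append({"bite": None, "interval": k, "kind": "FN"})
    return MatchResult(TP=tp, FP=fp, FN=fn, assignments=log)


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall, F1 with the 0/0 convention mapped to 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def ptm_agreement(
    pred_durations: Sequence[float], ref_durations: Sequence[float]
) -> tuple[float, float]:
    """Mean squared and mean absolute error over paired PtM durations."""
    pred = np.asarray(pred_durations, dtype=float)
    ref = np.asarray(ref_durations, dtype=float)
    if pred.shape != ref.shape or pred.size == 0:
        raise ValueError("paired duration vectors must have equal non-zero length")
    diff = pred - ref
    return float(np.mean(diff**2)), float(np.mean(np.abs(diff)))
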