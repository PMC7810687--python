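"""Per-frame micromovement recognition.

Five atomic in-meal wrist-motion classes — pick food (p), upwards (u),
mouth (m), downwards (d), no movement (n) — are recognized with an array of
``c (c - 1) / 2 = 10`` binary one-vs-one RBF SVMs over the 116-dimensional
frame features.  Scoring a meal yields the ``K x 10`` matrix ``V`` of signed
hyperplane distances; max-wins voting over each row yields the ``K x 1``
label vector ``y_mm``.

Sign convention (fixed and persisted with the model): a positive score in
column j favors the lexicographically *first* class of pair j.  Pairs are
ordered lexicographically: (d,m), (d,n), (d,p), (d,u), (m,n), (m,p), (m,u),
(n,p), (n,u), (p,u).

Features are standardized with train-set mean/std before the SVMs: the RBF
kernel is scale-sensitive and the features mix units.
"""

from __future__ import annotations

import itertools
import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import SvmConfig
from .features import FeatureMatrix

CLASSES: tuple[str, ...] = ("d", "m", "n", "p", "u")
PAIRS: tuple[tuple[str, str], ...] = tuple(itertools.combinations(CLASSES, 2))
assert len(PAIRS) == len(CLASSES) * (len(CLASSES) - 1) // 2 == 10


class TrainingError(ValueError):
    pass


@dataclass
class SvmArray:
    """Ten trained one-vs-one binary RBF SVMs plus the feature scaler."""

    models: dict[tuple[str, str], SVC]
    scaler: StandardScaler
    config: SvmConfig = field(default_factory=SvmConfig)

    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        return PAIRS

    @property
    def n_features(self) -> int:
        return int(self.scaler.mean_.shape[0])

    # -- persistence (directory bundle: manifest + scaler + models) -------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "pairs.json").write_text(json.dumps([list(p) for p in PAIRS]))
        (path / "scaler.json").write_text(json.dumps({
            "mean": self.scaler.mean_.tolist(),
            "scale": self.scaler.scale_.tolist(),
        }))
        for pair, model in self.models.items():
            with open(path / f"svm_{pair[0]}{pair[1]}.pkl", "wb") as fh:
                pickle.dump(model, fh)

    @classmethod
    def load(cls, path: str | Path) -> "SvmArray":
        path = Path(path)
        pairs = [tuple(p) for p in json.loads((path / "pairs.json").read_text())]
        if tuple(pairs) != PAIRS:
            raise ValueError(f"{path}: pair manifest does not match {PAIRS}")
        sc = json.loads((path / "scaler.json").read_text())
        scaler = StandardScaler()
        scaler.mean_ = np.asarray(sc["mean"], dtype=float)
        scaler.scale_ = np.asarray(sc["scale"], dtype=float)
        scaler.var_ = scaler.scale_**2
        scaler.n_features_in_ = scaler.mean_.shape[0]
        models = {}
        for pair in PAIRS:
            with open(path / f"svm_{pair[0]}{pair[1]}.pkl", "rb") as fh:
                models[pair] = pickle.load(fh)
        return cls(models=models, scaler=scaler)


@dataclass
class ScoreMatrix:
    """``K x 10`` one-vs-one decision scores with voted labels and times."""

    V: np.ndarray
    y_mm: np.ndarray  # K-vector of labels from CLASSES
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.y_mm = np.asarray(self.y_mm)
        if self.V.ndim != 2 or self.V.shape[1] != len(PAIRS):
            raise ValueError(f"V must be K x {len(PAIRS)}, got {self.V.shape}")

    @property
    def k(self) -> int:
        return self.V.shape[0]

    @property
    def row_rate(self) -> float:
        """Rows of V per second (1 / frame step)."""
        if self.k < 2:
            raise ValueError("need >= 2 frames to infer row rate")
        return 1.0 / float(np.median(np.diff(self.frame_times)))


def train_svm_array(
    F: FeatureMatrix,
    labels: Sequence[str],
    config: SvmConfig | None = None,
) -> SvmArray:
    """Fit the one-vs-one SVM array on labeled frames.

    Each of the 10 pair models is fitted on the training examples of its two
    classes only, after standardization learned on the whole training set.
    Requires at least 2 examples of every class.
    """
    config = config or SvmConfig()
    config.validate()
    labels = np.asarray(labels)
    if labels.shape[0] != F.k:
        raise TrainingError(f"{labels.shape[0]} labels for {F.k} frames")
    counts = {c: int((labels == c).sum()) for c in CLASSES}
    missing = [c for c, n in counts.items() if n < 2]
    if missing:
        raise TrainingError(f"need >= 2 examples of every class; deficient: {missing}")
    unknown = set(np.unique(labels)) - set(CLASSES)
    if unknown:
        raise TrainingError(f"unknown labels {sorted(unknown)}")

    scaler = StandardScaler().fit(F.values)
    X = scaler.transform(F.values)
    models: dict[tuple[str, str], SVC] = {}
    for a, b in PAIRS:
        mask = (labels == a) | (labels == b)
        # map to {0, 1} with the pair-first class as 1 so that sklearn's
        # positive decision value favors it after no sign flip is needed
        y = (labels[mask] == a).astype(int)
        m = SVC(kernel="rbf", C=config.C, gamma=config.gamma)
        m.fit(X[mask], y)
        models[(a, b)] = m
    return SvmArray(models=models, scaler=scaler, config=config)


def score_frames(arr: SvmArray, F: FeatureMatrix) -> ScoreMatrix:
    """Score every frame with all 10 pair models and vote labels."""
    if F.l != arr.n_features:
        raise ValueError(f"feature dim {F.l} != training dim {arr.n_features}")
    X = arr.scaler.transform(F.values)
    V = np.column_stack([arr.models[pair].decision_function(X) for pair in PAIRS])
    y_mm = np.array([max_wins_vote(row) for row in V])
    return ScoreMatrix(V=V, y_mm=y_mm, frame_times=F.frame_times)


def max_wins_vote(scores: Sequence[float]) -> str:
    """Max-wins voting over one row of V.

    Each pair votes for the class its score favors (score >= 0 favors the
    lexicographically first class of the pair).  The class with most votes
    wins; ties break by the largest sum of |score| over the tied classes'
    pairs, then lexicographically.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (len(PAIRS),):
        raise ValueError(f"expected {len(PAIRS)} scores, got shape {scores.shape}")
    if not np.isfinite(scores).all():
        raise ValueError("non-finite score in max-wins vote")
    votes = {c: 0 for c in CLASSES}
    strength = {c: 0.0 for c in CLASSES}
    for (a, b), s in zip(PAIRS, scores):
        votes[a if s >= 0 else b] += 1
        strength[a] += abs(s)
        strength[b] += abs(s)
    best = max(votes.values())
    tied = [c for c in CLASSES if votes[c] == best]
    if len(tied) == 1:
        return tied[0]
    top = max(strength[c] for c in tied)
    return min(c for c in tied if strength[c] == top)
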