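"""End-to-end orchestration: train models, detect bites, extract PtM,
profile subjects, classify the cohort, and evaluate against ground truth.

A run consumes a directory with a ``manifest.json``::

    {
      "train_meals": [{"meal": "meals/x.csv", "annotations": "ann/x.json"}, ...],
      "subjects": [
        {"subject_id": "hc00", "label": "HC",
         "meals": [{"meal": "...", "annotations": "..."}, ...]},
        ...
      ]
    }

Training meals need frame labels in their annotations (they play the role
of an externally annotated training corpus).  Stage outputs are JSON files
embedding the config hash; per-meal failures are isolated and reported, and
the run exits nonzero only if every meal fails.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import signal_io
from .classify import LosoResult, loso_classify
from .config import PipelineConfig, derive_seed
from .features import extract_feature_matrix, FeatureMatrix
from .intake import (
    BiteLstm, BiteSet, detect_bites, predict_probabilities, train_rnn,
    window_labels, window_rows, window_scores,
)
from .metrics import match_bites, prf, ptm_agreement
from .micromovement import ScoreMatrix, SvmArray, score_frames, train_svm_array
from .preprocess import preprocess
from .profiling import SubjectProfile, build_profile, meal_descriptors
from .ptm_extract import PtMSet, extract_meal_ptm
from .signal_io import MealAnnotations, SensorMeal

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# stage helpers (usable directly from the library)
# ---------------------------------------------------------------------------

def meal_scores(meal: SensorMeal, arr: SvmArray, config: PipelineConfig) -> ScoreMatrix:
    """Raw meal -> resample -> denoise/high-pass -> features -> SVM scores."""
    if meal.fs != config.target_fs:
        meal = signal_io.resample(meal, config.target_fs)
    meal = preprocess(meal, config.filter)
    F = extract_feature_matrix(meal, config.frame_spec())
    return score_frames(arr, F)


def detect_meal(
    meal: SensorMeal, arr: SvmArray, net: BiteLstm, config: PipelineConfig
) -> tuple[ScoreMatrix, BiteSet]:
    """Full detection path for one meal: scores, probabilities, bites."""
    sm = meal_scores(meal, arr, config)
    windows, centers = window_scores(sm, config.rnn)
    p = predict_probabilities(net, windows)
    return sm, detect_bites(p, centers, config.rnn)


def train_models(
    train_meals: list[tuple[SensorMeal, list[str]]],
    config: PipelineConfig,
    seed: int | None = None,
) -> tuple[SvmArray, BiteLstm]:
    """Train the SVM array and the bite LSTM from labeled meals.

    ``train_meals`` pairs each meal with its frame-rate micromovement
    labels.  The LSTM trains on the *recognized* score matrices of the
    training meals (the scores it will see at inference), with window
    targets derived from the ground-truth labels.
    """
    seed = config.seed if seed is None else seed
    feats: list[FeatureMatrix] = []
    labels: list[np.ndarray] = []
    for meal, frame_labels in train_meals:
        if meal.fs != config.target_fs:
            meal = signal_io.resample(meal, config.target_fs)
        meal = preprocess(meal, config.filter)
        F = extract_feature_matrix(meal, config.frame_spec())
        if len(frame_labels) < F.k:
            raise ValueError(
                f"meal {meal.meal_id}: {len(frame_labels)} frame labels for {F.k} frames"
            )
        feats.append(F)
        labels.append(np.asarray(frame_labels)[:F.k])
    all_f = FeatureMatrix(
        values=np.vstack([f.values for f in feats]),
        frame_times=np.concatenate([f.frame_times for f in feats]),
    )
    arr = train_svm_array(all_f, np.concatenate(labels), config.svm)

    win_list = []
    lab_list = []
    for F, lab in zip(feats, labels):
        sm = score_frames(arr, F)
        rows, step = window_rows(config.rnn, sm.row_rate)
        if sm.k < rows:
            continue
        w, _ = window_scores(sm, config.rnn)
        win_list.append(w)
        lab_list.append(window_labels(lab, sm.k, rows, step))
    if not win_list:
        raise ValueError("no training meal long enough for the detection window")
    net, _curve = train_rnn(
        np.concatenate(win_list), np.concatenate(lab_list), config.rnn,
        seed=derive_seed(seed, "rnn"),
    )
    return arr, net


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

@dataclass
class MealOutput:
    meal_id: str
    subject_id: str
    bites: BiteSet | None = None
    scores: ScoreMatrix | None = None
    ptm: PtMSet | None = None
    annotations: MealAnnotations | None = None
    error: str | None = None


@dataclass
class PipelineResult:
    meals: list[MealOutput] = field(default_factory=list)
    profiles: list[SubjectProfile] = field(default_factory=list)
    loso: LosoResult | None = None
    evaluation: dict | None = None


def _load_manifest(input_dir: Path) -> dict:
    manifest = input_dir / "manifest.json"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.json in {input_dir}")
    return json.loads(manifest.read_text())


def run_pipeline(
    config: PipelineConfig, input_dir: str | Path, output_dir: str | Path | None = None
) -> PipelineResult:
    """Execute every stage over a manifest directory (see module docstring)."""
    config.validate()
    input_dir = Path(input_dir)
    man = _load_manifest(input_dir)

    train_meals: list[tuple[SensorMeal, list[str]]] = []
    for entry in man.get("train_meals", []):
        meal = signal_io.load_meal(input_dir / entry["meal"])
        ann = signal_io.load_annotations(input_dir / entry["annotations"])
        if ann.frame_labels is None:
            raise ValueError(f"training meal {entry['meal']} lacks frame labels")
        train_meals.append((meal, ann.frame_labels))
    if not train_meals:
        raise ValueError("manifest lists no training meals")
    arr, net = train_models(train_meals, config)

    result = PipelineResult()
    per_subject: dict[str, list[PtMSet]] = {}
    subject_labels: dict[str, str] = {}
    for subj in man.get("subjects", []):
        sid = subj["subject_id"]
        subject_labels[sid] = subj.get("label", "unknown")
        for entry in subj.get("meals", []):
            out = MealOutput(meal_id=Path(entry["meal"]).stem, subject_id=sid)
            try:
                meal = signal_io.load_meal(input_dir / entry["meal"], subject_id=sid)
                sm, bites = detect_meal(meal, arr, net, config)
                out.scores = sm
                out.bites = bites
                out.ptm = extract_meal_ptm(
                    sm.y_mm, sm.frame_times, bites, config.ptm
                ) if bites.n else PtMSet()
                if entry.get("annotations"):
                    out.annotations = signal_io.load_annotations(input_dir / entry["annotations"])
                per_subject.setdefault(sid, []).append(out.ptm)
            except Exception as exc:  # isolate per-meal failures
                logger.exception("meal %s failed", out.meal_id)
                out.error = f"{type(exc).__name__}: {exc}"
            result.meals.append(out)

    if result.meals and all(m.error for m in result.meals):
        raise RuntimeError("all meals failed; see per-meal errors")

    for sid, sets in per_subject.items():
        try:
            result.profiles.append(
                build_profile(sid, sets, label=subject_labels.get(sid, "unknown"),
                              cfg=config.profile)
            )
        except ValueError as exc:
            logger.warning("subject %s: %s", sid, exc)

    labels = [p.label for p in result.profiles]
    if labels.count("PD") >= 2 and labels.count("HC") >= 2:
        result.loso = loso_classify(result.profiles, config.classifier)

    result.evaluation = _evaluate(result)
    if output_dir is not None:
        _write_outputs(result, config, Path(output_dir))
    return result


def _evaluate(result: PipelineResult) -> dict | None:
    """Strict bite matching + PtM agreement over meals that carry GT."""
    tp = fp = fn = 0
    pred_d: list[float] = []
    ref_d: list[float] = []
    seen = False
    for m in result.meals:
        if m.error or m.annotations is None or not m.annotations.gt_intervals:
            continue
        seen = True
        match = match_bites(m.bites, m.annotations.gt_intervals)
        tp += match.TP
        fp += match.FP
        fn += match.FN
        # pair TP detections' PtM with the GT PtM of the interval they hit
        if m.ptm is not None and m.annotations.gt_upwards:
            gt_by_iv = _gt_ptm_by_interval(m.annotations)
            bite_to_rec = {round(r.b_i, 9): r for r in m.ptm.records if r.status == "ok"}
            for a in match.assignments:
                if a["kind"] != "TP":
                    continue
                rec = bite_to_rec.get(round(a["bite"], 9))
                gt = gt_by_iv.get(a["interval"])
                if rec is not None and gt is not None:
                    pred_d.append(rec.ptm)
                    ref_d.append(gt)
    if not seen:
        return None
    precision, recall, f1 = prf(tp, fp, fn)
    out = {"TP": tp, "FP": fp, "FN": fn,
           "precision": precision, "recall": recall, "f1": f1}
    if pred_d:
        mse, mae = ptm_agreement(pred_d, ref_d)
        out.update({"ptm_mse": mse, "ptm_mae": mae, "ptm_pairs": len(pred_d)})
    return out


def _gt_ptm_by_interval(ann: MealAnnotations) -> dict[int, float]:
    """True PtM per GT interval: summed upwards-span durations inside it."""
    out: dict[int, float] = {}
    for k, (s, e) in enumerate(ann.gt_intervals):
        spans = [ue - us for us, ue in ann.gt_upwards if us >= s and ue <= e]
        if spans:
            out[k] = float(sum(spans))
    return out


def _write_outputs(result: PipelineResult, config: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.content_hash()
    config.to_yaml(outdir / "config.yaml")

    def dump(name: str, obj: dict) -> None:
        obj = {"config_hash": chash, **obj}
        (outdir / name).write_text(json.dumps(obj, sort_keys=True, indent=1))

    meals = {}
    for m in result.meals:
        entry: dict = {"subject_id": m.subject_id}
        if m.error:
            entry["error"] = m.error
        else:
            entry["bites"] = m.bites.bites
            entry["p"] = [round(float(v), 9) for v in m.bites.probabilities]
            entry["p_times"] = [round(float(v), 9) for v in m.bites.prob_times]
            entry["ptm"] = [
                {"interval_index": r.interval_index, "b_prev": r.b_prev, "b_i": r.b_i,
                 "tau_s": r.tau_s, "tau_e": r.tau_e, "J": r.J, "ptm": r.ptm,
                 "status": r.status}
                for r in (m.ptm.records if m.ptm else [])
            ]
            desc = meal_descriptors(m.bites)
            entry["descriptors"] = {
                "duration": desc.duration, "n_bites": desc.n_bites,
                "inter_bite_intervals": desc.inter_bite_intervals,
            }
        meals[m.meal_id] = entry
    dump("meals.json", {"meals": meals})

    dump("profiles.json", {"profiles": {
        p.subject_id: {"label": p.label, "h_hat": p.h_hat,
                       "x": [round(float(v), 9) for v in p.x],
                       "x_f": [round(float(v), 9) for v in p.x_f]}
        for p in result.profiles
    }})

    if result.loso is not None:
        dump("classification.json", {
            "auc": result.loso.auc,
            "subjects": result.loso.subject_ids,
            "scores": [round(float(s), 9) for s in result.loso.scores],
            "labels": [int(v) for v in result.loso.labels],
            "roc": {"fpr": list(result.loso.fpr), "tpr": list(result.loso.tpr),
                    "thresholds": [float(t) for t in result.loso.thresholds]},
            "operating_points": {k: v.to_dict()
                                 for k, v in result.loso.operating_points.items()},
        })
    if result.evaluation is not None:
        dump("evaluation.json", result.evaluation)
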