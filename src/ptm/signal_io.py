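"""Reading, writing and resampling of 6-DoF IMU meal recordings.

A meal session is an ``N x 6`` matrix ``S = [a_x, a_y, a_z, g_x, g_y, g_z]``
(triaxial accelerometer + triaxial gyroscope) sampled at ``fs`` Hz for
``t = N / fs`` seconds.  The interchange format is a delimited text file with
header ``t,ax,ay,az,gx,gy,gz`` and time in seconds; annotations travel as
JSON.  Units are carried as metadata and never converted silently.

Time convention used throughout the package: seconds from meal start,
0-based, intervals half-open ``[start, end)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz")
DEFAULT_SCHEMA = {"t": "t", **{c: c for c in CHANNELS}}


class SchemaError(ValueError):
    """A required column could not be resolved in the input file."""


class DegenerateInputError(ValueError):
    """The input is too short for the requested operation."""


class OrderingError(ValueError):
    """Timestamps are not monotone non-decreasing."""


@dataclass
class SensorMeal:
    """One meal's synchronized accelerometer + gyroscope streams.

    samples
        ``N x 6`` float matrix, columns ordered as :data:`CHANNELS`.
    fs
        Sampling rate in Hz (> 0).
    t0
        Meal start time in seconds (timestamps are ``t0 + i / fs``).
    units
        Free-form unit metadata, e.g. ``{"accel": "m/s^2", "gyro": "rad/s"}``.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    meal_id: str = ""
    subject_id: str = ""
    units: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 6:
            raise SchemaError(f"samples must be N x 6, got shape {self.samples.shape}")
        if self.samples.shape[0] < 1:
            raise DegenerateInputError("meal must contain at least one sample")
        if not np.isfinite(self.samples).all():
            raise ValueError("meal contains non-finite samples")
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Meal duration t = N / fs in seconds."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def copy_with(self, samples: np.ndarray, fs: float | None = None) -> "SensorMeal":
        return SensorMeal(
            samples=samples,
            fs=self.fs if fs is None else fs,
            t0=self.t0,
            meal_id=self.meal_id,
            subject_id=self.subject_id,
            units=dict(self.units),
        )


@dataclass
class MealAnnotations:
    """Ground truth for one meal: bite timestamps, intake-cycle intervals,
    upwards-motion intervals and (optionally) per-frame micromovement labels.

    Intervals are half-open ``[start, end)``, sorted and non-overlapping.
    """

    gt_bites: list[float] = field(default_factory=list)
    gt_intervals: list[tuple[float, float]] = field(default_factory=list)
    gt_upwards: list[tuple[float, float]] = field(default_factory=list)
    frame_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.gt_bites = [float(b) for b in self.gt_bites]
        self.gt_intervals = [(float(s), float(e)) for s, e in self.gt_intervals]
        self.gt_upwards = [(float(s), float(e)) for s, e in self.gt_upwards]
        _check_intervals(self.gt_intervals, "gt_intervals")
        _check_intervals(self.gt_upwards, "gt_upwards")


def _check_intervals(ivs: Sequence[tuple[float, float]], name: str) -> None:
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"{name}: interval [{s}, {e}) is empty or inverted")
    for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
        if s1 < e0:
            raise ValueError(f"{name}: intervals [{s0},{e0}) and [{s1},{e1}) overlap/unsorted")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def load_meal(
    path: str | Path,
    schema: dict[str, str] | None = None,
    fs: float | None = None,
    meal_id: str = "",
    subject_id: str = "",
) -> SensorMeal:
    """Load a meal CSV (header ``t,ax,ay,az,gx,gy,gz``) into a SensorMeal.

    ``schema`` maps canonical column names to file column names.  ``fs`` is
    inferred from the median timestamp delta unless given.  Rows with
    unparseable values are dropped (count logged).
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path)
    missing = [schema[c] for c in ("t", *CHANNELS) if schema[c] not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    cols = [schema[c] for c in ("t", *CHANNELS)]
    raw = df[cols].apply(pd.to_numeric, errors="coerce")
    bad = raw.isna().any(axis=1)
    if bad.any():
        logger.warning("%s: dropped %d rows with unparseable values", path, int(bad.sum()))
    raw = raw[~bad]
    if len(raw) < 2:
        raise DegenerateInputError(f"{path}: fewer than 2 valid samples")
    t = raw[schema["t"]].to_numpy(float)
    if np.any(np.diff(t) < 0):
        raise OrderingError(f"{path}: timestamps are not monotone non-decreasing")
    if fs is None:
        dt = float(np.median(np.diff(t)))
        if dt <= 0:
            raise OrderingError(f"{path}: cannot infer fs from zero timestamp spacing")
        fs = 1.0 / dt
    samples = raw[[schema[c] for c in CHANNELS]].to_numpy(float)
    return SensorMeal(samples=samples, fs=fs, t0=float(t[0]),
                      meal_id=meal_id or Path(path).stem, subject_id=subject_id)


def save_meal(meal: SensorMeal, path: str | Path) -> None:
    """Write a meal as CSV with header ``t,ax,ay,az,gx,gy,gz``."""
    df = pd.DataFrame(meal.samples, columns=list(CHANNELS))
    df.insert(0, "t", meal.times)
    df.to_csv(path, index=False, float_format="%.9g")


def load_annotations(path: str | Path) -> MealAnnotations:
    """Read annotations JSON with keys bites / intervals / upwards / frame_labels."""
    d = json.loads(Path(path).read_text())
    return MealAnnotations(
        gt_bites=d.get("bites", []),
        gt_intervals=[tuple(iv) for iv in d.get("intervals", [])],
        gt_upwards=[tuple(iv) for iv in d.get("upwards", [])],
        frame_labels=d.get("frame_labels"),
    )


def save_annotations(ann: MealAnnotations, path: str | Path) -> None:
    d: dict = {
        "bites": ann.gt_bites,
        "intervals": [list(iv) for iv in ann.gt_intervals],
        "upwards": [list(iv) for iv in ann.gt_upwards],
    }
    if ann.frame_labels is not None:
        d["frame_labels"] = list(ann.frame_labels)
    Path(path).write_text(json.dumps(d, sort_keys=True))


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample(meal: SensorMeal, target_fs: float) -> SensorMeal:
    """Linearly interpolate every channel onto a uniform grid at ``target_fs``.

    The new sample count is ``floor(duration * target_fs)``; grid points past
    the last original sample hold its value (edge hold of ``np.interp``).
    """
    if target_fs <= 0:
        raise ValueError(f"target_fs must be > 0, got {target_fs}")
    if meal.duration < 2.0 / target_fs:
        raise DegenerateInputError(
            f"meal duration {meal.duration:.3f}s too short for target_fs={target_fs}"
        )
    if target_fs == meal.fs:
        return meal.copy_with(meal.samples.copy())
    new_n = int(np.floor(meal.duration * target_fs))
    old_t = np.arange(meal.n) / meal.fs
    new_t = np.arange(new_n) / target_fs
    out = np.empty((new_n, 6))
    for c in range(6):
        out[:, c] = np.interp(new_t, old_t, meal.samples[:, c])
    return meal.copy_with(out, fs=target_fs)
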