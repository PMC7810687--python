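"""Sliding-window framing and per-frame feature extraction.

A preprocessed meal is sliced into ``K = floor((N - w_l) / w_s)`` frames of
``w_l`` samples with step ``w_s`` (50 % overlap at the defaults
``w_l = 0.2 fs``, ``w_s = 0.1 fs``).  Each ``w_l x 6`` frame becomes an
L-dimensional feature vector; per channel: mean, standard deviation,
variance, min, max, range, zero-crossing rate, energy and the magnitudes of
the first ``w_l/2 + 1`` DFT coefficients; per sensor (accelerometer,
gyroscope): the simple moving average ``(1/w_l) * sum(|x| + |y| + |z|)``.
So ``L = 6 * (8 + w_l/2 + 1) + 2``; at ``fs = 100`` Hz (``w_l = 20``) that
is 116 features.

Conventions (documented because the statistics admit variants):

* standard deviation / variance are population (divide by ``w_l``);
* energy is the mean of squared samples;
* zero-crossing rate counts strict sign changes between consecutive samples
  divided by ``w_l - 1``; zeros are non-crossings (the zero signal has
  rate 0);
* DFT features are magnitudes of the unnormalized one-sided transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import FrameSpec
from .signal_io import CHANNELS, DegenerateInputError, SensorMeal

SENSORS = ("accel", "gyro")
_STATS = ("mean", "std", "var", "min", "max", "range", "zcr", "energy")


def n_features(w_l: int) -> int:
    """Feature-vector length: 6 * (8 + w_l/2 + 1) + 2."""
    return 6 * (len(_STATS) + w_l // 2 + 1) + 2


def feature_names(w_l: int = 20) -> list[str]:
    """Fixed feature order manifest (persisted alongside feature matrices)."""
    names: list[str] = []
    for ch in CHANNELS:
        names.extend(f"{ch}_{s}" for s in _STATS)
        names.extend(f"{ch}_dft{k}" for k in range(w_l // 2 + 1))
    names.extend(f"sma_{sensor}" for sensor in SENSORS)
    return names


@dataclass
class FeatureMatrix:
    """``K x L`` feature matrix with per-frame center times (seconds)."""

    values: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def k(self) -> int:
        return self.values.shape[0]

    @property
    def l(self) -> int:
        return self.values.shape[1]


def frame_count(n: int, spec: FrameSpec) -> int:
    """K = floor((N - w_l) / w_s); may be 0 for short meals."""
    return max(0, (n - spec.w_l) // spec.w_s)


def frame_meal(meal: SensorMeal, spec: FrameSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Slice a meal into overlapping frames.

    Returns ``(frames, center_times)`` where ``frames`` is ``K x w_l x 6``
    (frame i covers samples ``[i*w_s, i*w_s + w_l)``) and center time i is
    ``t0 + (i*w_s + w_l/2) / fs``.
    """
    spec = spec or FrameSpec.from_fs(meal.fs)
    spec.validate()
    if meal.n < spec.w_l:
        raise DegenerateInputError(f"meal length {meal.n} < window {spec.w_l}")
    k = frame_count(meal.n, spec)
    idx = np.arange(k)[:, None] * spec.w_s + np.arange(spec.w_l)[None, :]
    frames = meal.samples[idx]  # K x w_l x 6
    centers = meal.t0 + (np.arange(k) * spec.w_s + spec.w_l / 2) / meal.fs
    return frames, centers


def extract_features(frame: np.ndarray) -> np.ndarray:
    """Feature vector of a single ``w_l x 6`` frame (see module docstring)."""
    return _extract_batch(np.asarray(frame, dtype=float)[None, :, :])[0]


def _extract_batch(frames: np.ndarray) -> np.ndarray:
    """Vectorized feature extraction over ``K x w_l x 6`` frames."""
    if frames.ndim != 3 or frames.shape[2] != 6:
        raise ValueError(f"expected K x w_l x 6 frames, got shape {frames.shape}")
    w_l = frames.shape[1]
    if w_l % 2:
        raise ValueError(f"w_l must be even, got {w_l}")
    if not np.isfinite(frames).all():
        bad = np.argwhere(~np.isfinite(frames).all(axis=(0, 1)))[:, 0]
        raise ValueError(f"non-finite samples in channel(s) {[CHANNELS[int(b)] for b in bad]}")

    k = frames.shape[0]
    mean = frames.mean(axis=1)
    var = frames.var(axis=1)  # population
    std = np.sqrt(var)
    mn = frames.min(axis=1)
    mx = frames.max(axis=1)
    rng = mx - mn
    sgn = np.sign(frames)
    zcr = (sgn[:, 1:, :] * sgn[:, :-1, :] < 0).sum(axis=1) / (w_l - 1)
    energy = (frames**2).mean(axis=1)
    dft = np.abs(np.fft.rfft(frames, axis=1))  # K x (w_l/2 + 1) x 6

    per_channel = np.stack([mean, std, var, mn, mx, rng, zcr, energy], axis=2)  # K x 6 x 8
    per_channel = np.concatenate([per_channel, np.transpose(dft, (0, 2, 1))], axis=2)
    sma_accel = np.abs(frames[:, :, 0:3]).sum(axis=2).mean(axis=1)
    sma_gyro = np.abs(frames[:, :, 3:6]).sum(axis=2).mean(axis=1)
    out = np.concatenate(
        [per_channel.reshape(k, -1), sma_accel[:, None], sma_gyro[:, None]], axis=1
    )
    assert out.shape[1] == n_features(w_l)
    return out


def extract_feature_matrix(meal: SensorMeal, spec: FrameSpec | None = None) -> FeatureMatrix:
    """Frame a meal and extract the full ``K x L`` feature matrix."""
    frames, centers = frame_meal(meal, spec)
    if frames.shape[0] == 0:
        raise DegenerateInputError("meal yields zero frames")
    return FeatureMatrix(values=_extract_batch(frames), frame_times=centers)
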