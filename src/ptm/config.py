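"""Configuration objects for every pipeline stage.

Each stage owns a small frozen-ish dataclass; :class:`PipelineConfig` nests
them all and round-trips through YAML so a run can be reproduced from the
serialized copy written into its output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates its invariants."""


@dataclass
class FilterConfig:
    """Denoising / gravity-removal settings.

    median_order
        Order of the running median applied to every channel (odd, >= 1).
    fir_taps
        Number of coefficients of the linear-phase high-pass FIR used to
        strip the gravity component from the acceleration channels.  Must be
        odd: a Type-I (odd-length, symmetric) design is the only linear-phase
        FIR that can realize a high-pass response, and its group delay
        ``(taps - 1) / 2`` is then an integer number of samples.
    fir_cutoff_hz
        High-pass cutoff in Hz (must sit below Nyquist at run time).
    """

    median_order: int = 5
    fir_taps: int = 513
    fir_cutoff_hz: float = 1.0

    def validate(self, fs: float | None = None) -> None:
        if self.median_order < 1 or self.median_order % 2 == 0:
            raise ConfigError(f"median_order must be odd and >= 1, got {self.median_order}")
        if self.fir_taps < 3:
            raise ConfigError(f"fir_taps must be >= 3, got {self.fir_taps}")
        if self.fir_taps % 2 == 0:
            raise ConfigError(
                f"fir_taps must be odd (linear-phase high-pass), got {self.fir_taps}"
            )
        if self.fir_cutoff_hz <= 0:
            raise ConfigError(f"fir_cutoff_hz must be > 0, got {self.fir_cutoff_hz}")
        if fs is not None and self.fir_cutoff_hz >= fs / 2:
            raise ConfigError(
                f"fir_cutoff_hz={self.fir_cutoff_hz} must be below Nyquist ({fs / 2})"
            )


@dataclass
class FrameSpec:
    """Sliding-window framing of the sensor matrix.

    The window length is 0.2 s and the step 0.1 s of signal time (50 %
    overlap); in samples that is ``w_l = 0.2 fs`` and ``w_s = 0.1 fs``.
    """

    w_l: int = 20
    w_s: int = 10

    @classmethod
    def from_fs(cls, fs: float) -> "FrameSpec":
        return cls(w_l=int(round(0.2 * fs)), w_s=int(round(0.1 * fs)))

    def validate(self) -> None:
        if self.w_l < 1 or self.w_s < 1:
            raise ConfigError("w_l and w_s must be >= 1")
        if self.w_s > self.w_l:
            raise ConfigError(f"step w_s={self.w_s} must not exceed window w_l={self.w_l}")


@dataclass
class SvmConfig:
    """Hyperparameters of the one-vs-one micromovement SVM array."""

    C: float = 1.0
    gamma: str | float = "scale"  # 1 / (n_features * feature variance)

    def validate(self) -> None:
        if self.C <= 0:
            raise ConfigError("C must be > 0")


@dataclass
class RnnConfig:
    """Temporal bite-moment model and peak-picking settings.

    The LSTM consumes windows of the K x 10 SVM score matrix spanning
    ``window_seconds`` of signal time with step ``step_seconds`` (at the
    default framing, 30 rows with step 2).  Probabilities below ``p_t`` are
    zeroed before the local-maxima search with minimum peak separation
    ``min_peak_distance_seconds``.
    """

    hidden: int = 128
    layers: int = 2
    window_seconds: float = 3.0
    step_seconds: float = 0.2
    p_t: float = 0.89
    min_peak_distance_seconds: float = 3.0
    # training details (not pinned by the method description)
    epochs: int = 50
    learning_rate: float = 0.01
    batch_size: int = 64
    seed: int = 0

    def validate(self) -> None:
        if self.hidden < 1:
            raise ConfigError("hidden must be >= 1")
        if self.layers < 1:
            raise ConfigError("layers must be >= 1")
        if not (0.0 < self.p_t < 1.0):
            raise ConfigError(f"p_t must lie in (0, 1), got {self.p_t}")
        if not (self.window_seconds > self.step_seconds > 0):
            raise ConfigError("need window_seconds > step_seconds > 0")


@dataclass
class PtmConfig:
    """Thresholds of the plate-to-mouth duration algebra (seconds)."""

    lambda_d: float = 0.5  # max bridgeable gap between u-regions
    lambda_b: float = 5.0  # max lag between merged-motion end and the bite

    def validate(self) -> None:
        if self.lambda_d < 0 or self.lambda_b < 0:
            raise ConfigError("lambda_d and lambda_b must be >= 0")


@dataclass
class ProfileConfig:
    """Subject-profile KDE grid: l_f points equally spaced on [lo, hi] s."""

    grid_lo: float = 0.0
    grid_hi: float = 3.0
    grid_points: int = 50

    def validate(self) -> None:
        if self.grid_points < 2:
            raise ConfigError("grid_points must be >= 2")
        if self.grid_hi <= self.grid_lo:
            raise ConfigError("grid_hi must exceed grid_lo")


@dataclass
class ClassifierConfig:
    """PD-vs-HC profile classifier (RBF SVM, leave-one-subject-out)."""

    C: float = 1.0
    gamma: str | float = "scale"
    sensitivity_floor: float = 0.85
    specificity_floor: float = 0.85


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs, nested per stage."""

    target_fs: float = 100.0
    filter: FilterConfig = field(default_factory=FilterConfig)
    svm: SvmConfig = field(default_factory=SvmConfig)
    rnn: RnnConfig = field(default_factory=RnnConfig)
    ptm: PtmConfig = field(default_factory=PtmConfig)
    profile: ProfileConfig = field(default_factory=ProfileConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    seed: int = 0

    def frame_spec(self) -> FrameSpec:
        return FrameSpec.from_fs(self.target_fs)

    def validate(self) -> None:
        if self.target_fs <= 0:
            raise ConfigError("target_fs must be > 0")
        self.filter.validate(self.target_fs)
        self.frame_spec().validate()
        self.svm.validate()
        self.rnn.validate()
        self.ptm.validate()
        self.profile.validate()

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (
            ("filter", FilterConfig),
            ("svm", SvmConfig),
            ("rnn", RnnConfig),
            ("ptm", PtmConfig),
            ("profile", ProfileConfig),
            ("classifier", ClassifierConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def content_hash(self) -> str:
        """Stable hash embedded in stage outputs so runs are self-describing."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def derive_seed(master: int, *context: object) -> int:
    """Deterministically fan a master seed out to per-stage/per-meal seeds.

    Hashes the master seed together with any context labels and folds the
    digest into a non-negative int below 2**31.
    """
    blob = json.dumps([int(master), *[str(c) for c in context]]).encode()
    return int.from_bytes(hashlib.sha256(blob).digest()[:4], "big") % (2**31)
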