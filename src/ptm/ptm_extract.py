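"""Plate-to-Mouth (PtM) duration extraction.

For every inter-bite interval ``[b_{i-1}, b_i]`` (the first starts at meal
time 0), the micromovement label vector is binarized to the upwards
indicator ``y_u``, maximal runs of upwards frames become *u-regions*
``r_j = [t_s, t_e]``, and a backward merge from the final region bridges
gaps shorter than ``lambda_d`` (0.5 s by default).  With ``J`` successful
merges and bridged-gap sum ``sum_d``:

    PtM_i = tau_e - tau_s             if J = 0
    PtM_i = tau_e - tau_s - sum_d     if J > 0

where ``tau_e`` is the final region's end and ``tau_s`` the start of the
last-merged region — equivalently, PtM is the summed duration of the merged
regions.  A record is discarded when the lag ``b_i - tau_e`` exceeds
``lambda_b`` (5 s), or impossible when the interval holds no u-region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import PtmConfig
from .intake import BiteSet
from .micromovement import CLASSES


@dataclass
class URegion:
    """Maximal run of consecutive upwards-labeled frames, as a time span."""

    t_s: float
    t_e: float

    def __post_init__(self) -> None:
        if self.t_e <= self.t_s:
            raise ValueError(f"u-region [{self.t_s}, {self.t_e}] is empty or inverted")

    @property
    def duration(self) -> float:
        return self.t_e - self.t_s


@dataclass
class PtMRecord:
    """PtM outcome for one inter-bite interval."""

    interval_index: int
    b_prev: float
    b_i: float
    tau_s: float | None = None
    tau_e: float | None = None
    J: int = 0
    ptm: float | None = None
    status: str = "ok"  # ok | discarded_lambda_b | no_uregions


@dataclass
class PtMSet:
    """All per-interval records of one meal plus the retained durations."""

    records: list[PtMRecord] = field(default_factory=list)

    @property
    def durations(self) -> list[float]:
        return [r.ptm for r in self.records if r.status == "ok"]

    @property
    def u_prime(self) -> int:
        return len(self.durations)


def binarize_upwards(y_mm: Sequence[str]) -> np.ndarray:
    """1 where the frame label is "u", 0 for p/m/d/n; errors on anything else."""
    y_mm = np.asarray(y_mm)
    unknown = set(np.unique(y_mm)) - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown micromovement labels {sorted(unknown)}")
    return (y_mm == "u").astype(int)


def extract_uregions(
    y_u: np.ndarray,
    frame_times: np.ndarray,
    interval: tuple[float, float],
    frame_step: float,
) -> list[URegion]:
    """u-regions of the interval ``[b_prev, b_i)``.

    Frames are point-labeled at their center times but represent spans, so
    a run from frame centers ``c_first .. c_last`` becomes the region
    ``[c_first - frame_step/2, c_last + frame_step/2]``.
    """
    y_u = np.asarray(y_u)
    frame_times = np.asarray(frame_times, dtype=float)
    if np.any(np.diff(frame_times) < 0):
        raise ValueError("frame times must be sorted")
    lo, hi = interval
    mask = (frame_times >= lo) & (frame_times < hi)
    yy = y_u[mask]
    tt = frame_times[mask]
    regions: list[URegion] = []
    start = None
    for j in range(len(yy)):
        if yy[j] and start is None:
            start = j
        if start is not None and (j == len(yy) - 1 or not yy[j + 1]):
            if yy[j]:
                regions.append(URegion(tt[start] - frame_step / 2, tt[j] + frame_step / 2))
                start = None
            elif not yy[j]:
                start = None
    return regions


def merge_backward(
    regions: Sequence[URegion], lambda_d: float
) -> tuple[float, float, int, float]:
    """Backward merge from the final u-region.

    Walks from the last region towards the first, merging while the gap
    ``t_s(kept) - t_e(previous)`` is strictly below ``lambda_d``; stops at
    the first failure.  Returns ``(tau_s, tau_e, J, gap_sum)``.
    """
    if not regions:
        raise ValueError("merge_backward requires at least one u-region")
    for r0, r1 in zip(regions, regions[1:]):
        if r1.t_s < r0.t_e:
            raise ValueError("u-regions must be sorted and non-overlapping")
    tau_e = regions[-1].t_e
    j = 0
    gap_sum = 0.0
    d = len(regions) - 1
    while d > 0:
        gap = regions[d].t_s - regions[d - 1].t_e
        if gap < lambda_d:
            gap_sum += gap
            j += 1
            d -= 1
        else:
            break
    return regions[d].t_s, tau_e, j, gap_sum


def compute_ptm(
    tau_s: float,
    tau_e: float,
    j: int,
    gap_sum: float,
    b_i: float,
    lambda_b: float,
    interval_index: int = 0,
    b_prev: float = 0.0,
) -> PtMRecord:
    """Apply the duration formula and the lambda_b discard rule."""
    if gap_sum < 0 or (j == 0 and gap_sum != 0):
        raise ValueError("gap_sum must be >= 0 and zero when J = 0")
    ptm = tau_e - tau_s - gap_sum
    if ptm <= 0:
        raise ValueError(f"non-positive PtM {ptm} from tau=[{tau_s},{tau_e}], gaps {gap_sum}")
    status = "discarded_lambda_b" if (b_i - tau_e) > lambda_b else "ok"
    return PtMRecord(
        interval_index=interval_index, b_prev=b_prev, b_i=b_i,
        tau_s=tau_s, tau_e=tau_e, J=j, ptm=ptm, status=status,
    )


def extract_meal_ptm(
    y_mm: Sequence[str],
    frame_times: np.ndarray,
    bites: BiteSet | Sequence[float],
    cfg: PtmConfig | None = None,
    frame_step: float | None = None,
) -> PtMSet:
    """One PtM record per inter-bite interval ``[0,b_1], ..., [b_{U-1},b_U]``."""
    cfg = cfg or PtmConfig()
    cfg.validate()
    bite_list = bites.bites if isinstance(bites, BiteSet) else [float(b) for b in bites]
    if any(b2 <= b1 for b1, b2 in zip(bite_list, bite_list[1:])):
        raise ValueError("bites must be strictly increasing")
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_step is None:
        if len(frame_times) < 2:
            raise ValueError("cannot infer frame step from < 2 frames")
        frame_step = float(np.median(np.diff(frame_times)))
    y_u = binarize_upwards(y_mm)
    out = PtMSet()
    prev = 0.0
    for i, b in enumerate(bite_list):
        regions = extract_uregions(y_u, frame_times, (prev, b), frame_step)
        if not regions:
            out.records.append(
                PtMRecord(interval_index=i, b_prev=prev, b_i=b, status="no_uregions")
            )
        else:
            tau_s, tau_e, j, gap_sum = merge_backward(regions, cfg.lambda_d)
            out.records.append(
                compute_ptm(tau_s, tau_e, j, gap_sum, b, cfg.lambda_b,
                            interval_index=i, b_prev=prev)
            )
        prev = b
    return out
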