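"""Seedable synthetic meal and cohort simulator.

A meal is an alternation of idle stretches (label "n") and food-intake
cycles following the micromovement grammar ``p -> u (-> pause -> u)* -> m
-> d``: pick food, upwards transport (possibly fragmented by brief
sub-``lambda_d`` pauses), mouth, downwards return.  The generator works at
the label *slot* rate (0.1 s — the feature-frame step), books ground truth
(intake-cycle intervals, bite timestamps at the midpoint of each "m" phase,
upwards spans, and the per-cycle true PtM = summed upwards span durations),
and can render the label sequence into a 6-channel IMU trace: per class, a
mean template on the gyroscope channels plus a class-specific oscillation
on the accelerometer channels (so class signatures survive the high-pass
gravity filter), plus white noise and an optional 4-6 Hz tremor sinusoid.

Cohort effects model the slower, more fragmented upwards phase reported for
Parkinson's disease: PD subjects multiply the upwards-phase mean duration
and the fragmentation probability.

Phase durations are log-normal (positive, right-skewed gesture times).
Identical config + seed always reproduces identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .config import derive_seed
from .signal_io import MealAnnotations, SensorMeal

# per-class rendering model: gyro mean template and accelerometer
# oscillation (amplitude, frequency Hz); accel means are irrelevant after
# the high-pass stage, so classes are separated via oscillation + gyro
TEMPLATES: dict[str, dict] = {
    "p": {"accel": (0.5, -0.3, 0.2), "gyro": (0.8, 0.1, -0.4), "osc": (0.5, 3.0)},
    "u": {"accel": (-0.6, 0.7, 0.1), "gyro": (-0.2, 0.9, 0.3), "osc": (0.9, 4.0)},
    "m": {"accel": (0.1, 0.1, -0.8), "gyro": (0.4, -0.6, 0.7), "osc": (0.3, 6.0)},
    "d": {"accel": (0.7, 0.5, 0.6), "gyro": (-0.9, -0.2, -0.5), "osc": (0.7, 5.0)},
    "n": {"accel": (0.0, 0.0, 0.0), "gyro": (0.0, 0.0, 0.0), "osc": (0.0, 1.0)},
}


@dataclass
class SimConfig:
    """Study conditions of the simulator.

    Defaults emulate the published meal statistics: 100 Hz sampling, about
    35 bites per meal, ~13 s between bites (so meals of roughly 7-8 min),
    intake cycles of ~3.4 s, upwards phases of ~0.8 s fragmented with
    probability 0.3 by pauses of ~0.3 s (below the 0.5 s merge threshold).
    PD subjects double the upwards mean duration and multiply the
    fragmentation probability by 1.5.
    """

    fs: float = 100.0
    slot_s: float = 0.1  # label slot duration = feature-frame step
    n_bites_mean: float = 35.0
    n_bites_floor: int = 5
    n_bites_fixed: int | None = None
    # phase durations, arithmetic (mean, sd) seconds of a log-normal
    dur_p: tuple[float, float] = (0.8, 0.1)
    dur_u: tuple[float, float] = (0.8, 0.12)
    dur_m: tuple[float, float] = (1.0, 0.1)
    dur_d: tuple[float, float] = (0.8, 0.1)
    dur_idle: tuple[float, float] = (9.5, 3.0)
    frag_prob: float = 0.3
    frag_pause: tuple[float, float] = (0.3, 0.05)
    noise_sd: float = 0.3
    tremor_amplitude: float = 0.0
    tremor_freq_hz: float = 5.0
    pd_upwards_multiplier: float = 2.0
    pd_fragmentation_multiplier: float = 1.5
    seed: int = 0

    def for_pd(self) -> "SimConfig":
        """Config with the cohort effects applied."""
        out = dataclasses.replace(self)
        out.dur_u = (self.dur_u[0] * self.pd_upwards_multiplier, self.dur_u[1])
        out.frag_prob = min(1.0, self.frag_prob * self.pd_fragmentation_multiplier)
        return out

    def validate(self) -> None:
        for name in ("dur_p", "dur_u", "dur_m", "dur_d", "dur_idle", "frag_pause"):
            m, s = getattr(self, name)
            if m <= 0 or s < 0:
                raise ValueError(f"{name} must have positive mean, non-negative sd")
        if not (0.0 <= self.frag_prob <= 1.0):
            raise ValueError("frag_prob must lie in [0, 1]")
        if self.fs <= 0 or self.slot_s <= 0:
            raise ValueError("fs and slot_s must be > 0")


def preset(name: str) -> SimConfig:
    """Shipped study presets.

    ``realistic``
        The defaults above.
    ``easy``
        Scaled-down CI condition: 8 bites, short idle (2.5 s), tight phase
        durations, no fragmentation, low noise.  Cycle lengths of both the
        base and the PD-multiplied condition stay inside the detection
        window's reach.
    ``null``
        ``easy`` with all cohort multipliers at 1.0 (no PD effect).
    """
    if name == "realistic":
        return SimConfig()
    if name in ("easy", "null"):
        cfg = SimConfig(
            n_bites_fixed=8,
            dur_p=(0.8, 0.05), dur_u=(0.8, 0.08), dur_m=(1.0, 0.05), dur_d=(0.8, 0.05),
            dur_idle=(2.5, 0.4), frag_prob=0.0, noise_sd=0.1,
        )
        if name == "null":
            cfg.pd_upwards_multiplier = 1.0
            cfg.pd_fragmentation_multiplier = 1.0
        return cfg
    raise ValueError(f"unknown preset {name!r}; expected realistic/easy/null")


@dataclass
class SimMeal:
    """One simulated meal: slot labels, ground truth, optional IMU trace."""

    labels: list[str]
    annotations: MealAnnotations
    gt_ptm: list[float]
    slot_s: float
    meal: SensorMeal | None = None
    meal_id: str = ""
    subject_id: str = ""

    @property
    def slot_times(self) -> np.ndarray:
        """Center time of each label slot."""
        return (np.arange(len(self.labels)) + 0.5) * self.slot_s


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return mean
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def simulate_label_sequence(
    cfg: SimConfig, seed: int | None = None, n_bites: int | None = None
) -> SimMeal:
    """Generate one meal's slot-rate label vector with full ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if n_bites is None:
        if cfg.n_bites_fixed is not None:
            n_bites = cfg.n_bites_fixed
        else:
            n_bites = max(cfg.n_bites_floor, int(rng.poisson(cfg.n_bites_mean)))

    def slots(dur: float) -> int:
        return max(1, int(round(dur / cfg.slot_s)))

    labels: list[str] = []
    bites: list[float] = []
    intervals: list[tuple[float, float]] = []
    upwards: list[tuple[float, float]] = []
    gt_ptm: list[float] = []

    def t_now() -> float:
        return len(labels) * cfg.slot_s

    labels.extend("n" * slots(_lognormal(rng, *cfg.dur_idle)))
    for _ in range(n_bites):
        cycle_start = t_now()
        labels.extend("p" * slots(_lognormal(rng, *cfg.dur_p)))
        # upwards phase, possibly fragmented by a short non-upwards pause
        u_total = slots(_lognormal(rng, *cfg.dur_u))
        parts: list[int] = []
        pauses: list[int] = []
        if u_total >= 2 and rng.uniform() < cfg.frag_prob:
            cut = int(rng.integers(1, u_total))
            parts = [cut, u_total - cut]
            pauses = [slots(_lognormal(rng, *cfg.frag_pause))]
        else:
            parts = [u_total]
        ptm = 0.0
        for j, part in enumerate(parts):
            u_start = t_now()
            labels.extend("u" * part)
            upwards.append((u_start, t_now()))
            ptm += part * cfg.slot_s
            if j < len(pauses):
                labels.extend("n" * pauses[j])
        gt_ptm.append(ptm)
        m_start = t_now()
        labels.extend("m" * slots(_lognormal(rng, *cfg.dur_m)))
        bites.append((m_start + t_now()) / 2)
        labels.extend("d" * slots(_lognormal(rng, *cfg.dur_d)))
        intervals.append((cycle_start, t_now()))
        labels.extend("n" * slots(_lognormal(rng, *cfg.dur_idle)))

    ann = MealAnnotations(
        gt_bites=bites, gt_intervals=intervals, gt_upwards=upwards, frame_labels=labels
    )
    return SimMeal(labels=labels, annotations=ann, gt_ptm=gt_ptm, slot_s=cfg.slot_s)


def render_imu(sim: SimMeal, cfg: SimConfig, seed: int | None = None) -> SensorMeal:
    """Render slot labels into an ``N x 6`` IMU trace at ``cfg.fs``.

    Each slot expands to ``slot_s * fs`` samples of its class model: gyro
    mean template plus noise; accelerometer class oscillation (random phase
    per contiguous label segment) plus mean template, noise, and the
    optional tremor sinusoid.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    spp = int(round(cfg.slot_s * cfg.fs))  # samples per slot
    n = spp * len(sim.labels)
    t = np.arange(n) / cfg.fs
    out = np.zeros((n, 6))

    # contiguous segments of equal label share one oscillation phase
    labels = np.asarray(sim.labels)
    boundaries = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(labels)]])
    for s, e in zip(starts, ends):
        lab = labels[s]
        tpl = TEMPLATES[lab]
        lo, hi = s * spp, e * spp
        seg_t = t[lo:hi]
        amp, freq = tpl["osc"]
        phase = rng.uniform(0, 2 * np.pi)
        osc = amp * np.sin(2 * np.pi * freq * seg_t + phase)
        for c in range(3):
            out[lo:hi, c] = tpl["accel"][c] + osc
        for c in range(3):
            out[lo:hi, 3 + c] = tpl["gyro"][c]
    if cfg.tremor_amplitude > 0:
        trem = cfg.tremor_amplitude * np.sin(2 * np.pi * cfg.tremor_freq_hz * t)
        out[:, 0:3] += trem[:, None]
    if cfg.noise_sd > 0:
        out += rng.normal(0.0, cfg.noise_sd, size=out.shape)
    return SensorMeal(samples=out, fs=cfg.fs, meal_id=sim.meal_id,
                      subject_id=sim.subject_id,
                      units={"accel": "m/s^2", "gyro": "rad/s"})


def simulate_meal(
    cfg: SimConfig,
    seed: int,
    render: bool = True,
    pd: bool = False,
    meal_id: str = "",
    subject_id: str = "",
) -> SimMeal:
    """Simulate (and optionally render) one meal; PD applies cohort effects."""
    use = cfg.for_pd() if pd else cfg
    sim = simulate_label_sequence(use, seed=derive_seed(seed, "labels"))
    sim.meal_id = meal_id
    sim.subject_id = subject_id
    if render:
        sim.meal = render_imu(sim, use, seed=derive_seed(seed, "render"))
        sim.meal.meal_id = meal_id
        sim.meal.subject_id = subject_id
    return sim


@dataclass
class SimSubject:
    subject_id: str
    label: str  # PD | HC
    meals: list[SimMeal] = field(default_factory=list)


def simulate_cohort(
    n_hc: int,
    n_pd: int,
    meals_per_subject: int,
    cfg: SimConfig | None = None,
    seed: int = 0,
    render: bool = False,
) -> list[SimSubject]:
    """Simulate a cohort; per-subject/per-meal seeds derive from the master."""
    cfg = cfg or SimConfig()
    if n_hc < 1 or n_pd < 1 or meals_per_subject < 1:
        raise ValueError("cohort counts must be >= 1")
    subjects: list[SimSubject] = []
    for group, count in (("HC", n_hc), ("PD", n_pd)):
        for k in range(count):
            sid = f"{group.lower()}{k:02d}"
            subj = SimSubject(subject_id=sid, label=group)
            for mi in range(meals_per_subject):
                subj.meals.append(
                    simulate_meal(
                        cfg, seed=derive_seed(seed, sid, mi), render=render,
                        pd=(group == "PD"), meal_id=f"{sid}_meal{mi}", subject_id=sid,
                    )
                )
            subjects.append(subj)
    return subjects
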