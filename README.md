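# ptm — Plate-to-Mouth eating-behavior profiling from wrist IMU recordings

`ptm` turns 6-DoF smartwatch inertial recordings of meals (triaxial
accelerometer + triaxial gyroscope, nominally 100 Hz) into subject-level
eating-behavior profiles and screens them for Parkinson's disease (PD)
versus healthy control (HC).  The *Plate-to-Mouth duration* (PtM) — the
time the wrist spends transporting a loaded utensil upwards from plate to
mouth for one bite — is slower and more fragmented in PD, and its per-subject
distribution is discriminative even from unobtrusive, in-the-wild meal
recordings.

The pipeline, stage by stage (one module each under `src/ptm/`):

1. **signal_io** — CSV meal I/O (`t,ax,ay,az,gx,gy,gz`), JSON annotations,
   linear resampling to a common rate (100 Hz).
2. **preprocess** — 5th-order running median per channel; linear-phase
   high-pass FIR (513 taps, 1 Hz cutoff, group-delay compensated) strips
   gravity from the acceleration channels.
3. **features** — sliding windows of `w_l = 0.2·fs` samples with step
   `w_s = 0.1·fs` (50 % overlap); per frame, a 116-dimensional vector:
   per channel, mean / std / variance / min / max / range / zero-crossing
   rate / energy plus the magnitudes of the first `w_l/2 + 1` DFT
   coefficients; per sensor, the moving average `(1/w_l)·Σ(|x|+|y|+|z|)`.
4. **micromovement** — ten one-vs-one RBF SVMs over the five wrist
   micromovement classes {pick food `p`, upwards `u`, mouth `m`, downwards
   `d`, no movement `n`}; max-wins voting turns the `K×10` score matrix
   `V` into the label vector `y_mm`.
5. **intake** — a recurrent network (two LSTM layers, default 128 cells,
   then a single sigmoid unit; implemented in numpy with hand-written
   BPTT) scores 3 s windows of `V` as food-intake cycles (positive
   training windows start with `p`, end with `d`, and contain `m`).
   Probabilities are thresholded at `p_t = 0.89` and bites are local
   maxima at ≥ 3 s separation.
6. **ptm_extract** — per inter-bite interval `[b_{i−1}, b_i]`, maximal
   runs of upwards frames become *u-regions*; a backward walk from the
   last region merges gaps `< λ_d = 0.5 s`, giving

   `PtM_i = τ_e − τ_s − Σ gaps  (=  Σ merged u-region durations)`,

   discarded when `b_i − τ_e > λ_b = 5 s`.
7. **profiling** — a subject's durations pooled over meals feed a Gaussian
   KDE with Silverman bandwidth `ĥ = 0.9·min(σ̂, IQR/1.34)·n^(−1/5)`,
   evaluated at 50 points on [0, 3] s → the profile `x_f`.
8. **classify** — leave-one-subject-out RBF SVM (C = 1, inverse-frequency
   class weights) over profiles; threshold-sweep ROC, trapezoid AUC, and
   two operating points (sensitivity ≥ 0.85 / specificity ≥ 0.85).
9. **metrics** — the strict bite-matching scheme (first detection per
   ground-truth interval is a TP, extras and strays are FP, empty
   intervals FN), precision/recall/F1, and PtM MSE/MAE agreement.
10. **simulate** — a seedable generator of labeled synthetic meals and
    PD/HC cohorts (micromovement grammar → rendered IMU traces) so every
    stage is testable without access to clinical recordings.

## Worked example

Simulate a small cohort (2 HC + 2 PD, 2 meals each, plus 3 annotated
training meals), then run every stage:

```sh
ptm simulate --preset easy --n-hc 2 --n-pd 2 --meals-per-subject 2 \
    --train-meals 3 --seed 7 --out demo
ptm run-all --input demo --out demo_run
```

which prints (with a 24-cell LSTM configured for the demo):

```
wrote cohort to demo
8/8 meals processed
LOSO AUC 1.000
```

`demo_run/evaluation.json` holds the strict-scheme detection quality and
the PtM agreement against the generator's ground truth:

```
TP=64 FP=0 FN=0  precision/recall/F1 = 1.000/1.000/1.000
ptm_mse=0.0023  ptm_mae=0.0203   (64 matched bites)
```

i.e. all 64 simulated bites were detected exactly once and the extracted
PtM durations deviate from the true upwards-transport times by ~20 ms on
average.  `demo_run/classification.json` shows the four left-out subjects'
decision scores `[-0.675, -0.741, 0.083, 0.158]` for
`[hc00, hc01, pd00, pd01]` — the two PD subjects (whose upwards phases the
generator doubles) score above both controls, hence AUC 1.0.
`demo_run/profiles.json` contains each subject's pooled durations (HC
around 0.8 s, PD around 1.6 s), Silverman bandwidth, and 50-point profile.

All CLI commands (`simulate`, `train-mm`, `train-rnn`, `detect`,
`extract`, `profile`, `classify`, `evaluate`, `run-all`) are thin wrappers
over the library; `ptm <cmd> --help` shows the file contracts.

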