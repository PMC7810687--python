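# Methods

## Signal model and preprocessing

A meal is the matrix `S = [a_x, a_y, a_z, g_x, g_y, g_z]` of `N` samples
at `fs` Hz (`t = N/fs` seconds).  All streams are linearly resampled to a
common 100 Hz before processing; linear interpolation is the minimal
defensible kernel and is verified against closed-form sinusoids in the
tests.  Units are carried as metadata and never converted silently (the
accelerometer may report g or m/s²; nothing downstream depends on the
choice because features are learned per training corpus).

Each channel is smoothed with a running median of order 5 (edge handling:
edge-inclusive reflection padding, the `scipy.ndimage` "reflect" mode).
Gravity is removed from the acceleration channels only, with a linear-phase
windowed-sinc (Hamming) high-pass FIR at 1 Hz cutoff.  Two numerical
choices here:

* **513 coefficients.**  A "512-tap delay line" is read as filter order
  512, i.e. 513 coefficients.  This is not cosmetic: a symmetric
  linear-phase FIR with an *even* number of coefficients (Type II) has a
  structural zero at Nyquist and cannot realize a high-pass response, and
  an even length makes the group delay a half-sample.  With 513
  coefficients the group delay is exactly 256 samples and the output is
  shifted left by that amount, so bite timestamps and PtM endpoints stay
  aligned with annotations (an uncompensated ~2.56 s delay would corrupt
  every downstream duration).
* **Exact DC null.**  The windowed design leaves a ~−53 dB residual at DC;
  against a 9.81 m/s² gravity offset that is a visible output level.  The
  coefficients are shifted by `−sum(h)/taps`, forcing zero gain at DC
  while preserving the symmetric (linear-phase) structure; the pass-band
  perturbation is negligible (the 5 Hz attenuation stays below 5 % in the
  tests).

Convolution is zero-padded and length-preserving.  Meals shorter than the
filter fall back to per-channel mean subtraction with a warning.

## Frame features (L = 116)

Frames of `w_l = 0.2·fs` samples advance by `w_s = 0.1·fs`
(`K = ⌊(N − w_l)/w_s⌋` frames; centers at `(i·w_s + w_l/2)/fs`).  Per
channel: mean, standard deviation, variance, min, max, range,
zero-crossing rate, energy, and the magnitudes of the first `w_l/2 + 1`
DFT coefficients; per sensor: the moving average `(1/w_l)·Σ(|x|+|y|+|z|)`.
At `w_l = 20` this is `6·(8 + 11) + 2 = 116`.

Conventions fixed where the definitions admit variants: population
(divide-by-`w_l`) std/variance; energy = mean of squared samples
(scale-stable across window lengths); zero-crossing rate = strict sign
changes / `(w_l − 1)` with zeros as non-crossings (the zero signal has
rate 0); DFT features are magnitudes of the unnormalized one-sided
transform — magnitudes, rather than real parts or interleaved complex
pairs, are the reading that reproduces the 116 count with one number per
coefficient.  The feature order is fixed and exported
(`feature_names()`), and DFT values are verified against an `O(w_l²)`
direct-summation oracle.

## Micromovement recognition

Five classes (`p`, `u`, `m`, `d`, `n`) are separated by
`c(c−1)/2 = 10` one-vs-one binary SVMs with RBF kernel.  Defaults
`C = 1` and `gamma = 1/(L·Var)` (the scikit-learn "scale" rule) are
config-exposed; the kernel is the only structurally required choice.
Features are standardized with train-set mean/std before the SVMs — RBF
distances are scale-sensitive and the features mix units.  Pair order is
lexicographic and persisted with the model bundle; a positive score
favors the lexicographically first class of its pair.  Max-wins voting
takes the class with most pairwise votes; ties break by the largest sum
of |score| over the tied classes' pairs, then lexicographically (ties are
inevitable with 10 votes over 5 classes, so the rule must be total and
deterministic; it is checked against exhaustive enumeration).

## Bite-moment detection

Windows of the score matrix `V` spanning 3 s of signal time (30 rows at
the 10 rows/s frame rate) advance by 0.2 s (2 rows);
`K' = ⌊(K − 30)/2⌋ + 1`.  The window/step constants are deliberately
interpreted in *seconds of signal time*: read as raw row counts they
would span 30 s, an order of magnitude beyond a food-intake cycle and
incompatible with the cycle-aligned training rule below.

The classifier is two stacked LSTM layers (default 128 cells) and a
single sigmoid output on the final hidden state, implemented in numpy
with explicit backpropagation through time (gate order i/f/g/o, forget
bias +1, uniform `±1/√H` init) and Adam.  The gradients are verified
against central finite differences in the test suite.  A window is a
positive example iff its micromovement label sequence starts with `p`,
ends with `d`, and contains `m`.  Training uses balanced negative
sampling (each epoch: all positives plus an equal-size random draw of
negatives), binary cross-entropy, 50 epochs, learning rate 0.01 — all
config-exposed and seeded; the loss curve is returned for inspection.

At inference the probability vector is thresholded at `p_t = 0.89`
(an imported operating constant, kept as config) and peaks are picked
greedily by descending height with plateau ties to the earliest index,
suppressing anything within 3 s of an accepted peak (again seconds, 15
elements at the 5 Hz probability rate).  The bite timestamp is the peak
window's center — unbiased for a roughly symmetric gesture.  Raising
`p_t` can only remove bites (tested as a monotonicity property).

## PtM extraction

Labels binarize to the upwards indicator; maximal runs of upwards frames
inside each inter-bite interval `[b_{i−1}, b_i)` (the first interval
starts at meal time 0; there is no interval after the last bite) become
u-regions.  Frames are point-labels at centers but represent spans, so a
run is widened by half a frame step on each side.  The backward merge
bridges gaps strictly below `λ_d = 0.5 s` (a tie at exactly `λ_d` fails)
and stops at the first failure;

    PtM = τ_e − τ_s − Σ bridged gaps = Σ merged u-region durations.

That identity is exercised on 10⁴ random region sets.  Records are
discarded when `b_i − τ_e > λ_b = 5 s` and impossible when the interval
holds no u-region; both defaults are config fields.  Useful consequences
(all tested): PtM is monotone non-decreasing in `λ_d`; `λ_d = 0` reduces
to the final region alone; every retained duration is positive and
bounded by its interval.

## Subject profiles and classification

A subject's retained durations pool across meals in meal-then-bite order.
The profile is a Gaussian KDE with Silverman's rule-of-thumb bandwidth
`ĥ = 0.9·min(σ̂, IQR/1.34)·n^(−1/5)`, evaluated at 50 equally spaced
points on [0, 3] s (inclusive endpoints, `g_k = 3k/49`).  `σ̂` is the
sample (n−1) standard deviation — the rule is defined on the standard
deviation, and the min with IQR/1.34 is dimensionally consistent only
then; quantiles use linear interpolation.  Degenerate spreads floor the
bandwidth at 1 ms.

Classification is leave-one-subject-out: per fold, an RBF SVM (`C = 1`,
`gamma` = the "scale" rule on the 50-point profiles, class weights
inversely proportional to class frequency — the reading of
"proportionally weighted by prior probability" that counteracts rather
than amplifies imbalance) is fitted on the remaining profiles and its
decision value on the left-out subject recorded; PD is the positive
class.  Profiles enter as-is: their entries are already on a common
density scale.  The pooled scores yield a threshold-sweep ROC (positive
iff score ≥ threshold, swept over the unique scores from +∞), trapezoid
AUC — equal to the pairwise concordance statistic with ties at 0.5, which
the tests verify — and two operating points chosen on the pooled ROC: best
specificity subject to sensitivity ≥ 0.85, and the converse, each
reported with sensitivity, specificity, precision and F1.

## Evaluation machinery

Strict matching: within each ground-truth intake interval the earliest
detection is the TP; further detections and out-of-interval detections
are FP; empty intervals are FN; TN is undefined.  Boundaries are
half-open (a detection at the interval start is inside, at the end
outside), matching the global time convention.  `TP + FN` equals the
interval count on every instance.  Precision/recall/F1 define 0/0 as 0.
PtM agreement (MSE and MAE) pairs each TP detection's duration with the
true PtM of the interval it fell in.

## What the simulator emulates — and what it does not

A meal alternates idle stretches with intake cycles
`p → u (→ pause → u)* → m → d`.  Phase durations are log-normal
(positive, right-skewed gesture times).  Defaults reflect the published
meal-level statistics — 100 Hz, ~35 bites/meal, idle ~9.5 s so inter-bite
time is ~13 s and meals run ~7–8 min — with phase means chosen once at
plausible gesture scales (pick 0.8 s, upwards 0.8 s, mouth 1.0 s,
downwards 0.8 s); the upwards phase fragments with probability 0.3 into
two runs separated by a ~0.3 s pause (below `λ_d`, so extraction should
bridge it).  PD cohort effects: upwards mean ×2.0, fragmentation ×1.5 —
a deliberately strong, unambiguous effect direction.  Ground truth
bookkeeping: cycle spans, upwards spans, per-cycle true PtM (= summed
upwards spans), and the bite timestamp at the midpoint of the mouth
phase (the instant is otherwise undefined; the midpoint is symmetric).

Rendering expands each 0.1 s label slot to samples of a per-class model:
a mean template on the gyroscope channels plus a class-specific
oscillation (0.3–0.9 amplitude at 3–6 Hz, random phase per segment) on
the accelerometer channels, white noise (sd 0.3), and an optional 4–6 Hz
tremor sinusoid.  The oscillation carries the accelerometer's class
signature *through* the high-pass stage, where a constant template would
not survive.

Three presets ship: `realistic` (the defaults), `easy` (8 bites, idle
2.5 s, tight durations, no fragmentation, noise sd 0.1 — the scaled-down
condition used by the heavier tests so the suite runs in well under a
minute per case), and `null` (`easy` with all cohort multipliers at 1.0).

What passing tests show: the implementation recovers the generator's
ground truth through the full chain and separates cohorts whose only
difference is the upwards-phase distribution.  What they do not show:
performance on real recordings.  The simulator has no biomechanics, no
inter-subject template variability, no drinking gestures or bare-hand
eating, no sensor drift or dropped samples, and its class-conditional
signal model is far more separable than real wrist motion.  Detection
metrics on the easy preset are therefore ceiling-level by construction;
they validate the machinery, not clinical performance.

## Scale of the shipped experiments

The test and acceptance runs use the `easy` preset with a 24-cell LSTM:
3 training meals for the SVM array + LSTM; 8 held-out meals for the
detection F1 check; a 10 HC + 10 PD cohort with 5 meals per subject
(100 rendered meals through the full path) for the effect-size
discriminability check; and 20 seeds of the label-level null cohort for
the no-effect band, asserted on the mean AUC (a single LOSO AUC at 20
subjects has sampling sd ≈ 0.13).  The null arm omits rendering and
detection because, with no cohort effect anywhere in the generator, the
detector contributes no class information — only runtime.

## Known limitations

* The LSTM is plain numpy: fine at the shipped scales, but a 128-cell
  default on hour-long meals is CPU-minutes, not seconds.
* Bite timestamps inherit the probability grid (0.2 s) and window-center
  convention; sub-window timing precision is not attempted.
* The positive-window rule ties detectability to cycles of roughly the
  analysis-window length; very long cycles rely on the network's
  generalization rather than on exactly-aligned positive examples.
* Operating points are selected on the pooled LOSO ROC, not per fold, so
  their metrics are in-sample with respect to threshold choice.
* No drinking/bare-hand gesture handling and no meal start/end detection
  from all-day streams; recordings are assumed to delimit one meal.
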