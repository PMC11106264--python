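# Methods

This note documents the models, defaults and design decisions behind
`sleepstagekit`, and what the synthetic experiments do and do not show.

## Signal model of the synthetic cohort

The generator produces the *structure* a sleep-staging pipeline must cope
with, not physiological realism.

**Hypnograms.** Stages follow a first-order Markov chain over
{W, N1, N2, N3, R} at 30-s resolution, started in wake (lights off).  The
default transition matrix has sticky diagonals (e.g. p(N2→N2) = 0.90,
p(R→R) = 0.92), giving geometric stage dwell times with plausible medians
(N2 bouts ≈ 3.5 min).  No semi-Markov extension is attempted: geometric
dwell is sufficient to exercise every downstream stage and keeps the
stationary distribution analytic (the tests compare empirical stage
frequencies against the eigen-decomposition of the transition matrix).

**Tri-axial signal.**  `signal = gravity + movement + device noise`, in g:

* *Gravity* is a unit-norm orientation vector, piecewise constant between
  posture-shift events (Poisson, stage-dependent rate: 12/h awake down to
  1/h in N3) with ~20° jitter per shift.  Piecewise-constant orientation
  deliberately produces the low-variance stationary stretches that the
  non-wear detector keys on.  With all noise terms zero the signal is pure
  gravity, so every sample has norm exactly 1 g — a convenient calibration
  fixture.
* *Baseline movement* is Gaussian noise band-limited to ≈3.75 Hz
  (moving-average low-pass, variance-preserving), with per-stage sd
  **W 40, R 25, N1 20, N2 16, N3 14 mg**.  Two constraints shaped these
  defaults: the energy ordering wake ≫ REM > N1 > N2 > N3 that makes
  sleep/wake strongly and REM/NREM weakly separable, and keeping every
  sleep stage above the 13 mg stationarity threshold so genuine sleep is
  never mistaken for non-wear.  The band-limiting matters beyond cosmetics:
  with white baseline noise, self-supervised transformation discrimination
  can only learn sampler texture, which transfers negatively to staging.
* *Movement bursts* occur at stage-dependent Poisson rates (4/min awake,
  0.1/min in N3) with an abrupt-attack, gradual-decay envelope (attack
  fraction 0.1 of a 1-s burst).  The temporal asymmetry is intentional —
  real wrist movements are not time-symmetric — and is what makes
  time-reversal discrimination a learnable pretraining task.
* *Out-of-bed* daytime signal is high-variance wake movement (100 mg, 8
  bursts/min), which is what makes time in bed detectable at all.
* *Device noise* is 3 mg white.

**Subjects.** Each subject has stable traits — habitual bedtime
(between-subject sd 45 min) and habitual time in bed (sd 40 min) — around
which nights vary (sd 30 and 45 min respectively).  Without between-subject
variance the ICC analyses of the wear-time module would be degenerate by
construction.  Diaries report true onset/offset ± uniform(−15, +15) min,
emulating self-report imprecision.  Optional non-wear inserts (pure
stationary gravity) carry ground-truth intervals for cross-module tests.

All generator parameters are presets of this package, documented here;
none are estimates from any external dataset.

## Preprocessing

Linear interpolation onto the uniform 30 Hz grid anchored at the recording
start (exactly testable; idempotent on an already-clean recording), then
clipping to ±3 g and division into consecutive 30-s windows, dropping the
trailing partial window.  Non-wear: per-epoch per-axis sd < 13 mg, runs
strictly longer than 60 min (121 epochs qualify, 120 do not — a literal
reading of "greater than").  Quality control: recordings with ENMO-style
mean (‖a‖ − 1 g, floored at 0) above 200 mg are excluded as unrealistic
(interpreted at recording level — a per-sample rule would exclude all
normal wear); calibration error is the mean |‖a‖ − 1 g| over stationary
epochs (a simplified stationary-sphere statistic rather than full
gain/offset re-estimation), with a configurable 30 mg exclusion threshold.
Timestamps are UTC; intervals half-open [start, end).

## Time-in-bed detection

Features per wear epoch: ENMO mean; per-axis mean, sd and range;
vector-magnitude sd; arm angle (elevation of z over the horizontal plane)
mean, sd and change vs the previous epoch; the 0.3–3 Hz fraction of
non-DC spectral power; and a centred 5-min rolling ENMO median.  Published
feature batteries vary by toolchain, so this standard set is kept pluggable
rather than canonical.

A random forest (100 trees) trained on diary-derived in-bed labels yields
per-epoch probabilities; a two-state HMM smooths them.  Transitions come
from empirical label run lengths (p_stay = 1 − 1/mean run length, clamped
to [0.5, 0.999]); emissions are the forest probability binned into ten
equal-width bins with Laplace smoothing — a discrete alphabet keeps the
Viterbi step exactly testable against brute-force path enumeration.
Maximal in-bed runs become windows; windows separated by ≤ 60 min merge
transitively; per noon-to-noon interval the longest window wins, a window
belonging to the interval containing its midpoint (the boundary case is
otherwise undefined), ties broken toward the earlier start.

## The deep stager

Per 30-s window (3×900 at 30 Hz): mean-centering over time per channel,
a stem convolution, pre-activation residual blocks (BN–ReLU–conv ×2 with a
strided 1×1 projection where shapes change), BN–ReLU–global average
pooling to a feature vector; then a bidirectional LSTM over the night's
sequence of feature vectors and two fully-connected layers to five stage
logits.  The default preset stacks eight blocks (17 conv layers, channels
32→256); the `tiny` preset (stem 8, blocks 16/24, LSTM 16, ≈13.6k
parameters) is the test and demo surface — same topology, desk scale.

The input mean-centering deserves a note: the ±1 g gravity offset places
ReLUs deep in their linear regime, where global pooling averages away the
mg-scale movement fluctuations; removing each window's per-channel mean
(a high-pass, no variance scaling) restores sensitivity to movement
energy.  It is a config flag (`center_input`, default on).

Training: class-weighted (inverse-frequency) cross-entropy on randomly
phased non-overlapping crops of 24 epochs (memory-bounded), Adam at 3e-3,
full-night sequences at inference.  Batch-norm running statistics use
bias-corrected exponential averages so evaluation-mode inference is sound
after the few dozen updates of a small training budget.  Cross-validation
is subject-wise; a fold that would place a subject on both sides raises.
All randomness flows through seeds; runs are bit-reproducible.

The engine (`nn.py`) is NumPy with manual backprop — conv via im2col +
BLAS, explicit BPTT for the LSTM — and every layer's gradient is checked
against central finite differences in the test suite.

## Self-supervised pretraining

Three transformations, each applied independently with probability 0.5 to
an unlabelled window: time reversal; permutation of 4 equal segments
(identity permutations redrawn so the label is truthful); smooth monotone
time warp (log-normal knot speeds, σ = 0.2, resampled back to 900).  One
binary softmax head per task on the pooled extractor features; the joint
loss is the sum of per-task cross-entropies; the trained extractor state
warm-starts supervised training.

Two protocol choices were driven by what is honest to measure at desk
scale.  (1) The time-reversal mechanism check uses purpose-built windows
dominated by asymmetric bursts over a quiet baseline — a corpus where the
transformation is detectable by construction (held-out AUC > 0.9).  (2) On
the default variance-separable cohort, *random* rectified-conv features
already separate sleep from wake almost perfectly (linear probe ≈ 0.98),
leaving pretraining no headroom; the warm-vs-cold-start comparison
therefore uses a burst-morphology cohort in which stages share a baseline
variance and differ in burst rate/amplitude/shape, the regime where
pretrained movement-shape features genuinely help.  Warm and cold runs
share initialisation, batch order and budget (3 passes); the comparison is
paired over seeds.

## Sleep parameters

Within a bed window: total sleep = 30 s × non-wake epochs; efficiency =
total sleep / window duration × 100; WASO counts all wake after the first
sleep epoch up to the window end (no final-awakening truncation — the
simplest defensible reading, configurable in principle); REM/NREM ratios
are percentages of total sleep.  An all-wake window reports WASO 0 with a
`waso_defined=False` flag.  Sleep efficiency uses the selected overnight
window as time in bed.  Collapse maps are deterministic (N1/N2/N3→NREM;
all sleep→SLEEP) and commute with total-sleep computation.

Stage-probability trajectories report, per clock-time bin, the fraction of
person-epochs in each stage with `out_of_window` absorbing uncovered time,
so per-bin probabilities sum to 1.  Cohort filters: ≥ 3 days with ≥ 22 h
wear, at least one valid weekday and weekend (Sat/Sun) day, and
metadata-flag exclusions for shift work and daylight-saving cross-overs.

## Agreement battery

κ, macro F1 (per-class values also emitted), balanced accuracy and
per-class sensitivity/specificity/precision are computed directly from the
confusion matrix by their defining formulas; sklearn serves only as an
independent cross-check in tests.  Both epoch-pooled and subject-mean (±
between-subject sd) variants are always reported and labelled; subjects
with a single true class are excluded from the κ mean.  Bland-Altman uses
estimate − reference (positive bias = overestimation) and 95% limits of
agreement bias ± 1.96·sd with no repeated-measures correction (one night
per subject in the validation design).

## Wear-time simulation

Masking removes contiguous 1-h blocks (device non-wear is contiguous in
practice) until each retained day keeps exactly the target wear, and keeps
only the chosen days.  The weekly estimate is the mean over days with any
retained wear of per-day observed sleep.  ICC is the two-way
random-effects, absolute-agreement, single-measure ICC(2,1) from explicit
ANOVA sums of squares (cross-checked against pingouin's ICC(A,1)); the
grid search averages ICC over replicates and reports the cheapest
(hours × days) cell above the threshold, flagging monotonicity violations.
The specific real-world answer (22 h × 3 days) depends on the true
between/within-subject variance structure of a real cohort and is not a
claim of this package.

## Problem sizes

The reference experiments use 20 subjects × 2 nights × ~2.5 h in bed
(~12k labelled epochs) for cross-validated training, 1 200–1 500 windows
for pretraining corpora, 500 pairs for ICC calibration and 25 synthetic
weeks for the wear grid — large enough for the qualitative behaviour
(sleep/wake strongly separable, REM vs NREM weakly; two-class ≥
three-class ≥ five-class agreement) to emerge reliably, small enough to
run in minutes on one CPU.

## What passing tests do and do not show

The synthetic cohorts make stage-dependent movement the *only* signal, so
green tests demonstrate that every component is implemented correctly and
that the learning machinery extracts the signal that is there.  They say
nothing about accuracy on real polysomnography-labelled accelerometry,
where wake-in-bed without movement, sleep-stage physiology and device
artefacts dominate the difficulty.  Reported per-night agreement on
synthetic data (e.g. total-sleep bias of a few minutes) characterises the
pipeline, not clinical performance.
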