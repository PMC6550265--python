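# Methods

`thermowrist` analyzes labeled multichannel recordings from a wrist-worn
device — four thermopiles, two orientation-derived IMU channels and a
time-of-flight proximity channel, sampled irregularly at 5–7 Hz — in which
a participant held a hand at one of six head locations (mouth, nose,
cheek, eyebrow, top of head, back of head) for roughly 15 s per location
while rotating the elbow, plus an off-body recording. Two raters marked
samples *on-target*; a sample counts only when both agreed. The question
throughout is whether the thermal channels add information about hand
position beyond proximity and orientation alone.

## Data model and scaling

Channel order is a global constant `(thermal1..4, imu1, imu2, proximity)`;
all channel selection goes through named `ChannelSubset`s (`no-thermal` =
proximity + IMU, `with-thermal` = all seven, `thermal-only` = the four
thermopiles). Data are z-scaled before any analysis: one transform per
channel, pooled over all samples of all participants and segments, with
the population (n) denominator. A per-participant variant exists behind a
flag but the global transform is the default — the group-level analyses
and the participant-independent classifier both operate in one shared
feature space. Constant channels are rejected by name rather than scaled
by zero. Head-target statistics use only on-target samples by default
(`on_target_only=False` uses everything); off-body segments, whose mask is
all-False by construction, always contribute all samples.

## Discriminability distance

For one participant and one pair of head targets, each segment is reduced
to its per-channel median vector (even counts: mean of the two middle
order statistics) and the discriminability distance is the Euclidean
distance between the two vectors, computed on a channel subset. The
permutation baseline pools both segments' samples, re-partitions them into
the original group sizes (sample-level shuffling) `n_shuffles` times
(default 1000), and records the distance each time; empirical p-values use
the add-one convention (r+1)/(N+1) so they are never zero and remain
super-uniform under exchangeability. The same random re-partitions are
used for every channel subset of a pair (coupled nulls), so permutation
quantities obey the same algebra as observed ones.

Cohort-level inference is paired across participants with the Wilcoxon
signed-rank test: (i) observed vs. null-median distance without thermal
channels, (ii) the same with all channels, (iii) observed distance without
vs. with thermal channels. Each of the three families is Bonferroni
corrected at family size 15 (the number of target pairs). The paired
effect size is median(with − without) / MAD(with − without) with the MAD
unscaled (no 1.4826 normal-consistency constant). The signed-rank test
drops zero differences, mid-ranks tied magnitudes, enumerates all 2^n sign
assignments exactly for n ≤ 12 non-zero differences and otherwise uses the
normal approximation with continuity and tie corrections.

### The partition identity and the thermal-gain test

Because the channel subsets are nested, every computed pair satisfies

    d_with² = d_no² + d_thermal²

exactly (asserted at 1e-9). A consequence worth being explicit about: the
paired difference in analysis (iii) is strictly positive whenever the
thermal median vectors differ at all — with continuous noise, always — so
analysis (iii) measures the *size* of the thermal increment but is not a
null-calibrated test of whether the thermal channels carry information;
with 39 participants its p-value is ≈ 6e-8 even for pure thermal noise,
since the signed-rank statistic sees only signs and ranks. The package
therefore also reports a *thermal-gain* test built from the permutation
machinery: per participant, the observed thermal-only distance is referred
to its own coupled permutation null, giving a quantile p_i that is uniform
on (0,1] when the thermal channels are uninformative; across participants
the p_i are tested against 1/2 with the signed-rank test. Under the null
the p_i are symmetric about 1/2, so the test holds its level; when thermal
channels carry location information every p_i collapses toward 1/(N+1) and
the test is decisive. Use `p_no_vs_with` to quantify the increment and
`p_thermal_gain` to claim that thermal information exists.

## Synthetic cohorts

The generator emulates the study design so that every stage is testable
without recordings. Per sample:

    value = location mean + participant offset
            + participant-location jitter (optional, default off)
            + elbow-rotation sinusoid (IMU channels only)
            + i.i.d. Gaussian noise

Defaults (all in `CohortConfig`): 39 participants; 15 s segments;
inter-sample gaps uniform in [1/7, 1/5] s; ambient thermopile baseline
26 °C with head-target thermopile means 29.5–33.5 °C (each location a
different 4-vector, as the four thermopiles have different fields of
view); proximity between 22 and 68 device units at head targets against an
out-of-range ceiling of 255 off-body; orientation means per location with
a 0.5 Hz quadrature sinusoid of amplitude 0.25 for the circular elbow
rotation (random phase per segment); within-segment noise sd 0.3 °C /
0.15 / 5 units; between-participant offset sd 0.8 °C / 0.2 / 8 units; and
a 1 s rater lag trimming the on-target mask at both segment edges. The
signatures are chosen so that nose/cheek/eyebrow share nearly identical
proximity/orientation values and top-head/back-head share a raised-arm
orientation: every location has a neighbor it is confusable with in the
no-thermal subspace and separable from thermally. These numbers are design
choices for a plausible device, not estimates of any real hardware.

Two dials matter for experiments. `thermal_contrast` scales every thermal
deviation from ambient (including the thermal part of the location
jitter); at 0 the thermal channels are pure noise and any thermal-gain
claim is a false positive. `participant_location_sd` draws an independent
per-(participant, location) perturbation of the signature itself,
modeling people who hold the hand differently at each spot rather than
merely reading shifted sensors. This distinction is load-bearing: a shared
additive offset moves one participant's positive and negative windows
together, and AUROC depends only on within-participant ranking, so
offsets alone barely degrade a transferred classifier; signature jitter is
what makes an unseen participant genuinely harder, and it is the condition
under which the leave-one-participant-out penalty appears.

What the generator does **not** model: autocorrelated or heteroscedastic
sensor noise, drift, realistic arm kinematics, thermopile optics, or two
independent raters (the dual-rater mask is a single edge lag). Passing
tests on these cohorts show the statistics and protocols behave correctly
under the assumed structure; they do not certify performance on real
recordings.

## Classification

Each head target defines a one-vs-rest binary problem over sliding windows
(default length 10 samples ≈ 1.5–2 s, stride 2; windows never cross
segment boundaries). A window is positive only if it comes from the
target's segment and every sample is on-target. The classifier is a small
LSTM implemented in numpy: two stacked layers of 50 units (input dropout
0.20 on the second layer, one mask per sequence) and a single sigmoid
unit, trained with class-weighted binary cross-entropy ("balanced"
weights; unweighted training is available and reproduces the degenerate
all-negative predictor on imbalanced data, which still scores AUROC 0.5 by
the tie convention). Optimization is Adam (lr 1e-3, batch 32, default 20
epochs) with global gradient-norm clipping at 5; forget-gate biases start
at 1; the backward pass is verified against finite differences in the test
suite. Training, the 25% stratified hold-out split, and dropout are all
deterministic in `random_state`.

Evaluation reports AUROC (Mann–Whitney formulation, ties one half) and a
2×2 confusion matrix at threshold 0.5 per participant, summarized as
median ± MAD across participants with an elementwise median of
row-normalized confusion matrices. `evaluate_per_participant` trains and
tests within each participant; `evaluate_general` is
leave-one-participant-out. The split is stratified at the window level by
default (adjacent overlapping windows can fall on both sides; a
segment-level split is a known stricter alternative left to future work).

## Problem sizes and numerical choices

The bundled experiments run the discriminability analysis at the full
default cohort (39 participants, 1000 shuffles) and the classification
experiments at a reduced scale chosen for single-CPU runs: 10
participants and 5 training epochs, which this generator separates
cleanly. Null-calibration experiments use 20 cohorts at 300 shuffles and
200 exchangeable replicates at 999 shuffles (Kolmogorov–Smirnov check at
α = 0.01). Ties in medians and ranks follow the conventions above;
degenerate inputs (constant channels, single-class windows, all-zero
paired differences, zero MAD) raise or exclude with a warning rather than
silently producing numbers. Master-seed convention: stage seeds are the
master seed plus fixed offsets (simulate +0, discriminate +1000, classify
+2000); per-participant and per-pair streams are spawned through
`numpy.random.SeedSequence` so results are independent of iteration order.

## Known limitations

- The i.i.d.-Gaussian noise model understates the difficulty of real
  sensor data; reported AUROCs and effect sizes on synthetic cohorts are
  upper bounds in spirit.
- Window-level splitting lets overlapping windows straddle the train/test
  boundary within a participant; per-participant AUROCs are accordingly
  optimistic relative to a segment-level split.
- The Wilcoxon normal approximation is used above n = 12 non-zero
  differences; exact enumeration covers the small-n regime only.
- The cohort confusion matrix is a median of row-normalized matrices and
  need not have rows summing to exactly one.
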