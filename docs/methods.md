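# Methods

This note documents the models, numerical choices and limitations behind
`posefreq`: what each stage computes, which parameters matter, what the
synthetic trial generator does and does not emulate, and where the design
was genuinely open.

## Input model

The package consumes the per-frame JSON dialect of the OpenPose demo: one
file per video frame named `<prefix>_NNNNNNNNNNNN_keypoints.json`
(12-digit zero-padded frame index), each holding a `people` array whose
entries carry flat `[x, y, confidence]` triples — 75 values for the
BODY_25 body model, 63 per 21-point hand model. Coordinates are image
coordinates (origin top-left, y downward, pixels); confidences are in
[0, 1] with 0 meaning "not detected". Face keypoints are ignored.

A keypoint sample is *missing* when its confidence is ≤ the missingness
threshold. The default threshold is 0.0 inclusive, matching OpenPose's own
encoding of undetected keypoints as zero-confidence triples; it is
configurable (`--confidence-threshold`) because stricter screening of
low-confidence detections can be appropriate for difficult recordings.

The recording protocol assumes a single person in view. When a frame
nevertheless contains several people, the person with the highest summed
body confidence is kept (ties to the lowest array index); this is a
robustness measure, not a tracking algorithm — identities are not linked
across frames. Gaps in the frame numbering are inserted as all-missing
frames so time never silently skips.

## Preprocessing

**Gap filling.** Interior runs of missing samples are replaced by linear
interpolation between the nearest observed neighbours, independently for x
and y of each keypoint. Boundary gaps are held at the first/last observed
value rather than linearly extrapolated: with noisy endpoints,
extrapolation can diverge by hundreds of pixels over a long leading gap,
whereas a hold is bounded and bias-free for a signal at rest. The
operation is idempotent and never alters observed samples. A keypoint
needs at least two observed frames; with fewer it stays all-missing and
any task needing it fails with an explicit error.

**Low-pass filtering.** Every coordinate series is filtered with a
zero-lag 4th-order Butterworth low-pass, cut-off 5 Hz — comfortably above
the 1–4 Hz band of voluntary repetitive movement and low enough to
suppress pose-estimator jitter. "Zero-lag 4th order" follows the
biomechanics convention: a 2nd-order filter is designed and applied
forward then backward (`scipy.signal.filtfilt`), giving an effective
4th-order zero-phase response. The alternative reading — a 4th-order
design double-passed, effectively 8th order — is available as
`filter_convention="design"`. No cut-off correction is applied for the
double pass. Edge handling uses odd reflective padding of
3 × (design order + 1) samples, `filtfilt`'s convention, stated here for
bit-reproducibility. DC gain is exactly 1; the zero-phase property is what
licenses reading event *times* off the filtered signal.

## Task signals and event detection

Each task reduces to one scalar signal per trial:

| task | signal | events |
|---|---|---|
| finger tapping | ‖thumb tip − index tip‖ (px) | minima (taps) |
| hand open/close | ‖thumb tip − index tip‖ (px) | minima (closures) |
| pronation/supination | thumb-tip elevation (−y) | maxima = supination, minima = pronation |
| toe tapping | big-toe elevation (−y) | minima (ground contacts) |
| leg agility (heel tapping) | heel elevation (−y) | minima (heel strikes) |

Elevation is the negated image-y, so "down" events are minima in code as
in description. The thumb tip is used for pronation/supination because,
in the sagittal-view recordings the protocol prescribes, it is the hand
landmark with the largest vertical excursion between thumb-up and
thumb-down; each pronation and each supination counts as one event
(metronome beats alternate between them). Minima of the toe/heel are taken
in elevation, i.e. maxima of image-y: the physical reading (ground
contact) rather than the pixel-coordinate one.

Detection is `scipy.signal.find_peaks` on the (negated, for minima)
signal with two scale-free parameters:

* **minimum separation** between same-polarity events: half the dominant
  period of the mean-subtracted signal (periodogram argmax), floored at
  0.1 s. This adapts across the 1–4 Hz range without per-trial tuning;
  for pronation/supination the dominant period is the full
  pronate-supinate cycle, so the same rule spaces same-polarity extrema
  correctly.
* **minimum prominence**: 20% of the signal's 10th–90th percentile range,
  making detection invariant to recording scale and robust against
  filtered pixel noise (~1 px after the 5 Hz low-pass, versus tens of
  pixels of movement amplitude).

Events are reported at integer frame resolution — no sub-frame parabolic
refinement — because the manual ground truth they are compared against is
frame-by-frame by construction. On an exactly flat extremum plateau the
earliest frame is the event. For the dual-polarity task, consecutive
same-polarity extrema (a noise artifact) are resolved by keeping the more
extreme one, preserving the pronation/supination alternation invariant.

A flat signal yields an empty event series; frequency computation then
refuses with an explicit error rather than returning a number.

**Frequency.** `f = (N − 1)/(t_N − t₁)` over the detected events. For
periodic events this estimator is unbiased, uses the longest available
baseline, and ignores idle video before the first and after the last
event. A mean-of-inverse-intervals alternative is available
(`estimator="mean_rate"`); it is noisier because short intervals dominate.

## Event matching and agreement statistics

Pose-detected and manually-annotated event series for the same trial may
differ in count, typically by a surplus detection at the start or end of
the trial. Matching proceeds as:

1. While counts differ, remove from the longer series the event whose
   nearest-neighbour distance to the other series is largest, recomputing
   distances after every removal; ties remove the earliest such event
   (determinism). One-at-a-time removal with recomputation was chosen over
   batch removal and verified against exhaustive enumeration (below).
2. Pair the i-th events of the equal-length series.
3. Equal-count boundary rule: if the first and last pairs are both
   separated by more than the unmatched-gap threshold, with the shifts in
   the same direction (one method has an extra event at the start, the
   other an extra at the end), both unmatched boundary events are
   discarded and the series re-paired.

The unmatched-gap threshold is half the median inter-event interval of
the manual series — unit-free, and at any tested frequency it cleanly
separates timing jitter (a fraction of an interval) from a genuinely
unshared event (about a whole interval).

The greedy procedure equals the exhaustive order-preserving
minimum-cost pairing (enumerating all discard sets, ≤ 6 events per side)
across 10,000 simulated scenarios in which both methods observe a jittered
periodic core and one method adds boundary extras — the regime the
procedure exists for. It is *not* a general assignment optimizer:
counterexamples exist when the shorter series contains interior events
the longer series never saw; in that regime no order-preserving complete
pairing is meaningful either.

On the matched pairs: event-time errors are manual − pose (positive =
pose early), in seconds and frames. Pearson r comes from
`scipy.stats.pearsonr`. ICCs use the McGraw–Wong single-rater forms on
the n×2 (events × methods) table, from the two-way ANOVA mean squares
MS_R (rows/events), MS_C (columns/methods), MS_E (residual):

* ICC(C,1) = (MS_R − MS_E) / (MS_R + MS_E) — consistency, two-way mixed;
* ICC(A,1) = (MS_R − MS_E) / (MS_R + MS_E + (2/n)(MS_C − MS_E)) —
  absolute agreement, two-way random.

Both are tested against zero with F = MS_R/MS_E on (n−1, n−1) degrees of
freedom, the standard test for these forms (and what `pingouin` reports;
the test suite cross-checks both coefficients and p-values against it and
against an explicit sums-of-squares computation). A constant offset
between methods leaves ICC(C,1) at 1 while strictly lowering ICC(A,1),
which is the reason both are reported. When either series has zero
variance, r is undefined and flagged; the ICCs are still reported from
the mean squares. At least 3 pairs are required.

## Synthetic trials

The simulator generates what the workflow consumes — full-body keypoint
JSON — for study conditions matching the validation protocol: 10 s trials
at 30 frames/s, target frequencies 1–4 Hz, a seated adult filling a
720×1280 portrait frame. Amplitude defaults are task-specific, plausible
pixel excursions at that framing (e.g. 80 px finger-tap aperture, 60 px
toe lift).

A static full-body pose is held; the task keypoints follow a train of
raised-cosine movement cycles, one event per cycle at its extremum.
Toe/heel cycles overshoot the ground line slightly and are clamped there,
producing a ~60 ms flat contact dwell as real taps have — deliberately
stressing the detector's plateau handling; the planted event is the first
contact frame, and the detector's plateau tie-break (earliest frame)
agrees with it in the noiseless limit. Pronation/supination oscillates the
thumb tip at half the target event rate so that each half-oscillation
extreme is one event and the event rate equals the metronome rate. By
default the cycle train is phase-shifted so planted events fall exactly on
frame boundaries (`frame_aligned`), which makes the noiseless
detected-equals-truth fixed point exact where the frame rate permits.

Noise model: i.i.d. Gaussian pixel jitter (default σ = 2 px) on every
coordinate of every keypoint, and Bernoulli dropouts (default 5% per
keypoint-frame) serialized as `(0, 0, 0)` triples, OpenPose's encoding of
undetected keypoints. Confidences of observed keypoints are uniform in
[0.5, 0.95]. All randomness derives from one seeded generator per trial.

For exercising the matcher, the generator can plant count mismatches:
`spurious_events` prepends full-amplitude leading cycles that are real
movements *excluded* from the ground truth (false starts a human rater
would not count), which the pipeline duly detects as surplus leading
events; `missed_events` scales trailing cycles to 5% amplitude —
*included* in the truth but below the detector's prominence floor, so the
pipeline misses them.

What the simulator does **not** emulate: camera perspective and parallax,
correlated (non-white) tracking error, keypoint identity swaps, occlusion
bursts longer than independent dropouts produce, amplitude decrement or
hesitations within a trial, and multi-person scenes. Consequently, passing
the synthetic validation demonstrates that the *signal-processing chain*
recovers known kinematics under realistic noise and dropout — it does not
by itself establish accuracy on patient videos, where tracking failures
are structured rather than white.

## Numerical and degenerate-input choices

* Filter: series must exceed 3 × (design order + 1) samples (padding
  requirement); cut-off must lie below Nyquist; both are validated with
  explicit errors.
* Gap filling requires ≥ 2 observed samples per keypoint coordinate.
* A constant task signal produces zero events, not an error; frequency
  then refuses (< 2 events).
* `pearsonr` on exactly identical series is returned as r = 1, p = 0
  directly (the limit value) to avoid a spurious constant-input warning.
* Zero residual variance in the ICC table (exactly consistent methods)
  reports p = 0 when the row effect is positive.
* Event CSV times are written to 4 decimal places (0.1 ms at 30 fps, two
  orders below frame resolution); all CSVs use LF endings so outputs are
  byte-reproducible across platforms.
* Acceptance-style checks measure sinusoid amplitude as √2·RMS and phase
  by projection, because at 30 fps the extrema of a 10 Hz probe tone fall
  between samples and max-based estimates read ~13% low.

## Problem sizes in the shipped checks

The validation study run by `scripts/acceptance.py` and the test suite
uses 5 tasks × 4 frequencies × 5 seeds (100 trials of 300 frames), 1,000
random tables for the ICC oracle comparison, and 10,000 scenarios for the
matching oracle comparison — sizes at which the exhaustive oracles are
exact and the whole suite completes in well under a minute on one core.

## Known limitations

* The pipeline estimates frequency only; movement amplitude, decrement
  and hesitation metrics are out of scope.
* Single-person analysis: multi-person frames are resolved per frame by
  total confidence, without temporal identity tracking.
* The dominant-period heuristic assumes one repetitive movement per
  trial; signals with two competing periodicities (e.g. tremor plus
  voluntary movement) may mis-set the minimum event separation.
* ICC p-values assume the usual two-way ANOVA normality conditions;
  event-time tables with strong trends satisfy the consistency model only
  approximately.
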