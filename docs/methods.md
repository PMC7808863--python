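# Methods

`larvatrack` quantifies the horizontal locomotion of a single insect larva
(the motivating system is a *Bombyx mori* caterpillar, mock- or
baculovirus-infected, filmed in a 100 mm dish) from time-lapse frames, and
ships a ground-truthed simulator so every stage can be validated without
original videos. This note documents the models, the defaults and why, the
numerical choices, and what the synthetic validation does and does not show.

## Tracking model

Frames are 8-bit greyscale (RGB input is collapsed by an unweighted channel
mean, rounded half-up). The background model is the per-pixel arithmetic
mean over all frames of the recording; each frame is reduced to the
*absolute* difference from this background. Absolute (rather than signed)
subtraction makes the detector indifferent to whether the animal is lighter
or darker than the substrate. The difference image is binarized either by
Otsu's method (default) or a fixed grey-level threshold; because Otsu always
splits the histogram somewhere, a guard declares the mask empty when the
Otsu threshold falls below `min_fg_level` (default 10 grey levels), which
handles frames containing only noise. Particles are 8-connected components
with at least `min_area` pixels (default 10, suppressing noise speckle);
the centroid is the unweighted mean of member-pixel coordinates — after
binarization the particle is mass-uniform, so no intensity weighting is
applied. Coordinates are image-convention `(x, y) = (column, row)`, pixel
centres at integers, origin top-left.

A known limitation of average-intensity backgrounds is inherited
deliberately: an animal that dwells in one spot for a substantial share of
the recording contaminates the background there, leaving a "ghost" that can
distort detections near the resting site. The trajectory module therefore
flags a larva for exclusion when more than 20 % of frames lack a detection
(an automated proxy for the manual validity inspection such recordings
otherwise require; threshold configurable).

## Trajectory QC

Detections outside the dish circle plus a 2-px tolerance (centroid jitter
at the wall) are removed. Frames with several detections take the
unweighted mean of the centroids; frames with none take the immediately
previous position (carry-forward). Frames before the first detection are
back-filled from it rather than dropped, keeping the full frame grid intact
for windowed analyses; per-frame provenance
(`detected`/`averaged`/`carried_forward`/`back_filled`) is recorded. A
consequence of carry-forward worth knowing: the interval *ending* at a
filled frame has distance 0 and the following interval absorbs the jump.

## Locomotion quantification

Per-interval displacement is Euclidean distance between adjacent frames
(3 s apart by default). An interval with displacement strictly greater than
0.5 px is *movement*; a displacement of exactly 0.5 px counts as stationary
("exceeded" is read strictly; configurable). Displacements are averaged
over consecutive non-overlapping 30-s windows (10 intervals) anchored at
interval 0; a trailing partial window is included and averaged over its
actual members, so no data are discarded. A window whose mean exceeds the
same 0.5-px threshold is a *moving* window, and maximal runs of moving
windows are single continuous-locomotion events (bouts). Four per-larva
metrics summarise a record: total distance (px, sum of all steps), median
speed over moving intervals only (px per 3-s interval; divide by the frame
interval for px/s), median bout duration (in 30-s windows), and bout count.
Medians over empty support (a larva that never moves, or has no bouts) are
reported as NaN and dropped from group tests rather than imputed.

## Spatial occupancy

A record is split into `n_segments` (default 8, i.e. 3-h segments of a 24-h
record) contiguous equal parts; when the frame count is not divisible the
remainder goes to the last segment, so the segments always partition the
record exactly. Each segment's position cloud is summarised by the median
radial fraction (distance from the dish centre over dish radius), the
fraction of frames within the food radius + 10 px of the food centre, and
the edge fraction (radial fraction > 0.8). The 0.8 cutoff and 10-px food
margin quantify the otherwise qualitative notions of "at the edge" and
"near the diet"; both are configurable.

## Statistics

Group comparisons use the two-sided Wilcoxon–Mann–Whitney rank-sum test.
For combined samples of at most 16 (the regime of 6-per-group dish assays)
the null distribution of U is obtained by complete enumeration of all
C(n1+n2, n1) assignments of the pooled mid-ranks, which stays exact under
ties; `p = min(1, 2·min(P(U ≤ u), P(U ≥ u)))`. Larger samples use the
tie-corrected normal approximation with continuity correction. No
multiple-testing correction is applied across the four metrics — the
workflow this reproduces applies none — so interpret the four p-values
jointly with that in mind.

## Synthetic larva model

The simulator is a two-state semi-Markov process observed at the frame
interval:

* **Bout onsets.** The target bout-to-bout cycle is `1/bout_rate_per_h`.
  Stationary gaps are exponential with mean equal to the cycle target minus
  the mean bout duration (floored at one frame interval), so the expected
  number of bouts per hour equals `bout_rate_per_h` *independently of bout
  duration*. This is deliberate: bout frequency and bout duration are
  separable axes of the phenotype, and a comparison of two regimes differing
  only in duration must not show a frequency difference by construction.
* **Bout durations** are gamma (shape `bout_duration_shape`, default 2;
  mean `bout_duration_mean_s`, default 300 s) — the simplest family giving
  independent control of mean and spread.
* **Movement** is a correlated random walk: per-interval step lengths are
  lognormal with arithmetic mean `step_mean_px` (default 3 px per 3 s) and
  log-sd `step_dispersion` (0.5); turn angles are wrapped-normal with sd
  `(1 − heading_persistence)·π` (persistence 0.7). The dish wall reflects
  specularly.
* **Stationary intervals** jitter uniformly within a 0.15-px disc around
  the resting point (max net step 0.3 px): real centroids fluctuate, and
  sub-threshold jitter exercises the 0.5-px classifier near its boundary
  instead of handing it exact zeros.
* **Spatial modes.** `food_centered` steers the heading fractionally toward
  the food centre each step; `edge_following` steers outward until ~0.8 of
  the wall radius and then along the closer wall tangent. A regime with
  `mode="edge_following", mode_switch_h=9` behaves food-centred for the
  first 9 h and wall-follows afterwards — the late-infection thigmotaxis
  pattern.

The default mock regime is 2 bouts/h, 300-s bouts, 3 px/interval; the
default infected regime doubles step mean and bout duration at an unchanged
rate and adds the 9-h edge switch. No numeric speed or duration values are
published for the motivating assay (its outcomes are box plots), so these
magnitudes are calibration choices producing a clearly detectable but not
degenerate contrast; what matters downstream are the *ratios* (2×) and the
frequency neutrality, which the pipeline is required to recover.

Cohorts derive per-larva seeds from a master seed through numpy's
`SeedSequence.spawn`, so any cohort size is reproducible and the two
groups' streams are disjoint even with identical parameters (null
calibration).

The renderer draws the larva as an anti-aliased ellipse (half-axes 6×3 px,
soft 1-px coverage edge) oriented along its recent heading, over a uniform
dark background (intensity 30) with a static food disc (90) — the bright
animal on dark paper matches how such assays are filmed — plus per-pixel
Gaussian noise (sd 2), optional per-frame larval dropout (exercises gap
filling) and spurious clutter blobs (exercise multi-detection averaging).

### What the synthetic validation does and does not show

Passing tests demonstrate the pipeline's correctness on data whose
generating process is known: detection accuracy to sub-pixel RMS, exact
agreement of particle and bout segmentation with brute-force oracles,
recovery of imposed effect ratios, calibration of the exact test, and the
spatial signature of a mode switch. The simulator does not model body
posture or peristalsis (the larva is a rigid blob), feeding interactions
with the diet, illumination drift, shadows, reflections, or camera shake;
real recordings can fail the average-background assumption in ways the
generator only mimics via dropout. Results on real videos therefore still
require the plotted-position validity check the trajectory module's
exclusion rule approximates.

## Problem sizes used in the bundled checks

The validation suite and `scripts/acceptance.py` use a 500-frame render for
end-to-end tracking, exhaustive 4×4 plus 50 random 64×64 masks for the
component oracle, 1 000 random patterns for the bout oracle, 20 replicate
cohorts of 6 + 6 larvae (24 h each) for effect recovery, 50 cohorts of
10 + 10 for the significance pattern, 1 000 null datasets for test
calibration, and 20 seeds for the edge-following contrast. These sizes give
stable Monte-Carlo estimates (binomial SE below ~7 points on the reported
percentages) while keeping a full run in the low minutes on one CPU.
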