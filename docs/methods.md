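# Methods

This note documents the models implemented in `filmgaze`, their assumptions,
the tunable parameters and their defaults, and the design decisions taken
where the underlying methodology is genuinely open.

## Gaze similarity

### Model

Gaze of a viewing condition at frame *f* is treated as a two-dimensional
density landscape: the sum of unit-height circular Gaussian kernels centred
on every viewer's frame-resolved gaze position within a temporal window
around *f*. Kernels are evaluated in degree coordinates — pixel offsets are
divided by the per-axis pixels-per-degree ratios before computing distance —
so they are circular in visual angle even on anisotropic screens (the
default geometry, 720 × 480 px over 21.42° × 16.10°, has 33.6 px/° horizontal
versus 29.8 px/° vertical). Kernels are deliberately *unnormalized*
(unit height, not unit mass): the subsequent z-scoring removes any global
scale, which the affine-invariance test makes explicit.

For the leave-one-out score, the landscape for viewer *p* omits *p*'s own
gaze; the raw score is the landscape sampled at *p*'s position, and the
z-score standardizes it with constants pooled over the whole video. For
cross-condition scoring, the full reference landscape is used (the scored
gaze does not belong to it, so nothing is sampled twice) with the
reference's own constants; identical conditions therefore produce raw
values that exceed the reference's leave-one-out raws by exactly the
viewer's own kernel contribution (between 1 and the window size), and
co-fluctuating z time-courses. The shuffled baseline permutes each
reference viewer's valid positions uniformly over their own valid frames
and scores the result against the unshuffled landscape.

### Normalization population

What population the constants are pooled over is ambiguous in this family of
metrics, and it changes the scale and interpretation of z. Both options are
implemented and recorded in every result:

* `normalization_population="grid"` (default): landscape values on a regular
  pixel grid (default stride 8 px, cell centres) across all scored
  (viewer, frame) pairs. z then measures elevation above the average
  landscape level anywhere on the screen; its pooled mean grows with how
  tightly the group clusters, which is what makes mean z a usable synchrony
  summary (it decreases monotonically in the synthetic dispersion dial).
* `"samples"`: the sampled values themselves. z is then exactly centred
  (pooled mean 0, population SD) and measures synchrony *relative to the
  video's own average moment*; group means near zero, as typically reported
  for this metric, correspond to this convention.

The grid stride perturbs the grid-pooled constants slightly; it is a speed
knob, not a scientific parameter, and results record it. Degeneracy is
flagged when the normalization population has zero SD (e.g., every viewer
frozen on one point under sample pooling); flagged results carry NaN z
values rather than silent zeros.

### Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `kernel_sd_deg` | 1.2° | kernel SD, ≈ foveal radius |
| `window_ms` | 225 ms | temporal window, ≈ one average fixation |
| `grid_stride_px` | 8 px | grid resolution for grid-pooled constants |
| `normalization_population` | `"grid"` | see above |
| `truncate_sd` | `None` | optional kernel cutoff in SDs |

The window is centred on the scored frame and slides per frame, so every
frame gets a value; at 30 fps and 225 ms it spans 7 frames (midpoint-to-
midpoint distance ≤ 112.5 ms). Kernel evaluation is exact by default:
vectorized evaluation makes a distance cutoff unnecessary, and exactness is
what allows the implementation to agree with an independent brute-force
oracle to 1e-9 on small instances. A `truncate_sd` cutoff (e.g., 4 SD,
error < 3e-4 of a unit kernel) exists for very large cohorts.

Frames where a viewer has no valid gaze (no fixation sample in the frame,
blink, or off-screen) contribute nothing to any landscape and receive no z
value; per-shot means average over defined frames only.

## Frame resampling

Raw samples (e.g., 2000 Hz or the generator's 500 Hz) are reduced to one
position per viewer per video frame as the mean of the frame's
fixation-labelled, on-screen samples. Only fixations contribute: saccade
samples do not reflect where a viewer is attending, and the processing-load
measure already accounts for saccade time separately. The mean-of-in-frame-
fixation-samples rule is this package's choice (the reduction is rarely
reported in the literature) and is exposed via `position_events` /
`drop_offscreen`.

## Foveation probability

Frame *f* spans `[f, f+1)/fps` seconds and is foveated iff some fixation
overlaps the span with positive duration (any-overlap convention). This
convention — rather than, say, a time-fraction rule — is the one that
reproduces the hand-calculable examples exactly (.93 = 28/30 and .87 =
26/30 for the two viewers described in the README; a time-fraction rule
would give .90 for both). Zero-measure boundary touches are excluded, with
a 1e-7-frame tolerance absorbing float error in the ms-to-frame conversion.
Fixations spanning a cut contribute frames to both shots — the measure
exists precisely because assigning such fixations to one shot is arbitrary.
Mean fixation duration per shot attributes each fixation to the shot
containing its onset.

Monotonicity caveat: the flag set is monotone in the fixation *set*
(expanding fixations in place never unflags a frame), and foveation
probability correlates positively with mean fixation duration across
viewers. But lengthening fixations while holding saccade durations fixed
shifts later events, and a shifted saccade can newly cover an entire frame,
so strict pathwise monotonicity in fixation duration does not hold — a
property-test counterexample, not an implementation artifact.

## Heat maps

A frame's heat map sums circular Gaussians (default SD 2°; a half-width-at-
half-maximum reading is available via `radius_is_sd=False`) around each gaze
point and divides by the frame's maximum. Per-frame max-normalization means
maps are comparable across frames in shape only, not in total gaze mass —
adequate for the QC role they play; a global normalization would be needed
for cross-frame amplitude comparisons.

## Synthetic cohorts

The generator emulates the features of film-viewing gaze that the analyses
are sensitive to:

* alternating fixation/saccade event streams with no gaps or overlaps;
* lognormal fixation durations (right-skewed, standard for eye movements),
  median 250 ms (`fixation_log_mu = ln 250`, `fixation_log_sigma = 0.4`);
* constant 50 ms saccades — the value used in the hand-built reference
  examples, and long enough to occasionally cover an entire 30-fps frame so
  foveation probabilities fall realistically below 1;
* a per-shot attractor (centre of interest), static by default, optionally
  a time-parameterized path; fixation landings scatter isotropically around
  it with SD `synchrony_sigma_deg` (the synchrony dial, default 2°);
* post-cut response: gaze keeps tracking the previous shot's attractor for
  `post_cut_latency_ms` (default 333 ms ≈ ten frames; per-viewer Gaussian
  jitter, SD 50 ms), then re-fixates the screen centre before moving to the
  new attractor — reproducing the post-cut dip-then-rise in similarity;
* samples at 500 Hz with correct event labels, fully reproducible from one
  seed, recorded in the output metadata.

Fixation durations are a cohort-shared base sequence plus per-viewer
Gaussian timing jitter (SD 50 ms): the shared rhythm stands in for
scene-driven pacing and yields the useful degenerate case that all noise
terms at zero produce byte-identical viewers. Conditions meant to have
watched the *same* film should share `attractor_tracks`
(`sample_attractor_tracks` draws a reusable set).

What the generator does **not** emulate: image-computable saliency (the
attractors are abstract targets, not film pixels), blinks and tracker
dropout, smooth pursuit (moving attractors are fixated in steps, not
pursued), head-motion artifacts, and systematic centre bias beyond the
post-cut re-fixation. Passing tests on synthetic cohorts therefore
demonstrate that the metrics recover known synchrony structure under
controlled conditions; they say nothing about eye-tracker noise or
content-driven gaze on real film.

## Comprehension statistics

* **Chi-square**: uncorrected Pearson statistic (the convention that
  reproduces the published reference values this package tests against);
  Yates continuity correction behind a flag. Tables with a zero margin are
  rejected outright.
* **Small-cell guard**: refuses tables with any *observed* cell ≤ 5
  (threshold configurable); such tables are reported as not computable
  instead of yielding a fragile statistic. Observed rather than expected
  counts are used, matching the practice the guard encodes.
* **Cohen's kappa** via scikit-learn, with the convention κ = 1 (logged)
  when both coders are constant and identical, where the chance-agreement
  denominator vanishes.
* **Mixed ANOVA**: classic split-plot sums of squares — group, subjects
  within groups, within-factor, group × within interaction, residual — with
  the sequential partition that is exactly additive for complete within
  designs, including unequal group sizes. Partial eta-squared is
  SS_effect / (SS_effect + SS_error) with the effect's own error term. No
  sphericity correction is applied (uncorrected df are reported); the
  design is validated (each subject in one group, observed once per within
  level) and unbalanced-within data are rejected rather than imputed.
  Degenerate inputs: zero total variance yields NaN F with an explicit
  note; a zero error term under a positive effect yields an infinite-F
  sentinel. The implementation is cross-checked in the tests against both a
  sequential GLM projection oracle and pingouin.
* **Post-hoc t-tests**: pooled-variance two-sample t per group pair
  (Welch behind a flag), Bonferroni p_adj = min(1, p·m) over the family of
  comparisons performed, Cohen's d with pooled SD.

## Problem sizes

Unit and property tests run on compact instances chosen to keep the full
suite fast while exercising every code path: oracle-equivalence on ≤ 4
viewers × ≤ 5 frames with a 60-px grid; directional and monotonicity
properties on 6–8-viewer cohorts over 6 × 30-frame clips with a 24–32-px
grid, majority-voted over 5 seeds; ANOVA calibration on 2000 null
simulations of a 3 × 6 design with 8 subjects per group. Defaults for real
use (stride 8 px, full-length clips) are unchanged by any of this.

## Known limitations

* The similarity computation is O(viewers² × frames × window) for sampling
  plus O(viewers × frames × grid) for grid constants; hour-long videos with
  large cohorts will want the `truncate_sd` cutoff, a coarser grid, or the
  sample-pooled normalization (which skips the grid entirely).
* Event labels are taken as input; no fixation detection from raw samples
  is provided, and smooth pursuit must be coded upstream (if coded as
  fixation, it counts as foveating).
* The shuffled baseline preserves each viewer's marginal spatial repertoire
  but not fixation-duration autocorrelation; it is a generous chance level,
  not a full generative null.
* Heat-map normalization is per frame; cross-frame amplitude comparisons
  are out of scope.
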