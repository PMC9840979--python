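# Methods

## The assay and its model

A restrained (thorax-glued) fly cannot locomote but can move its legs,
wings and abdomen. Its behavior decomposes into two macroscopic states:
*flailing* — bursts of high motor activity interpreted as escape struggle —
and *immobility* — sustained quiescence. `strifkit` models an assay as an
alternating sequence of such bouts and recovers that sequence from video by
thresholding a per-fly motion-energy signal.

The operational definition of immobility is asymmetric: quiescence counts
as immobility only when it lasts at least `min_immobility` seconds
(default 5 s). Shorter quiescent runs are treated as pauses within
activity and absorbed. Activity has no minimum duration; a single
supra-threshold excursion can interrupt a long immobile stretch. Epochs at
the assay edges are kept and truncated rather than discarded, so total
active plus inactive time always equals the analyzed window exactly, and
active/inactive epoch counts differ by at most one.

## Synthetic ground truth

The generator (`synthvideo`) is first-class, tested code, not a fixture.
It emulates the acquisition geometry of the real assay: six dark fly-sized
disks on a light background, RGB (or grayscale) frames at 30 frames/s,
300 s assays, optional global illumination step ("flash") at a configured
frame, optional salt-and-pepper noise.

* **Bout durations** are drawn per state from a shifted exponential,
  `floor + Exponential(mean − floor)` with a 1 s floor, so durations are
  heavy-tailed, never sub-floor, and their expectation equals the requested
  mean exactly. The final bout is truncated at the assay end.
* **Motion** is rendered as integer-pixel jitter of the whole disk, uniform
  on `[−amplitude, +amplitude]` per axis per frame during active bouts; the
  disk sits exactly on its anchor during quiescence, so a noiseless
  quiescent scene is bit-static. The amplitude of real flailing has no
  empirical pixel scale; it is a free parameter (default 3 px against a
  6 px body radius).
* **Noise** corrupts exactly `round(fraction · n_pixels)` pixels per frame
  to black or white (half each, odd counts favouring white).
* **Flash** adds a constant shift to the red channel of all frames from the
  flash index onward.

What the generator does *not* emulate: body-part articulation (legs and
wings move independently of the body in real footage, whereas a rigid disk
translates), illumination gradients and flicker, compression artifacts,
occlusion or glue-failure escapes, and sub-behaviors such as grooming or
wing flapping. Passing the recovery tests therefore demonstrates that the
segmentation logic and noise handling are correct at realistic
signal-to-noise ratios, not that the defaults are tuned for any particular
camera.

Ground-truth scoring (`compare_to_program`) first applies the immobility
rule to the program itself: generated quiescent bouts shorter than 5 s are
not recoverable as immobility *by definition of the assay*, so the target
of recovery is the program's ideal segmentation, not its raw bout list.

## Detection and motion

Detection runs on the first frame only and ROIs stay fixed: the flies are
glued, so there are no trajectories to track, and a fixed ROI removes
identity ambiguity. The pipeline is standard: luma grayscale, Otsu
threshold (dark-fly polarity by default), morphological opening/closing
with a disk of radius 1, 8-connected components, area filter. Fly
identifiers follow arena raster order; centroids are grouped into row
bands (gap > median blob height) before sorting by column so a few pixels
of first-frame jitter cannot swap neighbours. The analysis ROI is grown by
`roi_pad` (default 4 px) on each side so jitter excursions stay inside.

Motion is the mean absolute grayscale difference between consecutive
frames within the ROI, per pixel, so ROI size does not bias between flies.
Two denoising stages target impulse (salt-and-pepper) noise:

1. **Image level** — a per-pixel temporal median-of-three across frames.
   A corrupted pixel is almost never corrupted in two consecutive frames,
   so this removes virtually all impulse noise while leaving sustained
   intensity changes (real motion, flash steps) intact. It is fully
   vectorised and costs one pass over the stack.
2. **Trace level** — a temporal median filter (window 5 frames) followed
   by a minimum-difference floor that zeroes sub-threshold values.

The floor is data-driven: the 99th percentile of the median-filtered
background trace, **rescaled by `n_background_pixels / n_roi_pixels`**.
The rescaling is essential for impulse noise: one surviving corrupted
pixel shifts a region's mean difference in inverse proportion to the
region's area, so a floor measured on the large background region must be
amplified before being applied to a small ROI. Without it, rare paired
corruptions fragment quiescent runs and destroy segmentation; with it, the
denoised trace of a static fly under 1% noise is identically zero. The
activity threshold for segmentation then defaults to the 99th percentile
of the (already floored, hence almost surely zero) background — in
practice "any nonzero denoised motion is activity". Genuine motion at the
default geometry is two orders of magnitude above the floor; extremely
low-contrast or sub-pixel motion below the floor would be classified as
quiescence, a documented limitation.

STRIF-speed averages stride-2 frame differences over active epochs
(configurable to the whole assay). Stride-2 differencing is blind to
strictly period-2 motion — frames t and t−2 are identical while
consecutive frames differ — an aliasing consequence of the definition that
is surfaced by a dedicated test rather than hidden.

Flash onset is the first frame whose background channel mean steps by more
than max(5 × rolling SD of the preceding 15 frames, 5 intensity units);
the absolute floor guards against zero variance on clean footage. Trace
samples within one median window of the flash are zeroed before
segmentation: the global jump is illumination, not fly motion. A flash
already on at frame 0 is undetectable by differencing and reported as
absent.

## Statistics

* Glass Δ divides the mean difference (experiment − control) by the control
  SD; Cohen's *d* by the pooled SD (n−1 weights). Paired *d* standardizes
  by the SD of within-pair differences by default (an average-SD
  standardizer is exposed as an option). Magnitudes use the conventional
  0.2 / 0.5 / 0.8 cuts.
* The BCa bootstrap computes the bias correction from the fraction of the
  bootstrap distribution below the point estimate and the acceleration
  from jackknife skewness; two-sample intervals resample groups
  independently and jackknife the concatenation. Degenerate bootstrap
  distributions fall back to the percentile interval with a warning; an
  all-equal sample yields a zero-width interval. Default 5000 resamples.
* The permutation test uses the mean difference as statistic (for
  equal-size label permutation this orders arrangements identically to the
  t statistic). Arrangements are enumerated exhaustively when their count
  is ≤ 20,000 (label splits, or sign flips for paired data); otherwise
  random arrangements are drawn with the identity arrangement counted in
  numerator and denominator, so p > 0 and the test is exact-level
  conservative.
* Power of the two-sided two-sample t-test is computed from the noncentral
  t with noncentrality d·√(n/2) and 2n − 2 df, reading "n" as per-group
  size (the paired and total-n readings would give different, larger
  powers for the same n; the per-group unpaired reading is the
  conservative one).
* Delta regression is ordinary least squares on per-manipulation (x, y)
  effect pairs, reporting slope, adjusted R² = 1 − (1 − R²)(n − 1)/(n − 2)
  and the two-sided slope p from the t distribution.
* No multiple-testing correction is applied by default across contrast
  grids; this mirrors common practice in single-experiment estimation
  plots but is a caveat, and Benjamini–Hochberg adjustment is provided.

All resampling is seeded and recorded in outputs; identical config + seed
reproduce byte-identical CSVs.

## Numerical and design choices

* Grayscale uses BT.601 luma weights; frame stacks are uint8 end to end
  with int16 differencing to avoid overflow, chunked over time to bound
  memory.
* Median filtering at trace edges uses nearest-extension (shrunken-window
  behaviour); the temporal median-of-three copies the first and last
  frames.
* ROI clipping at frame edges slides the square inside the frame where
  possible and only then shrinks it, flagging the detection.
* The ethogram's time base is the difference series: an N-frame video
  spans (N − 1)/fps seconds, so a 9000-frame, 30 fps assay yields a
  299.97 s ethogram; ground-truth comparisons account for the one-frame
  difference.
* A fully quiescent assay is one inactive epoch regardless of length (the
  merge rule needs an active neighbour to absorb into); a fully active
  window flags the activity:inactivity ratio as undefined rather than
  reporting infinity.
* Walking trajectories use the same segmentation with a speed threshold
  (default 0.5 mm/s) on centroid displacement × fps; gaps over 1 s are an
  error unless linear interpolation is enabled.

## Problem sizes used in validation

The recovery suite validates segmentation on one hundred 300 s, 30 fps,
six-fly renders at 160×120 resolution with 1% salt-and-pepper noise and
mixed bout-duration programs (means 10–30 s active, 8–20 s inactive,
amplitudes 2–4 px) — the full assay duration and fly count at a reduced
frame size chosen so a batch run stays cheap on a single CPU. Statistical
calibration uses 2000 null replications (type-I error at n = 20 per
group), 1000 replications of BCa coverage at n = 50, and 1000-replication
effect-size recovery at n = 45 per group. The acceptance script runs a
20-video recovery batch and a six-arena simulated silencing experiment at
120 s per video; its results are stable across seeds.

## Known limitations

* Rigid-disk motion is a crude surrogate for articulated flailing; motion
  energy magnitudes are not calibrated to real footage.
* Fixed ROIs assume glued flies; a detached fly walks out of its ROI and
  surfaces only as an anomalous trace, not as a tracked trajectory.
* The minimum-difference floor targets impulse noise; Gaussian sensor
  noise of comparable magnitude would require a different (variance-based)
  floor.
* Flash detection assumes an abrupt global step; gradual ramps would be
  missed.
* Exact permutation enumeration is capped at 20,000 arrangements; beyond
  that, p-values carry Monte-Carlo error of order 1/√n_perm.
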