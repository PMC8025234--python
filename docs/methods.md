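# Methods

This note records the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical choices that matter when reproducing results.

## Synthetic data model

Every generator emits the data plus a ground-truth table (one row per
object) and a JSON echo of the generating spec, so any downstream claim can
be audited. Identical seeds give bit-identical output; all randomness flows
through one `numpy` generator per call.

**Puncta fields.** Spots are rendered as analytic 2-D Gaussians evaluated
at pixel centers, not as disks convolved with a PSF. The point of that
choice is exact truth: a spot of amplitude A and width σ (px) has noiseless
integrated intensity A·2πσ², so intensity-conservation checks have a closed
form. Defaults emulate a confocal acquisition of immunostained tissue:
0.1 µm/px, σ = 2 px, background 10 AU, amplitudes 80–120 AU. Noise is shot
noise (Poisson on signal/`poisson_scale`, rescaled) plus additive Gaussian
read noise; the defaults (`poisson_scale` = 1, `gaussian_sd` = 18 AU) put
the peak SNR near 5 — low enough that detection is non-trivial, high
enough that a tuned detector should find essentially all spots. No
acquisition SNR is reported for the emulated instruments, so this is a
package choice, made once. Spot placement is rejection sampling with a
minimum center separation and bounded retries; an infeasible density raises
rather than silently under-filling. Spots whose center lies within 3σ of
the border are flagged `clipped` in the truth (their rendered mass is
truncated).

**Two-channel fields** support two modes: `shared_fraction` (that fraction
of spots appears at identical centroids in both channels, amplitudes drawn
independently; the rest are channel-exclusive, still respecting the
separation constraint across channels) and `center_offset` (every pair is
displaced by exactly the requested offset along a fixed direction). The
first mode calibrates colocalization statistics, the second the
segregation-distance measurements.

**Transport movies** render particles as Gaussians positioned along a 1-D
path coordinate embedded in 2-D frames — the same reduction a kymograph
performs — with per-particle constant velocity (signed; positive =
anterograde, path vertex 0 = proximal), optional per-frame pausing, and a
Bernoulli cotransport flag per particle so realized co-fractions are
binomial. Defaults: 100 nm pixels, 1 s frames, 40 frames, a 61 µm straight
path — long enough that the fastest default cargo (1.2 µm/s) never reaches
the path end. A particle that does hit an end is clamped there and flagged
`truncated` in the truth, since its net-displacement speed is no longer the
drawn one.

**EM sections** are non-overlapping rotated ellipses drawn into an integer
label image; the truth records the drawn axes (default long diameter
~72 nm, elongation ~1.8, matching tubule-shaped immature precursor
profiles). A separate generator builds the stereology oracle: equal spheres
rejection-packed into a box periodic along z, sectioned by random
horizontal planes, so the expected areal fraction of a section equals the
volume fraction exactly (Delesse) with no edge bias.

**Evoked traces** are sums of difference-of-exponentials transients
`A·norm·(exp(−t/τ_d) − exp(−t/τ_r))` with `norm` fixing the continuous-time
peak at exactly A, plus Gaussian noise. Defaults: 10 kHz sampling, A =
−75 nA (inward negative), τ_r = 0.5 ms, τ_d = 5.5 ms.

What the generators deliberately do **not** model: 3-D PSF anisotropy,
photobleaching, stage drift beyond rigid translation, autofluorescence
texture, vesicle shapes beyond ellipses, and stimulus artifacts. Passing
tests therefore demonstrate correctness of the measurement chain under the
stated image-formation model, not robustness to every pathology of real
data.

## Puncta detection

Pipeline order is fixed: restrict to ROI → background subtraction →
threshold on the original (pre-blur) intensities → Gaussian blur σ = 0.5 px
→ local maxima inside the mask → marker-seeded watershed → statistics on
the pre-blur, background-subtracted intensities. The blur exists for
segmentation only; projecting the binary mask back onto the unmodified
image (a per-pixel min) is what makes integrated densities comparable
across parameter settings.

- *Background subtraction*: rolling ball (radius 50 px) by default, the
  de-facto standard of the source software; a percentile subtraction is
  available and is what the fast tests use.
- *Threshold*: a manual value is the primary interface (batch-reproducible);
  Otsu inside the ROI is the clearly-labeled automatic fallback.
- *Maxima*: "prominence" is implemented as the h-maxima transform —
  a regional maximum survives iff its dynamics (height above the saddle
  where its basin merges into a higher peak's) reach the configured value.
  Marker plateaus use full (8-)connectivity to match the transform. The
  test suite checks this against an exhaustive union-find computation of
  dynamics on small images. Default prominence 40 AU ≈ 2× the read-noise
  SD after accounting for blur; with the default generator it neither
  splits noise wiggles nor merges spots 4σ apart.
- *Watershed* on the negated blurred image, constrained to the threshold
  mask, partitions touching spots; fragments below `min_particle_area`
  (default 5 px², 9 px² in the SNR-5 benchmarks) are discarded.

Intensity conservation holds to <1 % only when the threshold is a small
fraction of spot amplitude (the mask misses mass ≈ thr/A per spot); the
conservation benchmark therefore thresholds a noiseless field at 0.5 AU.

## Colocalization

Qualifying pixels use the OR rule (either channel above its threshold).
The OR selection has a known statistical consequence: for *independent*
channels it preferentially admits pixels bright in exactly one channel and
therefore produces a systematically negative r — the same behavior visible
in mirrored-channel chance controls, which come out slightly negative
rather than zero. The unbiased null (|r| ≤ 0.05 on independent fields) is
recovered when the thresholds sit below the data minimum so every ROI pixel
qualifies; the calibration benchmark does exactly that, while the sweep
benchmark (mean r monotone in the generated shared fraction) runs with the
default Otsu thresholds. The AND rule is available (`qualify="and"`) but
inflates r for partially shared fields. The flip control mirrors the second
channel left–right within the ROI bounding box; mirrored pixels falling
outside the ROI are excluded from the correlation.

## Distances

Line profiles are sampled by bilinear interpolation at 1 px arc-length
steps, averaged over `width` perpendicular offsets. Peak positions are
refined by parabolic interpolation of the three samples around a maximum,
which is what lets a 0.4 µm offset land in the [0.36, 0.42) histogram bin
rather than smearing across pixel-quantized values. Channel-2 peaks must
clear both a relative prominence (10 % of the profile's range) and an
absolute height floor (median + 5·MAD of the whole image by default):
without the floor, noise wiggles near the channel-1 peak masquerade as
"nearest peaks" and collapse the shifted-null distribution. The null shifts
channel 2 circularly (wrap-around) by 80 px; wrapping preserves the pixel
population so data and null histograms are built from the same intensity
distribution. Whether the emulated procedure wrapped or cropped is not
documented anywhere; wrap is this package's choice. Histogram frequencies
are percentages of retained (≤ cutoff) distances and sum to 100 per column.

Center-of-mass distances use intensity-weighted centroids (not binary
centroids) over each channel's thresholded ROI, matching the named
measurement function of the source software.

## Transport

Kymographs: per frame, percentile background subtraction, σ = 0.5 px blur,
then the path profile becomes one row; row t always corresponds to frame t.
Streak detection thresholds the kymograph at median + 4·MAD, links blobs
across consecutive rows within a horizontal reach corresponding to
1.5 µm/s (a fast cargo moves several columns per frame and would otherwise
disconnect), labels components, and reduces each to per-frame
intensity-weighted centroid positions. A component is a track iff:

- unidirectional: at most 10 % of frame-to-frame steps oppose the net
  direction, counting only steps larger than one position step — sub-pixel
  centroid jitter and pauses are not reversals;
- spatial extent ≥ 4 µm and temporal extent ≥ 30 s, both inclusive and
  compared with half a position-step / half a frame-interval of slack so a
  particle traveling exactly 4.0 µm for exactly 30.0 s is accepted despite
  pixel quantization.

Speed is net path length / duration; anterograde means increasing path
coordinate (path files list the proximal end first). Cotransport samples
the second channel's kymograph in a ±2 px band along the track's space-time
line; ≥ 3 distinct positive frames (the weaker of the stated 3-or-4
criteria, configurable) flag the track co-positive. Registration
(translation by phase correlation against frame 0) is provided for jittery
in vivo movies; it is off by default because movies whose only features
are the moving cargoes give phase correlation nothing stationary to lock
onto.

## Morphometry

Diameters come from the moment-equivalent ellipse (second central moments)
per label, robust to pixelation; a maximal-Feret alternative exists.
Elongation is defined long/short ≥ 1. (The emulated study's figure label
reads short/long, but its printed means — ~41 nm short, ~72 nm long, ratio
~1.8 — are only consistent with long/short; this package standardizes on
the internally consistent definition.) Volume fraction is exhaustive areal
measurement, not point counting, since label images make that exact. 3-D
surface area uses marching cubes on the binary label smoothed with a
σ = 1 voxel Gaussian (isosurface at 0.5): raw binary isosurfaces
overestimate a sphere's area by ~9 % (staircase effect), the smoothed
version is accurate to well under 1 % at r = 30 voxels. Volume remains the
raw voxel count × voxel volume. Labels touching the volume border are
flagged `clipped`. T-bar roof/pedestal lines and area polygons are
user-supplied annotations; both lines are plain polylines because how
"pedestal height" was oriented in the source material is unstated.

## Evoked-current metrics

Baseline is the mean of a pre-stimulus window; the response gate requires a
~1 ms-smoothed deflection beyond 3× the baseline SD (the raw per-sample
maximum of a thousand noise samples crosses 3 SD routinely, so the gate is
applied to the smoothed trace). A 0.5 ms post-stimulus blanking window
excludes the stimulation artifact region from the peak search — and must
stay shorter than the time-to-peak, which is ~1.3 ms at the default
kinetics. Decay τ is a least-squares mono-exponential fit ending at 10 % of
peak recovery (capped at the integration window, so a second stimulus never
enters the fit) and starting two rise-times past the peak: immediately at
the peak the not-yet-vanished rising exponential biases a single-exponential
fit of the difference-of-exponentials response by ~3 %; skipping two rise
times brings recovery of τ = 5.5 ms within 0.5 %. The start of the fit
window is configurable back to the peak itself. The paired-pulse A₂ is
corrected by extrapolating the first response's fitted decay to the second
peak's time (alternative: subtract the pre-pulse-2 current); ratios are
reported on magnitudes, amplitudes signed (inward negative).

## Statistics

Routing is a pure function of (per-group n, per-group normality, number of
groups). The D'Agostino–Pearson omnibus test needs ≥ 8 samples; smaller
groups are assumed normal, and the cutoff is exposed because the emulated
methods text states it inconsistently ("n > 7" in one place, "n < 7" in
another — n < 8 ⇒ assume normal is the reading implemented). One
non-normal group routes the whole comparison nonparametric. Tukey's post
hoc comes from statsmodels; Dunn's post hoc (rank-based z statistics with
tie correction, Bonferroni-adjusted) is implemented here because no
installed package provides it. The routed two-group test holds its nominal
type-I error on normal data (checked by simulation against the exact
binomial interval).

## Problem sizes

The benchmarks run at the sizes their statements prescribe: 200 spots for
count recovery, 30 pairs per offset for center distances, 50 particles /
40 cotransport movies (one particle per movie, matching how single events
are cropped and traced in practice), 100 random sections for stereology,
1000 replicates for the type-I simulation. The full benchmark sweep
completes in ~25 s on one CPU.

## Known limitations

- Detection assumes approximately Gaussian, roughly isotropic puncta;
  elongated structures will be split by the watershed.
- Kymograph analysis handles one dominant trajectory per component;
  crossing streaks merge and are rejected by the unidirectionality gate
  rather than disentangled.
- The Pearson OR-rule null bias is inherent to thresholded correlation and
  documented above rather than "corrected".
- The minimal Feret diameter is approximated by the moment-ellipse minor
  axis when the Feret mode is selected.
- Percent-of-control propagates no uncertainty from the control mean.
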