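# Methods

This note documents the models, estimators, numerical choices and known
limitations of the pipeline. Units: lengths in µm (pixels where stated),
times in ms, intensities in detector digital numbers (DN) or normalized
ΔF/F₀.

## Acquisition model and configuration

The pipeline targets dual-channel x-y-t recordings of single ventricular
cardiomyocytes: a calcium-indicator channel (the quantitative channel) and a
membrane-stain channel, acquired simultaneously at high frame rate with
field stimulation whose synchronization pulse train is recorded alongside.
`AnalysisConfig` defaults encode the reference instrument: 395 fps
(frame period 2.532 ms), 44× magnification of 6.5 µm camera pixels
(0.1477 µm sample pixels; the constructor enforces consistency of the three
constants to 1e-4), 0.5 Hz pacing with 2 ms pulses. Stimulus pulses are
shorter than a frame period, so pacing edge times are kept in milliseconds
at the trace's native sampling and floor-converted to frame indices only
where an operation needs one.

All intensities are processed as floating point regardless of input bit
depth. Ventricle labels ("A"/"B") are opaque metadata; unblinding is a
metadata join, never pipeline logic.

## Pre-processing

**Co-registration.** The two spectral channels differ by a fixed instrument
magnification ratio (0.9× for the reference instrument, 1.0 for phantoms)
plus a translation. The membrane channel is rescaled by the inverse ratio
(bilinear, about the image centre) and shifted by the integer-pixel offset
that maximizes the normalized cross-correlation of the two temporal-mean
images (phase correlation). The calcium channel is never resampled, so
ΔF/F₀ fidelity is preserved. A correlation peak below a configurable floor
(default 0.1) leaves the channels untransformed with a warning. Registration
is integer-pixel by design; sub-pixel and non-rigid registration are out of
scope.

**Background.** Per-frame scalar background: the median intensity outside a
dilated provisional cell region, subtracted and clipped at zero. A frame
with no extracellular pixels falls back to the global 1st percentile. The
estimator tracks temporal drift (it is per-frame) and is idempotent to
within 1 DN.

**Cell segmentation.** Threshold of the temporal-mean calcium image,
followed by morphological closing (disk radius ≈ 0.5 µm), hole filling, and
retention of the largest connected component. The threshold is Otsu refined
by Ridler–Calvard (isodata) iteration: on low-noise images both intensity
clusters are much tighter than their separation, every threshold in the gap
scores the same binned between-class variance, and raw Otsu returns the
plateau's lowest bin (inside the background cluster); the isodata fixed
point — the midpoint of the class means — is well defined regardless.
Segmentation is invariant to global intensity scaling.

## Structure

**Tubule mask.** Computed in image space with no orientation prior
(deliberately not a Fourier-domain method, which privileges transverse or
longitudinal elements): white top-hat of the temporal-mean membrane image
with a disk element of radius 2× the nominal tubule width (default 0.3 µm,
i.e. a 4 px radius at 0.1477 µm/px — wide enough that detected ridges
broader than the anatomical ~0.25 µm tubule are preserved), then Otsu
thresholding restricted to the cell mask. An empty tubule mask is permitted
(warning); the whole cell is then detubulated.

**Tubule period.** Mean of consecutive peak-to-peak gaps along a line
profile (sampled at one-pixel steps, bilinear interpolation, peaks by
prominence). Fewer than two peaks is an undefined-period error.

**Nuclei.** Filled polygons from manually drawn outlines (JSON polygon
list), clipped to the cell mask; polygons entirely outside the cell are
dropped with a warning. Zero nuclei is a valid state.

**DNT.** Exact Euclidean distance transform of the tubule mask, in pixels,
computed on the full frame and interpreted inside the cell. Categories:
epitubular (DNT = 0), paratubular (0 < DNT ≤ 5 px), detubulated (DNT > 5 px);
the 5 px bound is stored in pixels with the µm equivalent (0.74 µm) derived
from the pixel size. The implementation is tested for exact equality with a
brute-force min-over-all-tubule-pixels oracle. `mean_random_dnt` — the mean
DNT over all cell pixels — is the null reference against which spark
centre-of-mass DNT is compared.

## Spark detection

Performed on the unpaced segment (by default the last 5 × 1000-frame blocks;
both block length and count are configurable, and the test suite uses
500-frame blocks on shorter phantoms to stay desk-scale — the methods are
identical at any block size that keeps single events a small fraction of a
block).

1. **Smoothing**: normalized box kernel, 5 × 5 spatial × 3 temporal. A box
   kernel is the simplest reading of an unqualified "smoothing kernel" of
   that size; it sums to one, so event mass is conserved.
2. **Normalization**: each block's per-pixel temporal mean F₀ divides the
   smoothed data; the working signal is ΔF/F₀ = F/F₀ − 1. Detection is
   therefore invariant to any positive gain applied to the raw data.
3. **Thresholds**: per pixel and per block, T_L = µ + 2.9 σ and
   T_H = µ + 5.4 σ, where µ and σ are the mean and SD of ΔF/F₀ across the
   block. Candidate events are connected components above T_L containing at
   least one voxel above T_H (hysteresis). Connectivity is face-adjacent
   (6-neighbour) in x-y-t; "minimum 6-pixel connectivity" is ambiguous
   between a 6-neighbourhood and a 6-voxel minimum size, so the
   6-neighbourhood is the default and the size reading is subsumed by the
   area/duration filters; vertex connectivity is selectable in config.
4. **Two passes**: pass-1 events bias µ, σ and F₀, so their voxels are
   masked, F₀ is re-estimated per pixel over the first 100 frames of each
   block excluding masked voxels (pixels fully masked there fall back to the
   block mean), µ and σ are recomputed excluding masked voxels, and
   detection repeats. Pixels with σ = 0 (possible in noiseless synthetic
   data) receive a machine-epsilon floor and cannot seed events.
5. **Blocks are hard boundaries**: a spark spanning two blocks yields a
   component in each; components touching a block's temporal edge are
   flagged `boundary-truncated`. Such events are retained (their part
   containing the peak is a valid detection) but flagged so duration/mass
   statistics can exclude them.

**Characterization.** The x-y-t component collapses along time to a 2D
footprint (area in px and µm²). The temporal profile is the footprint-mean
of F/F₀ per frame within the block; its baseline is the footprint-mean of
1 + µ. F50 = baseline + half of the profile's peak above baseline. FDHM is
the time between the first and last frames at or above F50 around the peak
(with this convention the widening from temporal smoothing and the discrete
sampling bias approximately cancel; recovery is within one frame period for
triangular test events). A profile still at or above F50 at the block end is
flagged `unfinished`. **Amplitude** is (peak − baseline)/baseline with the
peak taken at the event's brightest voxel: the footprint-mean would dilute a
Gaussian event by the ratio of its core to its threshold contour (~5× at
these thresholds), whereas the peak-voxel estimate recovers injected
amplitudes to within the smoothing attenuation. That attenuation — spatial
box on a 2 µm FWHM Gaussian plus temporal box on a ~30 ms event — is about
12% and is the dominant, documented bias of the amplitude estimator (bound:
15%). **COM** is the ΔF/F₀-weighted centroid of the footprint at the peak
frame (integrating over all frames accumulates clipped noise and biases the
centroid). **FWHM** in x and y counts the contiguous run of pixels at or
above the per-line F50 along the row/column through the COM at the peak
frame (per-line F50 keeps the measurement local; counting non-contiguous
pixels would inflate widths with distant noise). **Mass** =
amplitude × mean(FWHM_x, FWHM_y) × FDHM, an exact identity on every emitted
event.

**Filtering.** Area < 50 px rejected (strict-below; 50 px is kept), on-time
< 4 frames rejected, unfinished events rejected. The 50 px count is treated
as authoritative (at 0.1477 µm pixels it equals 1.09 µm²).

**Rates.** Per DNT category: n / (category area / 100 µm²) / duration.
A zero-area category has an undefined (missing) rate, not zero.

## Transient T50

The paced part of the recording is smoothed with a 5 × 5 spatial median and
a 3-frame centred moving average. Cell-average peaks are found with a
minimum separation of 95% of a pacing period and a prominence floor of 25%
of the trace range; the first three consecutive peaks whose 525-frame
windows fit the recording and contain a preceding pacing edge are selected.
Per window: baseline map = mean of the 50 frames up to the edge; peak map =
mean of 20 frames from the cell-average peak frame; F50 = (baseline +
peak)/2. The crossing is searched on the rising limb between the stimulus
edge and the cell-average peak frame; the first frame at or above F50 is
linearly interpolated against the previous frame, and T50 is the crossing
time minus the edge time. Pixels with peak ≤ baseline or no bracketed
crossing are undefined. Using the 20-frame peak average slightly lowers F50
relative to the instantaneous peak; the closed-form oracle (below) accepts
the same convention so validation compares like with like.

Aggregation over the three transients is the pixel-wise mean and sample SD
where all per-transient maps are defined. Regional summaries assume an
approximately horizontal cell: cell length is taken from the first and last
columns with defined T50, the central ROI spans the middle half, the two
outer quarters are pooled, and nuclear pixels are excluded from the
central/outer and exonuclear populations. The dyssynchrony index is the IQR
of the per-pixel T50 distribution. T50-vs-DNT correlation is ordinary least
squares of T50 (ms) on DNT (px) separately for tubulated (DNT ≤ 5 px) and
detubulated (DNT > 5 px) pixels, with the slope's 95% CI from its standard
error and the t distribution; classes with < 3 pixels or degenerate DNT are
omitted.

## Statistical routing

Each sample is tested with D'Agostino–Pearson at α = 0.05 (the paper-style
significance level is reused for the routing tests, which the source leaves
unspecified). Both normal → t-test (paired PT; unpaired UT, or UTWC when a
two-sided F-test finds unequal variances). Otherwise, if all values are
positive and both log-transformed samples pass, the t-tests run on logs.
Otherwise Mann–Whitney (unpaired) or Wilcoxon signed-rank (paired, zeros
dropped; identical paired samples report p = 1 by convention). Samples below
n = 8 cannot be normality-tested (the test needs that many observations) and
take the nonparametric route with a warning. The route taken is recorded in
every result. Null calibration (uniform p under the null) is asserted in the
test suite for both the router and the per-heart aggregation.

Per-heart aggregation averages cell values within heart, excludes hearts
with fewer than two cells, and applies a one-sample t-test to the heart
means; fewer than two qualifying hearts yields an "underpowered" result with
no p-value. The imaging-time-window filter scans candidate window starts
(every observed time) and keeps the window maximizing the smaller group's
count, tie-broken by total cells then earliest start; an explicit start
overrides the scan. Multilevel models and multiple-testing correction are
out of scope.

## Synthetic phantoms

The generator emulates the preparation end-to-end: an elliptical cell
(default 34 × 14 µm in a 256 × 128 px field at 0.1477 µm/px — reduced from
the instrument's full field so the default phantom renders in seconds;
every length is configurable) with transverse tubule stripes at 2.0 µm
period. The rendered stripe width (0.65 µm) is the mask-equivalent width of
a *detected* tubule, which is broader than the ~0.25 µm anatomical tubule;
this puts default coverage near 30%, in the range reported for healthy
cells. Zero to two nuclei (tubule-free ellipses) and seeded circular
detubulated patches complete the structure. Truth DNT uses the package's own
oracle-verified transform.

**Transients**: ΔF/F₀(t) = A·(1 − e^−t/τr)·e^−t/τd after a per-pixel onset
delay (defaults τr = 15 ms, τd = 200 ms, A = 1.5). The delay field is a
uniform base latency (5 ms) plus optional nuclear extra delay, central-half
extra delay (the ends lead), and a DNT-proportional term (optionally
confined to detubulated regions). The product form is a deliberately simple
synthetic stand-in with closed-form structure: the peak time is
τr·ln(1 + τd/τr), and `analytic_half_rise_ms` solves for the half-rise by
bisection to 1e-6 ms, optionally averaging the peak over the pipeline's
20-frame window. Pipeline T50 on noiseless phantoms agrees with this oracle
to well under half a frame period.

**Sparks**: counts are Poisson per DNT category (rate × category area ×
duration), placed uniformly within the category; morphology draws truncated
normals around amplitude 0.6, FWHM 2.0 µm, FDHM 27 ms — the scale reported
for rat ventricular sparks. Each event renders as an isotropic spatial
Gaussian times an asymmetric triangle whose base is 2 × FDHM (time above
half maximum of any triangle is half its base, so the nominal FDHM is exact).
Sparks multiply the baseline, so they vanish outside the cell; the truth
table therefore records the brightness centroid of the clipped Gaussian
(what a detector can recover), alongside the placement pixel. Events whose
time course crosses the movie end are flagged truncated.

**Noise**: Gaussian read noise, default SD 30 DN against a 1000 DN cell
baseline — the shot-noise-equivalent level for such a signal — with optional
true Poisson noise. **Pacing**: a top-hat train at 0.5 Hz (2 ms pulses,
10 kHz sampling), optionally covering only the first fraction of the movie
to mimic the stimulate-then-rest protocol.

Everything is deterministic given the seed (bit-identical movies and truth
tables; the render uses an RNG stream independent of the structure draws).

### What the phantoms do and do not establish

Phantom tests validate the estimators against known truth: segmentation and
tubule Dice, exact DNT, spark recall/precision ≥ 0.9 at paper-plausible
morphology (matched within 2 px / 2 frames), amplitude bias within the
documented attenuation, T50 against the closed-form oracle, regional-delta
recovery within ±0.3 ms, and slope-contrast direction. They do not emulate
optical sectioning physics, photobleaching, motion, out-of-focus events,
spatially structured noise, or spark time courses beyond the separable
form — so passing tests demonstrate correctness of the measurement chain,
not robustness to every property of real recordings. Two further documented
detector limitations: concurrent events closer than the sum of their
sub-threshold footprints merge into one component (test phantoms keep the
areal event density near the sparse regime reported in vivo, where such
collisions are rare), and re-firings of one site within a spark's base
duration are read as a single event.

## Problem sizes in the validation suite

Spark-recovery phantoms: 96 × 192 px, 2000 frames in 4 × 500-frame blocks,
~6 events each, 20 seeds pooled. Transient phantoms: 80 × 160 px, 2700
frames (three usable 0.5 Hz transients at 395 fps). The acceptance script
uses 8 spark phantoms plus one structural, one regional, one noiseless and
one slope phantom, and 200 null draws for the router calibration.
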