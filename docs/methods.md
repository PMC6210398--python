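# Methods

This note documents the models, estimators and numerical choices behind
`boundless`, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the design was genuinely
open.

## Design and data model

The analysis targets a graded-state design: each recording block holds
three one-minute conditions in fixed order (SB1 → SB2 → SB3) followed by
one minute of rest.  The fixed order is a property of the design (the
states cannot be produced in random order), and two consequences run
through the statistics: permutation nulls respect the block structure,
and a presentation-order control exists to probe temporal drift.

Coordinates are head-frame meters with the origin at the conductor
sphere's centre.  Recordings travel as FIF with a TSV schedule
(onset/duration/label); statistical volumes are exported as RAS NIfTI
with a millimetre diagonal affine; simulation ground truth as JSON.

## Forward model

The magnetic field of a current dipole inside a homogeneous conducting
sphere has the closed Sarvas form; the field is independent of sphere
radius and conductivity, and a radially oriented dipole is silent.
Sensors are point magnetometers: the reading is the projection of B on
the sensor orientation.  This replaces a realistic single-shell
conductor: no head-shape data exists for the synthetic setting, and the
sphere preserves every property the statistics depend on (linearity,
radial silence, distance decay).  The test suite checks the
implementation against an independent numerical oracle — point-dipole
Biot–Savart plus the Geselowitz surface integral of the classic
Legendre-series surface potential — and agreement is better than 1%
(in practice ~1e-6 relative).

The source space is a regular axis-aligned lattice anchored at the
sphere's bounding-box corner; voxels with |p − c| < r − margin are
"inside".  The margin (default 5 mm) keeps voxels away from the
conductor boundary where adaptive filters become unstable.  Default
spacing is 1 cm.

## Spectral estimation

Per epoch and channel, overlapping windows (slide 50 ms) are demeaned,
tapered and projected on the Fourier basis of the window's natural
bins; per-window, per-taper power estimates are averaged.  Two settings
cover the two ranges: 0.5-s windows with ±2 Hz smoothing for
2–40 Hz and 0.2-s windows with ±14 Hz smoothing for 40–90 Hz.  A lone
Hanning taper cannot smooth ±14 Hz on a 0.2-s window, so the smoothing
is implemented as a DPSS multitaper family sized to the bandwidth
(K = ⌊2·T·W⌋ − 1 tapers), falling back to a single Hanning taper when
the requested smoothing does not exceed the window's native resolution
— which is exactly the case for the ±2 Hz low-band setting.  Window
power (not amplitude) is averaged; there is no zero padding.

Normalization is variance per bin: summing the estimate over a window's
natural bins recovers the windowed signal variance, so a sinusoid of
amplitude A carries total power A²/2 in its smoothing band (verified to
5% in the tests).

The nominal output grid is 1 Hz, mapped without interpolation to each
window's nearest natural bin.  Because the 0.5-s window's natural
resolution is 2 Hz, neighbouring output frequencies share a natural
bin.  Band averages therefore select bins by the *natural-bin*
frequency actually estimated, using each natural bin once: otherwise
the bin at 30 Hz would be double-counted and — via the nominal label
31 Hz — copied into the low-gamma band, leaking the beta effect across
the band boundary.

## Sensor-level inference

The response defaults to log power.  The generator places the graded
effect multiplicatively on source variance (equal log-power steps), so
log power is linear in the ordinal code 1/2/3 — the regression model is
correctly specified by construction, which is the premise of parameter
recovery.  Raw-power regression is available by flag.

The FOI scan regresses sensor-averaged log power on the ordinal code at
each frequency and applies Benjamini–Hochberg step-up FDR across the
scanned frequencies; the FOI is the span of the longest contiguous
significant run (ties resolved toward the lowest frequency).  The SOI
stage averages power over the FOI per sensor and uses cluster-based
permutation: sensors with |t| above the two-sided forming threshold
(default α = 0.05, configurable; no single standard value exists) are clustered on the neighbourhood graph
separately by sign; cluster mass is the summed t; the null is the
maximum |mass| over permutations of the condition labels *within
blocks*, preserving the block structure of the fixed-order design (free
permutation is available).  Monte-Carlo p-values use the add-one
convention p = (1 + #{null ≥ |mass|}) / (n_perm + 1) and are verified
against exhaustive enumeration on a 90-labeling instance.

The order control re-runs the scan with surrogate "conditions" built
from presentation order alone.  Within-block temporal thirds would
reproduce the condition code exactly under the fixed order (a vacuous
control), so the default surrogate ranks epochs within each
block-condition interval and splits them into thirds: a condition-driven
effect constant within intervals shows nothing, genuine temporal drift
does.  The within-block coding is retained as an option.

Baseline correction divides each block's SB power by that block's mean
rest power per channel and frequency.  Percent signal change is
100·(mean_b − mean_a)/mean_a over the FOI per channel.

## Beamformer

The cross-spectral density at the FOI peak frequency is computed from
per-epoch multitaper Fourier coefficients over the full 2-s epoch
(±4 Hz smoothing → 15 tapers), averaged over epochs and tapers.  The
real part, ridge-regularized with λ = 5% of the mean diagonal
(configurable), is inverted for the unit-gain minimum-variance filter.
Orientation: in a spherical conductor every location has a silent
radial direction, so the lead field is first reduced to its rank-2
non-silent subspace (SVD); within it the max-power orientation is the
minimum eigenvector of LᵀC⁻¹L.  Fully silent voxels (the sphere centre)
get zero filters and drop out of the statistics with t = 0.  Unit gain
wᵀl = 1 holds exactly at every live voxel.  Per-epoch log source power
is log of the taper-averaged |wᵀF|², and the volumetric inference
reuses the sensor cluster engine with 6-connectivity on the lattice.

Filters are built from all conditions pooled, so the filter itself
cannot manufacture a condition effect.  A known behaviour worth
stating: with a very strong source falling *between* grid points, the
minimum-variance filter partially suppresses it at every mismatched
voxel.  At the 1-cm default spacing and physiologically plausible
effect sizes (below) the mismatch stays inside the beamformer's
resolution and recovery is reliable; a 2-cm grid with a very strong
source is not a configuration the defaults produce.

## Group statistics

Per subject and canonical band, sensor-averaged log power is regressed
on the ordinal code; the band t-values pool across subjects into
one-sample t-tests (df = n − 1) with Bonferroni over bands (default 6,
configurable).  Group source maps pool per-subject voxelwise regression
t-values (scale-free across subjects; coefficients optional) with a
sign-flipping cluster permutation — exhaustive over all 2ⁿ patterns for
n ≤ 12 by default, verified against Monte-Carlo flips.  ROI masking
restricts testing to a mask; a reference map tests subjects minus a
reference subject's values.  The synthetic atlas is a nearest-seed
parcellation of the inside voxels with placeholder region names; the
overlap table reports 100·|significant ∩ label|/|significant| per label.

## Synthetic data: what it emulates, and what it does not

Full-scale defaults reproduce the study conditions: 248 point
magnetometers on a quasi-uniform spherical cap (Fibonacci lattice,
radial orientations — the true helmet geometry is not public),
1017.25 Hz sampling, 4 blocks × (3 × 60 s + 60 s rest), 2-s epochs with
a 3-s lead-in discard.  The target source is a band-limited Gaussian
process (FIR bandpass, 27 ± 2 Hz) at a tangential right-parietal dipole;
its variance halves at each condition step and runs at the SB1 level
during rest.  Background: 20 dipoles with stationary 1/f spectra.
Artifacts: a quasi-periodic QRS-like cardiac source near the inferior
boundary and a Poisson blink source frontally, both projected through
the same physics, with their time courses exported as ICA ground truth.
Line noise is a 50 Hz sinusoid with per-channel coupling; sensor noise
is white.

Free parameters the reference design does not fix were chosen once for
physical plausibility: target 15 nAm (a typical cortical oscillatory
source), background 50 nAm per dipole, cardiac 300 nAm (≈3 pT at the
sensors), sensor noise 1e-13 T per sample.  These sit where the three
competing demands meet — the FOI scan needs the target visible above
background, band specificity needs the background to mask spectral
leakage of the target into neighbouring bands, and beamformer recovery
needs the source not to overwhelm its own off-grid suppression.  The
power ratio (halving per step) is a free parameter of the recovery
experiments, not a claim about real effect sizes.

What passing tests do **not** show about real data: the generator's
condition effect is exactly log-linear, its noise is Gaussian and
stationary, sensor geometry is ideal, and there is no head movement,
coregistration error or non-stationary artifact.  Recovery results
certify the pipeline's statistical machinery, not the detectability of
any real effect.

## Reduced Monte-Carlo scale

The calibration and recovery experiments run at a reduced problem size
chosen for desk-scale runtimes: 50 channels on a 7.5-cm shell around a
6-cm sphere, 256 Hz, 2 blocks of 40-s conditions with 20-s rests
(108 graded epochs), 8 background dipoles, artifacts off.  Null
(flat-power) calibration runs shorten intervals to 12 s — calibration
needs no statistical power — and use the 2-cm grid with 500
permutations; recovery uses the full 1-cm grid spacing.  Family-wise
error of the sensor, volume and group cluster tests is ≤ 0.075 at
nominal 0.05 over 40 null seeds; recovery rates over 20 seeds are
reported by `scripts/acceptance.py`.

## Numerical notes and degenerate inputs

* Slope t with zero residual variance returns ±∞ with p = 0, flagged
  degenerate; constant y returns t = 0, p = 1.  Zero-variance x raises.
* BH-FDR is the classic step-up; m = 0 returns an empty mask.
* Resampling 1017.25 → 300 Hz uses the exact rational ratio 1200/4069
  (polyphase), preceded by a zero-phase 8th-order Butterworth low-pass
  at 90% of the new Nyquist.
* Line-noise regression fits sin/cos over an integer number of line
  cycles so the regressors stay orthogonal to the rest of the spectrum.
* ICA (FastICA) is estimated on data downsampled to 300 Hz and applied
  at full rate; the component count equals the number of good channels,
  reduced only if the data matrix is rank-deficient.  Non-convergence is
  retried once with a new seed and then tolerated with a warning:
  rotations within a near-Gaussian background subspace have no strict
  fixed point, while the non-Gaussian artifact components stabilize
  early (template correlation with the injected cardiac trace exceeds
  0.8 in the recovery tests).
* Artifact-epoch rejection uses median/MAD z-scores (threshold 5) of a
  jump metric (max |first difference|) and a high-frequency RMS metric
  (110–140 Hz, capped below Nyquist); heavy-tailed metrics make robust
  scaling necessary.  Rejecting twice equals rejecting once.
* Cluster p-values can never be below 1/(n_perm + 1); n_perm < 100
  warns.

## Known limitations

Point magnetometers (no pickup-coil integration), spherical conductor
only, no coregistration or head-movement compensation, no
reference-sensor environmental denoising (line regression stands in),
scalar (not vector) beamformer output, and a synthetic placeholder
atlas.  The CLI covers the simulate/preprocess/sensor/source/group path
but is a thin convenience layer; the library functions are the primary
interface.
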