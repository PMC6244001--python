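# Methods

## The question the simulations answer

Sub-millimetre isotropic BOLD fMRI (0.7–0.8 mm voxels) resolves cortical
depth only indirectly: voxels are large relative to laminae, so the
standard analysis upsamples the functional image, assigns interpolated
samples to depth bins, and averages over an extended region of interest
(ROI), relying on the quasi-random (jittered) position of voxels relative
to the laminae. `laminarsim` quantifies what that pipeline can actually
recover: it injects a known laminar activation profile into a synthetic
cortex, samples it with jittered isotropic voxel grids, runs the standard
reconstruction, and measures the agreement between induced and
reconstructed profiles.

## Synthetic cortex

The cortex is a 2-D ribbon (tangential distance `x`, normal direction
`y`) bounded by the GM–CSF boundary (CSFB) above and the GM–WM boundary
(WMB) below. Even a convoluted cortex is locally flat, so a ribbon with
slowly varying boundaries stands in for a flat patch of real cortex.
Two generators exist:

* `make_flat_patch(thickness_mm, length_mm)` — parallel boundaries,
  useful for closed-form oracles (a 3 mm cortex holds exactly four
  0.75 mm voxel rows).
* `make_variable_patch(1.7, 3.7, length_mm, smoothness_mm, seed)` — the
  anatomically-inspired default: the thickness field is seeded Gaussian-
  filtered white noise rescaled to span exactly 1.7–3.7 mm (the human
  range), with tangential correlation length `smoothness_mm`
  (default 5 mm) and a smooth midline undulation of peak amplitude
  0.3 mm emulating local curvature. Identical seeds give bit-identical
  patches.

Normalized depth is equidistant: `d = 0` on the CSFB, `d = 1` on the
WMB. In a 2-D ribbon the equidistant and equivolume conventions
coincide (no volume wedge), so only the equidistant convention is
implemented; it is recorded in patch metadata. All fields are evaluated
on an internal raster of pitch 0.01 mm — at least 10x finer than the
finest voxel considered (0.1–0.125 mm) — so partial-volume integration
error is negligible against every tolerance used.

## Activation fields

* **Induced laminar PSF** — a Gaussian in normalized depth, centred
  mid-cortex (`d = 0.5`) with FWHM one fifth of the cortical depth.
  Because depth is normalized, the physical FWHM tracks the local
  thickness (0.34–0.74 mm across the 1.7–3.7 mm range). The PSF is an
  activation profile, not a density: truncation at `d = 0, 1` loses the
  tails without renormalization.
* **Pial rim field** — a boxcar band of width 0.1 mm centred on the
  CSFB (half in CSF, half in the most superficial GM), emulating BOLD
  signal confined to the pial/CSF surface vessels.
* **Trial generator** — per-trial signals
  `gain_t x response(t) x depth_gain(d) x modulation(x) + noise`. The
  response is a double-gamma HRF (peak delay 5.5 s, undershoot delay
  12 s, undershoot ratio 0.35) convolved with the stimulus boxcar
  (onset 10 s, duration 20 s, 1 s sampling, unit peak). `depth_gain` is
  linear from 1 at the WMB to 3 at the CSFB, so both the positive
  response and the post-stimulus undershoot grow toward the CSF
  boundary, as observed empirically. `modulation(x)` is seeded smoothed
  noise (mean 1, SD 0.3, correlation length 1 mm) shared across trials —
  the reproducible tangential structure. `gain_t ~ 1 + N(0, 0.2)`
  models the global trial-to-trial response-strength fluctuation of real
  BOLD data; without it an across-trial, column-centred PCA would see no
  shared structure at all, because a trial-invariant signal is removed
  exactly by centering.

## Voxel sampling

An isotropic square lattice is placed over the patch at an offset drawn
uniformly from `[0, voxel_size)^2` (the jitter). The noiseless voxel
signal is the mean of the field over the voxel footprint — a boxcar
sampling kernel, computed exactly on the raster via summed-area tables.
The true acquisition PSF of the 0.75 mm EPI protocol the simulations
model is not public; the boxcar is the minimal defensible kernel, and a
tabulated 1-D depth-direction kernel can be supplied instead
(`kernel=(offsets_mm, weights)`) when a measured PSF is available. This
choice matters quantitatively: a broader kernel lowers the overlap
numbers by a point or two (see "Calibration" below).

Noise is additive white Gaussian with SD = (peak noiseless voxel signal)
/ SNR, independent across voxels and realizations — the thermal-noise
regime. `SNR = inf` is the ideal case (measured = noiseless exactly);
`SNR = 1` is the realistic case, with noise on the scale of the
strongest voxel. Grid rotation is not modelled (acquisitions are aligned
to the cortex in the ROI).

## Depth-profile estimation

* `upsample_and_bin` — the standard pipeline: voxel values are linearly
  interpolated onto a grid 10x finer (configurable), every fine sample
  with `0 <= d <= 1` is assigned to one of N equidistant half-open depth
  bins `[k/N, (k+1)/N)` (last bin closed), and bins are averaged over
  the ROI. All grid rows of the ROI block participate in the
  interpolation — including the CSF/WM-adjacent partial-volume rows —
  exactly as upsampling a real image would; this is also what feeds
  boundary leakage into superficial bins. Empty bins are reported as
  missing (NaN), never as zero.
* `centroid_sort_profile` — the interpolation-free alternative: whole
  voxels are binned by the normalized depth of their centroids; voxels
  with non-GM centroids are excluded.

Profiles are ordered CSFB -> WMB (index 0 at `d = 0`). Normalization is
`peak` (max |value| = 1) or `unit_area` (trapezoidal area 1). Window
averaging of per-depth timecourses uses a 2 s rise lag: positive BOLD
over `[onset+2, onset+duration]` s, undershoot over `[offset+2,
offset+12]` s.

## Overlap metric

`overlap_percent(induced, reconstructed)` resamples the reconstructed
profile onto the induced profile's dense depth grid (201 points) by
linear interpolation, clips negative lobes to zero (with a warning),
unit-area-normalizes both curves, and integrates the pointwise minimum
(x100). The metric is bounded in [0, 100], symmetric, invariant to
rescaling of either profile, and equals 100 iff the curves coincide.
A profile whose positive part vanishes entirely (possible at SNR = 1
with small ROIs) has overlap 0 by continuity. Profiles with missing
bins are refused rather than imputed.

## Monte-Carlo experiments

**PSF overlap vs ROI size.** Per realization: a fresh jittered grid over
a fixed variable-thickness patch, a measurement at the configured SNR,
then — per requested ROI size — a contiguous tangential block starting
at a random feasible column, accumulated column by column until the
GM-centroid voxel count first reaches the request (exact on flat
patches; on variable patches the actual count, at most one column's rows
above the request, is recorded). The block is reconstructed at 21 (or 3)
depths and compared with the induced Gaussian. Means, SDs and
Monte-Carlo SEs are reported across realizations. Defaults: 0.75 mm
voxels, 21 depths, 10x upsampling, 500 realizations (200 for the
headline ~24-voxel condition, which is stable to ~0.3 points of SE).

**Pial leakage.** The rim field is sampled at 0.75 mm and 0.125 mm on
the same patch over jittered grids (100 realizations); the mean
full-grid profile per voxel size is summarized by the deepest bin centre
still at >= 10% of the profile maximum. Larger voxels spread the
boundary signal several times deeper (typical extents ~0.3 vs ~0.05 of
cortical depth), which is the partial-volume mechanism behind the
inflated superficial signal of isotropic acquisitions.

**Trial PCA.** Trials are collapsed to positive-BOLD tangential
profiles (window mean, then mean over GM depths), stacked as a
trials x positions matrix, column-mean centred and decomposed by SVD.
Explained variance of component k is `100 s_k^2 / sum s^2`; PC1's sign
is fixed to correlate non-negatively with the mean profile; no rotation.
With reproducible tangential structure present, PC1 recovers the
generator's modulation (r > 0.9 at noise SD 1.0, ten trials — a level
chosen by pilot runs of the generator itself) and its explained variance
falls monotonically as noise grows, which is the logic for reading a
high PC1 percentage as non-thermal structure.

## Calibration of the headline number

At the study conditions (variable cortex, ~24-voxel ROI, 21 depths,
SNR inf, boxcar kernel) the mean overlap comes out at 67–70% depending
on the seeded cortex realization, brushing the upper edge of the
expected 61–68% range for this regime; the 3-depth companion value is
~59%, brushing the lower edge. Both offsets are consistent with the
boxcar kernel being slightly narrower than a real EPI acquisition PSF;
substituting a tabulated measured kernel shifts both values down.
No generator parameter was adjusted to move these numbers.

## Numerical choices and degenerate inputs

* Voxel footprints snap to raster cell boundaries (error << pitch).
* Summed-area-table cancellation error is orders of magnitude below the
  1e-6 relative tolerance used for the erf oracles at the pitches tested.
* Depth bins: half-open with last bin closed; `d` exactly 1 is GM.
* Zero-variance trial stacks, all-zero profiles, empty windows, rims
  wider than the thinnest cortex, non-positive SNR and out-of-domain
  points are rejected with descriptive errors; degenerate thickness
  ranges fall back to the mid-thickness flat ribbon.
* All randomness flows from one master seed through
  `numpy.random.SeedSequence` spawning; identical configs reproduce
  byte-identical outputs.

## What the generator does not model

Ascending-vein drainage and other vascular biophysics, susceptibility
"blooming" beyond vessels, k-space/EPI distortions, T2* decay during
readout, slice profiles, 3-D gyral folding and mesh-based equivolume
layering, and real-data preprocessing (motion, registration,
segmentation) are all out of scope. Passing tests therefore show what
the *sampling and analysis pipeline* does to a known signal under
thermal noise — not that real laminar profiles are recovered correctly
in the presence of vascular bias. Real-data statistics (subject-level
PC1 percentages, F-tests) are not reproducible here; the package
reproduces the procedures and their statistical behaviour on synthetic
data.
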