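# Methods

This note documents the models, numerical choices and limitations behind
naturalscan, stage by stage.

## Stimulus annotations

Audio descriptors are computed in non-overlapping 1-s windows over a mono
waveform, giving exactly `floor(duration)` samples per track:

- **Zero-crossing rate**: sign changes per window, with exact-zero samples
  dropped before counting (a `+,0,−` sequence counts once).  A crossing
  falling between the final sample of a window and the window boundary is
  unobservable, so a pure `f` Hz tone yields `2f` or `2f − 1` depending on
  phase; both are correct counts of observable crossings.
- **RMS energy**: root mean square amplitude.
- **Spectral spread**: the standard deviation (Hz) of the distribution
  obtained by normalising the magnitude of the real FFT of the full
  window.  No taper is applied by default (a Hann option exists): the
  descriptors target broadband texture, and tapering changes closed-form
  test values without changing their interpretation.
- **Spectral entropy**: Shannon entropy of the normalised magnitude
  spectrum divided by `log(n_bins)`, so a flat spectrum maps to exactly 1
  and a pure tone to ≈ 0.  Entropy is undefined in silent windows; those
  windows inherit the entropy of the quietest non-silent window (RMS below
  `1e−6 ×` track maximum counts as silent; ties resolve to the earliest
  window).  This substitution mirrors how an annotator would extend the
  "most silent part" of a soundtrack and fails loudly if every window is
  silent.

Visual complexity ("contrast edges") is the mean absolute intensity of each
frame after 2-D DCT high-pass filtering: coefficients with radial frequency
`sqrt(ωx² + ωy²) < 2π/16` rad/pixel are zeroed (per-axis `ω = πk/N`).  The
radial mask is the default because the cutoff is a scalar frequency; a
separable per-axis mask is available.  The DC term always falls below the
cutoff, making the measure exactly invariant to global brightness shifts
and linear in contrast scaling.  Frame values are averaged within 1-s
windows.  Colour frames are converted with ITU-R 601 luma weights before
filtering.

Object motion is scored 0–4 per category (body, head, hand, mechanical)
and 1-s window.  Manual scoring sums a shot-size score (0–2) and a motion
strength score (0–2), forced to 0 when strength is 0 — a motionless
close-up is not motion.  Track-based scoring maps, per object and window,
the maximum bounding-box area fraction (breaks 1/10 and 1/6 of frame area)
and the summed instantaneous centroid displacement (breaks 15 and 50 px/s)
to 0–2 sub-scores, takes each measure's maximum over the category's
objects, and sums.  The zero-when-static rule is applied to track scoring
too (configurable), keeping the two scoring routes on the same scale.

## Design construction

The canonical HRF is a difference of two gamma densities with the gamma
shape chosen as `delay/dispersion + 1` so the positive lobe's *mode* sits
exactly at the 6-s peak delay (and the undershoot's at 16 s; undershoot
ratio 1/6; kernel length 32 s), normalised to unit peak.  Annotations are
convolved causally at 1 Hz, truncated to stimulus length, and resampled to
the TR grid by decimation at grid points (exact for integer TR; linear
interpolation available).  Convolving at 1 Hz before downsampling keeps
boxcar onsets at their annotated second.

High-pass detrending fits, at every time point, an intercept-plus-slope
model to the whole series under Gaussian weights (SD σ = 100 s by default)
centred there, subtracts the fitted value and restores the global mean.
Constants and linear ramps are removed exactly and sinusoids below
`1/(2σ)` Hz are attenuated by more than half.  Because this running-line
smoother is not a projection, the filter is only approximately idempotent
(refiltering perturbs the output by a few percent of its SD); this is a
property of the filter's definition, not of the implementation.

Group-level voxel-wise analysis standardises each subject's voxel time
courses to zero mean and unit variance before averaging across subjects;
zero-variance voxels are set to zero and flagged.

## Synthetic studies

The generator emulates a 10-subject free-viewing study (TR 2 s, 679
retained volumes, 1-Hz annotations: 4 sound-category boxcars, 4 continuous
acoustic features, 1 edge-density track, 6 ordinal motion tracks) at a
desk-scale default of 5 subjects, 300 volumes, 2000 voxels and 4 planted
components; the full geometry is one config away.

Each planted component time course is a weight-matrix combination of the
standardized HRF-convolved regressors, rescaled to unit variance, plus a
shared AR(1) signal (SD 0.3, common to all subjects) and an idiosyncratic
AR(1) perturbation per subject (SD 0.3); voxel noise is AR(1) with SD 0.5.
All AR(1) processes share φ = 0.3 — the minimal temporally autocorrelated
noise model, chosen so circular-shift nulls are non-trivial.  ISC of a
planted component is therefore controlled by the ratio of shared to
subject-specific variance and decreases monotonically in the
subject-noise SD.  The default weight matrix plants a core auditory
network, a speech-selective network, an early-visual (edges + global
motion) network and a dorsal hand/mechanical-motion network; rows of zeros
create pure shared-noise networks for specificity testing.

Spatial maps are Gaussian blobs (σ ≥ 1 voxel) placed one per cell of a
greedy lattice partition of the mask volume, which bounds their pairwise
spatial correlation below 0.3 and keeps ICA recovery well posed.  Boxcar
segments are placed with Poisson-distributed lengths into free time slots,
hitting a requested active density exactly; with overlap fraction 0 the
four sound categories are mutually disjoint.  Toy audio (silence / tone /
chord / noise seconds with closed-form RMS, ZCR and spread) and toy video
(constant-velocity rectangles with exact tracking tables, truncated and
flagged at the frame boundary) provide analytic fixtures for the feature
extractors.

What the generator does **not** emulate: hemodynamic nonlinearity, head
motion, scanner drift beyond AR(1), spatial noise correlations, and
anatomically shaped networks.  Passing recovery tests therefore validate
the analysis machinery, not its robustness to those real-data features.

## Group ICA and stability

Subjects are temporally concatenated (optional per-subject PCA first) and
PCA-reduced to the target dimensionality (config parameter; 40 in the
emulated study, 4–5 at desk scale — model-order estimation is out of
scope).  Each of `n_runs` decompositions (default 100; acceptance checks
use 20) runs a fixed-point maximal-non-Gaussianity estimator (FastICA)
with a fresh random initialisation; with bootstrap enabled the ICA samples
— voxels, the observations of spatial ICA — are resampled with replacement
and the learned unmixing is applied to the full matrix.  Convergence
tolerance is 1e−7 with up to 1000 iterations: at looser tolerances the
estimator occasionally stops while two sources are still partially
rotated, which breaks run-level component matching.

Pooled maps from all runs are clustered agglomeratively (average linkage)
on `1 − |spatial Pearson ρ|` into `n_components` clusters, followed by a
one-pass reassignment of every map to its nearest centrotype (the member
with maximal summed intra-cluster similarity), which corrects borderline
assignments of bootstrap-perturbed estimates.  Per cluster: stability
index = mean pairwise intra-cluster |ρ| (1 for singletons), run count =
distinct runs represented, representative map = sign-aligned cluster mean
around the centrotype, z-scored over voxels.  Components pass the
stability screen when found in every run and stability exceeds 0.9 (both
configurable).  Subject time courses are back-reconstructed by projecting
each subject's centred data onto the pseudo-inverse of the map matrix; for
orthonormal maps this is exactly the map-weighted average of voxel time
courses.  All downstream statistics use absolute correlations where sign
matters, so component sign flips are immaterial.

## Inference

GLM fits use ordinary least squares with an intercept that is fitted but
never reported among the weights.  Rank-deficient designs raise an error
naming the dependent columns rather than silently pseudo-inverting, since
annotation collections can become collinear.  Normalized weights divide by
the largest |β| preserving signs, so a negative-dominant model yields −1
for its main feature rather than a global sign flip.

Circular-shift nulls refit the model at every rotation of every series —
identity rotation included, which reproduces the emulated study's
realization arithmetic (679 shifts × 40 components = 27,160) and is
conservative.  Implementation: the model's centred column space is
orthonormalised once (QR); each rotation's fit correlation is the norm of
the projection of the rotated, centred series onto that basis divided by
the series norm, so a full null costs one T×T gather and one matrix
product per series.  The pooled r values are tabulated into 100
equal-width bins with probabilities at bin centres;
`threshold_at(p)` linearly interpolates the upper-tail mass between
centres and is monotone in p.  Single-annotation nulls use the plain
signed Pearson correlation at every second rotation (half the
distribution), and a per-modality visualization threshold averages the
individual annotation thresholds.  Separate nulls per stimulus model
account for their different regressor counts.

At desk scale the null for *component selection* is pooled over all brain
voxels of the standardized-average data rather than over the component
time courses themselves: with only 4–5 extracted components, most of which
are stimulus-locked, a component-timecourse null's extreme tail consists
of the observed values themselves and the threshold degenerates to the
observed maximum.  The emulated study did not face this because 34 of its
40 components were not stimulus-locked; it likewise computed voxel-pool
thresholds for its voxel-wise analysis.  The voxel pool (~6×10⁵
realizations at desk scale) gives the α = 0.001 tail a noise-dominated
estimate.  Calibration is verified empirically: on AR(1) null series the
threshold's type-I rate lands inside the binomial confidence band at
nominal 0.05 and 0.01.

ISC is the mean of all pairwise subject correlations taken in Fisher-z
space and back-transformed, with coefficients clipped to ±(1 − 1e−12); the
dispersion is reported both as variance and SD of the pairwise values.
Its p-value circularly shifts one member of each pair by a random nonzero
rotation (default 1999 permutations, keeping the permutation p-value floor
1/(n+1) below α = 0.001; a parametric t on z-values is not provided —
permutation is the primary method and the floor is explicit).  Components
are selected when ISC p < α, at least one stimulus model's fit r exceeds
that model's threshold at α, and the stability screen passes.

Single-feature weights per subject feed two-sided one-sample t-tests
(weight ≠ 0) and paired t-tests (weight differs between two components).
All-zero values give t = 0, p = 1; zero-variance nonzero differences leave
p undefined and flagged.

## Network comparison

Component maps are binarized at |z| ≥ 3 by default — the binarization rule
for IC maps is a package choice, not sourced from the emulated study, and
is exposed in the config; correlation maps are thresholded at their
model's permutation threshold.  Connected components are labeled under
18-connectivity (faces + edges, not vertices) and clusters of ≤ 125 voxels
discarded at full scale (the bound is strict; desk-scale runs lower it via
config).  Voxel-wise and two IC masks are classified into the eight
overlap categories.  Functional connectivity between cluster mean time
courses uses a max-correlation null: each permutation draws a seed cluster
uniformly, rotates its time course by at least 5 samples, and records the
maximum signed correlation with all other clusters (absolute-max
optional); the desk default is 10⁵ permutations with the emulated study's
10⁷ reachable via config, and the Monte-Carlo standard error is reported.
Snapshot maps threshold the across-subject mean of standardized signals at
one time point against the one-sided normal quantile `z₁₋ₚ/√n` (two-sided
optional), e.g. 1.645/√10 ≈ 0.520 for ten subjects at p = 0.05.

## Reproducibility and scale

Every stochastic step takes an explicit seed; a pipeline run writes its
config hash (output path excluded) and seed into every table, and
re-running with the same config reproduces the summary exactly.  The
acceptance script runs at desk scale — 679-volume null series for
threshold checks, the 5-subject/300-volume/2000-voxel default for recovery
and selection (20 independent studies for the selection rate), 20
bootstrapped ICA runs — sizes chosen so the whole script completes in a
few minutes while keeping every statistical check adequately powered.

Known limitations: no slice-timing, motion or registration handling (data
are assumed preprocessed and in a common space); no multiple-comparisons
machinery beyond the uncorrected permutation thresholds; model-order
selection for ICA is the caller's responsibility (an exploratory
stability-vs-dimensionality sweep is provided); the bootstrap resamples
voxels, which ignores spatial dependence that real data would add.
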