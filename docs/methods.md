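# Methods

`prftuning` quantifies how spatially tuned cortical responses differ between
seeing a stimulus and remembering it, using population receptive field (pRF)
models as the spatial reference frame. This note documents the models, the
synthetic data the package analyzes, and the numerical choices, in enough
detail to reproduce or modify any stage.

## The analysis problem

Each cortical-surface vertex carries pRF parameters estimated from an
independent retinotopy session — visual-field position (polar angle θ,
eccentricity r, equivalently x = r·sin θ, y = r·cos θ with θ measured
clockwise from the upper vertical meridian), size σ, compressive exponent
n ∈ (0, 1], and model variance explained R² — plus GLM amplitudes (% BOLD
signal change) evoked by perceiving or remembering each of four isoeccentric
stimuli (45°/135°/225°/315° polar angle, 2° eccentricity, 1.5 dva diameter).
Because the stimuli are isoeccentric, spatial tuning collapses to one
dimension: the response as a function of polar-angle distance between a
vertex's pRF and the stimulus.

## Polar-angle response functions and the difference-of-von-Mises model

Vertices are gated per ROI: eccentricity in [0.5, 8]°, pRF R² ≥ 0.1, and —
for polar-angle profiles — pRF eccentricity within one (vertex-specific) σ
of the stimulus eccentricity. Each retained (vertex, stimulus) pair is
assigned the signed circular distance d = wrap(θ_vertex − θ_stimulus) ∈
(−180°, 180°] and binned into 18 bins of 20° centered on the multiples of
20° in (−180°, 180°]; bin edges fall on odd multiples of 10°, and a distance
exactly on an edge goes to the lower (more negative) bin — a deterministic,
measure-zero tie-break. Per participant and bin, the response is the median
β. The group profile is a normed mean: each participant's 18-vector is
divided by its L2 norm, averaged, and rescaled by the mean norm, so globally
strong responders do not dominate; bins missing for any participant are
undefined at the group level, and norms are taken over the commonly defined
bins.

The group profile is fit with a difference of two von Mises functions
sharing a location,

f(θ) = β₁·vM(θ; μ, κ₁) − β₂·vM(θ; μ, κ₂),  vM(θ; μ, κ) = e^{κ cos(θ−μ)} / (2π I₀(κ)),

evaluated as e^{κ(cos(θ−μ)−1)} / (2π·i0e(κ)) so concentrations up to the
κ ≤ 500 bound stay finite. Three population metrics are read off the fitted
curve on a 0.1° grid: location (= μ), amplitude (max − min, % signal
change), and FWHM — the width of the contiguous interval around the peak
where f ≥ (max f)/2, with linearly interpolated crossings. Half-maximum is
referenced to zero by default (the conventional reading of FWHM); a
relative-to-minimum variant is available via `fwhm_reference="min"` for
sensitivity analyses. Both are invariant to rescaling the curve by a
positive factor. A curve with non-positive maximum has no FWHM and is
flagged.

### Fitting

The least-squares problem is solved by variable projection: for fixed
(μ, κ₁, κ₂) the optimal (β₁, β₂) ≥ 0 follow from an exact two-column
non-negative linear solve, so the nonlinear search runs over three
parameters only, with bounds μ ∈ [−360°, 360°] (wrapped afterwards) and
κ ∈ [0, 500]. Eight multi-starts are used — μ ∈ {argmax bin, argmax ± 20°,
0°} × κ ∈ {2, 20} — and the smallest residual sum of squares wins, ties
broken toward the smaller κ₁. Because bootstrap inference and the noise
simulations require tens of thousands of fits, the optimizer is a projected
Levenberg–Marquardt vectorized across problems and starts (finite-difference
Jacobian; the inner non-negative solve makes the objective piecewise
smooth). It was validated against a bounded derivative-free polish (max RSS
excess 5.5 × 10⁻⁴ on noisy profiles, exact on noiseless ones) and against a
dense grid-search oracle in the test suite.

One guard is essential: with 20° bin spacing and κ up to 500 (component
FWHM ≈ 6°), the best-RSS solution can hide an enormous narrow component
*between* the sampled angles, improving the residual marginally while the
dense-grid amplitude explodes (e.g. a −168 %sc spike against a 0.5 %sc
profile). Candidate solutions whose dense curve anywhere exceeds 3× the
data range are therefore rejected during multi-start selection; if every
start is rejected the fit is flagged degenerate. Degenerate fits (also:
all-zero input, fewer than 5 valid bins) count as failures downstream.

### Inference

Confidence intervals come from resampling participants with replacement
(500 replicates by default), repeating the norm-average → fit → metrics
chain per replicate, and taking percentile intervals at 68% and 95% over
the non-degenerate replicates; replicate and failure counts are recorded,
and more than 50% failures is a hard error. Task/ROI effects are summarized
by an ordinary least-squares regression of each metric on task (+0.5
perception, −0.5 memory), ROI coded by its hypothesized hierarchy position
(V1 = 1 … V3ab = 6, centered), and their interaction, run once per bootstrap
replicate across the 12 (ROI, task) cells; coefficients get percentile CIs
over replicates. The coding is a package choice; the estimator behind the
reported coefficients is not otherwise constrained.

Individual-participant fits remove a baseline first — the mean of the three
bins farthest from the stimulus (−160°, 160°, 180°) is shifted to exactly
0% — because participant-specific offsets are outside the group model.
Eccentricity profiles (vertices within 15° of polar angle of a stimulus,
0.5-dva bins on [0.5, 8]) are reported as binned medians with bootstrap CIs
and no parametric fit. 2D visual-field maps linearly interpolate scattered
(x, y, β) per participant and stimulus after rotating the stimulus to the
upper vertical meridian, z-score each image over valid pixels, and average.

## pRF forward model

Predictions start from 101 × 101 binary contrast apertures over a 24°
field of view (the retinotopy stimulus extent); pixel centers define the
degree mapping. For the linear and CSS variants the spatial kernel is an
isotropic Gaussian normalized to unit sum over the grid, so a full-field
stimulus drives a vertex at exactly β; the response is β·(Σ aperture·kernel)ⁿ
with n = 1 for linear. The DoG+CSS variant converts each Gaussian pRF to a
difference of Gaussians with fixed surround:center ratios — size 2:1 and
peak height 1:2 — after pre-rescaling the center by σ·√2 and β·2, which
leaves the composite kernel with the same FWHM and peak as the original
Gaussian while adding suppressive flanks. The DoG plane integral is negative
by construction (2·2π(σ√2)² < 2π(2σ√2)²), so no positive full-field
normalization exists; the kernel is instead scaled so its peak equals the
peak of the unit-sum original-σ Gaussian, making DoG and CSS drives
comparable for compact stimuli. Negative DoG drive passes through the
compressive exponent by the signed-power rule sign(d)·|d|ⁿ so suppression
survives the nonlinearity; applying the exponent to center and surround
separately is a noted alternative we did not adopt. Predictions are scored
against observed profiles with R² = 1 − SS_res/SS_tot (negative when the
prediction is worse than the observed mean) before and after a single
least-squares rescale s* = Σ pred·obs / Σ pred², pooled across ROIs per
task.

## Synthetic cortical data

The generator emulates the study design — 9 participants × 6 ROIs (V1, V2,
V3, hV4, LO, V3ab) × 500 vertices — so every stage is testable without scan
data. Per vertex: polar angle uniform on [−180°, 180°); eccentricity
log-uniform on (0.5, 8); σ linear in eccentricity with ROI-specific slope
and intercept plus 10% lognormal scatter; exponent uniform on (0.3, 0.8);
and 15% of vertices drawn with pRF R² < 0.1 so the gate is exercised. The
σ lines are calibrated so the zero-noise group perception FWHM reproduces
the empirically observed ladder across the hierarchy, 38° in V1 rising to
97° in V3ab.

Perception truth is the DoG+CSS forward prediction with a per-ROI amplitude
scale calibrated so the noiseless group tuning curve has peak-to-trough
0.9 %sc (every pipeline stage is positively homogeneous in the response
scale, so the calibration is exact). Memory truth is generated
mechanistically — not by the hierarchy model, keeping the two halves of the
package independently testable — as attenuation × the forward prediction
computed with σ multiplied by a per-ROI widening factor (3.0 in V1 shrinking
linearly to 1.0 in V3ab); the memory scale is calibrated against the widened
profile, so attenuation 0.28 yields a memory group amplitude of
0.28 × 0.9 ≈ 0.25 %sc. These defaults place the synthetic group data in the
empirically reported regime: group amplitudes ≈ 0.9 vs ≈ 0.26 %sc, V1
memory/perception FWHM ratio ≈ 3.4 falling to ≈ 1 by V3ab.

Observed betas are truth + Gaussian noise, SD 0.25 %sc per vertex times a
per-participant lognormal multiplier (σ_log = 0.5) — real participants vary
severalfold in fMRI SNR, and that heterogeneity is also what makes
participant-resampled percentile intervals conservative. `beta_median` is
set to the truth and `beta_se` to the noise SD, playing the role of the
bootstrap summaries the noise simulations treat as signal and noise. The SE
is homogeneous within ROI and participant by default; a config flag makes it
eccentricity-dependent. Randomness is PCG64 with `SeedSequence` substreams
keyed on (seed; stage, participant, ROI), so identical configs give
bit-identical tables and stages are independently reproducible.

What the generator does *not* emulate: fMRI time series, hemodynamics, GLM
estimation, spatial noise correlations on the cortical surface, retinotopic
map geometry, or between-vertex correlations in tuning scatter. Passing
tests therefore certify the analysis machinery — gating, binning,
averaging, fitting, inference, simulation scoring — under a known ground
truth, not the empirical claims about cortex.

## Noise-confound simulations

Four families ask whether noisier perception data could mimic memory data.
All draw vertex values as median + z·SE with one standard-normal z shared
by every vertex of a (simulation, participant, ROI, stimulus) cell —
deliberately overcompensating for the spatial correlation of BOLD noise,
since independent vertex noise would average out of population tuning
curves. The per-stimulus z is the weakest correlation structure consistent
with sharing "across all vertices in an ROI"; a coarser one-z-per-dataset
variant would be a one-line change. The z stream is seeded independently of
each family's structural randomness, so lapse 0%, associative 0% and
angular SD 0 are dataset-identical to the SNR level-p simulation under a
shared seed.

- SNR: per-vertex SNR is |median| / SE. Level p keeps the perception SE;
  level m solves |perception median| / SE = memory SNR per vertex; m/2, m/4,
  m/8 multiply that SE by 2, 4, 8. Vertices whose perception or memory
  median is near zero (below 5% of the ROI median magnitude — the inversion
  is ill-posed there) receive the ROI's median target SE.
- Lapse: level/25 of the 4 stimuli per (simulation, participant) are drawn
  from zero signal with perception noise. Designation is per participant per
  dataset.
- Associative: the same counts of stimuli take a uniformly chosen *other*
  stimulus's perception median (SE unchanged); errors are always a multiple
  of 90°, the stimulus spacing.
- Angular: betas are plain level-p draws, but each (participant, stimulus)
  response is aligned downstream by a remembered angle ~ Normal(true angle,
  SD) instead of the true angle. At SD = 60° the error stays within the
  correct quadrant with probability 2Φ(0.75) − 1 ≈ 0.547.

Each simulated dataset runs through the identical binning → norm-average →
fit pipeline, and the fitted location and FWHM are scored by the fraction of
simulations inside the memory data's 95% CIs; degenerate fits count as
misses with the full simulation count as denominator.

A structural finding worth knowing: across-simulation FWHM dispersion grows
monotonically with level for the additive-noise families (SNR, lapse), but
*saturates* for the substitution families — a 100%-associative-error dataset
is a cleanly permuted perception dataset, not a noisier one, so its fit
dispersion can dip below the 75% level. Zero-referenced FWHM is also
sensitive to correlated baseline shifts, so dispersion orderings are only
stable when pooled over a few seeds.

## Hierarchical pooling model

A fully linear, untrained cascade on a 1D spatial axis: activity in layer 1
is a boxcar stimulus (15° wide, height 1, centered at 0°) convolved with a
fixed Gaussian kernel (σ = 15°); each next layer convolves the previous one
with the same kernel, for 8 layers. The feedback pass duplicates layer 8
(perfect reinstatement) and applies the transpose of the same pooling
operator downward; the operator is a symmetric Toeplitz matrix, so feedback
layer l equals feedforward layer 2L − l exactly, and deep-layer FWHM
approaches 2.3548·σ·√n. The axis is linear, not circular — the Toeplitz
formulation is linear convolution — with the kernel discretized at the grid
step (0.5° by default), truncated at ±5σ, and normalized to unit sum so a
constant profile is preserved in the interior and peak amplitudes decrease
down the cascade. The grid extent defaults to stimulus width + 8σ√(2L), an
edge guard keeping ±4 SD of accumulated spread inside the grid; FWHM numbers
quoted from this model should always be reported together with the grid step
and extent. Per-layer metrics mirror the fMRI ones: location = argmax (ties
averaged), amplitude = max − min, FWHM by interpolated half-maximum
crossings. Sweeps cover depths {4, 6, 8, 10} and all 16 combinations of
stimulus width {15, 30, 45, 60}° × kernel σ {5, 15, 30, 45}°. Model layers
deliberately carry no mapping onto specific cortical areas.

## Problem sizes and determinism

Default analyses run at 9 participants × 6 ROIs × 500 vertices with 500
bootstrap replicates; the acceptance script and the heavier tests use 200
replicates and a 2-participant × 2-ROI × 200-vertex fixture for the
simulation families (100 simulations per level, three seeds pooled), sizes
chosen so a full run completes in minutes on one core while leaving the
group-level estimates stable. All randomness flows from a single master
seed through named substreams; rerunning any stage with the same
configuration is bit-identical.

## Known limitations

- Percentile bootstrap intervals at n = 9 participants under-cover slightly
  (measured ≈ 91% for the location metric at nominal 95%); BCa or expanded
  percentile intervals would improve calibration but are not used, matching
  the plain-percentile convention.
- The spike guard's 3× data-range threshold is a heuristic; profiles whose
  true peak lies between bins and genuinely exceeds 3× the binned range
  would be misflagged (not observed in practice).
- The σ calibration targets group-level FWHM, not vertex-level size
  distributions; individual-vertex σ values should not be read as empirical.
- The DoG normalization (peak-matched to the unit-sum Gaussian) is one of
  several defensible conventions; only ratios and profile shapes, not
  absolute drives, are comparable across variants.
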