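# Methods

This note documents the models behind `vifstretch`, the choices made
where the underlying procedures were open, and what the synthetic tests
do and do not demonstrate about real data.

## Coordinate and unit conventions

Image row index is y — the stretch axis — and column index is x; pixel
indices are 0-based. Lengths are reported in μm (nm for AFM maps), strains
as dimensionless fractions internally (percent only in reports), and
angles in degrees from the +y axis, folded to [0°, 90°] (axial, sign-free)
unless a signed range is requested. All randomness flows through
`numpy.random.default_rng(seed)`; a run is bit-reproducible given its seed.

## Substrate strain model

The stretcher applies, at motor-position step k, the diagonal affine map
(x, y) → ((1+ε_xx,k)·x, (1+ε_yy,k)·y) about the field center, with both
strains linear in the step index and defaults ε_yy = +33%, ε_xx = −12% at
the last of 11 steps (ν = 0.36). Beads are Gaussian spots (σ = 2 px) with
0.1 px positional jitter per step and additive image noise; they are
placed ≥ 15 px apart because fiducial markers must stay individually
resolvable to be tracked.

Recovery: detection is smoothed-local-maximum blob finding with
center-of-mass refinement (≈ 0.05 px accuracy on clean spots); linking is
greedy nearest neighbor, or — for single large jumps — an iterated
link/affine-fit/relink loop with residual trimming (`affine_predicted`).
The pairwise Cauchy estimator pools bead pairs whose reference separation
lies within 15° of an axis, as Σ ΔL / Σ L₀ per axis. The length-weighted
pooling matters: an unweighted mean of ΔL/L₀ ratios is biased by noise in
the small denominators of short pairs (≈ +1 percentage point at the
default conditions). The affine estimator solves the bead correspondences
by least squares and reads strains off the diagonal; on noise-free fields
it is exact to machine precision and serves as the cross-check for the
pairwise route.

The zero-strain angle α₀ uses the closed form
sin²α₀ = (1 − b⁻²)/(a⁻² − b⁻²) with a = 1+ε_xx, b = 1+ε_yy, validated
against a Brent root-finder over a strain sweep (agreement < 10⁻⁶ rad).
At (0.33, −0.12) it evaluates to 50.7°.

## Filament model and strain transfer

Backbones are discrete 2D worm-like chains: the tangent angle performs a
random walk with variance ds/L_p per arc step, giving
⟨cos Δθ(s)⟩ = exp(−s/2L_p); default L_p = 2 μm, contour length
10 ± 2 μm, initial angles normal about the stretch axis (σ = 30°,
mirroring flush-induced anisotropy). Chains are sampled at ds = L₀/n so
the polyline arc length equals L₀ exactly.

Two deformation modes:

- **decoupled** (the mode used for parameter-recovery runs): at step k the
  filament keeps its shape, uniformly rescaled to contour length
  L₀·(1 + κ·ε_yy,k); its axis rotates to the angle a material line at its
  end-to-end angle attains under the substrate affine, and its centroid
  rides the affine. The recoverable strain-transfer slope equals κ by
  construction. Defaults κ_slow = 0.16 and κ_fast = 0.26 correspond to
  the two stretching speeds studied.
- **affine_pinned** (physically motivated): pinning points every
  0.5 μm of arc are displaced by I + κ·diag(ε_xx, ε_yy) and the backbone
  re-interpolated through them. The pin spacing is a free parameter — the
  membrane-anchor surface density does not translate to a unique spacing.

Two generator constraints keep the truth *measurable*:

1. **Band-limiting.** Backbones are low-passed along arc length
   (Gaussian, σ = 0.15 μm ≈ the PSF) before the truth length is fixed.
   A worm-like chain carries arc length in undulations below the optical
   resolution (≈ 4.5% at L_p = 2 μm under a 0.15 μm PSF) that no tracer
   can observe; worse, that hidden length re-emerges as the filament is
   scaled up, which would bias any measured slope upward by construction
   rather than through tracer error.
2. **Clearance.** Filaments are placed with ≥ 1 μm mutual clearance
   *evaluated on the deformed backbones* at the first, middle and last
   step (rotation toward the stretch axis can bring initially clear
   filaments into contact), and self-approaching (hairpin) backbones are
   rejected: a bend tighter than the mask width merges with itself in any
   skeleton-based tracer, and such filaments would not be selected for
   contour-length analysis in practice.

Tracing runs ridge enhancement (see tube filter below, scales 1.5/2.5 px)
→ Otsu threshold → skeletonization → spur pruning (endpoint twigs ≤ 8 px
at junctions) → junction breaking → path ordering → smoothing spline →
sub-pixel ridge refinement (parabolic maximum of the intensity sampled
perpendicular to the local tangent) → half-max end extension. The end
rule exploits that a PSF-convolved line's intensity at its true endpoint
is half the on-ridge plateau, so ends are restored to sub-pixel accuracy;
a straight synthetic filament is measured to 0.01%, curved ensembles to
≈ 1.5% (residual curvature bias of the blurred ridge). Traces are matched
across steps by greedy nearest-endpoint matching after pre-warping the
reference traces through the substrate affine.

Filament strain ε_VIF = (L_now − L_ref)/L_ref is regressed on the
substrate strain by ordinary least squares with a pointwise 95%
confidence band (t-distribution). At the default conditions the recovered
slope sits within ±0.01–0.02 of κ; the residual excess comes from the
remaining length-measurement bias shrinking as filaments grow.

## Angular segmentation and persistence length

Traces are resampled at 100 nm so the 5° rule is independent of pixel
sampling. The default **cumulative** rule starts a new segment at the
first tangent deviating more than 5° from the tangent at the segment's
start; the alternative **successive** rule compares consecutive tangents
(it never cuts a slow drift — on an arc turning 1°/point it yields one
segment where the cumulative rule cuts every 6th tangent). The wording of
the underlying procedure supports either reading; cumulative is the
default because it is stable against sampling density. Segment lengths
are measured along the original polyline so they sum to L_C exactly.

Apparent persistence length: ⟨cos Δθ(s)⟩ is pooled over traces up to half
the mean contour length and fitted log-linearly to exp(−s/2L_p)
(2D convention). Non-decaying correlations (straight traces) are reported
at a 10³ μm cap with a flag. 100 synthetic chains at L_p = 2 μm are
recovered within 15%.

## AFM tube filter

Tubes have Gaussian cross-sections (peak 10 nm — the single-filament
height; σ = 12 nm, an AFM tip-broadened apparent width) rendered along
worm-like-chain centerlines crossing a 2 × 2 μm field (10 tubes/map,
4 nm/px, 0.5 nm pixel noise); overlaps stack additively (a "max" rule is
available), so entangled networks produce heights above 10 nm exactly
where filaments cross.

The ridge response is |λ₂|·σ² (the more-negative Hessian eigenvalue of
the Gaussian-smoothed map, zeroed when positive), maximized over scales
{5, 10, 15} nm. A plain-|λ₂| response was chosen over ratio-based
vesselness because only the Hessian construction itself is prescribed;
the threshold is Otsu on the nonzero response (fixed-quantile option
provided). The background is the median of unmasked pixels, subtracted
everywhere; masked heights pool into a 1 nm histogram with bins centered
on integer multiples so a nominal height lands mid-bin; the mode is the
center of the highest bin.

A caveat worth stating: because the generator fixes the tube height, the
noiseless height distribution has a hard ceiling at 10 nm, making the top
bin an edge bin; 0.5 nm pixel noise pushes part of its mass above
10.5 nm, and the pooled mode lands at 9 nm — one bin below the nominal
height, within the intended one-bin tolerance. Real filaments fluctuate
around their nominal height, so real distributions peak *at* it; this is
a property of the idealized generator, not of the filter.

## Orientation fields

Structure tensor from Gaussian-derivative gradients (σ = 1 px),
window-averaged (σ = 4 px); orientation is the eigenvector of the smaller
eigenvalue (along-ridge), coherence (λ₁−λ₂)/(λ₁+λ₂), foreground by Otsu.
Histograms sample a regular grid (every 8 px) with a coherence floor of
0.2 to exclude isotropic background; the alignment fraction counts
vectors within 30° of the stretch axis. Window size, grid and coherence
floor are package choices — the corresponding plugin settings in the
underlying workflow are not documented.

## FRAP

The Soumpasis uniform-disk solution is evaluated with exponentially
scaled Bessel functions (`i0e + i1e` of 2τ_D/t), stable from t → 0⁺
through t ≫ τ_D. Curves carry 250 frames at 54 ms; the default truth is
D = 1.4 μm²/s in a w = 2 μm spot (τ_D = w²/4D ≈ 0.71 s), mobile fraction
0.91, noise σ = 0.02. The fit is nonlinear least squares over
(τ_D, F₀, F_∞) with τ_D initialized at the half-recovery time; D and the
mobile fraction M = (F_∞−F₀)/(F_pre−F₀) follow. The bleach-spot radius is
required metadata — without it only τ_D is meaningful. Recovery at the
default conditions is within ±0.1 μm²/s (spread over seeds), comfortably
inside the experimental ±0.2 spread.

## Tilt correction

Sharpness is the squared response of the 4-neighbor Laplacian, smoothed
by a 9×9 boxcar and normalized per pixel along z (the named operator's
kernel and window are not specified upstream; these are package
defaults). An 8×8 grid aggregates sharpness per cell; the per-cell best z
(argmax with parabolic sub-slice refinement) feeds an ordinary
least-squares second-order polynomial in (x, y), and the stack is
linearly interpolated along z onto that surface. Planar and quadratic
synthetic tilts are recovered to well under half a slice RMS; correcting
a flat-focus stack returns its best slice unchanged.

The synthetic tilted stacks approximate spatially varying defocus by
blending copies of the base image blurred at σ levels quantized in
0.5 px steps — adequate for focus-surface recovery, not a physical
optics model.

## Degree of labeling

DOL = (A_dye/ε_dye) / ((A_280 − f·A_dye)/ε_280) with ε_280 = 24,240
L mol⁻¹ cm⁻¹, ε_dye = 1.5×10⁵ L mol⁻¹ cm⁻¹, f = 0.03, path length 1 cm.
This is the conventional maleimide-labeling formula for the listed
constants.

## Problem sizes and runtime

Default verification runs use 30 filaments × 11 steps on 900² px for the
slow series and 86 filaments on 1100² px for the fast one, 50 beads on
512² px, 19 AFM maps of 500² px, and 20 FRAP seeds; the whole acceptance
computation completes in well under a minute on a single core, the test
suite in about half a minute.

## What the synthetic tests do not show

The generator omits labeling heterogeneity along filaments, out-of-focus
light and 3D excursions, camera shot noise statistics (a Poisson option
exists but Gaussian is the default), correlated AFM line noise and tip
convolution, filament height variability, and membrane-flow-mediated
interactions between filaments. Passing recovery tests therefore
demonstrates the correctness and calibration of the measurement chain on
data matching the stated models — not robustness to every artifact of
real microscopy.
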