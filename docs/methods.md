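# Methods

This note documents the models, numerical choices and known limitations of
the package. Everything quantitative stated here is computed by the test
suite or the acceptance script; nothing is quoted from external data.

## Oximetry model

The measurement chain assumes two co-registered grayscale images of the
same fundus, one at 532 nm (near-isosbestic: hemoglobin absorption nearly
independent of oxygenation) and one at 633 nm (oxygen sensitive). For each
vessel segment in the 1–2 ONH-radius annulus:

1. Intensity profiles are sampled perpendicular to the smoothed centerline
   every 5 px (bilinear interpolation, odd sample count centered on the
   axis, half-width 34 px — it must exceed ~2.6× the widest expected FWHM
   so the flanking background windows fit inside the profile).
2. The vessel boundary is the FWHM of the dip: background is estimated
   from the outer quarter of samples on each side, and the two edges are
   linearly interpolated crossings of background − depth/2. Profiles whose
   dip is shallower than `min_dip_depth` (default 0.02 intensity units)
   are skipped.
3. Per wavelength, OD = mean over profiles of (mean intensity inside the
   FWHM)/(mean intensity in two flanking windows, each one vessel-width
   wide and one vessel-width away from the edge). This literal
   inside/outside ratio is the default (`od_mode="ratio"`); note it is
   *inverted* relative to conventional log optical density (an opaque
   vessel gives OD→0, a transparent one OD→1), so a `log` mode
   (log₁₀(outside/inside)) is provided. The calibration coefficients must
   match the configured mode.
4. SO₂ = a + b·ODR with ODR = OD₆₃₃/OD₅₃₂, clamped to [0, 100] %
   (clamping is logged, not an error — noise can overshoot). The linear
   coefficients are instrument-specific required configuration; the package
   defaults (a = 120 %, b = −50 %/ODR) place SO₂ ∈ [40, 100] % inside the
   forward model's renderable optical-density window.
5. O₂ content = O₂max · HgB · SO₂/100, with O₂max = 1.34 mL O₂/g
   (configurable) and HgB = HCT/3 g/dL (the standard clinical rule,
   configurable).

Segments with fewer than 3 usable profiles, or whose measured FWHM caliber
is below 25 µm, are excluded with a logged reason. Profiles whose
background windows touch another vessel's mask component are skipped.

## Tortuosity model

Measured on the 532 nm image (higher vessel/tissue contrast) in the 1.5–5
ONH-radius annulus; vessels below 25 µm are excluded so small, intrinsically
tortuous capillaries do not skew the result.

*Centerlines.* The vessel mask is skeletonized; the skeleton pixel graph is
pruned of short spurs (≤ 8 px twigs), split at branch points, and each
branch-free path becomes one chain. Chain points are re-centered to
sub-pixel precision on the photometric dip along the local normal
(parabolic refinement; skeletons are only pixel-accurate and can sit ~1 px
off-axis). The first/last 4 px of each chain are discarded because
skeleton end caps hook off-axis (curvature excursions up to ~0.02 px⁻¹
were measured there on straight-vessel renders, versus a mid-chain noise
floor of ~4×10⁻³ px⁻¹).

*Smoothing.* x(u), y(u) are fitted independently by penalized cubic
splines on the chord-length parameter normalized to [0, 1], with penalty
weight 3×10⁻⁵ on the integrated squared second derivative, then resampled
at 1 px arclength steps. Because both coordinates share one penalty, the
fit commutes exactly with rigid motions — the basis of the rigid-invariance
guarantee. On this normalization the penalty removes pixel-scale
quantization ripple while attenuating a 2-period, 10 px-amplitude
undulation by well under 1 %.

*Metrics.* All angle/derivative quantities are evaluated in the
chord-aligned frame: the formulation's "x-axis" is read as the segment's
own chord, the only interpretation consistent with rigid invariance (the
alternative SDθ reading — SD of consecutive tangent-angle differences — is
exposed as `sdtheta_mode="diffs"` without endorsement). SDθ uses an
arclength-weighted (trapezoid) variance so its value does not depend on the
resampling grid; N counts sign changes of dy/ds with a dead zone; VII
counts sign changes of the signed curvature κ, ignoring crossings within an
endpoint buffer, and a crossing requires an actual sign flip across any
sub-threshold gap (zeros touched without crossing never count — this is
what makes a straight segment yield exactly 0). M partitions the curve at
inflection points plus endpoints and averages sub-arc/sub-chord ratios;
with no inflections M = L_A/L_C. VTI = 0.1·SDθ·N·M·L_A/L_C is therefore
exactly 0 for straight segments (N = 0) and dimensionless, hence scale
invariant.

Two tiers of dead zones: the library functions default to κ_eps = 10⁻⁶
px⁻¹ and a 2-sample buffer (appropriate for analytic centerlines), while
the image pipeline's configuration uses κ_eps = 5×10⁻³ px⁻¹, dy/ds dead
zone 2×10⁻², and a 5-sample buffer — above the measured skeleton
quantization noise and an order of magnitude below the curvature of any
genuine undulation the generator produces (≥ 3×10⁻²).

## Statistics

Aggregation is the arithmetic mean per subject × eye × vessel type.
The outlier rule — mean ± 3 SD per diagnosis × vessel-type stratum, strata
under 5 rows skipped — is this package's construction (the band is
computed with the suspect row included, so it needs stratum sizes of ~20+
to have power; the default cohort gives 24 rows per stratum). Mixed models
are fit by REML via statsmodels MixedLM with Wald two-sided p-values
(significance at p ≤ 0.05); a singular REML fit falls back to ML and is
flagged. Entropy and MI use equal-width histograms with ⌈√n⌉ bins and log
base 2; MI of an exactly factorized joint table is 0 to rounding, and
MI(x, x) = H(x).

## Synthetic forward model

*Images.* A bright ONH disc (sigmoid edge, ~1.5 px soft) on a uniform
background of 0.55; vessels darken the local background multiplicatively
with an inverted-Gaussian cross-profile whose FWHM equals the nominal
diameter. The dip depth is (1 − OD)/0.8100, where 0.8100 is the mean of a
unit Gaussian over its FWHM interval, so the *mean* intensity inside the
FWHM equals background·OD — making both the caliber and the inside/outside
OD exactly recoverable in the noiseless limit (round-trip SO₂ errors on
noiseless renders are below 1 percentage point; the tested contract is
2 points, and 10 % on caliber). ODs outside [0.195, 0.98] are not
renderable and raise an error. Images are quantized to 16-bit on render so
in-memory arrays equal their TIFF round trip; identical seeds give
bit-identical images. Additive Gaussian noise is available (`noise_sd`)
but defaults to 0: the validation contracts are stated for noiseless
renders, and robustness to sensor noise is not a tested claim.

*Geometry.* Default frame 576×576 px at 8 µm/px with ONH radius 55 px —
chosen so 5 ONH radii fit the frame, the 25 µm caliber cutoff is ~3 px
(resolvable by the photometric width filter), and one eye analyzes in
~1.5 s. Cohort vessels are radial with a raised-cosine undulation confined
to the 1.8–4.6 ONH-radius band: the transverse displacement
(A/2)(1 − cos 2πmu) joins the straight tails with continuous tangent and
contributes exactly 2m interior curvature sign changes; pure sinusoid
specs (2k−1 sign changes) are used for fixtures. Undulation amplitudes
(~2.5 px) and period counts (m ≤ 6) keep the curvature radius well above
the vessel radius so the tube does not self-intersect.

*Cohort.* Two eyes per subject, 8 vessels per eye alternating artery/vein
(calibers ~60/80 µm), plus one 15 µm capillary to exercise the caliber
filter. Subject covariates are drawn from documented group distributions:
age 46 ± 4 vs 41 ± 15 y, MAP 93 ± 11 vs 82 ± 9 mmHg (controls vs SCR,
matching the demographic centers used as generator defaults), HCT 42 ± 3 vs
27 ± 3 % — the SCR anemia. Arterial SO₂ ~93 %, venous ~63 % in both
groups: the SCR oxygen-content deficit emerges physiologically from low
HCT rather than being painted onto SO₂ (an explicit SO₂ deficit knob
exists, default 0). Disease-linked undulation enters through a VII shift
(+2 inflections mean) and an O₂-vs-VII slope (−0.5 mL O₂/dL per
inflection) applied to per-vessel SO₂ targets.

*Table-level simulator.* `simulate_cohort_table` draws per-eye ×
vessel-type rows directly from the statistical model the mixed models
assume (type means 15/10 mL O₂/dL, subject random intercept sd 1.0,
residual sd 0.8, VII as the mean of four per-vessel counts). It exists to
validate inference at scale — CI coverage and false-positive rates over
many replicates — without the imaging cost. When validating slope
recovery, the unmediated group deficit is set to 0 so the imposed slope is
the only systematic O₂–VII pathway; a group deficit correlated with VII
would otherwise bias the slope estimate, which is a property of the design,
not of the estimator. What passing these simulations shows is that the
model recovers effects *under its own assumptions*; it does not certify
robustness to real-data violations (segmentation failure, mis-registration,
pigmentation texture).

## Known limitations

- Composite cohort vessels occasionally measure VII one or two counts above
  truth: the spline overshoots slightly where the straight tail meets the
  undulation band and the curvature dips past the dead zone. Pure-sinusoid
  renders are exact (tested for k = 1..4); per-eye VII averages preserve
  group contrasts.
- The skeleton of a rendered tube is biased inward at high curvature by
  roughly κσ²/2 even after photometric re-centering; fixtures keep
  curvature low enough that centerline error stays below 1 px.
- The renderer draws non-branching vessels on a textureless background and
  does not model eye motion, chromatic mis-registration, or the spectral
  differences of sickle hemoglobin; artery/vein identity comes from ground
  truth, not from image appearance.
- The literal inside/outside OD ratio and the calibration coefficients are
  configuration, not physics: real deployments must supply an instrument
  calibration, and forward and inverse must use the same `od_mode`.
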