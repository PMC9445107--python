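# Methods

## Scope and model

`phantomiq` studies one question: how the positron range of a PET
nuclide propagates into the standard NEMA NU 2 image-quality metrics and
into sphere-based spatial-resolution estimates. Everything happens in
image space. A physical acquisition chain (sinograms, attenuation,
scatter, randoms, OSEM/PSF/ToF reconstruction) is deliberately not
modelled: the analysis consumes reconstructed images, and the resolution
estimator assumes a Gaussian PSF, so the generator produces exactly the
class of images the analysis is defined on — a piecewise-constant
activity field convolved with a Gaussian, optionally edge-enhanced, with
Poisson count noise.

### Phantom geometry

The IEC body phantom is described parametrically: six spheres (default
diameters 10, 13, 17, 22, 28, 37 mm) centred on a 114.4-mm-diameter ring
in one transaxial plane (z = 0), a cold cylinder of 50 mm diameter along
the axis (the "lung" insert; its analysis VOI is 30 mm wide), and a
torso cross-section built from two half-discs joined by a rectangle
(300 × 230 mm envelope, 180 mm interior length). The published study
this package replicates prints neither the sphere positions nor the
glass wall thickness; the standard ring layout and a 1.0-mm wall are the
defaults, and both are configurable. Generator and fitter share the wall
default, which matters more than its absolute value.

Rasterization classifies supersampled subvoxel centres (default 4³ per
voxel near sphere shells, 4² in-plane for body and lung, exact interval
overlap axially), so edge voxels carry their exact partial-volume
average. The default grid reproduces a 440 × 440 matrix with
(1.65 × 1.65 × 1.5) mm³ voxels.

### Degradation

1. **Blur.** System PSF (default 4.4 mm FWHM) and the nuclide's
   positron-range kernel combine in quadrature. The range kernel is an
   isotropic Gaussian whose half-width at half maximum equals the mean
   positron range in water (σ = R_mean/√(2 ln 2)); the physical
   annihilation-point distribution is cusp-like, but a Gaussian composes
   analytically with the system PSF — which is what the resolution
   estimator assumes — and preserves the ordering Ga-68 ≫ Cu-64 > F-18.
   Because the kernel puts all its mass at the scale of the *mean*
   range, it overstates Ga-68's degradation relative to a cusp of equal
   mean range: simulated Ga-68 FWHM comes out near 7.8 mm where the
   physical scanner measured ≈ 5.4 mm. Comparisons across nuclides are
   therefore directional, not calibrated. The 4.4-mm system default was
   chosen so that F-18 (range 0.6 mm) lands at ≈ 4.55 mm total FWHM,
   the study's measured F-18 operating point at 4:1 contrast.

2. **Edge enhancement** (optional; on in `run_experiment` defaults,
   amount 0.7, scale 4 mm). An unsharp mask
   `image + a·(image − G_s(image))` mimicking the Gibbs overshoot of
   resolution-modelling reconstruction. The linear mask reproduces the
   qualitative signature reported for PSF reconstruction — the 10-mm
   sphere's RC_max overtakes the 37-mm sphere's — because a small
   sphere's entire bump lies in the passband the mask amplifies.
   Negative undershoot values are retained.

3. **Count noise.** Voxel intensities are scaled to expected counts with
   one global normalizer chosen so the image total equals the target
   trues (default 7.1×10⁷, the study's normal-weight operating point,
   times an obese factor, default 0.62, matching the reported ~36–38%
   true-count loss under cooling-pack attenuation), Poisson-sampled with
   a single seeded generator stream, and rescaled to kBq/mL. Noise is
   drawn after blurring, so background voxels are independent and the
   per-voxel CoV prediction 1/√(mean counts) is exact rather than
   approximate.

### Voxel-aperture correction

Partial-volume rasterization is a convolution with the voxel box, which
adds h²/12 of variance per axis. `blur_image` therefore subtracts this
variance from the Gaussian's per-axis σ² (option
`voxel_aperture_correction`, default on), so the *total* image-domain
PSF — Gaussian ∘ box — carries the nominal FWHM. Without the correction
fitted FWHMs read ~3% wide. The option is switched off for the second
stage of sequential-blur composition tests, where the aperture is
already accounted for.

## Metric suite

* Segmentation: threshold T = B + 0.5·(S_max − B) with S_max searched in
  a ball of sphere radius + 5 mm (the margin avoids locking onto a
  neighbour); mask is the 26-connected suprathreshold component at the
  sphere, ties (≥ T) included. The published study cites an isocontour
  method without printing the formula; this background-corrected 50%
  contour is the standard reading, and plain 50%-of-max is available for
  sensitivity checks. A flat neighbourhood raises a segmentation error.
* RCs are computed on kBq/mL directly (in a phantom, SUV is the
  measured/true concentration ratio; no body-weight normalisation).
  RC_peak averages a 12-mm ball centred on the hottest voxel,
  intersected with the isocontour mask.
* Background VOIs: three cylinders, 20 mm radius × 50 mm height
  (62.8 mL ≥ the required 61 mL), axes parallel to the phantom axis at
  70 mm from centre and 120° apart, shifted 60 mm axially from the
  sphere plane. This placement keeps ≥ 15 mm clearance from sphere
  walls, lung insert and body outline and is purely deterministic; the
  study's supplementary figure is not machine-readable, so placement is
  by convention, checked geometrically at call time. CoV_BG is the mean
  of the per-VOI coefficients of variation; CNR uses the pooled SD over
  the three VOIs.
* Lung error: mean over a 30-mm-diameter cylinder spanning the sphere
  plane ± 30 mm, relative to the background mean. Without scatter,
  randoms or the single-photon contamination of Ga-68 decay — none of
  which are modelled — this reads near zero at clinical PSF widths and
  grows with blur; the study's measured 4–13% reflects physics outside
  this package's scope.

## Resolution estimator

Voxels within r_max = R + w + 4σ₀ + 2 mm of the (centroid-refined)
centre are binned into 0.5-mm radial shells; each bin contributes its
mean value at its members' mean radius, weighted by its voxel count
(central bins hold few voxels). Using the member-mean radius instead of
the geometric bin centre removes the first-order binning bias on curved
profiles, which otherwise pushes recovery errors past 1% for some
sphere/lattice alignments. (S, B, FWHM) are fitted by trust-region
least squares with R and w fixed, FWHM bounded in [1, 12] mm,
initialised from the profile itself (S: maximum, B: outer bins,
FWHM: 4 mm). A fit is flagged unconverged — never silently returned —
when the optimiser fails, the FWHM lands at a bound, the profile has no
dynamic range (no sphere), or the fitted signal does not exceed the
background. Aggregation over spheres reports mean and sample SD (n − 1)
of converged fits and requires at least two.

Measured performance under the defaults: noiseless recovery error
< 0.2% per sphere; across FWHM ∈ {3.5, 4.5, 5.5} mm and diameters
{10, 37} mm, < 1%; with Poisson noise at 7×10⁷ trues the per-sphere
bias over 20 seeds stays below 1.6%.

## Acquisition matching

Expected trues are integrated continuously over the scan,
N(T) = yield·A₀·(1 − e^(−λT))/λ, rather than midpoint-corrected, because
matching Cu-64 (17.4% yield, 12.7 h half-life) against F-18 requires
~5× longer scans over which midpoint correction biases the total. The
matched duration has a closed form and is the exact inverse of the
integral; an unreachable target (more trues than full decay can deliver)
raises an explicit error. Yields are stored as fractions; Ga-68's minor
1.1% β⁺ branch is not included.

## Rounding and comparison arithmetic

All printed-style rounding is half-away-from-zero. Headline
aggregations ("up to X% worse") are computed on the two-decimal FWHM
means as printed in the packaged tables, matching how the published
percentages were formed. The published results text attaches 36.1% to
the low-contrast Ga-68 rows while the table arithmetic attaches it to
the 9.4:1 rows, and prints 38.4% where the tabulated counts give 38.3%;
the package computes both decreases from the tabulated counts and
reports their min and max without asserting either label.

## Problem sizes

The test suite runs every image-based check on a cropped 120×120×120
grid at the production voxel size — the sphere ring, lung insert and
all VOIs are interior to it, so no metric geometry changes — and the
acceptance script runs the full 440×440×120 matrix. Monte-Carlo checks
use 20 seeds (FWHM bias) and 100 seeds (noise unbiasedness) on small
uniform grids.

## What passing tests do and do not show

The generator reproduces the *mechanism* under study — quadrature
composition of positron range with the system PSF, partial-volume
recovery loss, Poisson count statistics at matched trues — and the
analysis reproduces the published headline arithmetic exactly. It does
not reproduce scanner-calibrated absolute values: background CoV is
raw-Poisson (higher than reconstructed-image noise at equal trues),
lung error lacks scatter physics, Ga-68's Gaussian range kernel
overstates its blur, and the obese setup is a pure count-reduction
(the study attributes obese-setup resolution loss to reconstruction
behaviour, which is out of scope). Cross-nuclide assertions on
simulated data are therefore directional only.
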