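# Methods

`maculaflow` quantifies two linked readouts of early macular degeneration
from swept-source OCT/OCTA of the central macula: photoreceptor integrity,
via the normalized reflectivity of the en-face ellipsoid-zone (EZ) image,
and choriocapillaris (CC) perfusion, via compensated, locally thresholded
flow-deficit metrics. Both are measured in a 5 mm fovea-centered circle and
separately in the drusen-free part of that circle, because drusen distort
the EZ slab and shadow the CC signal. Since no public datasets carry the
required volume + en-face pairs with ground truth, the package ships a
synthetic phantom generator that plants known truth for every stage, and
the validation suite is built entirely on recovery from those phantoms.

## Geometry and conventions

Arrays are row-major, origin top-left, pixel/voxel centers at integer
coordinates. Volumes are (depth, rows, cols) with depth running vitreous to
choroid; axial positions are micrometres from the top of the volume. All
physical quantities cross API boundaries in um or mm, never pixels. The
native lateral grid is 500 x 500 over a 6 x 6 mm field (12 um/px); the
analysis circle has a 5.0 mm diameter and a pixel belongs to it iff its
center lies within the radius. Scans are analyzed at their native grid; no
resampling to 1024 x 1024 is performed (whether the device's published
binarization calibration implies such resampling is not documented; the
window radius is therefore kept in pixels and configurable).

## RPE surface and Bruch's-membrane floor

`segment_rpe` is a phantom-grade stand-in for the device's multilayer
segmentation. Each A-scan profile is Gaussian-smoothed along depth
(default 10 um) and lightly across neighboring A-scans (1 px), and the
surface is the *deepest* local maximum within 80% of the profile peak —
the EZ band is bright but always lies above the RPE, so taking the deepest
strong peak removes the dominant failure mode of a plain argmax. The peak
is refined to sub-voxel precision with a three-point parabola and the
surface is median-filtered (5 x 5). A-scans without intensity variation are
flagged; more than 5% flagged rejects the scan.

The Bruch's-membrane proxy (`fit_rpe_floor`) fits a total-degree-2
polynomial to the RPE surface and iteratively discards points elevated
more than 10 um above the fit (drusen are upward outliers), re-fitting to
convergence (max 10 iterations). If over 60% of the surface is discarded
the fit is declared unreliable rather than returned. Degree 2 is enough
for the tilt/curvature of a 6 mm macular scan and keeps the fit testably
simple.

## Drusen segmentation

Elevation = max(0, floor_z − RPE_z), rendered on an 8-bit [0, 100] um scale
(heights above 100 um saturate, matching the elevation heat-map
convention). The rendering inside the ROI is binarized with the Kapur
maximum-entropy threshold: the gray level maximizing the summed Shannon
entropies of the two class histograms over 256 bins, ties to the lowest
level, zero-count bins contributing zero. The grayscale quantization of
elevation replaces the colormapped heat-map image of the original
procedure; the algorithm is unchanged.

Two plausibility guards follow the binarization. Detected components must
exceed the conventional 63 um small-druse equivalent diameter and must
contain a pixel at least 15 um high. The source procedure had two graders
visually accept the binarization; without a guard, a maximum-entropy split
of a drusen-free (noise-only) elevation map fabricates a drusen region in
every healthy eye. Drusen area/volume use a separate, configurable height
criterion (default 20 um — the device's internal "considerably elevated"
definition is proprietary, so this is an explicit stand-in).

## EZ normalized reflectivity

The EZ en-face image is the mean intensity in a 21 um slab whose inner
boundary lies 45 um above the RPE, following its contour. Reflectivity is
normalized per eye with the two-point linear rescaling

    norm = (mu_EZ − mu_vitreous) / (mu_RNFL − mu_vitreous)

using the vitreous as dark and the RNFL as bright reference — the
canonical reading of a dark/bright-reference normalization; values are not
clipped to [0, 1]. The normalization makes the readout exactly invariant
to global affine intensity changes of the scan, which is its purpose:
absolute OCT brightness depends on uncontrollable acquisition factors.
Reference regions are sampled globally (not per B-scan) from configurable
bands: the top of the volume for vitreous, a band below the inner surface
(superior quarter of the field in the phantom) for RNFL. Major retinal
vessels are excluded from all regional means via a user- or truth-supplied
mask; no vessel segmentation is implemented. Beam-directionality effects
on EZ reflectivity are not modeled.

## CC flow deficits

The CC slab (20 um thick, 29 um under the RPE-fit floor) is projected by
mean intensity when starting from a volume; phantom CC pairs are en-face
already and skip this step. Shadow compensation multiplies the flow image
by S_ref / max(S_smooth, 0.1 * S_ref), where S_smooth is the Gaussian-
smoothed (3 px) structure image and S_ref its ROI median; gain is capped at
10x and output clipped to the input range. Binarization is the Phansalkar
local threshold on [0, 1] intensities over a circular window of radius
3 px:

    T = m * (1 + 2 e^(−10 m) + 0.25 (s / 0.5 − 1))

with m, s the in-window mean and SD; a pixel is a deficit iff value <= T.
Only the window radius is documented for this application; the remaining
constants are the method's published defaults. Border windows are
truncated, never padded. Isolated deficits with equivalent diameter
strictly below 24 um are removed as presumed noise. FD%, deficit count and
mean deficit size (um^2) are computed within each analysis region;
components are labeled on the full raster but measured by in-mask area,
which makes whole-ROI FD% exactly the area-weighted mean of the regional
values. Vessel pixels are excluded from the analyzed area (not counted as
deficit). Integer images are normalized by their dtype maximum; float
images already in [0, 1] are used as-is; float images outside [0, 1] are
min-max rescaled (a constant such image is rejected as degenerate).

## Statistics

Group comparisons run Shapiro-Wilk on both samples; if either rejects at
alpha = 0.05 a two-sided Mann-Whitney U is reported, otherwise an
independent-samples t-test, and the chosen test is recorded. Associations
of EZ reflectivity with CC and drusen metrics use Spearman rank
correlation (midranks for ties). No multiple-testing correction is
applied, matching the analysis plan this package reproduces. Power for the
two-sided two-sample t-test uses the noncentral t distribution; at n = 35
per group the 80%-power effect size is d ~= 0.68, cross-checked against a
200k-replicate simulation.

## The phantom

The generator emulates the statistical structure the analysis assumes, not
device physics (no wave optics, polarization or motion artifacts).

**Volume.** A layer stack (vitreous 4, RNFL 180, inner 80, EZ 200, RPE 240,
choroid 55, on an arbitrary 8-bit-like scale; thicknesses 120/40/160/32/25
um with a 24 um outer-segment gap at 30) over a tilted-plane Bruch floor.
The RPE band is symmetric about the planted surface, so the band's
reflectivity peak is the RPE reference. Voxelization is anti-aliased: each
voxel integrates the stack over its axial extent, so boundary voxels carry
partial-volume mixtures and sub-voxel surface positions are encoded in the
data, as a finite axial PSF would. The EZ band covers the analysis slab
with margins on both sides so segmentation error up to one voxel cannot
push the slab out of the band. Speckle is multiplicative unit-mean gamma
noise, shape 10 by default (the device-exported structural product is a
processed multi-frame composite, not raw speckle; at raw-speckle noise
levels the planted RPE band is not reliably the brightest structure, which
no acceptable-quality commercial scan exhibits), and `None`/`inf` disables
it for noiseless tests.

**Drusen.** Plateau-cored domes with a raised-cosine taper over the outer
10% of the radius, peaks capped at 150 um, overlaps combined by maximum so
every planted peak is exact. A pure raised-cosine dome was rejected: its
detected footprint varies strongly with the threshold-to-peak ratio, so
with peaks spanning 30-100 um no single global threshold footprint is
well-defined, and a footprint-recovery test would measure the dome shape
rather than the detector. The truth mask is the half-peak footprint.
Drusen centers are stored in um so one drusen set renders consistently on
the volume grid and the finer CC grid.

**CC pair.** Bright flow background (210) with planted dark blobs
(contrast 0.12) — random disks with diameters 0.8-1.8x the 36 um blob
scale, wholly inside the grid, painted until the target area fraction is
reached; the recorded fraction, not the target, is the oracle. Both flow
and structure are multiplied by the shadow factor under the drusen
footprint, carry gamma speckle (shape 40 — en-face OCTA products are
averaged composites), an additive unshadowed noise floor (12), and a 6 um
PSF blur (14 um FWHM lateral resolution). The structure raster carries the
shadow but not the deficits, which makes the compensation identity exactly
recoverable.

**Cohort.** Two arms of per-eye phantoms. Per-eye EZ targets and deficit
fractions are drawn from the arm's distributions — defaults mirror the
reported cohort: EZ 0.76 +/- 0.10 vs 0.85 +/- 0.08, deficit fraction
0.241 +/- 0.053 vs 0.192 +/- 0.062, 4-10 drusen per AMD eye with a 0.6
shadow and a 0.9 extra EZ attenuation under drusen. The EZ target is
planted by inverting the normalization against the configured layer means.
The AMD arm's rank coupling between EZ attenuation and deficit fraction
(default rho = −0.4) is imposed on the sample by construction: normal
scores are correlated exactly at the Gaussian-copula level
r = 2 sin(pi rho / 6) (Iman-Conover style) and the permutation is refined
by greedy pair swaps until the realized Spearman rho is within 0.02 of the
target. A stochastic copula at n = 35 has sampling SD ~0.16, which would
make any recovery band a property of the draw rather than of the pipeline.
Cohort eyes use down-scaled problem sizes — 120 x 120 volumes at 50 um
pitch and 400 x 400 CC rasters at 15 um — chosen so a 70-eye cohort runs
in ~20 s while every stage still operates far above its resolution limits.

## What the phantom does and does not show

Passing recovery tests shows the pipeline correctly measures what the
phantom plants: surfaces, elevations, attenuation fields, deficit
fractions and their couplings, under speckle, shadowing and blur. The
phantom does not reproduce real outer-retinal texture, drusen
substructure, projection artifacts beyond a mask, motion, or the true
deficit-size distribution of the choriocapillaris (planted blobs merge
into larger clusters than real inter-capillary spacings, so absolute mean
deficit sizes are phantom-specific). Agreement with planted truth is
therefore evidence of algorithmic correctness, not of clinical accuracy on
patient scans.

## Numerical choices

Kapur threshold: 256 bins, 0 log 0 = 0, ties to the lowest level.
Phansalkar: deficits are `<= T` (flow is the bright phase); border windows
truncated. Small-deficit removal: strict `<` at 24 um, 8-connectivity.
Floor fit: normalized [-1, 1] coordinates, least squares via `lstsq`.
Elevation: clamped at 0 (an RPE fitted below the floor is not a negative
druse). Compensation: floor fraction 0.1 of the ROI median caps gain at
10x. Empty regions propagate as NaN with a warning rather than as errors
wherever a healthy eye can legitimately produce them (no drusen region,
vessel-covered region). Determinism: every stochastic step draws from
`numpy` Generators seeded from the configuration; identical configs give
bit-identical phantoms.

## Validation problem sizes

The validation suite (`maculaflow.validation`, exercised by the test suite
and `scripts/acceptance.py`) uses: FD recovery at planted fractions
10/20/30% on native 500 x 500 rasters, 10 seeds; drusen-mask Dice on
native-scale volumes with 5-15 random domes, 10 seeds; compensation
efficacy with a 0.5 shadow, 10 seeds; cohort recovery with 35 + 35 eyes,
20 seeds; type-I calibration with 2000 null simulations and a 200k-rep
power oracle. These sizes keep a full run in the ten-minute range on one
CPU while leaving every acceptance margin comfortably measurable.
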