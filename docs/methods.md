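# Methods

`opmflow` simulates and analyses high-throughput 3D imaging flow cytometry in
which the sample's own flow provides the scan axis: cells translate through a
stationary oblique light sheet, the camera records a diagonal stack of tilted
optical sections, and a shear transform (deskew) turns the stack into a
Cartesian volume.  This note records the models, the parameters that matter,
the numerical choices, and what the synthetic data do and do not establish.

## Coordinates and channel flow

Lab frame in micrometres: `x` across the channel width (camera columns), `y`
the flow axis (cells move toward −y), `z` the channel height.  The channel is
a wide, shallow rectangle (default 200 μm × 2 mm).  Away from the side walls
the velocity field is plane Poiseuille,

    u(z) = 6 ū (z/h)(1 − z/h),      ū = Q/(w·h),

so at the default Q = 10 μL min⁻¹ the mid-height maximum is
u(h/2) = 1.5 ū = 625 μm s⁻¹.  Cells are only placed at least one channel
height away from each side wall, where the 1D parabola is accurate: the
Fourier-series solution for a 10:1 rectangular duct gives a centreline
velocity that matches the parallel-plate value to a few parts in 10⁷ at equal
pressure gradient (`duct_center_to_plane_ratio`).  At equal *flow rate* the
side-wall flux deficit instead raises the true duct centreline to 1.601 ū;
the simulator deliberately uses the parallel-plate profile, which is the
model the narrow imaged core of the channel sees.  The only velocity gradient
a cell samples is vertical, so its speed is a function of its height alone;
the shear tumbling rate is ω(z) = ½|du/dz| = 3 ū |1 − 2z/h| / h.

## Acoustic focusing

Focusing is modelled at its steady-state endpoint, not as force dynamics (no
acoustic energy density is available to calibrate a relaxation time):

* transducer on — `z ~ Normal(node, residual_sigma_z)` truncated to the
  channel interior, with the node at mid-height (half-wave resonance) and a
  2 μm default residual spread; spin is zero (focused cells do not rotate);
* transducer off — cells sediment into an exponential boundary layer,
  `z = r + Exp(15 μm)` truncated to the interior, and tumble at the local
  shear rate.

Both samplers use inverse-CDF draws so the random-stream consumption is
fixed and runs are exactly reproducible.  With these defaults the kinematic
speed CV is ≈ 5×10⁻⁴ focused (measurement noise dominates any tracked CV)
and ≈ 0.6 unfocused, reproducing the direction and separation of the
measured focused/unfocused contrast (0.09 vs 0.74).

## Scene generation

`sample_population` draws cell diameters from a normal distribution
(default 10 ± 1 μm), positions uniformly in the allowed interior with a
minimum *lateral* centre separation of 0.8 diameters (lateral, because
focusing later collapses `z` and only the in-plane spacing protects the
watershed), phases from one multinomial draw (default 96% interphase, 4%
mitotic split by phase duration), and orientations uniformly on the rotation
group.  An odd telophase count is decremented by one so telophase cells
always form mutual partner pairs, placed 1.2 diameters apart along a random
direction that keeps both partners inside the channel.

Nuclear geometry per phase (DNA channel), in units of the nuclear radius
r_n = 0.6 R_cell: interphase — uniform sphere r_n; prophase and each
telophase partner — condensed sphere 0.8 r_n at conserved photon budget;
metaphase — oblate plate with c/a = 0.35 oriented by the cell quaternion;
anaphase — two equal oblate masses (half budget each) at ±r_n along the
spindle axis.  The cytoplasmic stain fills the whole cell; the mitotic
marker is spatially uniform with a strongly bimodal budget (150 photons
nonspecific vs 6000 mitotic), giving a clean gating gap.  These shape
constants are package choices exposed in the cell's `nucleus_params`; only
their ratios enter any downstream statistic.

## Oblique acquisition

Pixel (row r, col c) of the tilted sheet (default θ = 67° from the lateral
plane) sits at `x = x₀ + c·px_x`, `z = z₀ + r·row_dz`, `y = −r·row_dy` with
`row_dy = row_dz/tan θ`.  The expected photon count is the emission density
integrated along the sheet normal under a peak-normalised Gaussian of FWHM
`sheet_fwhm` (Gauss–Hermite quadrature, 11 nodes), times the in-plane pixel
area `px_x · row_dz/sin θ`; frames are blurred by the lateral PSF, scaled by
gain, offset, and given Poisson shot noise plus Gaussian read noise (the
standard sCMOS model).  Default pitches are calibration-consistent with the
instrument modelled: px_x = 724/2560 = 0.283 μm, row_dz = 38/128 = 0.297 μm
(refractive axial scaling folded into the calibration), 720 frames s⁻¹.
θ itself is not a measured value; 67° makes a 600-frame acquisition at
0.5 mm s⁻¹ reproduce the known reconstructed extents (433 μm scan + shear in
y, 38 μm in z).  Photon bookkeeping: one complete transit deposits
`gain × budget × σ_sheet √(2π) f/(v sin θ)` counts above background,
independent of speed, which the tests assert to 5%.

Lateral widefield movies (velocimetry input) render each cell's z-projected
column density at 44 fps with the same camera model.

## Deskew

Sample (n, r, c) maps to `y = n·frame_dy − r·row_dy` with `frame_dy = v/f`.
Because frame index and row shear both advance toward −y, the reconstruction
reads in +y with no extra flip.  Per z-slice the map is a constant fractional
shift along the frame axis, evaluated by gather (inverse-map) interpolation —
linear by default (a partition of unity, so interior intensity is conserved
exactly), nearest-neighbour for integer-shift tests.  Output voxels are the
native anisotropic (px_x, frame_dy, row_dz); an `isotropize` resampler exists
for display only, and all morphometry uses physical voxel sizes, which makes
the choice immaterial.  The reconstruction velocity comes from stack metadata
or from tracking; a >5% mismatch triggers a warning because it shears cells.

## Segmentation and count validation

Gaussian smooth (1 μm) → Otsu (or fixed) threshold → Euclidean distance
transform with physical voxel sampling → seeds at distance maxima with a
minimum physical separation (default 8 μm ≈ 0.8 median diameters, enforced
by a separable maximum filter plus greedy suppression) → watershed on the
inverted distance transform restricted to the mask → minimum-volume filter.
Records carry lab-frame centroids, volumes, per-channel background-subtracted
integrated intensities (background = volume median, valid because cells are
sparse), and a `clipped` flag for bboxes within 2 voxels of the y/z
boundaries or touching unmasked (never-acquired) voxels.

Count validation follows the area-sum/area-median rule: for similar-sized
cells Σ(volumes)/median(volume) equals the label count; an unsplit doublet
raises the ratio by one.  A relative discrepancy ≥ 10% is flagged.
Detection throughput is count/duration.

## Velocimetry

Detection: Gaussian-difference band-pass, local maxima above an amplitude
and an integrated-mass threshold, subpixel refinement by intensity-weighted
centroid.  Linking: per-frame globally optimal assignment (Hungarian
algorithm on squared displacement, birth/death padded at the gate cost) with
a hard search radius and gap-closing memory; gap-closed candidates compete
on per-frame displacement.  Speeds are |Δposition| between consecutive
linked detections times the frame rate (n − 1 speeds per track of n
detections); statistics are pooled over all steps with population SD, and
the histogram uses 25 μm s⁻¹ bins over 0–1000 μm s⁻¹.

## Mitotic morphometry and phase calls

Marker-positive cells are gated by integrated marker intensity (threshold or
polygon in log-log marker/DNA space).  DNA regions inside a cell are the
26-connected components of the background-subtracted DNA intensity above
half its in-cell maximum, with a 2 μm³ minimum.  Principal axes come from
the intensity-weighted covariance of voxel coordinates in physical μm;
axis lengths use L = 4√λ (any constant cancels in every reported ratio; a
uniform ellipsoid would need 2√5 ≈ 4.47 for absolute lengths).  The 3D
aspect ratio is L₃/((L₁+L₂)/2); the 2D one is the shorter/longer axis of
the xy-projected 2D PCA — the quantity a lateral-only (2D) imaging flow
cytometer would measure.  Binary-mask (unweighted) PCA is available; on
phantoms the two modes agree within a few per cent.

Decision tree on positives: clipped → omitted; two DNA regions → anaphase;
two single-region positives that are mutual nearest positives within 1.5
median diameters → telophase pair; otherwise metaphase if ar3d ≤ 0.6 else
prophase.  τ = 0.6 sits midway between the archetype ratios (≈1 prophase,
0.35 metaphase) and is a config knob, as is the pair distance.

The projection inequality ar2d ≥ ar3d is exact for continuum oblate
spheroids (Cauchy interlacing of the projected covariance plus λ₁ ≥ λ₂);
for voxelized phantoms it holds up to discretization error of order 10⁻⁴
near orientations where the symmetry axis lies almost in the projection
plane, so the test asserts the per-phantom margin above −10⁻⁴ (the mean
margin is ≈ 0.26).  Phantoms use first-order antialiased occupancy weights
to suppress grid anisotropy.

## Study sizes and estimators used in the shipped experiments

The `opmflow.experiments` module fixes the scenario sizes the tests and the
acceptance script run, chosen as single-CPU-scale versions of the study
conditions:

* PZT contrast: 250 cells, 100 movie frames at 44 fps over a 400 μm window.
* Round trip: one 8 μm sphere per speed (250/500/750 μm s⁻¹) through a
  64 × 128-pixel ROI with shot + read noise at peak SNR ≥ 10.  Sphere
  volume is estimated from the half-maximum isosurface of a lightly
  smoothed reconstruction with the first-order curvature correction
  R → R + σ_sheet²/R (the isosurface of a blurred ball sits inward by
  σ²/R); this removes a ≈7% systematic bias and leaves ≈1% error.
* Extent check: 600 frames × 128 rows at default calibration (64 columns —
  the x extent is n_cols·px_x by construction).
* Segmentation: ≈500 focused cells imaged at ≈1 μm pitches through a
  40-row ROI centred on the node, scored by one-to-one centroid matching
  within 5 μm.
* Phase recovery: 200 mitotic cells voxelized as per-cell phantoms at
  0.4 μm with Poisson noise at an integration level giving peak-voxel
  SNR ≥ 10, then segmented, gated, region-counted and classified; isolated
  noise-free archetype phantoms check the decision tree itself.

## What the synthetic data do not show

Cells are smooth uniform-density geometric bodies: no chromatin texture, no
cell-to-cell biological variability beyond size/phase/budget scatter, no
optical aberrations, field-dependent PSF, camera fixed-pattern noise, or
rolling-shutter skew, and no acoustic streaming, inertial focusing or
cell–cell hydrodynamics.  Passing tests therefore validate the geometry,
photometry bookkeeping, reconstruction, and the analysis operators — not
instrument-level image quality on real specimens.  Real-data anomalies the
count validator is designed to catch (clumping, debris) are only emulated
indirectly through overlapping-cell phantoms.  The adjacency rule for
telophase is intrinsically fallible at high positive density: two unrelated
adjacent mitotic cells are indistinguishable from a true pair, which bounds
cohort accuracy slightly below 1 even without noise (≈0.98–0.99 at the
cohort's density).
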